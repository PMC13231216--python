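"""Diffusion acquisition schemes: gradient waveforms, timing and b-values.

The package works internally in (µm, ms, µm²/ms, mT/m).  b-values are
exposed in the conventional s/mm² and converted once at the boundary
(1 s/mm² = 1e-3 ms/µm²).  Two effective waveforms are supported:

* PGSE  — two rectangular lobes of duration ``delta`` separated by ``Delta``
  (leading-edge to leading-edge).
* cosine OGSE — two lobes of ``n_periods`` full cosine cycles at
  ``frequency`` Hz, so ``delta = n_periods / frequency``.

Exactly one of {gradient amplitude, b-value} is free; the other is derived
from the closed-form b-value of the waveform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

# Proton gyromagnetic ratio in rad / (ms * mT/m * µm):
# 2.675e8 rad/s/T * 1e-9 T/µm per mT/m * 1e-3 s/ms
GAMMA = 2.675e-4

#: 1 s/mm² expressed in ms/µm²
B_SI_TO_INTERNAL = 1.0e-3

PGSE = "pgse"
OGSE_COS = "ogse_cos"


class SchemeError(ValueError):
    """Invalid waveform timing or scheme composition."""


@dataclass(frozen=True)
class GradientWaveformSpec:
    """One diffusion measurement: waveform kind, timing and weighting.

    Parameters
    ----------
    kind : {"pgse", "ogse_cos"}
    delta : float
        Gradient-lobe duration in ms.
    Delta : float, optional
        Lobe separation in ms.  Required for PGSE; for OGSE it defaults to
        contiguous lobes (``Delta = delta``).
    frequency : float, optional
        Oscillation frequency in Hz (OGSE only).
    n_periods : int, optional
        Full cosine periods per lobe (OGSE only); must satisfy
        ``frequency = 1000 * n_periods / delta`` with delta in ms.
    b_value : float, optional
        Diffusion weighting in s/mm².  Give either this or ``amplitude``.
    amplitude : float, optional
        Gradient strength in mT/m.
    """

    kind: str
    delta: float
    Delta: float | None = None
    frequency: float | None = None
    n_periods: int | None = None
    b_value: float | None = None
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (PGSE, OGSE_COS):
            raise SchemeError(f"unknown waveform kind {self.kind!r}")
        if self.delta <= 0:
            raise SchemeError("delta must be positive")
        if (self.b_value is None) == (self.amplitude is None):
            raise SchemeError("exactly one of b_value and amplitude must be given")
        if self.b_value is not None and self.b_value < 0:
            raise SchemeError("b_value must be non-negative")
        if self.amplitude is not None and self.amplitude < 0:
            raise SchemeError("amplitude must be non-negative")
        if self.kind == PGSE:
            if self.Delta is None:
                raise SchemeError("PGSE requires Delta")
            if self.delta > self.Delta:
                raise SchemeError(
                    f"non-physical PGSE timing: delta={self.delta} > Delta={self.Delta}"
                )
        else:
            if self.frequency is None or self.frequency <= 0:
                raise SchemeError("OGSE requires a positive frequency")
            n = self.frequency * self.delta / 1000.0
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise SchemeError(
                    "OGSE lobe must contain a positive integer number of periods "
                    f"(frequency*delta = {n:.6g})"
                )
            if self.n_periods is not None and self.n_periods != round(n):
                raise SchemeError("n_periods inconsistent with frequency and delta")
            object.__setattr__(self, "n_periods", int(round(n)))
            if self.Delta is None:
                object.__setattr__(self, "Delta", self.delta)
            elif self.Delta < self.delta:
                raise SchemeError("OGSE lobe separation shorter than the lobe itself")

    # -- closed-form b-value -------------------------------------------------

    @property
    def omega(self) -> float:
        """Angular frequency in rad/ms (OGSE only)."""
        if self.frequency is None:
            raise SchemeError("omega undefined for PGSE")
        return 2.0 * math.pi * self.frequency * 1.0e-3

    def _b_per_unit_amplitude(self) -> float:
        """b (ms/µm²) produced by unit gradient amplitude (1 mT/m)."""
        if self.kind == PGSE:
            return GAMMA**2 * self.delta**2 * (self.Delta - self.delta / 3.0)
        return GAMMA**2 * self.delta / self.omega**2

    def b_internal(self) -> float:
        """b-value in ms/µm²."""
        if self.b_value is not None:
            return self.b_value * B_SI_TO_INTERNAL
        return self.amplitude**2 * self._b_per_unit_amplitude()

    def b_si(self) -> float:
        """b-value in s/mm²."""
        return self.b_internal() / B_SI_TO_INTERNAL

    def gradient_amplitude(self) -> float:
        """Gradient strength in mT/m (derived from b when b was given)."""
        if self.amplitude is not None:
            return self.amplitude
        return math.sqrt(self.b_internal() / self._b_per_unit_amplitude())

    # -- bookkeeping ----------------------------------------------------------

    @property
    def sequence_key(self) -> tuple:
        """Groups measurements that share one ADC fit (kind + frequency + timing)."""
        if self.kind == PGSE:
            return (PGSE, self.delta, self.Delta)
        return (OGSE_COS, self.frequency, self.delta, self.Delta)

    @property
    def label(self) -> str:
        if self.kind == PGSE:
            return "pgse"
        return f"ogse_{self.frequency:g}Hz"

    def with_b(self, b_si: float) -> "GradientWaveformSpec":
        return GradientWaveformSpec(
            kind=self.kind,
            delta=self.delta,
            Delta=self.Delta,
            frequency=self.frequency,
            b_value=b_si,
        )

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "delta": self.delta, "b_value": self.b_si()}
        if self.kind == PGSE:
            d["Delta"] = self.Delta
        else:
            d["frequency"] = self.frequency
            d["n_periods"] = self.n_periods
            if self.Delta != self.delta:
                d["Delta"] = self.Delta
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GradientWaveformSpec":
        return cls(
            kind=d["kind"],
            delta=float(d["delta"]),
            Delta=float(d["Delta"]) if "Delta" in d else None,
            frequency=float(d["frequency"]) if "frequency" in d else None,
            b_value=float(d["b_value"]) if "b_value" in d else None,
            amplitude=float(d["amplitude"]) if "amplitude" in d else None,
        )


@dataclass
class AcquisitionScheme:
    """Ordered list of diffusion measurements.

    Each distinct sequence (PGSE, each OGSE frequency) must contain a b=0
    entry for normalization and at least two distinct b-values so that a
    monoexponential ADC is identifiable.
    """

    measurements: list[GradientWaveformSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.measurements:
            raise SchemeError("scheme has no measurements")
        for key in self.sequence_keys():
            bs = sorted({m.b_si() for m in self.for_sequence(key)})
            if bs[0] > 1e-12:
                raise SchemeError(f"sequence {key} lacks a b=0 measurement")
            if len(bs) < 2:
                raise SchemeError(f"sequence {key} needs >= 2 distinct b-values")

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def sequence_keys(self) -> list[tuple]:
        seen: list[tuple] = []
        for m in self.measurements:
            if m.sequence_key not in seen:
                seen.append(m.sequence_key)
        return seen

    def for_sequence(self, key: tuple) -> list[GradientWaveformSpec]:
        return [m for m in self.measurements if m.sequence_key == key]

    def indices_for_sequence(self, key: tuple) -> list[int]:
        return [i for i, m in enumerate(self.measurements) if m.sequence_key == key]

    def b_si_array(self):
        import numpy as np

        return np.array([m.b_si() for m in self.measurements])

    # -- JSON round trip ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"measurements": [m.to_dict() for m in self.measurements]}, indent=2
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AcquisitionScheme":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls([GradientWaveformSpec.from_dict(m) for m in d["measurements"]])


def default_scheme() -> AcquisitionScheme:
    """The package's stand-in clinical 3-T protocol.

    PGSE delta=12 ms / Delta=30 ms at b = {0, 300, 600, 1000, 1500} s/mm²;
    cosine OGSE at 20 Hz (1 period, 50 ms lobes) with the same b-values and at
    40 Hz (2 periods, 50 ms lobes) capped at b = 1000 s/mm² by gradient
    amplitude.
    """
    meas = []
    for b in (0.0, 300.0, 600.0, 1000.0, 1500.0):
        meas.append(GradientWaveformSpec(kind=PGSE, delta=12.0, Delta=30.0, b_value=b))
    for b in (0.0, 300.0, 600.0, 1000.0, 1500.0):
        meas.append(
            GradientWaveformSpec(kind=OGSE_COS, delta=50.0, frequency=20.0, b_value=b)
        )
    for b in (0.0, 300.0, 600.0, 1000.0):
        meas.append(
            GradientWaveformSpec(kind=OGSE_COS, delta=50.0, frequency=40.0, b_value=b)
        )
    return AcquisitionScheme(meas)
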