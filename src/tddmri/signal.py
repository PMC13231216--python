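"""Closed-form restricted-diffusion signals for spheres under PGSE and cosine OGSE.

The intracellular compartment is an impermeable sphere of diameter ``d``.
Under the Gaussian phase approximation (GPA) the log-signal is a sum over
the eigenmodes of diffusion in the sphere.  With eigenvalue roots
``mu_k`` of ``j1'(mu) = 0`` (derivative of the first spherical Bessel
function), radius ``R = d/2`` and intracellular diffusivity ``D``:

    lambda_k = mu_k² D / R²                 (decay rate, 1/ms)
    B_k      = 2 R² / (mu_k² (mu_k² - 2))   (mode weight, µm²; sum = R²/5)

    ln S = -gamma² g² sum_k B_k F_k(timing)

where ``F_k`` is the double time-integral of the effective gradient
against ``exp(-lambda_k |t1 - t2|)``, evaluated in closed form for two
rectangular lobes (PGSE, the Murday–Cotts expression) and for two lobes
of an integer number of cosine periods (OGSE).

The extracellular compartment is hindered Gaussian diffusion,
``ln S = -b D_ex``, frequency independent.  The two-compartment signal is

    S/S0 = f_in · S_in(d, D_in) + (1 - f_in) · exp(-b · D_ex).

All functions accept scalar parameters and are exact at b = 0.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import spherical_jn

from .scheme import (
    GAMMA,
    OGSE_COS,
    PGSE,
    AcquisitionScheme,
    GradientWaveformSpec,
    SchemeError,
)

__all__ = [
    "sphere_bessel_roots",
    "pgse_sphere_log_attenuation",
    "ogse_cos_sphere_log_attenuation",
    "sphere_log_attenuation",
    "two_compartment_signal",
    "apparent_adc",
    "scheme_adcs",
]

D_IN_FIXED = 1.56  # µm²/ms, intracellular diffusivity held fixed throughout

_ROOT_CACHE: list[float] = []


def _j1p(x: float) -> float:
    return spherical_jn(1, x, derivative=True)


def sphere_bessel_roots(k_max: int) -> np.ndarray:
    """First ``k_max`` positive roots of j1'(x) = 0.

    Roots are located by sign-change scanning and polished with Brent's
    method; each returned root satisfies |j1'(root)| < 1e-10.
    """
    if not isinstance(k_max, (int, np.integer)) or k_max < 1:
        raise ValueError("k_max must be a positive integer")
    while len(_ROOT_CACHE) < k_max:
        # scan one pi-wide window past the last known root
        start = _ROOT_CACHE[-1] + 1e-6 if _ROOT_CACHE else 1e-3
        stop = start + np.pi + 1.0
        xs = np.linspace(start, stop, 400)
        vals = _j1p(xs)
        hits = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        for i in hits:
            root = brentq(_j1p, xs[i], xs[i + 1], xtol=1e-14, rtol=1e-15)
            if not _ROOT_CACHE or root > _ROOT_CACHE[-1] + 1e-8:
                _ROOT_CACHE.append(root)
    return np.array(_ROOT_CACHE[:k_max])


def _mode_spectrum(d: float, D: float, k: int):
    """Mode rates lambda_k (1/ms) and weights B_k (µm²) for a sphere."""
    mu = sphere_bessel_roots(k)
    R = d / 2.0
    lam = mu**2 * D / R**2
    B = 2.0 * R**2 / (mu**2 * (mu**2 - 2.0))
    return lam, B


def _pgse_F(lam: np.ndarray, delta: float, Delta: float) -> np.ndarray:
    """Murday–Cotts time factor per mode for two rectangular lobes."""
    e = np.exp
    return (
        2.0 * (lam * delta - 1.0 + e(-lam * delta))
        + 2.0 * e(-lam * Delta)
        - e(-lam * (Delta - delta))
        - e(-lam * (Delta + delta))
    ) / lam**2


def _ogse_cos_F(lam: np.ndarray, delta: float, sep: float, omega: float) -> np.ndarray:
    """Time factor per mode for two cosine lobes (integer periods each).

    ``sep`` is the start-to-start lobe separation (>= delta).
    """
    e = np.exp
    den = lam**2 + omega**2
    intra = lam * delta / den - 2.0 * lam**2 * (1.0 - e(-lam * delta)) / den**2
    cross = (
        lam**2
        * (e(-lam * (sep - delta)) + e(-lam * (sep + delta)) - 2.0 * e(-lam * sep))
        / den**2
    )
    return intra - cross


def _gpa_log_attenuation(wf: GradientWaveformSpec, d: float, D_in: float) -> float:
    """Adaptive-truncation GPA sum; tail bound < 1e-8 on the ln-signal."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    if D_in <= 0:
        raise ValueError("D_in must be positive")
    g = wf.gradient_amplitude()
    if g == 0.0:
        return 0.0

    def partial(k: int) -> float:
        lam, B = _mode_spectrum(d, D_in, k)
        if wf.kind == PGSE:
            F = _pgse_F(lam, wf.delta, wf.Delta)
        else:
            F = _ogse_cos_F(lam, wf.delta, wf.Delta, wf.omega)
        return -(GAMMA**2) * g**2 * float(np.sum(B * F))

    k = 32
    prev = partial(k)
    while k < 4096:
        k *= 2
        cur = partial(k)
        if abs(cur - prev) < 1e-8 * max(1.0, abs(cur)):
            return cur
        prev = cur
    return prev


def pgse_sphere_log_attenuation(
    wf: GradientWaveformSpec, d: float, D_in: float = D_IN_FIXED
) -> float:
    """ln S of spins restricted in a sphere under a PGSE waveform."""
    if wf.kind != PGSE:
        raise SchemeError("waveform is not PGSE")
    return _gpa_log_attenuation(wf, d, D_in)


def ogse_cos_sphere_log_attenuation(
    wf: GradientWaveformSpec, d: float, D_in: float = D_IN_FIXED
) -> float:
    """ln S of spins restricted in a sphere under a cosine-OGSE waveform."""
    if wf.kind != OGSE_COS:
        raise SchemeError("waveform is not cosine OGSE")
    return _gpa_log_attenuation(wf, d, D_in)


def sphere_log_attenuation(
    wf: GradientWaveformSpec, d: float, D_in: float = D_IN_FIXED
) -> float:
    """Kind-dispatching intracellular ln-signal."""
    if wf.kind == PGSE:
        return pgse_sphere_log_attenuation(wf, d, D_in)
    return ogse_cos_sphere_log_attenuation(wf, d, D_in)


def two_compartment_signal(
    scheme: AcquisitionScheme,
    d: float,
    f_in: float,
    D_ex: float,
    D_in: float = D_IN_FIXED,
) -> np.ndarray:
    """Normalized two-compartment signal S/S0 per scheme measurement.

    Restricted intracellular spheres (volume fraction ``f_in``) plus a
    hindered extracellular compartment with mono-exponential attenuation.
    """
    if not 0.0 <= f_in <= 1.0:
        raise ValueError("f_in must lie in [0, 1]")
    if D_ex < 0:
        raise ValueError("D_ex must be non-negative")
    out = np.empty(len(scheme))
    for i, wf in enumerate(scheme):
        s_in = np.exp(sphere_log_attenuation(wf, d, D_in)) if f_in > 0 else 0.0
        s_ex = np.exp(-wf.b_internal() * D_ex)
        out[i] = f_in * s_in + (1.0 - f_in) * s_ex
    return out


def apparent_adc(b_si: np.ndarray, signals: np.ndarray) -> float:
    """Monoexponential ADC (µm²/ms): least-squares slope of -ln S against b.

    Fitted with a free intercept; exact for noise-free monoexponential input.
    ``b_si`` in s/mm².
    """
    b = np.asarray(b_si, dtype=float) * 1.0e-3  # ms/µm²
    s = np.asarray(signals, dtype=float)
    if b.size < 2 or np.unique(b).size < 2:
        raise ValueError("ADC fit needs >= 2 distinct b-values")
    if np.any(s <= 0) or np.any(s > 1.0 + 1e-9):
        raise ValueError("signals must lie in (0, 1]")
    slope = np.polyfit(b, -np.log(s), 1)[0]
    return float(slope)


def scheme_adcs(scheme: AcquisitionScheme, signals: np.ndarray) -> dict:
    """ADC per sequence in the scheme, keyed by sequence label."""
    signals = np.asarray(signals, dtype=float)
    out = {}
    for key in scheme.sequence_keys():
        idx = scheme.indices_for_sequence(key)
        b = np.array([scheme.measurements[i].b_si() for i in idx])
        out[scheme.measurements[idx[0]].label] = apparent_adc(b, signals[idx])
    return out
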