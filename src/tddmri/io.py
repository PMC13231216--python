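"""NIfTI and tabular I/O plus run-configuration handling.

Volumes are stored as NIfTI-1 with a shared affine; masks round-trip as
booleans.  No resampling ever happens here: a signal/mask grid or affine
mismatch is an error naming both shapes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "write_volume",
    "read_volume",
    "read_mask",
    "check_same_grid",
    "RunConfig",
]


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write an array as NIfTI-1 (bool masks as uint8, floats as float32)."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype != np.float64:
        data = data.astype(np.float32)
    affine = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI mask as boolean; returns (mask, affine)."""
    data, affine = read_volume(path)
    return data > 0, affine


def check_same_grid(
    shape_a, affine_a, shape_b, affine_b, what: str = "signal/mask"
) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(
            f"{what} grid mismatch: shapes {tuple(shape_a)} vs {tuple(shape_b)}"
        )
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise ValueError(f"{what} affine mismatch; no silent resampling is done")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class RunConfig(dict):
    """Run configuration: a JSON document validated for explicit seeds.

    Every stochastic stage present in the config must carry its own
    ``seed``; validation happens before any computation.  CLI flags
    override file values.
    """

    STOCHASTIC_STAGES = ("phantom", "cohort", "test_retest", "reader_masks", "split")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls(json.loads(Path(path).read_text()))
        cfg.validate()
        return cfg

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self, indent=2, sort_keys=True))

    def validate(self) -> None:
        for stage in self.STOCHASTIC_STAGES:
            if stage in self and "seed" not in self[stage]:
                raise ValueError(f"config stage {stage!r} is missing an explicit seed")

    def round_trip_equal(self, path) -> bool:
        return json.loads(Path(path).read_text()) == dict(self)
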