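"""Fit microstructural parameter maps on the simulated phantom.

Inverts the noisy phantom from 01_simulate_inputs.py voxel by voxel,
writes the parameter maps (NIfTI) and the VOI summary, and reports
recovery accuracy against the phantom's ground truth.
Writes results/maps/ and results/voi_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tddmri.fitting import fit_maps
from tddmri.io import check_same_grid, read_mask, read_volume, write_volume
from tddmri.scheme import AcquisitionScheme

ROOT = Path(__file__).resolve().parents[1] / "results"
INP = ROOT / "inputs"
OUT = ROOT / "maps"
OUT.mkdir(parents=True, exist_ok=True)

scheme = AcquisitionScheme.from_json(INP / "scheme.json")
vols, aff = read_volume(INP / "phantom_signals.nii")
mask, aff_m = read_mask(INP / "phantom_mask.nii")
check_same_grid(vols.shape[:-1], aff, mask.shape, aff_m)

maps, voi = fit_maps(vols, mask, scheme)
for k, v in maps.items():
    write_volume(OUT / f"map_{k}.nii", v, aff)

truth = {"d": 14.0, "f_in": 0.35, "D_ex": 2.0, "cellularity": 100 * 0.35 / 14.0}
rows = []
for k, t in truth.items():
    est = voi.means[k]
    rows.append({"parameter": k, "truth": t, "voi_mean": est,
                 "relative_bias_pct": 100 * (est / t - 1)})
    print(f"{k:12s} truth {t:7.3f}  VOI mean {est:7.3f}  "
          f"bias {100 * (est / t - 1):+5.2f}%")
summary = pd.DataFrame(rows)
summary.to_csv(ROOT / "voi_recovery.csv", index=False)
pd.DataFrame([{"n_voxels": voi.n_voxels, **voi.means}]).to_csv(
    ROOT / "voi_summary.csv", index=False
)
adc = {k: voi.means[k] for k in ("adc_pgse", "adc_20hz", "adc_40hz", "radc")}
print(f"\nfitted {voi.n_voxels} voxels; ADC metrics "
      + ", ".join(f"{k}={v:.3f}" for k, v in adc.items()))
print("all relative biases "
      + ("within" if (summary.relative_bias_pct.abs() < 5).all() else "OUTSIDE")
      + " 5% at SNR 50")
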