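"""Synthetic-data generators: every input the analysis pipeline consumes.

All generators are pure functions of (configuration, seed).  They emulate:

* digital phantoms — voxel grids of two-compartment tissue with Rician
  magnitude noise at a configured b=0 SNR;
* same-day test-retest replicates with controlled between- and
  within-subject variability;
* dual-reader tumor masks with a controlled Dice overlap;
* a synthetic nasopharyngeal-carcinoma cohort whose covariate marginals,
  imaging group contrasts and response prevalence follow the published
  training-set summaries the package's statistics are exercised against;
* imaging/histology metric pairs with configured Pearson correlations.

The Monte-Carlo physics oracle lives in :mod:`tddmri.montecarlo` and is
re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fitting import compute_cellularity, compute_radc
from .montecarlo import mc_sphere_attenuation  # noqa: F401  (oracle re-export)
from .scheme import AcquisitionScheme
from .signal import two_compartment_signal

__all__ = [
    "PhantomSpec",
    "add_rician_noise",
    "generate_phantom",
    "generate_test_retest",
    "generate_reader_masks",
    "generate_cohort",
    "generate_histology_pairs",
    "assign_labels_logistic",
    "mc_sphere_attenuation",
    "COHORT_CONFIG",
]


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Digital phantom layout: grid, per-region tissue, noise level.

    The default geometry is a 32³ grid at 2 mm isotropic voxels holding an
    ellipsoidal tumor of roughly 9–10 cm³, the median tumor volume scale of
    the cohort being emulated.
    """

    shape: tuple = (32, 32, 32)
    voxel_mm: float = 2.0
    regions: dict = field(
        default_factory=lambda: {1: {"d": 14.0, "f_in": 0.35, "D_ex": 2.0}}
    )
    semiaxes_mm: tuple = (14.0, 10.0, 8.0)
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")


def _ellipsoid_mask(shape, voxel_mm, semiaxes_mm) -> np.ndarray:
    center = (np.array(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(
        ((g - c) * voxel_mm / a) ** 2 for g, c, a in zip(grids, center, semiaxes_mm)
    )
    return r2 <= 1.0


def add_rician_noise(signal: np.ndarray, snr: float, rng: np.random.Generator):
    """Rician magnitude noise with sigma = 1/SNR (SNR defined at b=0, S0=1)."""
    sigma = 1.0 / snr
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def generate_phantom(spec: PhantomSpec, scheme: AcquisitionScheme):
    """Noisy signal volumes plus ground-truth maps and tumor mask.

    Regions split the ellipsoidal tumor into equal slabs along the first
    axis (one slab per region label, in key order).  Returns
    ``(volumes, truth_maps, mask)`` with ``volumes`` of shape
    ``spec.shape + (len(scheme),)``.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.shape, spec.voxel_mm, spec.semiaxes_mm)
    labels = sorted(spec.regions)
    label_map = np.zeros(spec.shape, dtype=np.int16)
    xs = np.nonzero(mask.any(axis=(1, 2)))[0]
    edges = np.linspace(xs[0], xs[-1] + 1, len(labels) + 1)
    for i, lab in enumerate(labels):
        sl = (
            (np.arange(spec.shape[0]) >= edges[i])
            & (np.arange(spec.shape[0]) < edges[i + 1])
        )[:, None, None]
        label_map[mask & sl] = lab

    volumes = np.zeros(spec.shape + (len(scheme),), dtype=float)
    truth = {
        k: np.full(spec.shape, np.nan, dtype=np.float32)
        for k in ("d", "f_in", "D_ex", "cellularity")
    }
    for lab in labels:
        p = spec.regions[lab]
        sig = two_compartment_signal(scheme, p["d"], p["f_in"], p["D_ex"])
        sel = label_map == lab
        volumes[sel] = sig
        truth["d"][sel] = p["d"]
        truth["f_in"][sel] = p["f_in"]
        truth["D_ex"][sel] = p["D_ex"]
        truth["cellularity"][sel] = compute_cellularity(p["f_in"], p["d"])
    if np.isfinite(spec.snr):
        noisy = add_rician_noise(volumes, spec.snr, rng)
        volumes = np.where(mask[..., None], noisy, 0.0)
    return volumes, truth, mask


# --------------------------------------------------------------------------
# test-retest replicates
# --------------------------------------------------------------------------


def generate_test_retest(
    n_subjects: int = 54,
    mean: float = 2.4,
    between_cv: float = 0.20,
    within_cv: float = 0.09,
    seed: int = 0,
    metric: str = "cellularity",
) -> pd.DataFrame:
    """Paired same-day measurements with multiplicative within-subject noise.

    Subject means are lognormal around ``mean`` with coefficient of
    variation ``between_cv``; each replicate multiplies the subject mean by
    a unit-mean lognormal factor with coefficient of variation
    ``within_cv``.  ``attrs`` records both the configured ``within_cv``
    and the population estimand of the within-subject-SD method on this
    generator, ``wcv = within_cv·sqrt(1 + between_cv²)`` (the raw-scale
    pooled wSD divided by the grand mean, inflated because multiplicative
    noise scales with each subject's level); recovery tests compare
    against the estimand.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if between_cv <= 0 or within_cv < 0:
        raise ValueError("CVs must be positive (within_cv may be 0)")
    rng = np.random.default_rng(seed)
    s_b = np.sqrt(np.log1p(between_cv**2))
    mu = np.log(mean) - s_b**2 / 2.0
    subject_means = np.exp(rng.normal(mu, s_b, n_subjects))
    s_w = np.sqrt(np.log1p(within_cv**2))
    reps = subject_means[:, None] * np.exp(
        rng.normal(-s_w**2 / 2.0, s_w, (n_subjects, 2))
    )
    df = pd.DataFrame(
        {
            "subject": [f"S{i:03d}" for i in range(n_subjects)],
            "value1": reps[:, 0],
            "value2": reps[:, 1],
            "metric": metric,
        }
    )
    df.attrs["true_within_cv"] = within_cv
    df.attrs["true_wcv_estimand"] = within_cv * float(np.sqrt(1.0 + between_cv**2))
    df.attrs["true_wsd_estimand"] = (
        within_cv * mean * float(np.sqrt(1.0 + between_cv**2))
    )
    df.attrs["true_mean"] = mean
    return df


# --------------------------------------------------------------------------
# dual-reader masks
# --------------------------------------------------------------------------


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def generate_reader_masks(
    base_mask: np.ndarray, target_dice: float, seed: int = 0, tol: float = 0.01
) -> np.ndarray:
    """A second-reader mask whose Dice overlap with ``base_mask`` hits a target.

    Boundary voxels (inner and outer shells of the base mask) are flipped
    with a probability found by bisection under common random numbers, so
    the achieved Dice is monotone in the flip probability and lands within
    ``tol`` of the target.  Shells are widened if a single shell cannot
    reach the target.
    """
    base = np.asarray(base_mask, dtype=bool)
    if not 0.0 < target_dice <= 1.0:
        raise ValueError("target_dice must be in (0, 1]")
    if target_dice > 1.0 - 1e-12 or _dice(base, base) <= target_dice:
        return base.copy()
    rng = np.random.default_rng(seed)
    u = rng.random(base.shape)
    for width in range(1, 8):
        outer = ndimage.binary_dilation(base, iterations=width) & ~base
        inner = base & ~ndimage.binary_erosion(base, iterations=width)
        shell = outer | inner

        def mask_at(p: float) -> np.ndarray:
            flip = shell & (u < p)
            return base ^ flip

        if _dice(mask_at(1.0), base) > target_dice + tol:
            continue  # widest flip still too similar; widen the shell
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if _dice(mask_at(mid), base) > target_dice:
                lo = mid
            else:
                hi = mid
        cand = mask_at((lo + hi) / 2.0)
        if abs(_dice(cand, base) - target_dice) <= tol:
            return cand
    raise ValueError("target Dice unattainable on this mask")


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

# Per-response-group covariate and imaging-metric distributions of the
# emulated 220-participant training population.  Categorical entries are
# (levels, responder probabilities, nonresponder probabilities); continuous
# entries are per-group (mean, sd) on the sampling scale.
COHORT_CONFIG = {
    "n": 220,
    "responder_fraction": 151.0 / 220.0,
    "categorical": {
        "sex": (["male", "female"], [0.660, 0.340], [0.750, 0.250]),
        "t_stage": (
            ["T1", "T2", "T3", "T4"],
            [0.075, 0.208, 0.292, 0.425],
            [0.042, 0.104, 0.500, 0.354],
        ),
        "n_stage": (
            ["N0", "N1", "N2", "N3"],
            [0.057, 0.415, 0.330, 0.198],
            [0.042, 0.271, 0.417, 0.271],
        ),
        "ajcc_stage": (["III", "IVa"], [0.453, 0.547], [0.458, 0.542]),
        "ebv_dna": (["<4000", ">=4000"], [0.698, 0.302], [0.542, 0.458]),
        "ki67": (["<50%", ">=50%"], [0.623, 0.377], [0.667, 0.333]),
        "tsr": (["<50%", ">=50%"], [0.613, 0.387], [0.417, 0.583]),
        "chemo_cycles": (["two", "three"], [0.670, 0.330], [0.729, 0.271]),
    },
    # age and log tumor volume are near-symmetric on their scales
    "age": ((53.5, 6.8), (54.0, 8.0)),
    "log_tumor_volume": ((np.log(9.44), 0.633), (np.log(9.94), 0.655)),
    "imaging": {
        "d": ((14.65, 1.51), (14.25, 1.58)),
        "f_in": ((0.35, 0.08), (0.37, 0.07)),
        "D_ex": ((2.00, 0.55), (2.00, 0.56)),
        "adc_pgse": ((0.79, 0.20), (0.79, 0.21)),
        "adc_20hz": ((1.04, 0.34), (0.97, 0.33)),
        "adc_40hz": ((1.20, 0.26), (1.17, 0.28)),
    },
}


def _trunc_normal(rng, mean, sd, size, lo, hi):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    n: int = 220,
    responder_fraction: float = 151.0 / 220.0,
    effect_scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic cohort table with exact response-label counts.

    Labels are assigned deterministically (``round(n·responder_fraction)``
    responders); covariates and imaging VOI means are sampled conditionally
    on the response group.  ``effect_scale`` interpolates every group
    contrast toward the pooled distribution (0 → null generator, 1 → the
    published contrasts).  Cellularity is derived as 100·f_in/d and rADC
    from the sampled ADCs, so the deterministic relations between reported
    metrics hold row-wise.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must be in [0, 1]")
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    rng = np.random.default_rng(seed)
    n_resp = int(round(n * responder_fraction))
    response = np.array([1] * n_resp + [0] * (n - n_resp))
    rng.shuffle(response)
    w = responder_fraction

    def blend(resp_val, nonresp_val):
        pooled = w * np.asarray(resp_val, float) + (1 - w) * np.asarray(
            nonresp_val, float
        )
        rv = pooled + effect_scale * (np.asarray(resp_val, float) - pooled)
        nv = pooled + effect_scale * (np.asarray(nonresp_val, float) - pooled)
        return rv, nv

    cols: dict = {"subject": [f"P{i:04d}" for i in range(n)], "response": response}
    cfg = COHORT_CONFIG
    for name, (levels, p_resp, p_non) in cfg["categorical"].items():
        pr, pn = blend(p_resp, p_non)
        pr, pn = pr / pr.sum(), pn / pn.sum()
        vals = np.empty(n, dtype=object)
        vals[response == 1] = rng.choice(levels, (response == 1).sum(), p=pr)
        vals[response == 0] = rng.choice(levels, (response == 0).sum(), p=pn)
        cols[name] = vals

    def cont(name, group_params, lo, hi, transform=None):
        (m1, s1), (m0, s0) = group_params
        mr, mn = blend(m1, m0)
        vals = np.empty(n)
        vals[response == 1] = _trunc_normal(rng, mr, s1, (response == 1).sum(), lo, hi)
        vals[response == 0] = _trunc_normal(rng, mn, s0, (response == 0).sum(), lo, hi)
        cols[name] = transform(vals) if transform else vals

    cont("age", cfg["age"], 18, 90)
    cont("tumor_volume_cm3", cfg["log_tumor_volume"], -2, 5, transform=np.exp)
    img = cfg["imaging"]
    cont("d", img["d"], 5.0, 25.0)
    cont("f_in", img["f_in"], 0.02, 0.98)
    cont("D_ex", img["D_ex"], 0.1, 3.1)
    cont("adc_pgse", img["adc_pgse"], 0.1, 3.0)
    cont("adc_20hz", img["adc_20hz"], 0.1, 3.5)
    cont("adc_40hz", img["adc_40hz"], 0.1, 3.5)
    df = pd.DataFrame(cols)
    df["cellularity"] = compute_cellularity(df["f_in"].to_numpy(), df["d"].to_numpy())
    df["radc"] = [
        compute_radc(a40, ap) for a40, ap in zip(df["adc_40hz"], df["adc_pgse"])
    ]
    return df


def assign_labels_logistic(
    X: np.ndarray, beta: np.ndarray, intercept: float, seed: int = 0
) -> np.ndarray:
    """Bernoulli labels from a logistic model — the generative counterpart
    used by parameter-recovery and calibration simulations."""
    rng = np.random.default_rng(seed)
    eta = intercept + np.asarray(X, float) @ np.asarray(beta, float)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(p)) < p).astype(int)


# --------------------------------------------------------------------------
# histology pairs
# --------------------------------------------------------------------------

HISTOLOGY_TARGETS = {"d": 0.67, "cellularity": 0.34, "f_in": 0.27}


def generate_histology_pairs(
    cohort: pd.DataFrame,
    targets: dict | None = None,
    n_subset: int = 97,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired imaging/histology metrics with configured Pearson correlations.

    A Gaussian-copula construction: the histology value is a linear blend
    of the standardized imaging value and independent Gaussian noise with
    weight ``r``, so the expected Pearson correlation equals the target.
    """
    targets = HISTOLOGY_TARGETS if targets is None else targets
    for m, r in targets.items():
        if abs(r) > 1:
            raise ValueError(f"|r| must be <= 1 for {m}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cohort), size=min(n_subset, len(cohort)), replace=False)
    sub = cohort.iloc[np.sort(idx)].reset_index(drop=True)
    out = {"subject": sub["subject"]}
    for metric, r in targets.items():
        x = sub[metric].to_numpy(dtype=float)
        z = (x - x.mean()) / x.std(ddof=0)
        if abs(r) == 1.0:
            h = np.sign(r) * z
        else:
            h = r * z + np.sqrt(1.0 - r**2) * rng.standard_normal(len(z))
        out[f"imaging_{metric}"] = x
        out[f"histology_{metric}"] = h  # standardized histology scale
    return pd.DataFrame(out)
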