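"""Reader-agreement and test-retest repeatability statistics.

Implements the quantitative-imaging-biomarker repeatability toolkit:
Bland-Altman limits of agreement, the repeatability coefficient (RC) from
the within-subject SD with a chi-square confidence interval, the
within-subject coefficient of variation (wCV), the two-way mixed-effects
absolute-agreement ICC with its F-based interval, the Dice overlap of two
segmentations, and unweighted Cohen's kappa with the conventional
agreement bands (poor < 0.21 <= fair <= 0.40 < moderate <= 0.60 <
substantial <= 0.80 < excellent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "bland_altman",
    "repeatability_coefficient",
    "within_subject_cv",
    "agreement_report",
    "icc",
    "dice",
    "cohens_kappa",
    "kappa_band",
]

Z95 = 1.96  # conventional normal quantile used for LoA and RC


def _pairs(value1, value2):
    v1 = np.asarray(value1, dtype=float)
    v2 = np.asarray(value2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("value1/value2 must be equal-length 1-D arrays")
    if v1.size < 2:
        raise ValueError("need at least 2 complete pairs")
    if not (np.isfinite(v1).all() and np.isfinite(v2).all()):
        raise ValueError("non-finite measurement")
    return v1, v2


def bland_altman(value1, value2) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean ± 1.96·SD, n−1 SD)."""
    v1, v2 = _pairs(value1, value2)
    diff = v1 - v2
    md = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return md, md - Z95 * sd, md + Z95 * sd


def repeatability_coefficient(value1, value2, ci: float = 0.95):
    """RC = 1.96·√2·wSD with wSD = sqrt(Σdᵢ²/(2n)) (within-subject SD method).

    The CI follows from Σdᵢ² / (2·wSD²) ~ chi-square with n degrees of
    freedom (exact under normal, zero-bias differences).
    """
    v1, v2 = _pairs(value1, value2)
    diff = v1 - v2
    n = diff.size
    ssq = float(np.sum(diff**2))
    wsd = np.sqrt(ssq / (2.0 * n))
    rc = Z95 * np.sqrt(2.0) * wsd
    alpha = 1.0 - ci
    lo = Z95 * np.sqrt(ssq / stats.chi2.ppf(1.0 - alpha / 2.0, df=n))
    hi = Z95 * np.sqrt(ssq / stats.chi2.ppf(alpha / 2.0, df=n))
    return float(rc), (float(lo), float(hi)), float(wsd)


def within_subject_cv(value1, value2) -> float:
    """wCV (%) = 100 · wSD / grand mean of all measurements (both occasions)."""
    v1, v2 = _pairs(value1, value2)
    grand = float(np.mean(np.concatenate([v1, v2])))
    if grand <= 0:
        raise ValueError("grand mean must be positive for a CV")
    _, _, wsd = repeatability_coefficient(v1, v2)
    return 100.0 * wsd / grand


@dataclass
class AgreementReport:
    """Bland-Altman / RC / wCV summary for one metric's paired measurements."""

    metric: str
    n: int
    mean_difference: float
    loa_lower: float
    loa_upper: float
    rc: float
    rc_ci: tuple
    wcv_percent: float

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.mean_difference <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the mean difference")
        if self.rc < 0:
            raise ValueError("RC must be non-negative")


def agreement_report(value1, value2, metric: str = "") -> AgreementReport:
    v1, v2 = _pairs(value1, value2)
    md, lo, hi = bland_altman(v1, v2)
    rc, rc_ci, _ = repeatability_coefficient(v1, v2)
    wcv = within_subject_cv(v1, v2) if np.mean(np.concatenate([v1, v2])) > 0 else np.nan
    return AgreementReport(
        metric=metric,
        n=v1.size,
        mean_difference=md,
        loa_lower=lo,
        loa_upper=hi,
        rc=rc,
        rc_ci=rc_ci,
        wcv_percent=wcv,
    )


def icc(matrix, ci: float = 0.95):
    """ICC(A,1): two-way mixed effects, absolute agreement, single measurement.

    ``matrix`` is subjects × raters/occasions.  Returns (icc, (lo, hi),
    degenerate_flag); for a zero-variance matrix the ICC is defined as 1
    with a degenerate-CI flag.  The interval is the standard F-based one.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5 or X.shape[1] < 2:
        raise ValueError("need >= 5 subjects and >= 2 columns")
    n, k = X.shape
    if np.allclose(X, X.flat[0]):
        return 1.0, (np.nan, np.nan), True
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong F-based interval for ICC(A,1)
    alpha = 1.0 - ci
    a = k * val / (n * (1.0 - val))
    b = 1.0 + k * val * (n - 1) / (n * (1.0 - val))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_hi = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lo = n * (msr - f_lo * mse) / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = (
        n * (f_hi * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
    )
    return float(val), (float(lo), float(hi)), False


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|) of two boolean masks on one grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Dice undefined for two empty masks")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


KAPPA_BANDS = (
    (0.21, "poor"),
    (0.41, "fair"),
    (0.61, "moderate"),
    (0.81, "substantial"),
    (np.inf, "excellent"),
)


def kappa_band(kappa: float) -> str:
    """Conventional qualitative band for a kappa value."""
    for upper, name in KAPPA_BANDS:
        if kappa < upper:
            return name
    return "excellent"


def cohens_kappa(ratings_a, ratings_b):
    """Unweighted Cohen's kappa with its agreement band.

    Returns (kappa, band, p_observed).  When both raters use a single
    shared category with perfect agreement, kappa is undefined
    (chance agreement is 1); reported as (nan, "degenerate", 1.0).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length non-empty 1-D arrays")
    cats = np.unique(np.concatenate([a, b]))
    po = float(np.mean(a == b))
    pe = float(
        sum(np.mean(a == c) * np.mean(b == c) for c in cats)
    )
    if pe >= 1.0 - 1e-12:
        return float("nan"), "degenerate", po
    k = (po - pe) / (1.0 - pe)
    return float(k), kappa_band(k), po
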