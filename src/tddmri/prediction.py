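"""The study-style statistical pipeline for chemotherapy-response prediction.

Covers the full modelling chain: stratified 7:3 splitting with
largest-remainder apportionment, two-group comparisons, univariable and
multivariable logistic regression with smallest-category reference coding,
VIF-based collinearity screening, ROC analysis (tie-corrected Mann-Whitney
AUC, stratified percentile bootstrap, DeLong comparison of correlated
AUCs, Youden-index cutoffs), Hosmer-Lemeshow calibration, decision-curve
net benefit, stratified k-fold cross-validation, subgroup evaluation, the
Hanley-McNeil AUC sample-size calculation and Pearson correlation.

Logistic fits go through statsmodels; everything that constitutes a
checkable statistic (AUC, Youden scan, DeLong covariance, net benefit,
Hosmer-Lemeshow) is computed explicitly so tests can compare it against
brute-force oracles and library implementations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "stratified_split",
    "compare_groups",
    "build_design",
    "univariable_logistic",
    "collinearity_screen",
    "multivariable_logistic",
    "auc_mann_whitney",
    "roc_auc",
    "delong_test",
    "precision_recall_curve",
    "youden_cutoff",
    "hosmer_lemeshow",
    "decision_curve",
    "kfold_cv",
    "subgroup_eval",
    "sample_size_auc",
    "pearson_correlation",
    "LogisticModelReport",
]


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------


def stratified_split(
    cohort: pd.DataFrame,
    ratio: float = 0.7,
    strata: str = "response",
    seed: int = 0,
) -> pd.Series:
    """Training/test assignment with per-stratum largest-remainder counts.

    The total training size is ``round(ratio·n)``; per-stratum training
    counts take the floor of ``ratio·n_s`` and distribute the remaining
    slots by largest fractional remainder, so stratum totals and the grand
    total are simultaneously consistent.  Membership within a stratum is
    random given the seed.  Returns a Series of {"training", "test"}
    indexed like ``cohort``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    labels = cohort[strata]
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("every stratum must be non-empty")
    total_train = int(round(ratio * len(cohort)))
    quota = {s: ratio * c for s, c in counts.items()}
    base = {s: int(np.floor(q)) for s, q in quota.items()}
    leftover = total_train - sum(base.values())
    # largest remainder; ties broken by larger stratum then label order
    order = sorted(
        quota, key=lambda s: (-(quota[s] - base[s]), -counts[s], str(s))
    )
    for s in order[:leftover]:
        base[s] += 1
    rng = np.random.default_rng(seed)
    out = pd.Series("test", index=cohort.index, name="split")
    for s, n_train in base.items():
        idx = cohort.index[labels == s].to_numpy()
        chosen = rng.choice(idx, size=n_train, replace=False)
        out.loc[chosen] = "training"
    return out


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group: str = "response",
    kind: str = "auto",
) -> dict:
    """Two-group comparison with the conventional test-routing rules.

    Continuous variables use the independent t test when both groups pass
    Shapiro-Wilk normality (alpha = .05) and Mann-Whitney U otherwise;
    categorical variables use the chi-square test without continuity
    correction, routed to the Fisher exact test when any expected cell
    count is below 5 (2x2 only).
    """
    groups = table[group].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = table.loc[table[group] == groups[0], variable]
    b = table.loc[table[group] == groups[1], variable]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if kind == "auto":
        kind = (
            "continuous"
            if pd.api.types.is_numeric_dtype(table[variable])
            else "categorical"
        )
    if kind == "continuous":
        normal = all(
            len(g) >= 3 and stats.shapiro(g).pvalue > 0.05 for g in (a, b)
        )
        if normal:
            stat, p = stats.ttest_ind(a, b)
            test = "t"
            summary = {
                g: f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
                for g, v in ((groups[0], a), (groups[1], b))
            }
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
            summary = {
                g: f"{v.median():.2f} ({v.quantile(.25):.2f}-{v.quantile(.75):.2f})"
                for g, v in ((groups[0], a), (groups[1], b))
            }
    else:
        ct = pd.crosstab(table[variable], table[group])
        expected = stats.contingency.expected_freq(ct.to_numpy())
        if (expected < 5).any() and ct.shape == (2, 2):
            stat, p = stats.fisher_exact(ct.to_numpy())
            test = "fisher"
        else:
            if (expected < 5).any():
                logger.warning(
                    "expected cell < 5 on a %s table; chi-square used", ct.shape
                )
            stat, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
            test = "chi2"
        summary = {
            g: {lvl: f"{c} ({100*c/ct[g].sum():.1f}%)" for lvl, c in ct[g].items()}
            for g in ct.columns
        }
    return {"test": test, "statistic": float(stat), "p": float(p), "summary": summary}


# --------------------------------------------------------------------------
# logistic modelling
# --------------------------------------------------------------------------


@dataclass
class LogisticModelReport:
    """Per-predictor OR table plus per-subject scores from one logistic fit."""

    terms: pd.DataFrame  # index: term; columns: beta, or, ci_low, ci_high, p
    intercept: float
    converged: bool
    separation: bool
    reference: dict
    probabilities: np.ndarray = field(repr=False, default=None)
    linear_predictor: np.ndarray = field(repr=False, default=None)
    model: object = field(repr=False, default=None)
    design_columns: list = field(default_factory=list)


def _reference_level(series: pd.Series) -> str:
    """Smallest category is the reference; ties broken alphabetically."""
    counts = series.value_counts()
    smallest = counts.min()
    return sorted(str(c) for c in counts[counts == smallest].index)[0]


def build_design(
    data: pd.DataFrame, predictors: list[str]
) -> tuple[pd.DataFrame, dict]:
    """Design matrix with categorical predictors reference-coded by the
    smallest category.  Returns (X, reference-level map)."""
    cols = {}
    refs = {}
    for p in predictors:
        s = data[p]
        if pd.api.types.is_numeric_dtype(s):
            cols[p] = s.astype(float)
        else:
            ref = _reference_level(s)
            refs[p] = ref
            for lvl in sorted(str(v) for v in s.unique()):
                if lvl != ref:
                    cols[f"{p}[{lvl}]"] = (s.astype(str) == lvl).astype(float)
    return pd.DataFrame(cols, index=data.index), refs


def _fit_logit(X: pd.DataFrame, y: np.ndarray) -> tuple:
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            separation = True
            res = sm.Logit(y, Xc).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
    if not separation and np.abs(res.params).max() > 15:
        separation = True  # practically separated; Wald CIs meaningless
    return res, converged, separation


def _logistic_report(data, predictors, outcome) -> LogisticModelReport:
    y = data[outcome].to_numpy(dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must be binary 0/1 with both classes present")
    X, refs = build_design(data, predictors)
    if any(X[c].nunique() < 2 for c in X.columns):
        raise ValueError("a predictor column has no variation")
    res, converged, separation = _fit_logit(X, y)
    params = res.params
    if separation:
        ci = pd.DataFrame(np.nan, index=params.index, columns=[0, 1])
        pvals = pd.Series(np.nan, index=params.index)
    else:
        ci = res.conf_int()
        pvals = res.pvalues
    rows = []
    for term in X.columns:
        rows.append(
            {
                "term": term,
                "beta": float(params[term]),
                "or": float(np.exp(params[term])),
                "ci_low": float(np.exp(ci.loc[term, 0])),
                "ci_high": float(np.exp(ci.loc[term, 1])),
                "p": float(pvals[term]),
            }
        )
    terms = pd.DataFrame(rows).set_index("term")
    eta = res.predict(sm.add_constant(X, has_constant="add"), which="linear")
    return LogisticModelReport(
        terms=terms,
        intercept=float(params["const"]),
        converged=converged,
        separation=separation,
        reference=refs,
        probabilities=1.0 / (1.0 + np.exp(-np.asarray(eta))),
        linear_predictor=np.asarray(eta),
        model=res,
        design_columns=list(X.columns),
    )


def univariable_logistic(
    data: pd.DataFrame, predictor: str, outcome: str = "response"
) -> LogisticModelReport:
    """Maximum-likelihood univariable logistic fit with Wald CIs."""
    return _logistic_report(data, [predictor], outcome)


def multivariable_logistic(
    data: pd.DataFrame, predictors: list[str], outcome: str = "response"
) -> LogisticModelReport:
    """Joint ML logistic fit; per-subject probabilities retained for
    downstream model evaluation."""
    return _logistic_report(data, predictors, outcome)


def collinearity_screen(
    data: pd.DataFrame, predictors: list[str], vif_threshold: float = 5.0
) -> tuple[list[str], list[dict]]:
    """Iteratively drop the highest-VIF predictor until all VIF < threshold.

    Exact duplicate columns are removed first (second occurrence by order).
    Returns (retained predictors, exclusion log).
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 candidate predictors")
    X, _ = build_design(data, predictors)
    col_of = {}
    for p in predictors:
        col_of[p] = [c for c in X.columns if c == p or c.startswith(f"{p}[")]
    retained = list(predictors)
    log: list[dict] = []
    # duplicates
    for i, p in enumerate(list(retained)):
        for q in retained[:i]:
            if col_of[p] and col_of[q] and len(col_of[p]) == len(col_of[q]):
                if all(
                    np.allclose(X[a], X[b]) for a, b in zip(col_of[p], col_of[q])
                ):
                    retained.remove(p)
                    log.append({"excluded": p, "reason": f"duplicate of {q}"})
                    break
    while len(retained) > 1:
        cols = [c for p in retained for c in col_of[p]]
        M = sm.add_constant(X[cols], has_constant="add")
        vifs = {}
        for p in retained:
            v = 0.0
            for c in col_of[p]:
                j = list(M.columns).index(c)
                r2 = sm.OLS(M[c], M.drop(columns=[c])).fit().rsquared
                v = max(v, np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2))
            vifs[p] = v
        worst = max(vifs, key=lambda p: vifs[p])
        if vifs[worst] < vif_threshold:
            break
        retained.remove(worst)
        log.append(
            {"excluded": worst, "reason": f"VIF {vifs[worst]:.2f} >= {vif_threshold}"}
        )
    return retained, log


# --------------------------------------------------------------------------
# ROC machinery
# --------------------------------------------------------------------------


def _check_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present")
    return s, y


def auc_mann_whitney(scores, labels) -> float:
    """AUC via midranks (tie-corrected Mann-Whitney estimator)."""
    s, y = _check_scores(scores, labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_auc(
    scores, labels, n_boot: int = 1000, seed: int = 0, ci: float = 0.95
) -> tuple[float, tuple]:
    """AUC with a class-stratified percentile-bootstrap CI."""
    s, y = _check_scores(scores, labels)
    a = auc_mann_whitney(s, y)
    rng = np.random.default_rng(seed)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([bp, bn])
        boots[i] = auc_mann_whitney(s[idx], y[idx])
    alpha = 1.0 - ci
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return a, (float(lo), float(hi))


def _delong_components(scores, labels):
    s, y = _check_scores(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n          # structural components, positives
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # structural components, negatives
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong z-test for two correlated AUCs on identical subjects.

    Returns (z, two-sided p).
    """
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var <= 0:
        if auc_a == auc_b:
            return 0.0, 1.0
        raise ValueError("degenerate DeLong variance")
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def youden_cutoff(scores, labels) -> dict:
    """Youden-optimal threshold with explicit predictive-value fractions.

    Thresholds are midpoints between consecutive distinct scores (plus
    sentinels below/above the range); positive means ``score >= cutoff``.
    Ties in the Youden index break toward higher specificity.
    """
    s, y = _check_scores(scores, labels)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    n1 = int(y.sum())
    n0 = y.size - n1
    best = None
    for c in cands:
        pred = s >= c
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        sens = tp / n1
        spec = (n0 - fp) / n0
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, c, tp, fp)
    _, cutoff, tp, fp = best
    fn = n1 - tp
    tn = n0 - fp
    def frac(num, den):
        return {"value": num / den if den else np.nan, "num": num, "den": den}
    return {
        "cutoff": float(cutoff),
        "youden": best[0][0],
        "sensitivity": frac(tp, n1),
        "specificity": frac(tn, n0),
        "ppv": frac(tp, tp + fp),
        "npv": frac(tn, tn + fn),
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def hosmer_lemeshow(probabilities, labels, n_groups: int = 10) -> tuple[float, float, int]:
    """Hosmer-Lemeshow calibration chi-square over deciles of risk.

    Equal-count groups with tied probabilities kept together (groups are
    merged, with a warning, when there are fewer distinct probabilities
    than groups).  Returns (statistic, p, groups used); df = groups − 2.
    """
    p, y = _check_scores(probabilities, labels)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if p.size < 2 * n_groups:
        raise ValueError("need at least 2 observations per intended group")
    try:
        bins = pd.qcut(p, q=n_groups, duplicates="raise")
    except ValueError:
        logger.warning("tied probabilities: merging Hosmer-Lemeshow groups")
        bins = pd.qcut(p, q=n_groups, duplicates="drop")
    df_ = pd.DataFrame({"p": p, "y": y, "g": bins})
    stat = 0.0
    g_used = 0
    for _, grp in df_.groupby("g", observed=True):
        ng = len(grp)
        if ng == 0:
            continue
        o = grp["y"].sum()
        e = grp["p"].sum()
        pbar = e / ng
        denom = ng * pbar * (1.0 - pbar)
        if denom <= 0:
            continue
        stat += (o - e) ** 2 / denom
        g_used += 1
    dof = max(g_used - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, dof)), g_used


def decision_curve(probabilities, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit of treating at ``probability >= p_t`` across thresholds.

    NB(p_t) = TP/n − FP/n · p_t/(1−p_t), with treat-all and treat-none
    reference policies.
    """
    p, y = _check_scores(probabilities, labels)
    if thresholds is None:
        thresholds = np.arange(0.05, 0.96, 0.01)
    t = np.asarray(thresholds, dtype=float)
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    n = y.size
    prev = y.mean()
    rows = []
    for pt in t:
        pred = p >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        odds = pt / (1.0 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit": tp - fp * odds,
                "treat_all": prev - (1.0 - prev) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def precision_recall_curve(scores, labels) -> pd.DataFrame:
    """Precision-recall points over descending score thresholds."""
    s, y = _check_scores(scores, labels)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    precision = tp / (tp + fp)
    recall = tp / y.sum()
    return pd.DataFrame(
        {"threshold": s[order], "precision": precision, "recall": recall}
    )


# --------------------------------------------------------------------------
# cross-validation / subgroups / design
# --------------------------------------------------------------------------


def kfold_cv(
    data: pd.DataFrame,
    predictors: list[str],
    outcome: str = "response",
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold out-of-fold AUC for a logistic model."""
    from sklearn.model_selection import StratifiedKFold

    y = data[outcome].to_numpy(dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min(np.bincount(y)):
        raise ValueError("k exceeds the minority class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = data.iloc[train_idx]
        test = data.iloc[test_idx]
        rep = multivariable_logistic(train, predictors, outcome)
        Xte, _ = build_design(test, predictors)
        Xte = Xte.reindex(columns=rep.design_columns, fill_value=0.0)
        eta = rep.intercept + Xte.to_numpy() @ rep.terms["beta"].to_numpy()
        aucs.append(auc_mann_whitney(eta, y[test_idx]))
    aucs = np.array(aucs)
    return {
        "fold_auc": aucs,
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)),
    }


def subgroup_eval(
    data: pd.DataFrame,
    scores: np.ndarray,
    outcome: str,
    subgroup_vars: list[str],
) -> pd.DataFrame:
    """Fixed-model AUC within clinical subgroups (no refitting).

    Single-class subgroups are skipped with a warning row (auc = NaN).
    """
    scores = np.asarray(scores, dtype=float)
    rows = []
    for var in subgroup_vars:
        for level in sorted(map(str, data[var].unique())):
            sel = (data[var].astype(str) == level).to_numpy()
            y = data.loc[sel, outcome].to_numpy(dtype=int)
            if len(np.unique(y)) < 2:
                logger.warning("subgroup %s=%s has one class; skipped", var, level)
                rows.append(
                    {"variable": var, "level": level, "n": int(sel.sum()), "auc": np.nan}
                )
                continue
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "n": int(sel.sum()),
                    "auc": auc_mann_whitney(scores[sel], y),
                }
            )
    return pd.DataFrame(rows)


def _hanley_mcneil_var(auc: float, n_pos: float, n_neg: float) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc)
        + (n_pos - 1.0) * (q1 - auc**2)
        + (n_neg - 1.0) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def sample_size_auc(
    auc0: float,
    auc1: float,
    positive_fraction: float,
    alpha: float = 0.05,
    power: float = 0.90,
) -> int:
    """Smallest n for a two-sided test of AUC = auc0 against auc1.

    Normal approximation with Hanley-McNeil variances under the null and
    alternative; group sizes enter as fractions of n.
    """
    if not (0.5 <= auc0 < auc1 < 1.0):
        raise ValueError("need 0.5 <= auc0 < auc1 < 1")
    if not (0.0 < positive_fraction < 1.0):
        raise ValueError("positive_fraction must be in (0, 1)")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    delta = auc1 - auc0
    for n in range(4, 100_000):
        n_pos = positive_fraction * n
        n_neg = (1.0 - positive_fraction) * n
        if min(n_pos, n_neg) < 2:
            continue
        se0 = np.sqrt(_hanley_mcneil_var(auc0, n_pos, n_neg))
        se1 = np.sqrt(_hanley_mcneil_var(auc1, n_pos, n_neg))
        if za * se0 + zb * se1 <= delta:
            return n
    raise ValueError("no feasible sample size below 100000")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with its t-based two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need n >= 3 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
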