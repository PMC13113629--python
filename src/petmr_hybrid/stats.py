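"""Nonparametric univariate battery relating imaging parameters to biomarkers.

Spearman rank correlations (exact permutation p at small n), Mann-Whitney U
comparisons with Hodges-Lehmann shift estimates and Moses order-statistic
confidence intervals, Bonferroni family-wise correction, and ROC analysis with
a DeLong AUC interval and a Youden-index operating point.

The family-wise setup mirrors a 9-single + 14-hybrid parameter inventory:
factor 126 (= 9 x 14) for the single-vs-hybrid correlation matrix, factor 23
(= 9 + 14) for every biomarker association, and a matching
100 * (1 - 0.05/23) ~= 99.8% confidence level for the shift estimates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .quantify import FEATURE_DIRECTIONS, FEATURE_NAMES, HYBRID_PARAMS, SINGLE_PARAMS

#: per-biomarker Bonferroni factor (total parameter inventory)
DEFAULT_FACTOR = len(SINGLE_PARAMS) + len(HYBRID_PARAMS)
#: confidence level matching a 0.05 family-wise error split across the inventory
DEFAULT_CI_LEVEL = 1.0 - 0.05 / DEFAULT_FACTOR  # 0.99783, displayed as 99.8%

#: the five contrasts: (reference group, aggressive group); the aggressive
#: group is the ROC positive class and the HLE is reference minus aggressive.
CONTRASTS = (
    ("G1", "G2"),
    ("G1", "G3"),
    ("G2", "G3"),
    ("Ki67-", "Ki67+"),
    ("luminalA", "luminalB"),
)


@dataclass
class CorrelationResult:
    parameter: str
    biomarker: str
    rho: float
    p_raw: float
    p_adjusted: float
    correction_factor: int
    n: int


@dataclass
class GroupComparison:
    parameter: str
    contrast: str
    p_raw: float
    p_adjusted: float
    hle: float
    ci_low: float
    ci_high: float
    ci_level: float
    n1: int
    n2: int


@dataclass
class RocResult:
    parameter: str
    contrast: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    orientation: int


# ---------------------------------------------------------------------------
# Correlation


def _pairwise_valid(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation for n > ``exact_max_n`` and an exact
    permutation enumeration otherwise (all n! pairings of the observed ranks).
    A constant vector yields (nan, nan).
    """
    x, y = _pairwise_valid(x, y)
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 paired values")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > exact_max_n:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
        return rho, min(1.0, float(p))
    # exact permutation null: correlation is monotone in sum(rx * perm(ry))
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    obs = abs(float(rxc @ ryc)) / denom
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            stat = np.abs(ryc[np.array(chunk)] @ rxc) / denom
            count += int((stat >= obs - 1e-12).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        stat = np.abs(ryc[np.array(chunk)] @ rxc) / denom
        count += int((stat >= obs - 1e-12).sum())
        total += len(chunk)
    return rho, count / total


# ---------------------------------------------------------------------------
# Mann-Whitney / Hodges-Lehmann


def mann_whitney(x, y, exact_max_total: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first group, p).

    Exact enumeration when n1 + n2 <= ``exact_max_total`` and there are no
    ties, otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= exact_max_total and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def hodges_lehmann(x, y) -> float:
    """Median of all n1*n2 pairwise differences x_i - y_j."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return float(np.median(np.subtract.outer(x, y)))


@lru_cache(maxsize=256)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Null frequencies of the Mann-Whitney U statistic for group sizes
    (n1, n2), by the Gaussian-binomial convolution."""
    # Gaussian binomial [n1+n2, n1]_q = prod_i (1+...+q^{n2+i-1}) / (1+...+q^{i-1})
    poly = np.ones(1, dtype=object)
    for i in range(1, n1 + 1):
        poly = np.convolve(poly, np.ones(n2 + i, dtype=object))
        if i > 1:  # exact division by the all-ones polynomial of length i
            quotient = np.zeros(len(poly) - (i - 1), dtype=object)
            rem = poly.copy()
            for k in range(len(quotient)):
                quotient[k] = rem[k]
                for j in range(i):
                    rem[k + j] -= quotient[k]
            poly = quotient
    return tuple(int(c) for c in poly)


def _moses_k(n1: int, n2: int, alpha: float, exact_max_pairs: int = 400) -> int:
    """Largest k with P(U <= k) <= alpha/2 under H0; -1 when even U = 0 is too
    likely (degenerate interval)."""
    npairs = n1 * n2
    if npairs <= exact_max_pairs:
        counts = np.array(_u_counts(n1, n2), dtype=float)
        cdf = np.cumsum(counts) / counts.sum()
        ok = np.flatnonzero(cdf <= alpha / 2 + 1e-12)
        return int(ok[-1]) if ok.size else -1
    z = sps.norm.ppf(1.0 - alpha / 2)
    mu = npairs / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = math.floor(mu - z * sd)
    return max(-1, min(k, npairs // 2 - 1))


def hl_confidence_interval(x, y, level: float = DEFAULT_CI_LEVEL) -> tuple[float, float]:
    """Moses order-statistic confidence interval for the Hodges-Lehmann shift.

    With D the sorted pairwise differences and k the largest integer such that
    P(U <= k) <= alpha/2, the interval is (D_(k+1), D_(n1 n2 - k)). Small
    samples where no such k exists return the full difference range.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    k = _moses_k(x.size, y.size, 1.0 - level)
    if k < 0:
        return float(diffs[0]), float(diffs[-1])
    return float(diffs[k]), float(diffs[diffs.size - 1 - k])


# ---------------------------------------------------------------------------
# Multiple testing


def bonferroni(p_raw: float, factor: int) -> float:
    """Family-wise adjusted p-value, capped at 1."""
    if factor < 1:
        raise ValueError("correction factor must be >= 1")
    if math.isnan(p_raw):
        return math.nan
    return min(1.0, factor * p_raw)


def correction_factors(n_single: int = len(SINGLE_PARAMS), n_hybrid: int = len(HYBRID_PARAMS)) -> tuple[int, int]:
    """(matrix factor, per-biomarker factor) = (n_single * n_hybrid,
    n_single + n_hybrid)."""
    return n_single * n_hybrid, n_single + n_hybrid


# ---------------------------------------------------------------------------
# ROC


def _delong_se(oriented: np.ndarray, labels: np.ndarray, auc: float) -> float:
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    m, n = pos.size, neg.size
    # placement values
    v10 = np.empty(m)
    for i, xv in enumerate(pos):
        v10[i] = (np.sum(xv > neg) + 0.5 * np.sum(xv == neg)) / n
    v01 = np.empty(n)
    for j, yv in enumerate(neg):
        v01[j] = (np.sum(pos > yv) + 0.5 * np.sum(pos == yv)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return math.sqrt(s10 / m + s01 / n)


def roc_analysis(scores, labels, orientation: int = +1, ci_level: float = 0.95,
                 parameter: str = "", contrast: str = "") -> RocResult:
    """ROC analysis of a continuous score against binary labels.

    The score is oriented so that larger oriented values indicate the positive
    class; the AUC is the trapezoidal area (not forced above 0.5), its CI uses
    the DeLong variance, and the cutoff maximizes Youden's J (ties broken
    toward higher sensitivity, then toward the lower cutoff). The reported
    cutoff is on the original scale: positive calls are score >= cutoff when
    orientation is +1 and score <= cutoff when -1.
    """
    if orientation not in (+1, -1):
        raise ValueError("orientation must be +1 or -1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    oriented = orientation * scores
    auc = float(roc_auc_score(labels, oriented))
    se = _delong_se(oriented, labels, auc)
    z = sps.norm.ppf(0.5 + ci_level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)

    uniq = np.unique(oriented)
    if uniq.size == 1:
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    sens = np.array([(pos >= c).mean() for c in candidates])
    spec = np.array([(neg < c).mean() for c in candidates])
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(j >= best_j - 1e-12)
    tied = tied[sens[tied] >= sens[tied].max() - 1e-12]
    idx = int(tied[np.argmin(candidates[tied])])
    c = float(candidates[idx])
    tp = int((pos >= c).sum())
    fn = int((pos < c).sum())
    tn = int((neg < c).sum())
    fp = int((neg >= c).sum())
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) else math.nan
    npv = 100.0 * tn / (tn + fn) if (tn + fn) else math.nan
    return RocResult(
        parameter=parameter,
        contrast=contrast,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        cutoff=orientation * c,
        sensitivity=100.0 * sens[idx],
        specificity=100.0 * spec[idx],
        ppv=ppv,
        npv=npv,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# Battery


def _contrast_masks(histo: pd.DataFrame) -> dict[str, tuple[pd.Series, pd.Series]]:
    """Boolean row masks (reference, aggressive) for each contrast."""
    return {
        "G1 vs G2": (histo["grade"] == "G1", histo["grade"] == "G2"),
        "G1 vs G3": (histo["grade"] == "G1", histo["grade"] == "G3"),
        "G2 vs G3": (histo["grade"] == "G2", histo["grade"] == "G3"),
        "Ki67- vs Ki67+": (~histo["ki67_pos"].astype(bool), histo["ki67_pos"].astype(bool)),
        "luminalA vs luminalB": (histo["subtype"] == "luminalA", histo["subtype"] == "luminalB"),
    }


@dataclass
class BatteryResult:
    correlations: pd.DataFrame
    cross_correlations: pd.DataFrame | None
    comparisons: pd.DataFrame
    roc: pd.DataFrame | None
    warnings: list[str]


def run_univariate_battery(
    features: pd.DataFrame,
    histopath: pd.DataFrame,
    ci_level: float = DEFAULT_CI_LEVEL,
    bonferroni_factor: int | None = None,
    contrasts: list[str] | None = None,
    do_correlations: bool = True,
    do_cross_correlations: bool = True,
    do_roc: bool = True,
) -> BatteryResult:
    """Full univariate procedure on a features table and a histopathology
    table sharing a ``lesion_id`` column.

    Produces: 23 x {ER%, PgR%, Ki67%} Spearman correlations (factor 23), the
    9 x 14 single-vs-hybrid correlation matrix (factor 126), 23 x 5 group
    comparisons with Hodges-Lehmann estimates and 99.8% intervals (factor 23),
    and a ROC row per parameter x contrast. Missing values are dropped
    pairwise per parameter; a contrast with an empty class is skipped with a
    warning.
    """
    factor_matrix, factor_biomarker = correction_factors()
    if bonferroni_factor is not None:
        factor_biomarker = bonferroni_factor
    merged = features.merge(histopath, on="lesion_id", suffixes=("", "_histo"))
    warnings: list[str] = []

    corr_rows = []
    if do_correlations:
        for biomarker in ("er_pct", "pgr_pct", "ki67_pct"):
            for param in FEATURE_NAMES:
                xv, yv = _pairwise_valid(merged[param], merged[biomarker])
                if xv.size < 3:
                    warnings.append(f"correlation {param} vs {biomarker}: <3 valid pairs, skipped")
                    continue
                rho, p = spearman(xv, yv)
                corr_rows.append(
                    CorrelationResult(param, biomarker, rho, p, bonferroni(p, factor_biomarker), factor_biomarker, xv.size).__dict__
                )
    correlations = pd.DataFrame(corr_rows)

    cross = None
    if do_cross_correlations:
        cross_rows = []
        for single in SINGLE_PARAMS:
            for hybrid in HYBRID_PARAMS:
                xv, yv = _pairwise_valid(merged[single], merged[hybrid])
                if xv.size < 3:
                    continue
                rho, p = spearman(xv, yv)
                cross_rows.append(
                    CorrelationResult(hybrid, single, rho, p, bonferroni(p, factor_matrix), factor_matrix, xv.size).__dict__
                )
        cross = pd.DataFrame(cross_rows)

    comp_rows = []
    roc_rows = []
    masks = _contrast_masks(merged)
    wanted = contrasts if contrasts is not None else list(masks)
    for contrast in wanted:
        ref_mask, pos_mask = masks[contrast]
        if ref_mask.sum() < 2 or pos_mask.sum() < 2:
            warnings.append(f"contrast {contrast}: a class has <2 lesions, skipped")
            continue
        for param in FEATURE_NAMES:
            x = merged.loc[ref_mask, param].to_numpy(dtype=float)
            y = merged.loc[pos_mask, param].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            y = y[np.isfinite(y)]
            if x.size < 2 or y.size < 2:
                warnings.append(f"{param} on {contrast}: <2 valid values in a class, skipped")
                continue
            _, p = mann_whitney(x, y)
            hle = hodges_lehmann(x, y)
            lo, hi = hl_confidence_interval(x, y, ci_level)
            comp_rows.append(
                GroupComparison(param, contrast, p, bonferroni(p, factor_biomarker), hle, lo, hi, ci_level, x.size, y.size).__dict__
            )
            if do_roc:
                scores = np.concatenate([x, y])
                labels = np.concatenate([np.zeros(x.size, int), np.ones(y.size, int)])
                roc_rows.append(
                    roc_analysis(scores, labels, FEATURE_DIRECTIONS[param], parameter=param, contrast=contrast).__dict__
                )
    comparisons = pd.DataFrame(comp_rows)
    roc = pd.DataFrame(roc_rows) if do_roc else None
    return BatteryResult(correlations, cross, comparisons, roc, warnings)
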