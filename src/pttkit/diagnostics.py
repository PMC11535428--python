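"""Diagnostic-accuracy statistics for transit-time biomarkers.

Everything needed to evaluate PTT/nPTT as a rule-out test for relevant
diastolic dysfunction (DD) and mitral regurgitation (MVR):

* AUC as the tie-corrected pairwise probability that a positive scores
  higher than a negative (equivalently the normalized Mann–Whitney rank-sum
  statistic), with a stratified percentile bootstrap CI and a rank-sum
  p-value against AUC = 0.5.
* Confusion-matrix metrics at a threshold (higher score ⇒ test positive,
  matching "high PTT suggests disease; PTT < 8 s rules it out"), and
  threshold selection at a target specificity or sensitivity.
* PTT stratification tables (percent positive per PTT bin), quartile
  baseline tables, Kruskal–Wallis / rank-sum / t-test group comparisons,
  Pearson/Spearman correlations, and a Kolmogorov–Smirnov normality check.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import PatientRecord, cohort_to_dataframe

__all__ = [
    "AUCResult",
    "ThresholdMetrics",
    "StratumTable",
    "GroupComparison",
    "QuartileTable",
    "roc_auc",
    "evaluate_auc",
    "bootstrap_ci",
    "auc_p_value",
    "roc_curve_points",
    "threshold_metrics",
    "threshold_at_specificity",
    "threshold_at_sensitivity",
    "stratify_by_ptt",
    "quartile_table",
    "group_compare",
    "correlate",
    "ks_normality",
    "round_half_up_percent",
]

logger = logging.getLogger(__name__)


def round_half_up_percent(numerator: float, denominator: float) -> int:
    """Percent rounded half-up to the nearest integer (87.5% → 88)."""
    if denominator == 0:
        raise ZeroDivisionError("empty stratum")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


@dataclass(frozen=True)
class AUCResult:
    """AUC with a bootstrap CI, rank-sum p-value and resampling metadata."""

    auc: float
    n_pos: int
    n_neg: int
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must be in [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("percentile CI must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "n_pos": self.n_pos, "n_neg": self.n_neg,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n_boot": self.n_boot,
            "alpha": self.alpha, "seed": self.seed,
        }


def roc_auc(scores, labels) -> float:
    """Tie-corrected AUC: P(score_pos > score_neg) + ½·P(tie).

    Computed from midranks of the pooled sample, which is exactly the
    pairwise count (positive-over-negative pairs, ties ½) divided by
    n_pos·n_neg.
    """
    pos, neg = _split_scores(scores, labels)
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def _auc_from_rank_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC for (B, n_pos) and (B, n_neg) resample matrices."""
    pooled = np.concatenate([pos, neg], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    r_pos = ranks[:, : pos.shape[1]].sum(axis=1)
    n_pos, n_neg = pos.shape[1], neg.shape[1]
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_ci(
    scores, labels, n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Resampling is within each class (preserving n_pos and n_neg), so no
    resample can lose a class.  Percentile interval at level ``1 − alpha``.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is small; percentile CI will be unstable", n_boot)
    pos, neg = _split_scores(scores, labels)
    rng = np.random.default_rng(seed)
    pos_rs = rng.choice(pos, size=(n_boot, pos.size), replace=True)
    neg_rs = rng.choice(neg, size=(n_boot, neg.size), replace=True)
    aucs = _auc_from_rank_matrix(pos_rs, neg_rs)
    lo, hi = np.percentile(aucs, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    return float(lo), float(hi)


def auc_p_value(scores, labels) -> float:
    """Two-sided Mann–Whitney rank-sum p-value for the null AUC = 0.5.

    Normal approximation with tie and continuity correction.  Degenerate
    samples with zero rank variance (all observations tied) carry no
    evidence and return 1.0.
    """
    pos, neg = _split_scores(scores, labels)
    if np.ptp(np.concatenate([pos, neg])) == 0.0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(
            pos, neg, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(res.pvalue)
    return 1.0 if not math.isfinite(p) else min(p, 1.0)


def evaluate_auc(
    scores, labels, n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
) -> AUCResult:
    """Point AUC + stratified bootstrap CI + rank-sum p-value in one result."""
    pos, neg = _split_scores(scores, labels)
    auc = roc_auc(scores, labels)
    ci_low, ci_high = bootstrap_ci(scores, labels, n_boot=n_boot, alpha=alpha, seed=seed)
    # the percentile interval is random; clamp so it always brackets the point
    ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    return AUCResult(
        auc=auc, n_pos=pos.size, n_neg=neg.size,
        ci_low=ci_low, ci_high=ci_high,
        p_value=auc_p_value(scores, labels),
        n_boot=n_boot, alpha=alpha, seed=seed,
    )


# ---------------------------------------------------------------------------
# Threshold metrics
# ---------------------------------------------------------------------------

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion counts and proportions at one decision threshold.

    ``direction`` is always "higher_is_positive": test positive ⇔ score ≥
    threshold.  Proportions with a zero denominator are NaN and listed in
    ``undefined``.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    direction: str = "higher_is_positive"
    undefined: frozenset = frozenset()

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "direction": self.direction,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "undefined": sorted(self.undefined),
        }


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return UNDEFINED
    return num / den


def threshold_metrics(
    scores, labels, threshold: float, positive_if: str = "score_ge"
) -> ThresholdMetrics:
    """Confusion matrix with "test positive" ⇔ score ≥ threshold."""
    if positive_if != "score_ge":
        raise ValueError("only positive_if='score_ge' is supported")
    if not math.isfinite(threshold) and not math.isinf(threshold):
        raise ValueError("threshold must be finite or ±inf")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    undefined: set[str] = set()
    return ThresholdMetrics(
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn, "sensitivity", undefined),
        specificity=_ratio(tn, tn + fp, "specificity", undefined),
        ppv=_ratio(tp, tp + fp, "ppv", undefined),
        npv=_ratio(tn, tn + fn, "npv", undefined),
        undefined=frozenset(undefined),
    )


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique scores, plus ±inf."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve: (1−specificity, sensitivity) at every candidate
    threshold, sorted for trapezoidal integration."""
    scores = np.asarray(scores, dtype=float)
    rows = []
    for thr in _candidate_thresholds(scores):
        m = threshold_metrics(scores, labels, thr)
        rows.append({"threshold": thr, "fpr": 1.0 - m.specificity, "tpr": m.sensitivity})
    df = pd.DataFrame(rows).sort_values(["fpr", "tpr"]).reset_index(drop=True)
    return df


def _select_threshold(
    scores, labels, target: float, which: str
) -> tuple[float, ThresholdMetrics, bool]:
    scores = np.asarray(scores, dtype=float)
    _split_scores(scores, labels)  # validate both classes present
    candidates = _candidate_thresholds(scores)
    metrics = [threshold_metrics(scores, labels, thr) for thr in candidates]

    def primary(m: ThresholdMetrics) -> float:
        return m.specificity if which == "specificity" else m.sensitivity

    def secondary(m: ThresholdMetrics) -> float:
        return m.sensitivity if which == "specificity" else m.specificity

    eligible = [m for m in metrics if primary(m) >= target]
    if not eligible:
        # unreachable target: return the boundary threshold maximizing it
        best = max(metrics, key=lambda m: (primary(m), secondary(m)))
        return best.threshold, best, False
    best_primary = min(primary(m) for m in eligible)
    tied = [m for m in eligible if primary(m) == best_primary]
    best = max(tied, key=secondary)
    return best.threshold, best, True


def threshold_at_specificity(
    scores, labels, target_spec: float = 0.70
) -> tuple[float, ThresholdMetrics]:
    """Smallest-specificity threshold with specificity ≥ target.

    Among candidate thresholds (midpoints of adjacent unique scores and
    ±inf) the one whose specificity is the smallest value ≥ ``target_spec``
    is returned; ties break toward higher sensitivity.  A threshold of
    +inf always reaches specificity 1, so the target is always attainable.
    """
    thr, m, ok = _select_threshold(scores, labels, target_spec, "specificity")
    if not ok:
        logger.warning("specificity target %.3f unreachable; returning boundary", target_spec)
    return thr, m


def threshold_at_sensitivity(
    scores, labels, target_sens: float = 0.70
) -> tuple[float, ThresholdMetrics]:
    """Smallest-sensitivity threshold with sensitivity ≥ target; ties break
    toward higher specificity."""
    thr, m, ok = _select_threshold(scores, labels, target_sens, "sensitivity")
    if not ok:
        logger.warning("sensitivity target %.3f unreachable; returning boundary", target_sens)
    return thr, m


# ---------------------------------------------------------------------------
# Stratification and quartile tables
# ---------------------------------------------------------------------------

OUTCOMES = ("dd_relevant", "mvr_relevant", "dd_or_mvr")


def _as_cohort_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return cohort_to_dataframe(list(records))


def _outcome_column(df: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "dd_or_mvr":
        return (df["dd_relevant"].to_numpy(bool) | df["mvr_relevant"].to_numpy(bool))
    if outcome in ("dd_relevant", "mvr_relevant"):
        return df[outcome].to_numpy(bool)
    raise ValueError(f"outcome must be one of {OUTCOMES}")


@dataclass(frozen=True)
class StratumTable:
    """Counts and percent positive per PTT bin.

    With edges (e1, e2) the bins are [<e1), [e1, e2), [≥e2); percentages
    are rounded half-up to whole percent.
    """

    edges: tuple[float, ...]
    n: tuple[int, ...]
    n_positive: tuple[int, ...]
    pct_positive: tuple[int, ...]
    outcome: str = "dd_or_mvr"

    @property
    def n_total(self) -> int:
        return sum(self.n)

    def pooled_percent_above_first_edge(self) -> int:
        """Percent positive among everyone at or above the first edge —
        the positivity of the "test positive" (high-PTT) group."""
        return round_half_up_percent(sum(self.n_positive[1:]), sum(self.n[1:]))

    def to_dataframe(self) -> pd.DataFrame:
        labels = []
        bounds = (-math.inf, *self.edges, math.inf)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if math.isinf(lo):
                labels.append(f"< {hi:g}")
            elif math.isinf(hi):
                labels.append(f">= {lo:g}")
            else:
                labels.append(f"{lo:g}-{hi:g}")
        return pd.DataFrame(
            {"bin": labels, "n": self.n, "n_positive": self.n_positive,
             "pct_positive": self.pct_positive}
        )


def stratify_by_ptt(
    records, edges: tuple[float, float] = (8.0, 12.0), outcome: str = "dd_or_mvr",
    variable: str = "ptt_s",
) -> StratumTable:
    """Bin a cohort by PTT and count outcome-positive patients per bin."""
    df = _as_cohort_frame(records)
    if len(df) == 0:
        raise ValueError("records must be nonempty")
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    values = df[variable].to_numpy(float)
    positive = _outcome_column(df, outcome)
    bounds = (-math.inf, *edges, math.inf)
    ns, pos_ns, pcts = [], [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        in_bin = (values >= lo) & (values < hi)
        n = int(in_bin.sum())
        n_pos = int(positive[in_bin].sum())
        ns.append(n)
        pos_ns.append(n_pos)
        pcts.append(round_half_up_percent(n_pos, n) if n else 0)
    return StratumTable(edges=edges, n=tuple(ns), n_positive=tuple(pos_ns),
                        pct_positive=tuple(pcts), outcome=outcome)


@dataclass(frozen=True)
class QuartileTable:
    """Quartile groups of a ranking variable with per-group summaries."""

    variable: str
    boundaries: tuple[float, float, float]  # Q1, Q2, Q3 (25th/50th/75th pct)
    group: np.ndarray  # per-record group index 1..4
    sizes: tuple[int, int, int, int]
    summary: pd.DataFrame  # tidy: covariate, stat, Q1..Q4


def quartile_table(
    records, variable: str = "nptt", covariates: list[str] | None = None
) -> QuartileTable:
    """Assign quartile groups and summarize covariates per group.

    Boundaries are the 25th/50th/75th percentiles with linear interpolation.
    Assignment is half-open upward: group 1 is v ≤ Q1, group 2 is
    Q1 < v ≤ Q2, etc., so identical values all land in group 1.  Numeric
    covariates are summarized as median and IQR, binary ones as percent.
    """
    df = _as_cohort_frame(records)
    if len(df) < 4:
        raise ValueError("need at least 4 records for quartiles")
    v = df[variable].to_numpy(float)
    q1, q2, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    group = 1 + (v > q1).astype(int) + (v > q2).astype(int) + (v > q3).astype(int)
    sizes = tuple(int(np.sum(group == g)) for g in (1, 2, 3, 4))

    if covariates is None:
        covariates = [c for c in df.columns
                      if c not in (variable, "patient_id") and df[c].dtype != object]
    rows = []
    for cov in covariates:
        col = df[cov]
        is_binary = col.dtype == bool or set(pd.unique(col)) <= {0, 1, True, False}
        for g in (1, 2, 3, 4):
            vals = col.to_numpy()[group == g]
            if is_binary:
                rows.append((cov, "pct", g,
                             100.0 * float(np.mean(vals.astype(float))) if vals.size else UNDEFINED))
            else:
                vals = vals.astype(float)
                med = float(np.median(vals)) if vals.size else UNDEFINED
                lo, hi = (np.percentile(vals, [25, 75]) if vals.size else (UNDEFINED, UNDEFINED))
                rows.append((cov, "median", g, med))
                rows.append((cov, "q25", g, float(lo)))
                rows.append((cov, "q75", g, float(hi)))
    tidy = pd.DataFrame(rows, columns=["covariate", "stat", "group", "value"])
    summary = tidy.pivot_table(index=["covariate", "stat"], columns="group",
                               values="value").rename(columns=lambda g: f"Q{g}")
    return QuartileTable(
        variable=variable, boundaries=(float(q1), float(q2), float(q3)),
        group=group, sizes=sizes, summary=summary.reset_index(),
    )


# ---------------------------------------------------------------------------
# Group comparisons, correlations, normality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    test_name: str


def ks_normality(values) -> float:
    """Kolmogorov–Smirnov p-value against a normal with the sample moments."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest((x - x.mean()) / sd, "norm").pvalue)


def group_compare(values, group_labels, test: str = "auto",
                  normality_alpha: float = 0.05) -> GroupComparison:
    """Compare a continuous variable across groups.

    ``test="auto"``: Kruskal–Wallis (tie-corrected) for more than two
    groups, Wilcoxon rank-sum (Mann–Whitney, asymptotic with tie
    correction) for two.  ``test="ttest"`` requests Student's t for two
    groups but falls back to the rank-sum test — with a warning — unless a
    KS normality check passes in both groups and each has ≥ 2 observations.
    ``test="kruskal"`` or ``"ranksum"`` force the respective test.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group_labels must have equal length")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")

    if test == "auto":
        test = "kruskal" if len(groups) > 2 else "ranksum"
    if test == "kruskal":
        stat, p = stats.kruskal(*groups)
        return GroupComparison(float(stat), float(p), "kruskal-wallis")
    if len(groups) != 2:
        raise ValueError(f"test {test!r} requires exactly 2 groups")
    a, b = groups
    if test == "ttest":
        def _normalish(g: np.ndarray) -> bool:
            return g.size >= 3 and ks_normality(g) > normality_alpha

        if _normalish(a) and _normalish(b):
            stat, p = stats.ttest_ind(a, b)
            return GroupComparison(float(stat), float(p), "t-test")
        logger.warning("t-test requested but normality/size check failed; using rank-sum")
        test = "ranksum"
    if test == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return GroupComparison(float(res.statistic), float(res.pvalue), "rank-sum")
    raise ValueError(f"unknown test {test!r}")


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank correlation.

    Returns NaN (undefined) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1D of equal length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")
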