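"""ROC analysis for ordinal risk scores: AUC, Youden cutpoints, and
DeLong's test for paired (correlated) AUC comparison.

Orientation is fixed, not auto-detected: higher score means higher
predicted mortality risk, and the positive class is death.  The
classification rule at cutpoint ``c`` is "score >= c -> predicted death";
candidate cutpoints are the observed unique score values (the indices are
small integers, so no interpolated thresholds are used).

The AUC is the normalized Mann-Whitney statistic

    AUC = (1 / (m * n)) * sum_{i in pos} sum_{j in neg} psi(s_i, s_j),

with psi = 1 if s_i > s_j, 1/2 on ties, 0 otherwise — identical to the
trapezoidal area under the empirical ROC curve.  DeLong's variance
estimator is built from placement values: V10_i (fraction of negatives a
positive outscores) and V01_j (fraction of positives outscoring a
negative), with unbiased (m-1, n-1) covariance divisors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateVarianceError, UndefinedAUCError
from .records import PatientRecord
from .scoring import AugmentationRule, IndexDefinition, score_cohort

__all__ = [
    "RocCurve",
    "CutpointResult",
    "DeLongResult",
    "IndexComparison",
    "auc",
    "roc_curve",
    "youden_cutpoint",
    "delong_test",
    "auc_confidence_interval",
    "compare_indices",
]

_VAR_EPS = 1e-300


def _validate(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.ndim != 1 or y.ndim != 1 or s.shape != y.shape:
        raise ValueError("scores and outcomes must be 1-d sequences of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise UndefinedAUCError(
            "AUC is undefined: outcome vector contains a single class "
            f"({int(y.sum())} positive of {y.size})"
        )
    return s, y


def auc(scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Mann-Whitney AUC (ties credited 1/2), via midranks."""
    s, y = _validate(scores, outcomes)
    m = int(y.sum())
    n = y.size - m
    ranks = rankdata(s)
    return (ranks[y].sum() - m * (m + 1) / 2.0) / (m * n)


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve over the observed unique score values.

    ``thresholds`` are descending; point ``i+1`` of (``fpr``, ``tpr``)
    corresponds to the rule "score >= thresholds[i]", and point 0 is the
    (0, 0) endpoint (predict nobody positive).  The lowest threshold
    classifies everyone positive, so the curve always ends at (1, 1).
    Integer true/false-positive counts are kept alongside the rates so
    downstream tie-breaking can use exact arithmetic.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    tp_counts: np.ndarray
    fp_counts: np.ndarray
    n_pos: int
    n_neg: int

    def trapezoidal_area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores: Sequence[float], outcomes: Sequence[bool]) -> RocCurve:
    """ROC curve whose trapezoidal area equals :func:`auc` exactly."""
    s, y = _validate(scores, outcomes)
    m = int(y.sum())
    n = y.size - m
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # last occurrence of each distinct score in the descending order
    distinct_last = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    tp = np.cumsum(y_sorted)[distinct_last]
    fp = np.cumsum(~y_sorted)[distinct_last]
    thresholds = s_sorted[distinct_last]
    tp = np.r_[0, tp]
    fp = np.r_[0, fp]
    return RocCurve(
        thresholds=thresholds,
        fpr=fp / n,
        tpr=tp / m,
        tp_counts=tp,
        fp_counts=fp,
        n_pos=m,
        n_neg=n,
    )


@dataclass(frozen=True)
class CutpointResult:
    """Operating point of the rule "score >= cutpoint -> predicted death"."""

    cutpoint: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def youden_cutpoint(curve: RocCurve) -> CutpointResult:
    """Cutpoint maximizing Youden's J = sensitivity + specificity - 1.

    Ties on J are broken toward the LOWEST threshold (the most sensitive
    rule — prognostic screening favors sensitivity).  The comparison uses
    exact integer arithmetic (J ranked by tp*n_neg - fp*n_pos), so equal
    rational J values tie exactly regardless of float rounding.
    """
    tp = curve.tp_counts[1:]
    fp = curve.fp_counts[1:]
    j_scaled = tp * curve.n_neg - fp * curve.n_pos  # J * (n_pos * n_neg)
    best = int(np.flatnonzero(j_scaled == j_scaled.max())[-1])  # descending -> last = lowest
    return CutpointResult(
        cutpoint=float(curve.thresholds[best]),
        sensitivity=tp[best] / curve.n_pos,
        specificity=1.0 - fp[best] / curve.n_neg,
    )


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 over positives, V01 over negatives),
    computed from midranks in O(N log N)."""
    m = int(y.sum())
    n = y.size - m
    ranks_all = rankdata(s)
    ranks_pos = rankdata(s[y])
    ranks_neg = rankdata(s[~y])
    v10 = (ranks_all[y] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[~y] - ranks_neg) / m
    return v10, v01


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two AUCs measured on the same patients."""

    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float

    @property
    def auc_difference(self) -> float:
        return self.auc_a - self.auc_b


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[bool],
) -> DeLongResult:
    """DeLong's asymptotic test for two correlated ROC curves.

    Both score vectors must be aligned to the same patients.  Returns the
    two AUCs, the variance of their difference, the z statistic and the
    two-sided normal p-value.  Identical curves (var_diff = 0 with equal
    AUCs) give z = 0, p = 1; zero variance with differing AUCs raises
    :class:`DegenerateVarianceError`.
    """
    sa, y = _validate(scores_a, outcomes)
    sb, y2 = _validate(scores_b, outcomes)
    if not np.array_equal(y, y2):
        raise ValueError("outcome vectors must be identical (paired design)")
    m = int(y.sum())
    n = y.size - m
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs at least 2 positives and 2 negatives")
    v10_a, v01_a = _placements(sa, y)
    v10_b, v01_b = _placements(sb, y)
    # report AUCs via the shared Mann-Whitney routine so every AUC in the
    # package is bitwise identical to a direct auc() call (the placement
    # mean equals it mathematically but can differ in the last ulp)
    auc_a = auc(sa, y)
    auc_b = auc(sb, y)
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var_diff = float(
        (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    )
    var_diff = max(var_diff, 0.0)  # guard tiny negative rounding
    diff = auc_a - auc_b
    if var_diff <= _VAR_EPS:
        if abs(diff) <= 1e-12:
            return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_diff=0.0, z=0.0, p_value=1.0)
        raise DegenerateVarianceError(
            f"zero DeLong variance with differing AUCs ({auc_a:.6f} vs {auc_b:.6f})"
        )
    z = diff / np.sqrt(var_diff)
    p = 2.0 * norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_diff=var_diff, z=float(z), p_value=float(p))


def auc_confidence_interval(
    scores: Sequence[float], outcomes: Sequence[bool], level: float = 0.95
) -> tuple[float, float, float]:
    """(AUC, lower, upper) normal CI from the single-curve DeLong variance.

    Not part of the source analysis tables; provided as plumbing.
    """
    s, y = _validate(scores, outcomes)
    m = int(y.sum())
    n = y.size - m
    v10, v01 = _placements(s, y)
    a = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n) if m > 1 and n > 1 else np.nan
    half = norm.ppf(0.5 + level / 2.0) * np.sqrt(var)
    return a, max(0.0, a - half), min(1.0, a + half)


@dataclass(frozen=True)
class IndexComparison:
    """Base-vs-augmented evaluation of one index family at one horizon:
    exactly the cells of the source's per-horizon result tables."""

    index: str
    horizon: str
    auc_base: float
    auc_augmented: float
    cutpoint_base: CutpointResult
    cutpoint_augmented: CutpointResult
    delong: DeLongResult


def _outcomes_at(records: Sequence[PatientRecord], horizon: str) -> np.ndarray:
    if horizon not in ("1y", "3y"):
        raise ValueError(f"horizon must be '1y' or '3y', got {horizon!r}")
    attr = "dead_1y" if horizon == "1y" else "dead_3y"
    return np.array([getattr(r, attr) for r in records], dtype=bool)


def compare_indices(
    records: Sequence[PatientRecord],
    index: IndexDefinition,
    rule: AugmentationRule,
    horizon: str,
) -> IndexComparison:
    """Evaluate base and anemia-augmented scores against one mortality
    horizon: AUCs, Youden operating points, and the paired DeLong test."""
    table = score_cohort(records, index, rule)
    y = _outcomes_at(records, horizon)
    base = table["base_score"].to_numpy(dtype=float)
    augmented = table["augmented_score"].to_numpy(dtype=float)
    curve_base = roc_curve(base, y)
    curve_aug = roc_curve(augmented, y)
    dl = delong_test(augmented, base, y)  # auc_a = augmented, auc_b = base
    return IndexComparison(
        index=index.name,
        horizon=horizon,
        auc_base=dl.auc_b,
        auc_augmented=dl.auc_a,
        cutpoint_base=youden_cutpoint(curve_base),
        cutpoint_augmented=youden_cutpoint(curve_aug),
        delong=dl,
    )
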