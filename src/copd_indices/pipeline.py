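"""End-to-end evaluation of the four indices on a cohort.

``run_analysis`` reproduces the study's result structure: per index
(BODEx, BODEx-A3, ADO, ADO-A3) and horizon (1y, 3y) the AUC and the
Youden operating point; per base/augmented pair and horizon the paired
DeLong comparison; plus the anemia-weight sweep (1..4 points) and, as an
appendix beyond the source tables, cross-family comparisons (BODEx vs
ADO).  The report is a pure function of the cohort and the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedAUCError
from .records import PatientRecord, classify_anemia
from .roc import RocCurve, auc, compare_indices, delong_test, roc_curve
from .scoring import ADO, BODEX, AugmentationRule, IndexDefinition, score_cohort

__all__ = ["AnalysisReport", "run_analysis", "sweep_anemia_points"]

logger = logging.getLogger("copd_indices")

HORIZONS = ("1y", "3y")
FAMILIES: tuple[IndexDefinition, ...] = (BODEX, ADO)
ALPHA = 0.05


@dataclass
class AnalysisReport:
    """Full evaluation of one cohort.

    ``cells`` holds one row per index x horizon (8 with both horizons
    evaluable); ``comparisons`` one DeLong row per family x horizon (4);
    ``sweep`` the anemia-weight sweep table; ``cross_family`` the appendix
    comparisons.  ``horizon_errors`` records horizons that could not be
    evaluated (single outcome class) without failing the other horizon.
    """

    anemia_points: int
    cells: pd.DataFrame
    comparisons: pd.DataFrame
    sweep: pd.DataFrame
    cross_family: pd.DataFrame
    roc_curves: dict[tuple[str, str], RocCurve] = field(default_factory=dict)
    horizon_errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Result-table-shaped frame: index, horizon, auc, sensitivity,
        specificity, cutpoint, p_value (p on augmented rows)."""
        merged = self.cells.copy()
        pvals = {
            (row["index_augmented"], row["horizon"]): row["p_value"]
            for _, row in self.comparisons.iterrows()
        }
        merged["p_value"] = [
            pvals.get((row["index"], row["horizon"]), np.nan)
            for _, row in merged.iterrows()
        ]
        return merged[
            ["index", "horizon", "auc", "sensitivity", "specificity", "cutpoint", "p_value"]
        ]

    def roc_coordinates(self) -> pd.DataFrame:
        """Long-format ROC coordinates (index, horizon, threshold, fpr, tpr)
        for redrawing the curves."""
        rows = []
        for (name, horizon), curve in sorted(self.roc_curves.items()):
            for i, thr in enumerate(curve.thresholds):
                rows.append({
                    "index": name, "horizon": horizon, "threshold": thr,
                    "fpr": curve.fpr[i + 1], "tpr": curve.tpr[i + 1],
                })
        return pd.DataFrame(rows, columns=["index", "horizon", "threshold", "fpr", "tpr"])


def _outcome_vector(records: Sequence[PatientRecord], horizon: str) -> np.ndarray:
    attr = "dead_1y" if horizon == "1y" else "dead_3y"
    return np.array([getattr(r, attr) for r in records], dtype=bool)


def run_analysis(
    records: Sequence[PatientRecord],
    anemia_points: int = 3,
    sweep_points: Sequence[int] = (1, 2, 3, 4),
) -> AnalysisReport:
    """Score and evaluate a cohort at both horizons; deterministic."""
    if not records:
        raise ValueError("empty cohort")
    rule = AugmentationRule(anemia_points)
    logger.info("analysis: %d records, anemia_points=%d", len(records), anemia_points)
    n_anemic = sum(classify_anemia(r.hemoglobin, r.sex) for r in records)
    logger.info("anemia: %d/%d records (%.1f%%)", n_anemic, len(records),
                100.0 * n_anemic / len(records))

    cell_rows, cmp_rows, cross_rows = [], [], []
    curves: dict[tuple[str, str], RocCurve] = {}
    horizon_errors: dict[str, str] = {}
    family_scores: dict[tuple[str, str], np.ndarray] = {}

    for horizon in HORIZONS:
        y = _outcome_vector(records, horizon)
        try:
            for index in FAMILIES:
                comp = compare_indices(records, index, rule, horizon)
                aug_name = index.name + rule.label_suffix
                table = score_cohort(records, index, rule)
                base = table["base_score"].to_numpy(dtype=float)
                augmented = table["augmented_score"].to_numpy(dtype=float)
                family_scores[(index.name, horizon)] = base
                family_scores[(aug_name, horizon)] = augmented
                curves[(index.name, horizon)] = roc_curve(base, y)
                curves[(aug_name, horizon)] = roc_curve(augmented, y)
                for name, a, cut in (
                    (index.name, comp.auc_base, comp.cutpoint_base),
                    (aug_name, comp.auc_augmented, comp.cutpoint_augmented),
                ):
                    cell_rows.append({
                        "index": name, "horizon": horizon, "auc": a,
                        "cutpoint": cut.cutpoint, "sensitivity": cut.sensitivity,
                        "specificity": cut.specificity, "youden_j": cut.youden_j,
                    })
                    logger.info("%s @ %s: AUC=%.3f cutpoint=%g sens=%.2f spec=%.2f",
                                name, horizon, a, cut.cutpoint, cut.sensitivity,
                                cut.specificity)
                dl = comp.delong
                cmp_rows.append({
                    "index_base": index.name, "index_augmented": aug_name,
                    "horizon": horizon, "auc_base": dl.auc_b, "auc_augmented": dl.auc_a,
                    "z": dl.z, "p_value": dl.p_value,
                    "significant": dl.p_value < ALPHA,
                })
        except UndefinedAUCError as err:
            horizon_errors[horizon] = str(err)
            logger.warning("horizon %s not evaluable: %s", horizon, err)
            continue
        # appendix: cross-family comparison of the base indices (beyond the
        # source tables, which compare within-family only)
        dl = delong_test(
            family_scores[("ADO", horizon)], family_scores[("BODEx", horizon)], y
        )
        cross_rows.append({
            "index_a": "ADO", "index_b": "BODEx", "horizon": horizon,
            "auc_a": dl.auc_a, "auc_b": dl.auc_b, "z": dl.z, "p_value": dl.p_value,
        })

    sweep = sweep_anemia_points(records, sweep_points, horizons=[
        h for h in HORIZONS if h not in horizon_errors
    ])
    return AnalysisReport(
        anemia_points=anemia_points,
        cells=pd.DataFrame(cell_rows, columns=[
            "index", "horizon", "auc", "cutpoint", "sensitivity", "specificity", "youden_j",
        ]),
        comparisons=pd.DataFrame(cmp_rows, columns=[
            "index_base", "index_augmented", "horizon", "auc_base", "auc_augmented",
            "z", "p_value", "significant",
        ]),
        sweep=sweep,
        cross_family=pd.DataFrame(cross_rows, columns=[
            "index_a", "index_b", "horizon", "auc_a", "auc_b", "z", "p_value",
        ]),
        roc_curves=curves,
        horizon_errors=horizon_errors,
    )


def sweep_anemia_points(
    records: Sequence[PatientRecord],
    points: Sequence[int] = (1, 2, 3, 4),
    horizons: Sequence[str] = HORIZONS,
) -> pd.DataFrame:
    """AUC of each augmented index for each anemia weight and horizon.

    ``is_best`` marks the argmax weight within each family x horizon cell;
    exact AUC ties are marked jointly.
    """
    rows = []
    for horizon in horizons:
        y = _outcome_vector(records, horizon)
        for index in FAMILIES:
            table = score_cohort(records, index, AugmentationRule(0))
            base = table["base_score"].to_numpy(dtype=float)
            anemic = table["anemic"].to_numpy(dtype=bool)
            aucs = {}
            for k in points:
                aucs[k] = auc(base + k * anemic, y)
            best = max(aucs.values())
            for k in points:
                rows.append({
                    "index": index.name, "horizon": horizon, "anemia_points": int(k),
                    "auc": aucs[k], "is_best": aucs[k] == best,
                })
    return pd.DataFrame(rows, columns=["index", "horizon", "anemia_points", "auc", "is_best"])
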