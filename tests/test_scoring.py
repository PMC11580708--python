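"""Point tables, index ranges, and anemia augmentation."""

from itertools import product

import pytest
from hypothesis import given, strategies as st

from copd_indices import (
    ADO,
    BODEX,
    AugmentationRule,
    IndexDefinition,
    ScoringError,
    Sex,
    ado_score,
    augment_score,
    bodex_score,
    score_cohort,
)

from conftest import make_record


class TestBodex:
    @pytest.mark.parametrize(
        ("bmi", "fev1", "mmrc", "exac", "expected"),
        [
            (20.0, 30.0, 4, 4, 9),   # every component at its maximum
            (27.0, 70.0, 1, 0, 0),   # every component in its zero bin
            (27.0, 46.0, 2, 1, 4),   # 0 + 2 + 1 + 1
            (21.0, 46.0, 2, 1, 5),   # BMI exactly 21 scores the low-BMI point
            (21.1, 46.0, 2, 1, 4),
        ],
    )
    def test_totals(self, bmi, fev1, mmrc, exac, expected):
        rec = make_record(bmi=bmi, fev1_pct=fev1, mmrc=mmrc,
                          severe_exacerbations_prior_year=exac)
        assert bodex_score(rec) == expected

    @pytest.mark.parametrize(
        ("fev1", "points"),
        [(65.0, 0), (64.9, 1), (50.0, 1), (49.9, 2), (36.0, 2), (35.9, 3)],
    )
    def test_fev1_bin_edges_half_open(self, fev1, points):
        rec = make_record(bmi=27.0, fev1_pct=fev1, mmrc=0,
                          severe_exacerbations_prior_year=0)
        assert bodex_score(rec) == points

    @pytest.mark.parametrize(("exac", "points"), [(0, 0), (1, 1), (2, 1), (3, 2), (6, 2)])
    def test_exacerbation_bins(self, exac, points):
        rec = make_record(bmi=27.0, fev1_pct=70.0, mmrc=0,
                          severe_exacerbations_prior_year=exac)
        assert bodex_score(rec) == points


class TestAdo:
    @pytest.mark.parametrize(
        ("age", "mmrc", "fev1", "expected"),
        [
            (92, 4, 30.0, 10),  # maximum attainable
            (45, 0, 70.0, 0),   # all zero bins
            (73, 2, 46.0, 5),   # 3 + 1 + 1
        ],
    )
    def test_totals(self, age, mmrc, fev1, expected):
        rec = make_record(age=age, mmrc=mmrc, fev1_pct=fev1)
        assert ado_score(rec) == expected

    @pytest.mark.parametrize(
        ("age", "points"),
        [(49, 0), (50, 1), (59, 1), (60, 2), (70, 3), (80, 4), (89, 4), (90, 5), (105, 5)],
    )
    def test_age_decade_bins(self, age, points):
        rec = make_record(age=age, mmrc=0, fev1_pct=70.0)
        assert ado_score(rec) == points


class TestRanges:
    @pytest.mark.parametrize(
        ("index", "anemia_points", "expected_max"),
        [(BODEX, 0, 9), (ADO, 0, 10), (BODEX, 3, 12), (ADO, 3, 13)],
    )
    def test_every_total_attainable_by_enumeration(self, index, anemia_points, expected_max):
        """Brute force over all bin combinations x anemia status covers the
        published range exactly."""
        totals = {
            base + extra
            for base in index.attainable_scores()
            for extra in ((0, anemia_points) if anemia_points else (0,))
        }
        assert totals == set(range(expected_max + 1))
        assert index.min_score == 0
        assert index.max_score == expected_max - anemia_points

    def test_enumeration_agrees_with_record_scoring(self):
        """Scoring records built from per-bin representative values attains
        the same totals as the set-based enumeration."""
        reps = [c.representative_values() for c in BODEX.components]
        totals = set()
        for bmi, fev1, mmrc, exac in product(*reps):
            rec = make_record(bmi=float(max(bmi, 13.0)), fev1_pct=float(max(fev1, 6.0)),
                              mmrc=int(max(mmrc, 0)),
                              severe_exacerbations_prior_year=int(max(exac, 0)))
            totals.add(bodex_score(rec))
        assert totals == BODEX.attainable_scores()


class TestAugmentation:
    @pytest.mark.parametrize(
        ("base", "anemic", "points", "expected"),
        [(4, True, 3, 7), (4, False, 3, 4), (9, True, 3, 12), (10, True, 3, 13),
         (5, True, 0, 5)],
    )
    def test_examples(self, base, anemic, points, expected):
        assert augment_score(base, anemic, AugmentationRule(points)) == expected

    @given(
        base_a=st.integers(0, 10), base_b=st.integers(0, 10),
        pts_a=st.integers(0, 4), pts_b=st.integers(0, 4),
        anemic=st.booleans(),
    )
    def test_monotone_in_base_and_weight(self, base_a, base_b, pts_a, pts_b, anemic):
        if base_a <= base_b:
            assert augment_score(base_a, anemic, AugmentationRule(pts_a)) <= augment_score(
                base_b, anemic, AugmentationRule(pts_a)
            )
        if pts_a <= pts_b:
            assert augment_score(base_a, anemic, AugmentationRule(pts_a)) <= augment_score(
                base_a, anemic, AugmentationRule(pts_b)
            )

    def test_invalid_weight_rejected(self):
        with pytest.raises(ScoringError):
            AugmentationRule(5)


class TestScoreCohort:
    def test_empty_cohort_gives_empty_table(self):
        table = score_cohort([], BODEX, AugmentationRule(3))
        assert table.empty
        assert "augmented_score" in table.columns

    def test_no_anemia_means_augmentation_is_identity(self):
        records = [make_record(patient_id=f"P{i}", hemoglobin=15.0) for i in range(5)]
        table = score_cohort(records, BODEX, AugmentationRule(3))
        assert (table["augmented_score"] == table["base_score"]).all()

    def test_invariant_to_patient_order_and_unused_fields(self, default_cohort):
        table = score_cohort(default_cohort, BODEX, AugmentationRule(3))
        reversed_table = score_cohort(list(reversed(default_cohort)), BODEX, AugmentationRule(3))
        merged = table.set_index("patient_id").join(
            reversed_table.set_index("patient_id"), rsuffix="_rev"
        )
        assert (merged["base_score"] == merged["base_score_rev"]).all()
        # ADO ignores BMI entirely
        rec = make_record(bmi=15.0)
        assert ado_score(rec) == ado_score(make_record(bmi=35.0))

    def test_synthetic_cohort_scores_in_range(self, default_cohort):
        table = score_cohort(default_cohort, BODEX, AugmentationRule(3))
        assert table["base_score"].between(0, 9).all()
        assert table["augmented_score"].between(0, 12).all()


def test_table_definitions_roundtrip_through_dicts():
    rebuilt = IndexDefinition.from_dict(BODEX.to_dict())
    assert rebuilt == BODEX
    rec = make_record()
    assert rebuilt.score(rec) == bodex_score(rec)
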