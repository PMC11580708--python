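"""Synthetic-cohort generator: determinism, marginals, calibrated mortality."""

import numpy as np
import pytest
from scipy.special import logit

from copd_indices import (
    BODEX,
    CalibrationError,
    CohortConfig,
    ConfigError,
    calibrate_mortality,
    check_eligibility,
    classify_anemia,
    generate_cohort,
    read_cohort,
    summarize_cohort,
    write_cohort,
)


class TestGenerate:
    def test_cohort_size_and_eligibility(self, default_cohort):
        assert len(default_cohort) == 141
        for rec in default_cohort:
            assert check_eligibility(rec).eligible

    def test_same_seed_is_bit_identical(self):
        cfg = CohortConfig(seed=5)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seeds_differ(self):
        assert generate_cohort(CohortConfig(seed=5)) != generate_cohort(CohortConfig(seed=6))

    def test_no_anemia_when_prevalence_zero(self):
        records = generate_cohort(CohortConfig(seed=2, prop_anemia=0.0))
        assert not any(classify_anemia(r.hemoglobin, r.sex) for r in records)

    def test_all_anemic_when_prevalence_one(self):
        records = generate_cohort(CohortConfig(seed=2, prop_anemia=1.0))
        assert all(classify_anemia(r.hemoglobin, r.sex) for r in records)

    def test_death_is_absorbing_in_every_record(self, default_cohort):
        assert all(r.dead_3y or not r.dead_1y for r in default_cohort)

    def test_anemia_raises_mortality(self):
        """With beta_anemia > 0, anemic patients die more often (pooled over
        replicates so both strata are well populated)."""
        dead_anemic, n_anemic, dead_other, n_other = 0, 0, 0, 0
        for seed in range(20):
            for r in generate_cohort(CohortConfig(seed=seed)):
                if classify_anemia(r.hemoglobin, r.sex):
                    n_anemic += 1
                    dead_anemic += r.dead_3y
                else:
                    n_other += 1
                    dead_other += r.dead_3y
        assert dead_anemic / n_anemic > dead_other / n_other

    def test_marginals_near_targets(self):
        """Mean age/BMI/FEV1 and the zero-exacerbation share track the
        configured moments on a large cohort."""
        records = generate_cohort(CohortConfig(seed=4, n_patients=20_000))
        age = np.array([r.age for r in records], dtype=float)
        fev1 = np.array([r.fev1_pct for r in records])
        exac = np.array([r.severe_exacerbations_prior_year for r in records])
        assert abs(age.mean() - 73.0) < 1.0
        assert abs(fev1.mean() - 46.0) < 1.0
        assert abs((exac == 0).mean() - 0.49) < 0.02
        assert abs(exac.mean() - 1.3) < 0.05


class TestConfig:
    def test_infeasible_targets_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(mort_1y_target=0.5, mort_3y_target=0.3)
        with pytest.raises(ConfigError):
            CohortConfig(prop_anemia=1.5)
        with pytest.raises(ConfigError):
            CohortConfig(n_patients=0)

    def test_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(ConfigError, match="unknown"):
            CohortConfig.from_mapping({"n_patient": 10})

    def test_from_mapping_builds_config(self):
        cfg = CohortConfig.from_mapping({"seed": 9, "prop_anemia": 0.3})
        assert cfg.seed == 9 and cfg.prop_anemia == 0.3


class TestCalibration:
    def test_zero_betas_give_closed_form_logit(self):
        cfg = CohortConfig(beta_index=0.0, beta_anemia=0.0)
        a1, a3 = calibrate_mortality(cfg)
        assert a1 == pytest.approx(logit(0.15), abs=1e-12)
        assert a3 == pytest.approx(logit(0.34), abs=1e-12)

    def test_one_year_intercept_below_three_year(self):
        a1, a3 = calibrate_mortality(CohortConfig())
        assert a1 < a3

    def test_expected_mortality_matches_target(self):
        """The calibrated model realizes the 34% three-year target to within
        1 percentage point on a 50,000-draw cohort."""
        records = generate_cohort(CohortConfig(seed=8, n_patients=50_000))
        frac = np.mean([r.dead_3y for r in records])
        assert abs(frac - 0.34) < 0.01

    def test_unattainable_target_raises(self):
        # enormous positive shift: even alpha=-30 cannot push mortality down
        with pytest.raises(CalibrationError):
            calibrate_mortality(
                CohortConfig(beta_index=30.0, mort_1y_target=0.001, mort_3y_target=0.002)
            )

    def test_calibration_independent_of_cohort_seed(self):
        assert calibrate_mortality(CohortConfig(seed=1)) == calibrate_mortality(
            CohortConfig(seed=99)
        )


class TestSummary:
    def test_summary_rows_and_values(self, default_cohort):
        table = summarize_cohort(default_cohort)
        assert table.loc["Number of patients", "count"] == 141
        anemia_pct = table.loc["Anemia, n (%)", "percent"]
        assert 10 < anemia_pct < 40  # binomial noise around 24% at n=141
        for name in ("BODEx (range 0-9)", "ADO (range 0-10)",
                     "BODEx-A3 (range 0-12)", "ADO-A3 (range 0-13)"):
            assert name in table.index

    def test_single_record_flags_sd_undefined(self, default_cohort):
        table = summarize_cohort(default_cohort[:1])
        assert "n/a" in table.loc["Age (years)", "value"]

    def test_summary_survives_roundtrip(self, default_cohort, tmp_path):
        path = tmp_path / "c.csv"
        write_cohort(default_cohort, path)
        back = summarize_cohort(read_cohort(path))
        assert back["value"].equals(summarize_cohort(default_cohort)["value"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


def test_replicate_prevalences_track_configuration():
    """Over 30 replicate default cohorts the mean anemia prevalence and
    mortality fractions stay near 24% / 15% / 34%."""
    anemia, m1, m3 = [], [], []
    for seed in range(30):
        records = generate_cohort(CohortConfig(seed=seed))
        anemia.append(np.mean([classify_anemia(r.hemoglobin, r.sex) for r in records]))
        m1.append(np.mean([r.dead_1y for r in records]))
        m3.append(np.mean([r.dead_3y for r in records]))
    assert abs(np.mean(anemia) - 0.24) < 0.02
    assert abs(np.mean(m1) - 0.15) < 0.02
    assert abs(np.mean(m3) - 0.34) < 0.02
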