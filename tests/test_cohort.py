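import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import refrange as rr
from refrange.cohort import COHORT_COLUMNS


class TestSpecValidation:
    def test_invalid_fields_named(self):
        with pytest.raises(rr.CohortSpecError, match="female_fraction"):
            rr.CohortSpec(female_fraction=1.2)
        with pytest.raises(rr.CohortSpecError, match="age_range"):
            rr.CohortSpec(age_range=(15, 60))
        with pytest.raises(rr.CohortSpecError, match="glucose_healthy_sd"):
            rr.CohortSpec(glucose_healthy_sd=-1.0)
        with pytest.raises(rr.CohortSpecError, match="pathological_components"):
            rr.CohortSpec(pathological_components=[(0.25, 2.8, -0.1)])

    def test_weights_normalized_on_construction(self):
        spec = rr.CohortSpec(healthy_fraction=0.6,
                             pathological_components=[(0.6, 2.8, 0.4)])
        total = spec.healthy_fraction + sum(w for w, _, _ in
                                            spec.pathological_components)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert spec.healthy_fraction == pytest.approx(0.5)


class TestGenerateCohort:
    def test_schema_and_counts(self, default_cohort, default_spec):
        assert list(default_cohort.columns) == COHORT_COLUMNS
        assert len(default_cohort) == default_spec.n_subjects
        # female count forced by the rounding rule: round(20000 * 0.86)
        assert int((default_cohort["sex"] == "F").sum()) == 17_200

    def test_deterministic_for_fixed_seed(self):
        spec = rr.CohortSpec(n_subjects=500, seed=7)
        a = rr.generate_cohort(spec)
        b = rr.generate_cohort(rr.CohortSpec(n_subjects=500, seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = rr.generate_cohort(rr.CohortSpec(n_subjects=500, seed=8))
        assert not a["insulin_uU_mL"].equals(c["insulin_uU_mL"])

    def test_degenerate_all_healthy(self):
        spec = rr.CohortSpec(n_subjects=300, healthy_fraction=1.0,
                             pathological_components=[], seed=3)
        cohort = rr.generate_cohort(spec)
        assert cohort["is_healthy_truth"].all()

    def test_analytes_strictly_positive(self):
        # a mean close to zero forces the hard-resample path
        spec = rr.CohortSpec(n_subjects=2000, glucose_healthy_mean=1.0,
                             glucose_healthy_sd=5.0, seed=11)
        cohort = rr.generate_cohort(spec)
        for col in ("insulin_uU_mL", "glucose_mg_dL", "a1c_pct",
                    "hdl_mg_dL", "tg_mg_dL", "weight_kg"):
            assert (cohort[col] > 0).all(), col
        assert cohort["height_m"].between(1.2, 2.2, inclusive="neither").all()

    def test_ages_inside_window(self, default_cohort):
        assert default_cohort["age"].between(20, 60).all()

    def test_medication_prevalence_matches_total_probability(self, default_cohort,
                                                             default_spec):
        any_med = (default_cohort[["med_antidiabetic", "med_lipid_lowering",
                                   "med_antihypertensive"]].any(axis=1))
        p = (default_spec.healthy_fraction
             * default_spec.medication_prob_given_health
             + (1 - default_spec.healthy_fraction)
             * default_spec.medication_prob_given_pathology)
        n = len(default_cohort)
        half_width = 2.576 * math.sqrt(p * (1 - p) / n)   # binomial 99% bounds
        assert abs(any_med.mean() - p) < half_width


class TestTrueHealthyQuantiles:
    def test_zero_variance_quantile(self):
        spec = rr.CohortSpec(insulin_healthy_logmean_f=math.log(5.8),
                             insulin_healthy_logsd_f=0.0)
        assert rr.true_healthy_quantiles(spec, "F", [0.5])[0] == pytest.approx(5.8)

    def test_closed_form_lognormal(self):
        spec = rr.CohortSpec(insulin_healthy_logmean_f=math.log(5.8),
                             insulin_healthy_logsd_f=0.42)
        q = rr.true_healthy_quantiles(spec, "F", [0.025, 0.975])
        expected = np.exp(math.log(5.8) + np.array([-1, 1]) * 1.959964 * 0.42)
        np.testing.assert_allclose(q, expected, rtol=1e-6)

    def test_monte_carlo_cross_check(self):
        spec = rr.CohortSpec(insulin_healthy_logmean_f=math.log(5.8),
                             insulin_healthy_logsd_f=0.42)
        rng = np.random.default_rng(42)
        draws = rng.lognormal(math.log(5.8), 0.42, 1_000_000)
        mc = np.quantile(draws, [0.025, 0.975])
        np.testing.assert_allclose(
            rr.true_healthy_quantiles(spec, "F", [0.025, 0.975]), mc, rtol=5e-3)

    def test_identical_sexes_collapse_to_single_component(self):
        spec = rr.CohortSpec(
            insulin_healthy_logmean_m=rr.CohortSpec().insulin_healthy_logmean_f,
            insulin_healthy_logsd_m=rr.CohortSpec().insulin_healthy_logsd_f)
        probs = [0.025, 0.5, 0.975]
        np.testing.assert_allclose(rr.true_healthy_quantiles(spec, "all", probs),
                                   rr.true_healthy_quantiles(spec, "F", probs),
                                   rtol=1e-9)

    def test_mixture_inversion_satisfies_cdf(self, default_spec):
        probs = np.array([0.025, 0.5, 0.975])
        q = rr.true_healthy_quantiles(default_spec, "all", probs)
        w = default_spec.female_fraction
        cdf = (w * stats.norm.cdf((np.log(q) - default_spec.insulin_healthy_logmean_f)
                                  / default_spec.insulin_healthy_logsd_f)
               + (1 - w) * stats.norm.cdf((np.log(q) - default_spec.insulin_healthy_logmean_m)
                                          / default_spec.insulin_healthy_logsd_m))
        np.testing.assert_allclose(cdf, probs, atol=1e-9)

    def test_rejects_degenerate_probs(self, default_spec):
        with pytest.raises(ValueError):
            rr.true_healthy_quantiles(default_spec, "F", [0.0, 0.5])

    def test_empirical_quantiles_converge(self):
        spec = rr.CohortSpec(n_subjects=50_000, healthy_fraction=1.0,
                             pathological_components=[], seed=5)
        cohort = rr.generate_cohort(spec)
        women = cohort.loc[cohort["sex"] == "F", "insulin_uU_mL"]
        emp = np.quantile(women, [0.025, 0.5, 0.975], method="weibull")
        true = rr.true_healthy_quantiles(spec, "F", [0.025, 0.5, 0.975])
        np.testing.assert_allclose(emp, true, rtol=0.02)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        spec = rr.CohortSpec(n_subjects=200, seed=9)
        cohort = rr.generate_cohort(spec)
        path = tmp_path / "cohort.csv"
        rr.write_cohort_csv(cohort, path, spec=spec)
        back = rr.read_cohort_csv(path)
        pd.testing.assert_frame_equal(back, cohort, check_dtype=False)
        assert (tmp_path / "cohort.csv.provenance.json").exists()

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = rr.CohortSpec(n_subjects=123, seed=4,
                             pathological_components=[(0.2, 2.8, 0.4),
                                                      (0.05, 3.2, 0.3)])
        path = tmp_path / "spec.yaml"
        rr.spec_to_yaml(spec, path)
        assert rr.spec_from_yaml(path) == spec
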