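import math
import warnings

import numpy as np
import pytest
from scipy import stats

import refrange as rr
from refrange.estimate import (
    DEFAULT_CONFIG,
    RIConfig,
    TransformSpec,
    bootstrap_ci,
    choose_truncation,
    detect_outliers,
    estimate_percentile_ri,
    find_modes_antimodes,
    fit_mixture,
    run_indirect_ri,
    select_transform,
)


class TestDetectOutliers:
    def test_clean_symmetric_sample_untouched(self):
        x = np.linspace(-1, 1, 200)   # well inside any Tukey fence
        kept, removed = detect_outliers(x)
        assert removed.size == 0 and kept.size == 200

    def test_gross_outlier_removed(self):
        rng = np.random.default_rng(0)
        x = np.append(rng.normal(10, 1, 99), 1e6)
        kept, removed = detect_outliers(x)
        assert removed.tolist() == [1e6]
        assert kept.size == 99

    def test_clean_lognormal_not_mass_deleted(self):
        # the medcouple-adjusted fences must tolerate right skew
        x = np.random.default_rng(12).lognormal(0.0, 0.5, 10_000)
        kept, removed = detect_outliers(x)
        assert removed.size / x.size < 0.02

    def test_partition_preserved(self):
        x = np.random.default_rng(3).lognormal(1.0, 0.4, 500)
        kept, removed = detect_outliers(x)
        assert kept.size + removed.size == x.size
        np.testing.assert_array_equal(np.sort(np.concatenate([kept, removed])),
                                      np.sort(x))

    def test_small_sample_refused(self):
        with pytest.raises(ValueError, match="at least 20"):
            detect_outliers(np.arange(10.0))


class TestSelectTransform:
    def test_symmetric_sample_left_alone(self):
        x = np.random.default_rng(1).normal(0, 1, 10_000)
        assert select_transform(x).family == "identity"

    def test_lognormal_gets_log(self):
        x = np.random.default_rng(2).lognormal(1.8, 0.5, 10_000)
        spec = select_transform(x)
        assert spec.family == "box_cox" and spec.lam == 0.0

    def test_constant_vector_warns_identity(self):
        with pytest.warns(UserWarning, match="degenerate"):
            spec = select_transform(np.full(50, 3.0))
        assert spec.family == "identity"

    def test_transform_invertible_on_data(self):
        x = np.random.default_rng(5).lognormal(0.5, 0.8, 1000)
        spec = select_transform(x)
        np.testing.assert_allclose(spec.invert(spec.apply(x)), x, rtol=1e-9)


class TestFitMixture:
    def test_single_component_closed_form(self):
        x = np.random.default_rng(4).normal(3.0, 2.0, 1000)
        m = fit_mixture(x, k_max=1, seed=0)
        assert m.k == 1
        assert m.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert m.sds[0] == pytest.approx(x.std(), abs=1e-6)

    def test_bic_selects_one_component_for_clean_normal(self):
        x = np.random.default_rng(7).normal(0, 1, 10_000)
        assert fit_mixture(x, k_max=3, seed=0).k == 1

    def test_recovers_two_component_mixture(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 7000), rng.normal(6, 1, 3000)])
        m = fit_mixture(x, k_max=3, seed=0)
        assert m.k == 2
        np.testing.assert_allclose(m.weights, [0.7, 0.3], atol=0.03)
        np.testing.assert_allclose(m.means, [0.0, 6.0], atol=0.1)

    def test_agrees_with_sklearn_reference(self):
        # independent EM implementation as cross-check
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(21)
        x = np.concatenate([rng.normal(0, 1, 4000), rng.normal(5, 1.5, 2000)])
        ours = fit_mixture(x, k_max=2, seed=0)
        ref = sklearn_mixture.GaussianMixture(2, n_init=3, random_state=0,
                                              tol=1e-8, max_iter=1000).fit(
            x.reshape(-1, 1))
        order = np.argsort(ref.means_.ravel())
        np.testing.assert_allclose(ours.means, ref.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(ours.weights, ref.weights_[order], atol=0.01)
        assert ours.loglik == pytest.approx(float(ref.score(x.reshape(-1, 1))) * x.size,
                                            rel=1e-4)

    def test_small_sample_refused(self):
        with pytest.raises(ValueError, match="at least 100"):
            fit_mixture(np.arange(50.0), k_max=2, seed=0)


class TestModesAntimodes:
    def test_unimodal_sample(self):
        x = np.random.default_rng(9).normal(0, 1, 5000)
        info = find_modes_antimodes(x)
        assert info.modes.size == 1 and info.antimodes.size == 0

    def test_bimodal_sample_has_interleaved_antimode(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(6, 1, 5000)])
        info = find_modes_antimodes(x)
        assert info.modes.size == 2 and info.antimodes.size == 1
        assert 0.0 < info.antimodes[0] < 6.0

    @pytest.mark.parametrize("seed", range(4))
    def test_strict_interleaving(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 1, 3000),
                            rng.normal(rng.uniform(3, 8), 1, 2000)])
        info = find_modes_antimodes(x)
        merged = np.sort(np.concatenate([info.modes, info.antimodes]))
        kinds = ["m" if v in info.modes else "a" for v in merged]
        assert all(kinds[i] != kinds[i + 1] for i in range(len(kinds) - 1))
        assert info.antimodes.size == info.modes.size - 1


class TestChooseTruncation:
    def test_single_component_spans_data(self):
        x = np.random.default_rng(11).normal(0, 1, 2000)
        m = fit_mixture(x, k_max=1, seed=0)
        info = find_modes_antimodes(x)
        w = choose_truncation(m, info, TransformSpec(), x)
        assert (w.lower, w.upper) == (x.min(), x.max())
        assert w.source == "data_extreme"

    def test_upper_contamination_cut_between_means(self):
        # responsibility = 0.5 for 0.75 N(0,1) + 0.25 N(5,1) crosses at
        # 2.5 + ln(3)/5 = 2.72; the flanking antimode may pull it lower
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(0, 1, 7500), rng.normal(5, 1, 2500)])
        m = fit_mixture(x, k_max=3, seed=0)
        info = find_modes_antimodes(x)
        w = choose_truncation(m, info, TransformSpec(), x)
        assert 1.5 < w.upper < 3.5
        assert w.upper_source in ("posterior_responsibility", "antimode")
        assert w.lower_source == "data_extreme"

    def test_symmetric_contamination_isolates_centre(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(0, 1, 7000),
                            rng.normal(-6, 1, 1500), rng.normal(6, 1, 1500)])
        m = fit_mixture(x, k_max=3, seed=0)
        info = find_modes_antimodes(x)
        w = choose_truncation(m, info, TransformSpec(), x)
        assert w.lower < 0.0 < w.upper          # healthy mean inside
        assert w.lower > -6.0 and w.upper < 6.0  # contaminant means outside

    def test_window_invariant(self):
        with pytest.raises(ValueError, match="lower < upper"):
            rr.TruncationWindow(2.0, 1.0, "data_extreme", "data_extreme")


class TestPercentiles:
    def test_rank_convention_on_small_sample(self):
        values = np.arange(1.0, 40.0)   # n = 39, r = p(n+1)
        w = rr.TruncationWindow(0.0, 40.0, "data_extreme", "data_extreme")
        lo, hi = estimate_percentile_ri(values, w,
                                        config=RIConfig(min_n_window=20))
        assert (lo, hi) == (1.0, 39.0)

    def test_large_sample_normal_quantiles(self):
        x = np.random.default_rng(14).standard_normal(100_000)
        w = rr.TruncationWindow(float(x.min()), float(x.max()),
                                "data_extreme", "data_extreme")
        lo, hi = estimate_percentile_ri(x, w)
        assert lo == pytest.approx(-1.959964, abs=0.02)
        assert hi == pytest.approx(1.959964, abs=0.02)

    def test_below_floor_refused(self):
        w = rr.TruncationWindow(0.0, 1.0, "data_extreme", "data_extreme")
        with pytest.raises(ValueError, match="120"):
            estimate_percentile_ri(np.linspace(0.1, 0.9, 100), w)


class TestBootstrapCi:
    def test_deterministic_for_fixed_seed(self):
        x = np.random.default_rng(15).standard_normal(1000)
        assert bootstrap_ci(x, seed=5) == bootstrap_ci(x, seed=5)
        assert bootstrap_ci(x, seed=5) != bootstrap_ci(x, seed=6)

    def test_single_resample_degenerates(self):
        x = np.random.default_rng(16).standard_normal(500)
        lower_ci, upper_ci = bootstrap_ci(x, n_boot=1, seed=0)
        assert lower_ci[0] == lower_ci[1]
        assert upper_ci[0] == upper_ci[1]


class TestRunIndirectRi:
    def test_permutation_invariance(self, fast_config):
        rng = np.random.default_rng(17)
        x = rng.lognormal(1.8, 0.4, 3000)
        a = run_indirect_ri(x, config=fast_config, seed=1)
        b = run_indirect_ri(rng.permutation(x), config=fast_config, seed=1)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert a.lower_ci == b.lower_ci and a.upper_ci == b.upper_ci

    def test_k1_equals_plain_percentiles(self):
        x = np.random.default_rng(18).lognormal(1.8, 0.4, 5000)
        est = run_indirect_ri(x, config=RIConfig(k_max=1, n_boot=10), seed=2)
        kept, _ = detect_outliers(np.sort(x))
        lo, hi = np.quantile(kept, [0.025, 0.975], method="weibull")
        assert abs(est.lower - lo) <= 1e-12
        assert abs(est.upper - hi) <= 1e-12

    def test_affine_equivariance_with_identity_transform(self):
        x = np.random.default_rng(19).normal(50, 5, 4000)
        cfg = RIConfig(n_boot=10)
        base = run_indirect_ri(x, config=cfg, seed=3)
        scaled = run_indirect_ri(3.0 * x + 7.0, config=cfg, seed=3)
        assert base.transform.family == "identity"
        assert scaled.lower == pytest.approx(3.0 * base.lower + 7.0, rel=1e-9)
        assert scaled.upper == pytest.approx(3.0 * base.upper + 7.0, rel=1e-9)

    def test_clean_lognormal_recovery(self, fast_config):
        mu, sd = math.log(6.6), 0.35
        x = np.random.default_rng(20).lognormal(mu, sd, 20_000)
        est = run_indirect_ri(x, config=fast_config, seed=4)
        true_lo, true_hi = np.exp(mu + np.array([-1, 1]) * 1.959964 * sd)
        assert est.lower == pytest.approx(true_lo, rel=0.05)
        assert est.upper == pytest.approx(true_hi, rel=0.05)

    def test_truncation_shields_against_high_contamination(self, fast_config):
        # 25% contamination shifted ~5x upward: the truncated estimate moves
        # little while naive percentiles of the mixture explode
        mu, sd = math.log(6.6), 0.35
        rng = np.random.default_rng(22)
        clean = rng.lognormal(mu, sd, 15_000)
        contam = rng.lognormal(mu + 1.6, 0.45, 5_000)
        mixed = np.concatenate([clean, contam])
        est_clean = run_indirect_ri(clean, config=fast_config, seed=5)
        est_mixed = run_indirect_ri(mixed, config=fast_config, seed=5)
        move = abs(est_mixed.upper / est_clean.upper - 1.0)
        assert move < 0.10
        naive_hi = np.quantile(mixed, 0.975, method="weibull")
        assert naive_hi / est_clean.upper - 1.0 > 0.25

    def test_point_estimate_stable_across_seeds(self):
        x = np.random.default_rng(23).lognormal(1.887, 0.35, 8000)
        cfg = RIConfig(n_boot=5)
        ests = [run_indirect_ri(x, config=cfg, seed=s) for s in range(5)]
        lows = [e.lower for e in ests]
        highs = [e.upper for e in ests]
        assert (max(lows) - min(lows)) / np.mean(lows) < 0.005
        assert (max(highs) - min(highs)) / np.mean(highs) < 0.005

    def test_small_sample_warns(self, fast_config):
        x = np.random.default_rng(24).lognormal(1.8, 0.3, 300)
        with pytest.warns(UserWarning, match="below the recommended"):
            run_indirect_ri(x, config=fast_config, seed=6)

    def test_stage_errors_carry_stage_name(self, fast_config):
        with pytest.raises(ValueError, match="detect_outliers"):
            run_indirect_ri(np.arange(10.0), config=fast_config, seed=0)

    def test_provenance_counts_consistent(self, fast_config):
        x = np.random.default_rng(25).lognormal(1.8, 0.4, 3000)
        est = run_indirect_ri(x, config=fast_config, seed=7)
        assert est.n_input >= est.n_after_outliers >= est.n_in_window
        assert est.n_in_window >= DEFAULT_CONFIG.min_n_window
        assert est.window.lower <= est.lower < est.upper <= est.window.upper
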