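import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitamr import (
    SimulationConfig,
    cochran_q,
    egger,
    egger_bootstrap,
    harmonize_tables,
    ivw,
    mode_estimate,
    simulate_summary_stats,
    simulate_truth,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)
from conftest import make_pairs, random_instance


class TestWaldRatio:
    def test_arithmetic(self):
        (pair,) = make_pairs([0.10], [0.05], sx=[0.01], sy=[0.02])
        e = wald_ratio(pair)
        assert e.beta == pytest.approx(0.5) and e.se == pytest.approx(0.2)

    def test_null_outcome_gives_p_one(self):
        (pair,) = make_pairs([0.10], [0.0])
        e = wald_ratio(pair)
        assert e.beta == 0.0 and e.pval == pytest.approx(1.0)

    def test_joint_negation_invariance(self):
        (a,) = make_pairs([0.10], [0.05])
        (b,) = make_pairs([-0.10], [-0.05])
        ea, eb = wald_ratio(a), wald_ratio(b)
        assert ea.beta == eb.beta and ea.se == eb.se

    def test_second_order_se_is_larger(self):
        (pair,) = make_pairs([0.05], [0.05], sx=[0.02], sy=[0.02])
        assert wald_ratio(pair, second_order=True).se > wald_ratio(pair).se


class TestIVW:
    def test_equal_ses_give_mean_of_ratios(self):
        pairs = make_pairs([0.1, 0.1, 0.1], [0.01, 0.02, 0.06])
        e = ivw(pairs, "fixed")
        ratios = [0.1, 0.2, 0.6]
        assert e.beta == pytest.approx(np.mean(ratios), rel=1e-12)

    def test_matches_zero_intercept_weighted_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        for _ in range(20):
            pairs = random_instance(rng, int(rng.integers(3, 30)))
            bx = np.array([p.beta_exposure for p in pairs])
            by = np.array([p.beta_outcome for p in pairs])
            sy = np.array([p.se_outcome for p in pairs])
            fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
            e = ivw(pairs, "fixed")
            assert e.beta == pytest.approx(fit.params[0], abs=1e-10)
            # fixed-effect SE corresponds to the unscaled covariance
            se_fixed = float(np.sqrt(fit.normalized_cov_params[0, 0]))
            assert e.se == pytest.approx(se_fixed, abs=1e-10)

    def test_mre_clamps_at_fixed_when_underdispersed(self):
        pairs = make_pairs([0.1, 0.1, 0.1], [0.0101, 0.0100, 0.0099])
        assert ivw(pairs, "multiplicative_random").se == ivw(pairs, "fixed").se

    def test_mre_inflates_when_heterogeneous(self):
        pairs = make_pairs([0.1] * 4, [0.2, -0.2, 0.25, -0.3])
        assert ivw(pairs, "multiplicative_random").se > ivw(pairs, "fixed").se

    def test_single_pair_degrades_to_wald(self):
        (pair,) = pairs = make_pairs([0.1], [0.05])
        e = ivw(pairs, "fixed")
        w = wald_ratio(pair)
        assert e.beta == pytest.approx(w.beta) and e.se == pytest.approx(w.se)

    def test_global_sign_symmetry(self):
        rng = np.random.default_rng(3)
        pairs = random_instance(rng, 10)
        flipped = make_pairs(
            [p.beta_exposure for p in pairs],
            [-p.beta_outcome for p in pairs],
            [p.se_exposure for p in pairs],
            [p.se_outcome for p in pairs],
        )
        for variant in ("fixed", "multiplicative_random"):
            a, b = ivw(pairs, variant), ivw(flipped, variant)
            assert a.beta == pytest.approx(-b.beta, abs=1e-14)
            assert a.se == pytest.approx(b.se, abs=1e-14)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])  # all ratios 0.5
        het = cochran_q(pairs)
        assert het.Q == pytest.approx(0.0, abs=1e-20) and het.pval == pytest.approx(1.0)

    def test_hand_computed_two_pair_case(self):
        # ratios 0 and 2 with unit weights: pooled fit 1, Q = 1 + 1 = 2
        pairs = make_pairs([1.0, 1.0], [0.0, 2.0], sy=[1.0, 1.0])
        het = cochran_q(pairs)
        assert het.Q == pytest.approx(2.0) and het.df == 1

    def test_pleiotropy_inflates_q(self):
        qs = {}
        for mode, sd in (("none", 0.0), ("balanced", 0.05)):
            cfg = SimulationConfig(n_variants=80, pleiotropy_mode=mode,
                                   pleiotropy_sd=sd, seed=8)
            truth = simulate_truth(cfg)
            exposure, outcome = simulate_summary_stats(truth, cfg)
            pairs, _ = harmonize_tables(exposure, outcome)
            qs[mode] = cochran_q(pairs).Q
        assert qs["balanced"] > 2 * qs["none"]

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError):
            cochran_q(make_pairs([0.1], [0.05]))


class TestEgger:
    def test_exact_line_recovered(self):
        bx = [0.02, 0.05, 0.08, 0.11]
        pairs = make_pairs(bx, [0.3 * x for x in bx], sy=[0.05] * 4)
        slope, icept = egger(pairs)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert icept.alpha == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        bx = [0.02, 0.05, 0.08, 0.11]
        pairs = make_pairs(bx, [0.01 + 0.3 * x for x in bx], sy=[0.05] * 4)
        slope, icept = egger(pairs)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert icept.alpha == pytest.approx(0.01, abs=1e-12)

    def test_matches_generic_weighted_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(20):
            pairs = random_instance(rng, int(rng.integers(3, 30)))
            bx = np.array([p.beta_exposure for p in pairs])
            by = np.array([p.beta_outcome for p in pairs])
            sy = np.array([p.se_outcome for p in pairs])
            sign = np.where(bx < 0, -1.0, 1.0)
            x = sm.add_constant(np.abs(bx))
            fit = sm.WLS(by * sign, x, weights=1.0 / sy**2).fit()
            slope, icept = egger(pairs)
            assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert icept.alpha == pytest.approx(fit.params[0], abs=1e-10)

    def test_no_spread_is_an_error(self):
        pairs = make_pairs([0.1, 0.1, 0.1], [0.02, 0.03, 0.04])
        with pytest.raises(ValueError, match="spread"):
            egger(pairs)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(13)
        pairs = random_instance(rng, 12)
        flipped = make_pairs(
            [-p.beta_exposure for p in pairs],
            [-p.beta_outcome for p in pairs],
            [p.se_exposure for p in pairs],
            [p.se_outcome for p in pairs],
        )
        s1, i1 = egger(pairs)
        s2, i2 = egger(flipped)
        assert s1.beta == pytest.approx(s2.beta, abs=1e-14)
        assert i1.alpha == pytest.approx(i2.alpha, abs=1e-14)


class TestEggerBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(17)
        pairs = random_instance(rng, 10)
        a = egger_bootstrap(pairs, 200, seed=5)
        b = egger_bootstrap(pairs, 200, seed=5)
        assert a == b

    def test_concentrates_at_truth_with_tiny_noise(self):
        bx = [0.02, 0.05, 0.08, 0.11, 0.14]
        pairs = make_pairs(bx, [0.3 * x for x in bx], sx=[1e-8] * 5, sy=[1e-8] * 5)
        e = egger_bootstrap(pairs, 200, seed=1)
        assert e.beta == pytest.approx(0.3, abs=1e-5)

    def test_boot_count_stability(self):
        rng = np.random.default_rng(19)
        pairs = random_instance(rng, 15)
        small = egger_bootstrap(pairs, 1000, seed=2)
        large = egger_bootstrap(pairs, 10_000, seed=3)
        # medians agree within 3 Monte-Carlo SEs of the smaller run
        mc_se = small.se / math.sqrt(1000) * 1.2533  # SE of a median ~ 1.2533 sd/sqrt(B)
        assert abs(small.beta - large.beta) < 3 * mc_se + 3 * large.se / math.sqrt(10_000)


class TestWeightedMedian:
    def test_equal_weight_three_ratios(self):
        pairs = make_pairs([0.1, 0.1, 0.1], [0.01, 0.05, 0.09])  # ratios .1 .5 .9
        e = weighted_median(pairs, n_boot=0)
        assert e.beta == pytest.approx(0.5, abs=1e-12)

    def test_constant_ratios_return_constant(self):
        pairs = make_pairs([0.05, 0.1, 0.2], [0.05 * 0.7, 0.1 * 0.7, 0.2 * 0.7],
                           sy=[0.01, 0.05, 0.2])
        e = weighted_median(pairs, n_boot=0)
        assert e.beta == pytest.approx(0.7, abs=1e-12)

    def test_outlier_resistance_vs_ivw(self):
        bx = [0.1] * 10
        by = [0.02] * 9 + [0.9]  # one wild ratio (9.0) among nine at 0.2
        pairs = make_pairs(bx, by, sy=[0.05] * 10)
        wm = weighted_median(pairs, n_boot=0).beta
        iv = ivw(pairs, "fixed").beta
        assert wm == pytest.approx(0.2, abs=1e-10)  # stays in the concordant cluster
        assert abs(iv - 0.2) > abs(wm - 0.2)

    def test_bootstrap_se_deterministic(self):
        rng = np.random.default_rng(23)
        pairs = random_instance(rng, 8)
        a = weighted_median(pairs, n_boot=150, seed=9)
        b = weighted_median(pairs, n_boot=150, seed=9)
        assert a == b and a.se > 0

    def test_penalized_downweights_outlier(self):
        bx = [0.1] * 6
        by = [0.02, 0.025, 0.03, 0.035, 0.9, 0.95]  # two wild ratios
        pairs = make_pairs(bx, by, sy=[0.05] * 6)
        pen = weighted_median(pairs, penalized=True, n_boot=0).beta
        plain = weighted_median(pairs, penalized=False, n_boot=0).beta
        assert pen <= plain + 1e-12  # outliers pull less after penalization


class TestMode:
    def test_dominant_atom(self):
        pairs = make_pairs([0.1] * 4, [0.1, 0.1, 0.1, 0.5])  # ratios 1,1,1,5
        e = mode_estimate(pairs, n_boot=0)
        assert e.beta == pytest.approx(1.0, abs=0.05)

    def test_weight_dominance(self):
        pairs = make_pairs([0.1] * 4, [0.1, 0.1, 0.1, 0.5],
                           sy=[0.5, 0.5, 0.5, 0.005])
        e = mode_estimate(pairs, weighted=True, n_boot=0)
        assert e.beta == pytest.approx(5.0, abs=0.1)

    def test_symmetric_tie_breaks_to_lower_peak(self):
        pairs = make_pairs([1.0] * 4, [-1.0, -1.0, 1.0, 1.0], sy=[0.1] * 4)
        e = mode_estimate(pairs, phi=0.1, n_boot=0)
        assert e.beta == pytest.approx(-1.0, abs=0.05)
        assert mode_estimate(pairs, phi=0.1, n_boot=0).beta == e.beta

    def test_all_ratios_equal(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.04, 0.08, 0.12])
        assert mode_estimate(pairs, n_boot=0).beta == pytest.approx(0.4, abs=1e-12)

    def test_bootstrap_deterministic(self):
        rng = np.random.default_rng(29)
        pairs = random_instance(rng, 8)
        a = mode_estimate(pairs, weighted=True, n_boot=120, seed=4)
        b = mode_estimate(pairs, weighted=True, n_boot=120, seed=4)
        assert a == b


class TestOddsScale:
    def test_null_effect_is_or_one(self):
        pairs = make_pairs([0.1, 0.1], [0.0, 0.0])
        e = to_odds_scale(ivw(pairs, "fixed"))
        assert e.or_ == pytest.approx(1.0)
        assert e.or_ci_low * e.or_ci_high == pytest.approx(1.0, rel=1e-10)

    def test_reproduces_published_style_interval(self):
        # log-OR -0.051 (SE 0.064) must print as OR 0.95, CI (0.84, 1.08)
        from vitamr.estimators import _estimate

        e = to_odds_scale(_estimate("ivw_mre", -0.051, 0.064, 80))
        assert round(e.or_, 2) == 0.95
        assert round(e.or_ci_low, 2) == 0.84
        assert round(e.or_ci_high, 2) == 1.08

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_beta(self, b1, b2):
        from vitamr.estimators import _estimate

        e1 = to_odds_scale(_estimate("wald", b1, 0.1, 1))
        e2 = to_odds_scale(_estimate("wald", b2, 0.1, 1))
        if b1 <= b2:
            assert e1.or_ <= e2.or_
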