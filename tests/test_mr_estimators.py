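"""Wald ratio, IVW, Cochran Q, weighted median and MR-Egger."""

import numpy as np
import pandas as pd
import pytest

from mrpipe import (
    AnalysisError,
    Pleiotropy,
    SimulationScenario,
    cochran_q,
    ivw,
    mr_egger,
    orient_exposure_increasing,
    wald_ratio,
    weighted_median,
)
from mrpipe.synthetic_data import simulate_summary_stats, to_harmonized
from conftest import make_harmonized


def inst(gamma, se_gamma, Gamma, se_Gamma, vid="rs1"):
    return {"variant_id": vid, "gamma": gamma, "se_gamma": se_gamma,
            "Gamma": Gamma, "se_Gamma": se_Gamma}


class TestWaldRatio:
    def test_exact_division(self):
        assert wald_ratio(inst(0.1, 0.01, 0.02, 0.005)).ratio == pytest.approx(0.2)

    def test_exact_exposure_reduces_to_outcome_se(self):
        for order in ("first_simple", "first_full", "second"):
            r = wald_ratio(inst(1.0, 0.0, 0.02, 0.005), delta_order=order)
            assert r.ratio == pytest.approx(0.02)
            assert r.se == pytest.approx(0.005)

    def test_zero_gamma_rejected(self):
        with pytest.raises(AnalysisError):
            wald_ratio(inst(0.0, 0.01, 0.02, 0.005))

    def test_first_full_se_matches_parametric_bootstrap(self):
        """Two-term delta SE vs the SD of the ratio over a million
        parametric draws of (gamma, Gamma)."""
        g, sg, G, sG = 0.1, 0.01, 0.02, 0.005
        r = wald_ratio(inst(g, sg, G, sG), delta_order="first_full")
        assert r.se == pytest.approx(0.0539, abs=2e-4)
        rng = np.random.default_rng(42)
        draws = rng.normal(G, sG, 1_000_000) / rng.normal(g, sg, 1_000_000)
        assert r.se == pytest.approx(float(np.std(draws)), rel=0.02)

    def test_order_hierarchy(self):
        i = inst(0.1, 0.01, 0.02, 0.005)
        ses = [wald_ratio(i, delta_order=o).se
               for o in ("first_simple", "first_full", "second")]
        assert ses[0] < ses[1] < ses[2]


class TestIVW:
    def test_equal_weight_mean(self):
        h = make_harmonized([1, 1], [1e-9, 1e-9], [0.1, 0.3], [0.1, 0.1])
        assert ivw(h).beta == pytest.approx(0.2)

    def test_single_instrument_equals_wald(self):
        h = make_harmonized([0.1], [0.01], [0.02], [0.005])
        e = ivw(h)
        r = wald_ratio(h.iloc[0], delta_order="first_full")
        assert e.beta == pytest.approx(r.ratio)
        assert e.se == pytest.approx(r.se)
        assert e.n_snps == 1

    def test_hand_computed_weighted_mean(self):
        # ratios (0.1, 0.2, 0.4), ratio ses (0.05, 0.1, 0.2) -> weights
        # (400, 100, 25): sum(w*b)/sum(w) = (40+20+10)/525
        h = make_harmonized([1, 1, 1], [1e-12] * 3, [0.1, 0.2, 0.4],
                            [0.05, 0.1, 0.2])
        expected = (400 * 0.1 + 100 * 0.2 + 25 * 0.4) / 525
        assert expected == pytest.approx(0.13333333333)
        assert ivw(h, re_model="fixed").beta == pytest.approx(expected, rel=1e-12)

    def test_equals_origin_weighted_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        J = 10
        h = make_harmonized(rng.uniform(0.05, 0.2, J), np.full(J, 0.005),
                            rng.normal(0.01, 0.01, J), rng.uniform(0.004, 0.01, J))
        fit = sm.WLS(h["Gamma"], h[["gamma"]],
                     weights=1.0 / h["se_Gamma"] ** 2).fit()
        e = ivw(h, re_model="fixed")
        assert e.beta == pytest.approx(float(fit.params.iloc[0]), rel=1e-12)

    def test_multiplicative_p_never_smaller_than_fixed(self):
        rng = np.random.default_rng(2)
        J = 15
        # overdispersed ratios -> Q/(J-1) > 1
        h = make_harmonized(rng.uniform(0.05, 0.2, J), np.full(J, 0.001),
                            rng.normal(0.02, 0.05, J), np.full(J, 0.005))
        fixed = ivw(h, re_model="fixed")
        mult = ivw(h, re_model="multiplicative")
        Q, df, _ = cochran_q(h)
        assert Q / df > 1
        assert mult.beta == pytest.approx(fixed.beta, rel=1e-14)
        assert mult.pvalue >= fixed.pvalue

    def test_additive_dl_widens_ci_under_heterogeneity(self):
        rng = np.random.default_rng(3)
        J = 20
        h = make_harmonized(rng.uniform(0.05, 0.2, J), np.full(J, 0.001),
                            rng.normal(0.02, 0.05, J), np.full(J, 0.005))
        assert ivw(h, re_model="additive_dl").se > ivw(h, re_model="fixed").se

    def test_empty_raises(self):
        with pytest.raises(AnalysisError):
            ivw(make_harmonized([], [], [], []))

    def test_invariant_to_reordering(self):
        rng = np.random.default_rng(4)
        J = 12
        h = make_harmonized(rng.uniform(0.05, 0.2, J), np.full(J, 0.005),
                            rng.normal(0.01, 0.01, J), np.full(J, 0.005))
        perm = h.sample(frac=1, random_state=0).reset_index(drop=True)
        assert ivw(perm).beta == pytest.approx(ivw(h).beta, rel=1e-14)


def test_ivw_ci_coverage_under_valid_instruments():
    """Over 1,000 no-pleiotropy datasets the IVW 95% CI contains the true
    effect in 94-96% of replicates."""
    beta_true = 0.15
    covered = 0
    for seed in range(1000):
        exp, out, _ = simulate_summary_stats(SimulationScenario(
            J=30, beta_true=beta_true, seed=seed, min_abs_gamma=0.02))
        e = ivw(to_harmonized(exp, out), re_model="fixed")
        covered += e.ci_low <= beta_true <= e.ci_high
    assert 0.94 <= covered / 1000 <= 0.96


class TestCochranQ:
    def test_no_dispersion(self):
        h = make_harmonized([1, 1, 1], [1e-12] * 3, [0.2, 0.2, 0.2], [0.1] * 3)
        Q, df, p = cochran_q(h)
        assert Q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (2, pytest.approx(1.0))

    def test_hand_computed_two_variant_q(self):
        # ratios 0.1, 0.3 with ratio se 0.1 each: Q = 100*0.01 + 100*0.01 = 2
        h = make_harmonized([1, 1], [1e-12] * 2, [0.1, 0.3], [0.1, 0.1])
        Q, df, p = cochran_q(h)
        assert Q == pytest.approx(2.0, rel=1e-12)
        assert df == 1

    def test_requires_two(self):
        with pytest.raises(AnalysisError):
            cochran_q(make_harmonized([0.1], [0.01], [0.02], [0.005]))


class TestWeightedMedian:
    def test_middle_value_equal_weights(self):
        h = make_harmonized([1, 1, 1], [1e-12] * 3, [0.1, 0.2, 0.9], [0.1] * 3)
        assert weighted_median(h, n_boot=100, seed=0).beta == pytest.approx(0.2)

    def test_dominant_interior_instrument_wins(self):
        # middle ratio holds 60% of the weight -> exactly its value
        h = make_harmonized(
            [1, 1, 1], [1e-12] * 3, [0.1, 0.25, 0.9],
            [np.sqrt(1 / 20), np.sqrt(1 / 60), np.sqrt(1 / 20)])
        assert weighted_median(h, n_boot=100, seed=0).beta == pytest.approx(0.25)

    def test_four_equal_weights_interpolates(self):
        h = make_harmonized([1] * 4, [1e-12] * 4, [0.1, 0.2, 0.3, 0.4], [0.1] * 4)
        # cumulative midpoints (.125,.375,.625,.875); 0.5 between 0.2 and 0.3
        cw = np.cumsum([0.25] * 4) - 0.125
        expected = float(np.interp(0.5, cw, [0.1, 0.2, 0.3, 0.4]))
        assert expected == pytest.approx(0.25)
        assert weighted_median(h, n_boot=100, seed=0).beta == pytest.approx(expected)

    def test_requires_three(self):
        with pytest.raises(AnalysisError):
            weighted_median(make_harmonized([1, 1], [0.01] * 2, [0.1, 0.2],
                                            [0.1] * 2))

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(5)
        J = 10
        h = make_harmonized(rng.uniform(0.05, 0.2, J), np.full(J, 0.005),
                            rng.normal(0.02, 0.01, J), np.full(J, 0.005))
        a = weighted_median(h, n_boot=200, seed=9)
        b = weighted_median(h, n_boot=200, seed=9)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_tolerates_minority_invalid_instruments(self):
        """~40% of instruments given a large pleiotropic offset: the median
        stays near truth while IVW drifts."""
        beta_true = 0.2
        biases_med = []
        biases_ivw = []
        for seed in range(30):
            exp, out, _ = simulate_summary_stats(SimulationScenario(
                J=100, beta_true=beta_true, seed=seed,
                tau=0.1, min_abs_gamma=0.05,
                n_exposure=5_000_000, n_outcome=5_000_000,
                pleiotropy=Pleiotropy(kind="outliers", fraction=0.4, offset=10.0),
            ))
            h = orient_exposure_increasing(to_harmonized(exp, out))
            biases_med.append(weighted_median(h, n_boot=100, seed=seed).beta - beta_true)
            biases_ivw.append(ivw(h).beta - beta_true)
        assert abs(np.mean(biases_med)) < 0.1 * beta_true
        assert abs(np.mean(biases_ivw)) > abs(np.mean(biases_med))


class TestEgger:
    def test_exact_affine_points_recovered(self):
        g = np.array([0.05, 0.1, 0.15, 0.2])
        h = make_harmonized(g, [1e-6] * 4, 0.05 + 0.2 * g, [0.01] * 4)
        res = mr_egger(h)
        assert res.intercept == pytest.approx(0.05, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.2, abs=1e-12)

    def test_points_through_origin_zero_intercept(self):
        g = np.array([0.05, 0.1, 0.15, 0.2])
        h = make_harmonized(g, [1e-6] * 4, 0.3 * g, [0.01] * 4)
        res = mr_egger(h)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)

    def test_requires_three_and_gamma_variance(self):
        with pytest.raises(AnalysisError):
            mr_egger(make_harmonized([0.1, 0.2], [0.01] * 2, [0.0, 0.1], [0.01] * 2))
        with pytest.raises(AnalysisError):
            mr_egger(make_harmonized([0.1] * 4, [0.01] * 4, [0.0, 0.1, 0.2, 0.3],
                                     [0.01] * 4))

    def test_recovers_truth_under_directional_pleiotropy(self):
        """With InSIDE holding and mean pleiotropy 0.02, the Egger slope
        tracks the causal effect and its intercept the mean pleiotropy,
        while IVW is biased."""
        beta_true, mu_alpha = 0.1, 0.02
        slopes, intercepts, ivws = [], [], []
        for seed in range(60):
            exp, out, _ = simulate_summary_stats(SimulationScenario(
                J=100, beta_true=beta_true, seed=seed, min_abs_gamma=0.02,
                n_exposure=1_000_000, n_outcome=1_000_000,
                pleiotropy=Pleiotropy(kind="directional", mean=mu_alpha, sd=0.01),
            ))
            h = orient_exposure_increasing(to_harmonized(exp, out))
            res = mr_egger(h)
            slopes.append(res.slope.beta)
            intercepts.append(res.intercept)
            ivws.append(ivw(h).beta)
        assert np.mean(slopes) == pytest.approx(beta_true, abs=0.01)
        assert np.mean(intercepts) == pytest.approx(mu_alpha, abs=0.005)
        assert abs(np.mean(ivws) - beta_true) > 0.05 * beta_true
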