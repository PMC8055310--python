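"""Instrument selection, LD clumping and variance-explained metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrpipe import (
    AnalysisError,
    ConfigurationError,
    LDTable,
    clump,
    mean_f_statistic,
    select_instruments,
    variance_explained_binary_liability,
    variance_explained_continuous,
)
from mrpipe.instruments import attach_variance_explained
from mrpipe.synthetic_data import simulate_ld_block


def cand(vid, chrom, pos, p):
    return {"variant_id": vid, "chrom": str(chrom), "pos": pos, "pvalue": p,
            "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
            "beta": 0.1, "se": 0.01, "n": 1e5}


def cframe(*rows):
    df = pd.DataFrame(list(rows))
    df["pos"] = df["pos"].astype("Int64")
    return df


def oracle_clump(rows, ld_pairs, r2_max, window_kb):
    """Independent step-by-step greedy trace on plain Python structures."""
    def r2(a, b):
        return ld_pairs.get((a, b), ld_pairs.get((b, a), 0.0))

    remaining = sorted(rows, key=lambda r: (r["pvalue"], r["chrom"], r["pos"],
                                            r["variant_id"]))
    retained = []
    while remaining:
        best = remaining.pop(0)
        retained.append(best["variant_id"])
        survivors = []
        for r in remaining:
            close = (r["chrom"] == best["chrom"]
                     and abs(r["pos"] - best["pos"]) <= window_kb * 1000)
            if close and r2(best["variant_id"], r["variant_id"]) > r2_max:
                continue
            survivors.append(r)
        remaining = survivors
    return retained


class TestClump:
    def test_perfect_ld_keeps_lower_p(self):
        df = cframe(cand("a", 1, 1000, 1e-10), cand("b", 1, 6000, 1e-8))
        ld = LDTable([("a", "b", 1.0)])
        assert clump(df, ld, r2_max=0.01, window_kb=10) == ["a"]

    def test_independent_variants_all_retained(self):
        df = cframe(*[cand(f"v{i}", 1, i * 1000, 1e-9) for i in range(4)])
        assert len(clump(df, LDTable(), r2_max=0.01, window_kb=10_000)) == 4

    def test_window_limits_discarding(self):
        # high r2 but outside the window: both kept
        df = cframe(cand("a", 1, 0, 1e-10), cand("b", 1, 20_000_000, 1e-8))
        ld = LDTable([("a", "b", 0.9)])
        assert clump(df, ld, r2_max=0.01, window_kb=10_000) == ["a", "b"]

    def test_different_chromosomes_never_clumped(self):
        df = cframe(cand("a", 1, 1000, 1e-10), cand("b", 2, 1000, 1e-8))
        ld = LDTable([("a", "b", 1.0)])
        assert set(clump(df, ld, r2_max=0.01, window_kb=10_000)) == {"a", "b"}

    def test_empty_candidates_empty_result(self):
        assert clump(cframe(cand("a", 1, 1, 1))[:0], LDTable()) == []

    def test_missing_position_with_ld_raises(self):
        row = cand("a", 1, 1000, 1e-9)
        df = cframe(row, cand("b", 1, 2000, 1e-8))
        df.loc[0, "pos"] = pd.NA
        with pytest.raises(AnalysisError):
            clump(df, LDTable([("a", "b", 0.5)]))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_trace_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        rows = []
        for i in range(n):
            rows.append(cand(
                f"v{i}", chrom=int(rng.integers(1, 3)),
                pos=int(rng.integers(0, 30_000_000)),
                p=float(10.0 ** rng.uniform(-12, -4)),
            ))
        ld_pairs = {}
        ids = [r["variant_id"] for r in rows]
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5:
                    ld_pairs[(ids[i], ids[j])] = float(rng.random())
        df = cframe(*rows)
        ld = LDTable([(a, b, r) for (a, b), r in ld_pairs.items()])
        got = clump(df, ld, r2_max=0.1, window_kb=10_000)
        assert got == oracle_clump(rows, ld_pairs, 0.1, 10_000)
        # no retained pair may violate the constraint
        by_id = {r["variant_id"]: r for r in rows}
        for a in got:
            for b in got:
                if a < b and by_id[a]["chrom"] == by_id[b]["chrom"] \
                        and abs(by_id[a]["pos"] - by_id[b]["pos"]) <= 10_000_000:
                    assert ld.r2(a, b) <= 0.1

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        rows = [cand(f"v{i}", 1, int(rng.integers(0, 5_000_000)),
                     float(10.0 ** rng.uniform(-12, -6))) for i in range(8)]
        ld = LDTable([(f"v{i}", f"v{j}", 0.5) for i in range(8) for j in range(i + 1, 8)
                      if (i + j) % 3 == 0])
        base = clump(cframe(*rows), ld)
        for perm_seed in range(3):
            perm = np.random.default_rng(perm_seed).permutation(len(rows))
            shuffled = cframe(*[rows[k] for k in perm])
            assert clump(shuffled, ld) == base


class TestSelect:
    def test_filter_then_clump(self):
        rows = [cand(f"v{i}", 1, i * 20_000_000, 10.0 ** -(10 - i)) for i in range(10)]
        sel = select_instruments(cframe(*rows), p_threshold=5e-8)
        assert len(sel) == 3  # p = 1e-10, 1e-9, 1e-8
        assert sel.selection_params == (5e-8, 0.01, 10_000)

    def test_no_significant_variants_warns_empty(self):
        rows = [cand("v1", 1, 1, 0.5)]
        with pytest.warns(UserWarning, match="no variant"):
            sel = select_instruments(cframe(*rows))
        assert len(sel) == 0

    def test_relaxed_threshold_retains_superset(self):
        rng = np.random.default_rng(0)
        rows = [cand(f"v{i}", 1, i * 20_000_000,
                     float(10.0 ** rng.uniform(-10, -5))) for i in range(20)]
        strict = select_instruments(cframe(*rows), p_threshold=5e-8)
        relaxed = select_instruments(cframe(*rows), p_threshold=1e-6)
        assert set(strict.variant_ids) <= set(relaxed.variant_ids)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            select_instruments(cframe(cand("a", 1, 1, 1e-9)), p_threshold=2.0)


class TestVarianceExplainedContinuous:
    def test_freq_based_plugin(self):
        assert variance_explained_continuous(
            0.1, eaf=0.5, mode="freq_based") == pytest.approx(0.005)

    @pytest.mark.parametrize("mode,kw", [
        ("freq_based", dict(eaf=0.4)),
        ("z_based", dict(se=0.01, n=1e5)),
    ])
    def test_null_effect_is_zero(self, mode, kw):
        assert variance_explained_continuous(0.0, mode=mode, **kw) == 0.0

    def test_missing_field_named(self):
        with pytest.raises(ConfigurationError, match="eaf"):
            variance_explained_continuous(0.1, mode="freq_based")
        with pytest.raises(ConfigurationError, match="n"):
            variance_explained_continuous(0.1, se=0.01, mode="z_based")

    def test_z_based_matches_simulated_r2(self):
        """z-based formula vs the squared sample correlation of a matched
        genotype-phenotype simulation."""
        rng = np.random.default_rng(7)
        n, f, b = 60_000, 0.3, 0.05
        g = rng.binomial(2, f, n).astype(float)
        y = b * g + rng.normal(0, 1, n)
        # per-simulation summary stats
        X = np.column_stack([np.ones(n), g])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res[0] / (n - 2)
        se = float(np.sqrt(sigma2 / np.sum((g - g.mean()) ** 2)))
        r2_formula = variance_explained_continuous(coef[1], se=se, n=n, mode="z_based")
        r2_sample = float(np.corrcoef(g, y)[0, 1] ** 2)
        assert r2_formula == pytest.approx(r2_sample, rel=1e-3)

    def test_monotone_in_effect_size(self):
        vals = [variance_explained_continuous(b, se=0.01, n=1e5, mode="z_based")
                for b in (0.01, 0.02, 0.05, 0.1)]
        assert vals == sorted(vals)


class TestVarianceExplainedLiability:
    def test_null_odds_ratio(self):
        assert variance_explained_binary_liability(1.0, 0.3, 0.085) == 0.0

    def test_matches_liability_simulation_oracle(self):
        """Monte-Carlo oracle: simulate liabilities with the genotype mean
        shifts implied by the penetrances, threshold at 1 - prevalence, and
        check the realized odds ratio and variance."""
        orr, raf, K = 1.2, 0.3, 0.085
        got = variance_explained_binary_liability(orr, raf, K)

        from mrpipe.instruments import _liability_penetrances

        geno_freq, f = _liability_penetrances(orr, raf, K)
        T = stats.norm.isf(K)
        mu = T - stats.norm.isf(f)
        rng = np.random.default_rng(11)
        n = 2_000_000
        g = rng.choice(3, size=n, p=geno_freq)
        liab = mu[g] + rng.normal(0, 1, n)
        case = liab > T
        assert case.mean() == pytest.approx(K, rel=0.02)
        # realized per-genotype odds reproduce the multiplicative OR
        odds = [case[g == i].mean() / (1 - case[g == i].mean()) for i in range(3)]
        assert odds[1] / odds[0] == pytest.approx(orr, rel=0.03)
        var_mc = float(np.var(mu[g]))
        assert got == pytest.approx(var_mc, rel=0.01)

    def test_monotone_in_odds_ratio(self):
        vals = [variance_explained_binary_liability(o, 0.3, 0.085)
                for o in (1.05, 1.1, 1.3, 1.6, 2.0)]
        assert vals == sorted(vals)

    def test_small_effect_agrees_with_freq_based_on_liability_scale(self):
        """At 50% prevalence and OR near 1 the implied per-allele liability
        shift is ln(OR)·K(1−K)/φ(T); the liability VE then reduces to the
        continuous frequency formula to first order."""
        orr, raf, K = 1.02, 0.3, 0.5
        got = variance_explained_binary_liability(orr, raf, K)
        delta = np.log(orr) * K * (1 - K) / stats.norm.pdf(stats.norm.isf(K))
        expected = variance_explained_continuous(delta, eaf=raf, mode="freq_based")
        assert got == pytest.approx(expected, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            variance_explained_binary_liability(-1.0, 0.3, 0.085)
        with pytest.raises(ConfigurationError):
            variance_explained_binary_liability(1.2, 0.0, 0.085)

    def test_attach_totals(self, sumstats_factory):
        df = sumstats_factory([
            {"variant_id": "a", "beta": np.log(1.2), "se": 0.01, "eaf": 0.3,
             "effect_allele": "A", "other_allele": "G", "pvalue": 1e-9},
            {"variant_id": "b", "beta": np.log(0.9), "se": 0.01, "eaf": 0.6,
             "effect_allele": "A", "other_allele": "G", "pvalue": 1e-9},
        ])
        from mrpipe.instruments import InstrumentSet

        st_ = attach_variance_explained(
            InstrumentSet("t2d", df), trait_type="binary", prevalence=0.085)
        assert st_.total_r2 == pytest.approx(
            st_.members["variance_explained"].sum())
        assert (st_.members["variance_explained"] > 0).all()


class TestMeanF:
    def test_definition_single(self, harmonized_factory):
        h = harmonized_factory([0.1], [0.01], [0.0], [1.0])
        assert mean_f_statistic(h) == pytest.approx(100.0)

    def test_mean_of_two(self, sumstats_factory):
        df = sumstats_factory([
            {"variant_id": "a", "beta": 0.06, "se": 0.01,
             "effect_allele": "A", "other_allele": "G", "pvalue": 1e-9},
            {"variant_id": "b", "beta": 0.08, "se": 0.01,
             "effect_allele": "A", "other_allele": "G", "pvalue": 1e-9},
        ])
        assert mean_f_statistic(df) == pytest.approx(50.0)

    def test_empty_raises(self, sumstats_factory):
        df = sumstats_factory([{"variant_id": "a", "beta": 0.1, "se": 0.01,
                                "effect_allele": "A", "other_allele": "G",
                                "pvalue": 1e-9}])
        with pytest.raises(AnalysisError):
            mean_f_statistic(df[:0])

    def test_f_grows_with_sample_size(self):
        from mrpipe.synthetic_data import SimulationScenario, simulate_summary_stats

        fs = []
        for n in (10_000, 100_000, 1_000_000):
            exp, _, _ = simulate_summary_stats(
                SimulationScenario(J=50, n_exposure=n, seed=2))
            fs.append(mean_f_statistic(exp))
        assert fs == sorted(fs)


class TestLDBlockFixture:
    def test_independence_limit_retains_all(self):
        pos, ld = simulate_ld_block(6, decay_bp=1e-9)
        assert len(ld) == 0

    def test_perfect_ld_limit_retains_one_per_window(self):
        pos, ld = simulate_ld_block(6, spacing_bp=1000, decay_bp=1e12)
        df = pos.copy()
        df["pvalue"] = [1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5]
        kept = clump(df, ld, r2_max=0.01, window_kb=10_000)
        assert kept == [pos.loc[0, "variant_id"]]

    def test_mid_decay_matches_manual_trace(self):
        pos, ld = simulate_ld_block(10, spacing_bp=50_000, decay_bp=100_000)
        rng = np.random.default_rng(5)
        df = pos.copy()
        df["pvalue"] = 10.0 ** rng.uniform(-12, -6, 10)
        rows = df.to_dict(orient="records")
        ld_pairs = {}
        ids = list(df["variant_id"])
        for i in range(10):
            for j in range(i + 1, 10):
                r2 = ld.r2(ids[i], ids[j])
                if r2 > 0:
                    ld_pairs[(ids[i], ids[j])] = r2
        assert clump(df, ld, r2_max=0.1, window_kb=10_000) == \
            oracle_clump(rows, ld_pairs, 0.1, 10_000)
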