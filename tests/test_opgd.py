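"""GeoDetector q-statistic, discretization search, interaction and risk."""

import numpy as np
import pandas as pd
import pytest

from vegcarbon.opgd import (FactorLayer, classify_interaction, discretize,
                            factor_q, interaction_detect,
                            optimize_discretization, permutation_p,
                            risk_detect)


def q_brute_force(y, codes):
    """Independent group-by oracle: q = 1 − SSW/SST."""
    df = pd.DataFrame({"y": y, "g": codes})
    sst = df["y"].var(ddof=0) * len(df)
    ssw = sum(g["y"].var(ddof=0) * len(g) for _, g in df.groupby("g"))
    return 1.0 - ssw / sst


class TestDiscretize:
    def test_equal_interval_break(self):
        layer = discretize(np.arange(1.0, 11.0), "equal", 2)
        np.testing.assert_array_equal(layer.strata, [1] * 5 + [2] * 5)
        assert layer.provenance["breaks"] == [5.5]

    def test_quantile_balanced(self):
        layer = discretize(np.arange(1.0, 11.0), "quantile", 5)
        np.testing.assert_array_equal(layer.counts, [2, 2, 2, 2, 2])

    def test_natural_breaks_separates_modes(self):
        vals = np.concatenate([np.zeros(50), np.full(50, 100.0)])
        layer = discretize(vals, "natural_breaks", 2)
        assert layer.L == 2
        assert (layer.strata[:50] == 1).all() and (layer.strata[50:] == 2).all()

    def test_too_many_strata_named_failure(self):
        with pytest.raises(ValueError, match="elevation"):
            discretize(np.array([1.0, 1.0, 2.0]), "quantile", 3, name="elevation")

    @pytest.mark.parametrize("method", ["equal", "quantile", "natural_breaks",
                                        "geometric", "std_dev"])
    def test_every_method_covers_all_samples(self, method):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(1.0, 0.6, 300)
        layer = discretize(vals, method, 5)
        assert layer.strata.size == 300
        assert layer.counts.sum() == 300
        assert (layer.strata >= 1).all() and (layer.strata <= layer.L).all()


class TestFactorQ:
    def test_hand_cases(self):
        # perfect stratification: zero within-stratum variance
        res1 = factor_q([1.0, 1.0, 2.0, 2.0],
                        FactorLayer(np.array([1, 1, 2, 2]), L=2))
        assert res1.q == pytest.approx(1.0)
        # strata identical to the whole: no explanatory power
        res0 = factor_q([1.0, 2.0, 1.0, 2.0],
                        FactorLayer(np.array([1, 1, 2, 2]), L=2))
        assert res0.q == pytest.approx(0.0)
        # SSW = 1, SST = 5 → q = 0.8
        res = factor_q([0.0, 1.0, 2.0, 3.0],
                       FactorLayer(np.array([1, 1, 2, 2]), L=2))
        assert res.q == pytest.approx(0.8, abs=1e-15)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(20, 200)
            L = int(rng.integers(2, 6))
            codes = rng.integers(1, L + 1, n)
            if np.unique(codes).size < 2:
                continue
            y = rng.normal(size=n) + 0.5 * codes
            layer = FactorLayer(codes.astype(np.int32), L=L)
            res = factor_q(y, layer, significance="none")
            assert res.q == pytest.approx(
                np.clip(q_brute_force(y, codes), 0, 1), abs=1e-12)

    def test_invariances(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=120)
        codes = rng.integers(1, 4, 120).astype(np.int32)
        q0 = factor_q(y, FactorLayer(codes, L=3), significance="none").q
        # relabeling strata
        relab = np.array([0, 3, 1, 2])[codes]
        q1 = factor_q(y, FactorLayer(relab.astype(np.int32), L=3),
                      significance="none").q
        assert q1 == pytest.approx(q0, abs=1e-12)
        # location-scale transform of the response
        q2 = factor_q(5.0 * y - 7.0, FactorLayer(codes, L=3),
                      significance="none").q
        assert q2 == pytest.approx(q0, abs=1e-12)

    def test_refining_strata_never_decreases_q(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        coarse = rng.integers(1, 4, 200).astype(np.int32)
        fine = (coarse - 1) * 2 + rng.integers(1, 3, 200).astype(np.int32)
        q_c = factor_q(y, FactorLayer(coarse, L=3), significance="none").q
        q_f = factor_q(y, FactorLayer(fine, L=6), significance="none").q
        assert q_f >= q_c - 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            factor_q(np.ones(10), FactorLayer(np.tile([1, 2], 5), L=2))

    def test_significance_routes(self):
        rng = np.random.default_rng(4)
        codes = np.repeat([1, 2, 3], 40).astype(np.int32)
        strong = rng.normal(0, 1, 120) + 10.0 * codes
        layer = FactorLayer(codes, L=3)
        res_ncf = factor_q(strong, layer, significance="ncf")
        res_perm = factor_q(strong, layer, significance="permutation", seed=0,
                            n_permutations=199)
        assert res_ncf.p < 0.05 and res_perm.p < 0.05
        null = rng.normal(size=120)
        p_ncf = factor_q(null, layer, significance="ncf").p
        p_perm = factor_q(null, layer, significance="permutation", seed=0,
                          n_permutations=199).p
        assert p_ncf > 0.05 and p_perm > 0.05


class TestOptimize:
    def test_step_function_finds_three_strata(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 3, 300)
        y = np.floor(x)
        layer, res = optimize_discretization(x, y, L_range=range(3, 8))
        assert layer.L == 3
        assert res.q == pytest.approx(1.0)

    def test_null_factor_small_q(self):
        rng = np.random.default_rng(6)
        ok = 0
        for k in range(20):
            r = np.random.default_rng(100 + k)
            x = r.uniform(0, 1, 1000)
            y = r.normal(size=1000)
            _, res = optimize_discretization(x, y)
            ok += res.q < 0.1
        assert ok / 20 >= 0.95

    def test_tie_breaks_to_smaller_l(self):
        # y depends on x through 2 levels only: every L≥2 quantile split that
        # respects the boundary reaches the same q; smallest L must win
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(10, 11, 50)])
        y = np.concatenate([np.zeros(50), np.ones(50)])
        layer, res = optimize_discretization(x, y, methods=("quantile",),
                                             L_range=range(2, 6))
        assert res.q == pytest.approx(1.0)
        assert layer.L == 2

    def test_search_table_retained(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 200)
        y = x + rng.normal(0, 0.1, 200)
        _, res = optimize_discretization(x, y, methods=("equal", "quantile"),
                                         L_range=range(3, 6))
        table = res.discretization["search_table"]
        assert {"method", "L", "q"} <= set(table.columns)
        assert len(table) > 0

    def test_no_admissible_combination_raises(self):
        with pytest.raises(ValueError, match="admissible"):
            optimize_discretization(np.array([1.0, 2.0, 3.0]),
                                    np.array([1.0, 2.0, 3.0]),
                                    L_range=range(3, 4), name="tiny")


class TestInteraction:
    @pytest.mark.parametrize(
        "q1, q2, q12, expected",
        [
            (0.3, 0.4, 0.9, "nonlinear_enhancement"),
            (0.3, 0.4, 0.6, "linear_enhancement"),
            (0.3, 0.4, 0.7, "independence"),
            (0.3, 0.4, 0.35, "linear_weakening"),
            (0.3, 0.4, 0.2, "nonlinear_weakening"),
        ],
    )
    def test_rule_table(self, q1, q2, q12, expected):
        assert classify_interaction(q1, q2, q12) == expected

    def test_engineered_enhancement_on_data(self):
        # y needs both factors: q12 far exceeds q1 + q2
        rng = np.random.default_rng(8)
        n = 800
        a = rng.integers(1, 3, n).astype(np.int32)
        b = rng.integers(1, 3, n).astype(np.int32)
        y = 10.0 * ((a == 1) ^ (b == 1)) + rng.normal(0, 0.5, n)  # XOR pattern
        res = interaction_detect(y, FactorLayer(a, L=2), FactorLayer(b, L=2))
        assert res.interaction_type == "nonlinear_enhancement"
        assert res.q12 > 0.9 and max(res.q1, res.q2) < 0.1

    def test_engineered_redundancy_weakens(self):
        # two noisy copies of the same stratification: q12 < q1 + q2
        rng = np.random.default_rng(9)
        n = 800
        a = rng.integers(1, 4, n).astype(np.int32)
        y = 5.0 * a + rng.normal(0, 1.0, n)
        flip = rng.random(n) < 0.05
        b = a.copy()
        b[flip] = rng.integers(1, 4, int(flip.sum())).astype(np.int32)
        res = interaction_detect(y, FactorLayer(a, L=3), FactorLayer(b, L=3))
        assert res.q12 <= res.q1 + res.q2
        assert res.interaction_type in ("linear_enhancement", "linear_weakening")

    def test_small_cross_strata_merged(self):
        n = 60
        a = np.ones(n, dtype=np.int32)
        a[-1] = 2  # one lonely sample in stratum 2
        b = np.tile([1, 2], n // 2).astype(np.int32)
        y = np.random.default_rng(10).normal(size=n) + b
        res = interaction_detect(y, FactorLayer(a, L=2), FactorLayer(b, L=2))
        assert 0.0 <= res.q12 <= 1.0  # completes despite singleton cross-stratum


class TestRisk:
    def test_constructed_optimum(self):
        rng = np.random.default_rng(11)
        codes = np.repeat([1, 2, 3], 50).astype(np.int32)
        y = np.concatenate([rng.normal(100, 5, 50), rng.normal(300, 5, 50),
                            rng.normal(500, 5, 50)])
        res = risk_detect(y, FactorLayer(codes, L=3))
        assert res.optimal_stratum == 3
        assert res.minimal_stratum == 1
        assert res.pairwise_p[0, 2] < 0.05

    def test_null_rarely_significant(self):
        hits, reps = 0, 30
        for k in range(reps):
            rng = np.random.default_rng(200 + k)
            codes = np.repeat([1, 2, 3], 30).astype(np.int32)
            y = rng.normal(0, 1, 90)
            res = risk_detect(y, FactorLayer(codes, L=3))
            ps = res.pairwise_p[np.triu_indices(3, 1)]
            hits += (ps < 0.05 / 3).any()  # count-adjusted threshold
        assert hits / reps <= 0.10

    def test_recovery_from_generator_truth(self, small_drivers):
        drivers, effect, truth = small_drivers
        y = effect.values.ravel()
        layer = FactorLayer.from_codes(drivers["impervious_change"].values)
        res = risk_detect(y, layer)
        expected = truth.stratum_means["impervious_change"]
        np.testing.assert_allclose(res.stratum_means, expected, atol=20.0)
        assert res.optimal_stratum == int(np.argmax(expected)) + 1

    def test_singleton_stratum_mean_reported_but_untested(self):
        codes = np.array([1, 1, 1, 1, 2], dtype=np.int32)
        y = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        res = risk_detect(y, FactorLayer(codes, L=2))
        assert res.stratum_means[1] == 10.0
        assert np.isnan(res.pairwise_p[0, 1])

    def test_label_count_checked(self):
        codes = np.tile([1, 2], 10).astype(np.int32)
        with pytest.raises(ValueError, match="labels"):
            risk_detect(np.arange(20.0), FactorLayer(codes, L=2), labels=["a"])
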