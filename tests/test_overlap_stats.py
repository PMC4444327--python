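"""Z-test, status encoding, weighted kappa, permutation overlap test."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa
from statsmodels.stats.proportion import proportions_ztest

from cnvscan import (
    StatusPair,
    encode_status,
    enrichment_test,
    overlap_permutation,
    two_proportion_z,
    weighted_kappa,
)


class TestTwoProportionZ:
    def test_equal_proportions_zero(self):
        z, p = two_proportion_z(50, 100, 50, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # (30/100 vs 10/100), pooled p = 0.2: z = 0.2/sqrt(0.2*0.8*0.02)
        z, p = two_proportion_z(30, 100, 10, 100)
        assert z == pytest.approx(3.5355339, rel=1e-6)
        assert p == pytest.approx(2 * stats.norm.sf(3.5355339), rel=1e-6)

    def test_all_zero_counts(self):
        z, p = two_proportion_z(0, 10, 0, 10)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            z1, p1 = two_proportion_z(k1, n1, k2, n2)
            z2, p2 = two_proportion_z(k2, n2, k1, n1)
            assert z1 == pytest.approx(-z2)
            assert p1 == pytest.approx(p2)

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(10, 300)), int(rng.integers(10, 300))
            k1, k2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
            z, p = two_proportion_z(k1, n1, k2, n2)
            z_ref, p_ref = proportions_ztest([k1, k2], [n1, n2])
            assert z == pytest.approx(z_ref, rel=1e-9)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z(11, 10, 0, 10)


class TestEnrichmentTest:
    def test_equal_rates_zero(self):
        tested = {f"g{i}" for i in range(100)}
        cnv = {f"g{i}" for i in range(20)}
        de = {f"g{i}" for i in range(0, 100, 5)}  # 20% inside and outside
        z, p = enrichment_test(tested, cnv, de)
        assert z == pytest.approx(0.0)

    def test_concentrated_de_strongly_positive(self):
        tested = {f"g{i}" for i in range(100)}
        cnv = {f"g{i}" for i in range(10)}
        z, p = enrichment_test(tested, cnv, cnv)  # all DE genes inside CNVs
        assert z > 5 and p < 1e-6

    def test_null_calibration(self, rng):
        # p-values from counts are discrete, so calibration is checked
        # through the rejection rate and the mean rather than a KS test
        tested = [f"g{i}" for i in range(400)]
        cnv = set(tested[:80])
        ps = []
        for _ in range(1000):
            de = set(rng.choice(tested, size=100, replace=False))
            ps.append(enrichment_test(set(tested), cnv, de)[1])
        ps = np.asarray(ps)
        lo, hi = stats.binom.interval(0.999, len(ps), 0.05)
        assert lo <= (ps < 0.05).sum() <= hi
        assert abs(ps.mean() - 0.5) < 0.05

    def test_empty_cnv_set_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test({"a"}, set(), {"a"})


class TestEncodeStatus:
    def test_consistent_gene_single_row(self):
        pairs = encode_status([("g1", 1)], [("g1", 1)])
        assert pairs == [StatusPair("g1", 1, 1)]

    def test_contradictory_cnv_duplicates_both_signs(self):
        pairs = encode_status([("g1", 1), ("g1", -1)], [("g1", 1)])
        assert pairs == [StatusPair("g1", -1, 1), StatusPair("g1", 1, 1)]

    def test_gene_without_expression_status_excluded(self):
        assert encode_status([("g1", 1)], [("g2", -1)]) == []

    def test_row_count_bound(self, rng):
        genes = [f"g{i}" for i in range(30)]
        cnv = [(g, int(s)) for g in genes for s in rng.choice([-1, 1], rng.integers(1, 3), replace=False)]
        expr = [(g, int(s)) for g in genes[:20] for s in rng.choice([-1, 1], rng.integers(1, 3), replace=False)]
        pairs = encode_status(cnv, expr)
        both = {g for g, _ in cnv} & {g for g, _ in expr}
        assert len(pairs) >= len(both)
        contradiction_free = all(
            len({p.cnv_status for p in pairs if p.gene_id == g}) == 1
            and len({p.expr_status for p in pairs if p.gene_id == g}) == 1
            for g in both
        )
        if contradiction_free:
            assert len(pairs) == len(both)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        pairs = [(1, 1)] * 6 + [(-1, -1)] * 4
        k, p = weighted_kappa(pairs)
        assert k == pytest.approx(1.0)
        assert p < 0.05

    def test_independence_gives_zero(self):
        # counts = outer product of margins: (2,2;3,3) rows x cols
        pairs = [(1, 1)] * 2 + [(1, -1)] * 2 + [(-1, 1)] * 3 + [(-1, -1)] * 3
        k, _ = weighted_kappa(pairs)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2_table(self):
        # table (10, 2; 3, 15): p_o = 25/30, p_e = 462/900
        pairs = [(1, 1)] * 10 + [(1, -1)] * 2 + [(-1, 1)] * 3 + [(-1, -1)] * 15
        k, p = weighted_kappa(pairs)
        assert k == pytest.approx((25 / 30 - 462 / 900) / (1 - 462 / 900), rel=1e-12)

    def test_linear_equals_quadratic_for_binary(self, rng):
        pairs = [
            (int(c), int(e))
            for c, e in zip(rng.choice([-1, 1], 40), rng.choice([-1, 1], 40))
        ]
        if len({c for c, _ in pairs}) > 1 and len({e for _, e in pairs}) > 1:
            k_lin, p_lin = weighted_kappa(pairs, "linear")
            k_quad, p_quad = weighted_kappa(pairs, "quadratic")
            assert k_lin == pytest.approx(k_quad)
            assert p_lin == pytest.approx(p_quad)

    def test_matches_statsmodels_kappa(self):
        table = np.array([[10, 2], [3, 15]])
        pairs = [(1, 1)] * 10 + [(1, -1)] * 2 + [(-1, 1)] * 3 + [(-1, -1)] * 15
        k, _ = weighted_kappa(pairs)
        ref = cohens_kappa(table, wt="ca")  # linear weights == binary case
        assert k == pytest.approx(ref.kappa, rel=1e-9)

    def test_degenerate_margin_flagged(self):
        k, p = weighted_kappa([(1, 1), (1, -1), (1, 1)])
        assert np.isnan(k) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa([(1, 1)])


class TestOverlapPermutation:
    def test_zero_observed_p_one(self):
        res = overlap_permutation(100, 10, 10, 0, replicates=200, seed=1)
        assert res.p == 1.0

    def test_determinism_under_seed(self):
        a = overlap_permutation(200, 20, 30, 6, replicates=500, seed=42)
        b = overlap_permutation(200, 20, 30, 6, replicates=500, seed=42)
        assert a == b

    def test_p_monotone_in_observed(self):
        ps = [
            overlap_permutation(200, 20, 30, obs, replicates=500, seed=7).p
            for obs in range(0, 10)
        ]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_fix_a_matches_hypergeometric_tail(self):
        """p within 3 Monte-Carlo SE of the exact hypergeometric tail."""
        N, na, nb, obs, reps = 500, 68, 78, 15, 10_000
        res = overlap_permutation(N, na, nb, obs, replicates=reps, seed=3, mode="fix_a")
        exact = float(stats.hypergeom.sf(obs - 1, N, na, nb))
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(res.p - exact) <= 3 * se + 2 / reps

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            overlap_permutation(10, 20, 5, 1)
        with pytest.raises(ValueError):
            overlap_permutation(100, 10, 10, 11)
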