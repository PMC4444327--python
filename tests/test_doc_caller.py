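"""Depth-of-coverage caller: coverage rules, per-bin test, segmentation."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact

from cnvscan import (
    BinTrack,
    ChromMap,
    QTrack,
    bh_qvalues,
    bin_coverage,
    bin_fisher,
    call_doc,
    segment_cnvs,
)
from cnvscan.doc_caller import _fisher_batch

from conftest import make_read


def exact_fisher_two_sided(a, b, ta, tb):
    """Oracle: exact-rational two-sided Fisher via full hypergeometric
    enumeration over all tables with the observed margins."""
    K = a + b
    M = ta + tb

    def pmf(k):
        return (
            Fraction(math.comb(ta, k) * math.comb(tb, K - k), math.comb(M, K))
        )

    obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, K - tb), min(ta, K) + 1):
        p = pmf(k)
        if p <= obs:
            total += p
    return min(total, Fraction(1))


class TestBinCoverage:
    def test_single_read_counts_in_overlapped_bins(self, chrom_map):
        # 60 bp read fully inside bin 3 ([600, 800) at bin_size 200)
        reads = [make_read(start=650)]
        track = bin_coverage(reads, [], chrom_map)[0]
        assert track.counts_a[3] == 1
        assert track.counts_a.sum() == 1
        assert track.counts_b.sum() == 0

    def test_read_spanning_two_bins_counts_in_both(self, chrom_map):
        reads = [make_read(start=190)]  # spans bins 0 and 1
        track = bin_coverage(reads, [], chrom_map)[0]
        assert track.counts_a[0] == 1 and track.counts_a[1] == 1

    def test_pair_inner_span_covers_bins(self, chrom_map):
        # leftmost mate at 940, fragment 1280: inner span [1000, 2160)
        # covers bins 5..10; read spans add bins 4 (left) and 10-11 (right)
        reads = [
            make_read(start=940, insert_size=1280),
            make_read(start=2160, insert_size=-1280),
        ]
        track = bin_coverage(reads, [], chrom_map)[0]
        for b in range(5, 10):
            assert track.counts_a[b] >= 1
        assert track.counts_a[4] == 1  # left read only
        assert track.counts_a[2] == 0

    def test_no_reads_all_zero(self, chrom_map):
        tracks = bin_coverage([], [], chrom_map)
        assert all(t.counts_a.sum() == 0 and t.counts_b.sum() == 0 for t in tracks)
        assert tracks[0].n_bins == math.ceil(10_000 / 200)

    def test_bad_bin_size_rejected(self, chrom_map):
        with pytest.raises(ValueError):
            bin_coverage([], [], chrom_map, bin_size=0)


class TestBinFisher:
    def test_equal_proportions_p_one(self):
        assert bin_fisher(10, 10, 100, 100) == pytest.approx(1.0)

    def test_zero_counts_p_one(self):
        assert bin_fisher(0, 0, 100, 100) == pytest.approx(1.0)

    def test_matches_exact_enumeration_oracle(self, rng):
        for _ in range(200):
            ta = int(rng.integers(1, 501))
            tb = int(rng.integers(1, 501))
            a = int(rng.integers(0, ta + 1))
            b = int(rng.integers(0, tb + 1))
            expected = float(exact_fisher_two_sided(a, b, ta, tb))
            got = bin_fisher(a, b, ta, tb)
            assert got == pytest.approx(expected, rel=1e-9), (a, b, ta, tb)

    def test_matches_scipy_fisher_exact(self, rng):
        for _ in range(50):
            ta = int(rng.integers(1, 301))
            tb = int(rng.integers(1, 301))
            a = int(rng.integers(0, ta + 1))
            b = int(rng.integers(0, tb + 1))
            ref = fisher_exact([[a, ta - a], [b, tb - b]])[1]
            assert bin_fisher(a, b, ta, tb) == pytest.approx(ref, rel=1e-7)

    def test_batch_agrees_with_scalar(self, rng):
        counts_a = rng.integers(0, 50, size=30)
        counts_b = rng.integers(0, 50, size=30)
        batch = _fisher_batch(counts_a, counts_b, 1000, 900)
        for i in range(30):
            assert batch[i] == pytest.approx(
                bin_fisher(int(counts_a[i]), int(counts_b[i]), 1000, 900)
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bin_fisher(10, 0, 5, 100)
        with pytest.raises(ValueError):
            bin_fisher(0, 0, 0, 100)


def brute_force_bh(p):
    """Step-up definition: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = [(p[j], r + 1) for r, j in enumerate(order)]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(
            min(m * pj / rj for pj, rj in ranked if pj >= p[i]), 1.0
        )
    return q


class TestBhQvalues:
    def test_single_p_unchanged(self):
        assert bh_qvalues([0.3])[0] == pytest.approx(0.3)

    def test_hand_example(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_qvalues([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for n in (2, 7, 50, 1000):
            p = rng.random(n)
            assert bh_qvalues(p) == pytest.approx(brute_force_bh(p))

    def test_step_up_monotone_in_p_order(self, rng):
        p = rng.random(100)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


def _tracks(neglogq, counts_a=None, counts_b=None, bin_size=200):
    n = len(neglogq)
    q = 10.0 ** (-np.asarray(neglogq, dtype=float))
    ca = np.full(n, 100) if counts_a is None else np.asarray(counts_a)
    cb = np.full(n, 100) if counts_b is None else np.asarray(counts_b)
    bt = BinTrack(chrom="chr1", bin_size=bin_size, counts_a=ca, counts_b=cb)
    qt = QTrack(chrom="chr1", p=q, q=q)
    return qt, bt


class TestSegmentCnvs:
    def test_seed_with_flanking_extension_bins(self):
        neglogq = [0] + [11] + [13] * 8 + [11] + [0] * 9
        counts_a = np.where(np.array(neglogq) > 0, 200, 100)
        qt, bt = _tracks(neglogq, counts_a=counts_a)
        calls = segment_cnvs(qt, bt, seed_neglog_q=12, window=8, ext_neglog_q=10)
        assert len(calls) == 1
        call = calls[0]
        assert call.n_bins == 10
        assert call.length == 2_000
        assert (call.start, call.end) == (200, 2_200)
        assert call.direction == "gain"

    def test_seven_bins_below_window_no_call(self):
        neglogq = [0] * 5 + [13] * 7 + [0] * 8
        qt, bt = _tracks(neglogq)
        assert segment_cnvs(qt, bt, 12, 8, 10) == []

    def test_all_below_thresholds_empty(self):
        qt, bt = _tracks([1.0] * 30)
        assert segment_cnvs(qt, bt, 12, 8, 10) == []

    def test_minimum_call_length_by_construction(self, rng):
        # fuzz: random q-tracks never produce a call shorter than
        # window * bin_size, and boundaries are bin multiples
        for _ in range(200):
            neglogq = rng.random(60) * 20
            counts_a = rng.integers(50, 300, size=60)
            qt, bt = _tracks(neglogq, counts_a=counts_a)
            for call in segment_cnvs(qt, bt, 12, 8, 10):
                assert call.length >= 8 * 200
                assert call.start % 200 == 0 and call.end % 200 == 0

    def test_raising_seed_threshold_never_adds_calls(self, rng):
        neglogq = rng.random(200) * 25
        qt, bt = _tracks(neglogq)
        n_calls = [len(segment_cnvs(qt, bt, s, 8, 7.0)) for s in (8, 12, 16, 20)]
        assert all(a >= b for a, b in zip(n_calls, n_calls[1:]))

    def test_window_validation(self):
        qt, bt = _tracks([0.0] * 10)
        with pytest.raises(ValueError):
            segment_cnvs(qt, bt, 12, 0, 10)


class TestCallDoc:
    def test_identical_samples_no_calls(self, rng, chrom_map):
        reads = [
            make_read(start=int(s), insert_size=1500)
            for s in rng.integers(0, 8_000, size=2_000)
        ]
        assert call_doc(reads, list(reads), chrom_map, profile="desk") == []

    def test_swapping_samples_flips_directions(self):
        from cnvscan import PlantedCnv, SimConfig, chrom_map_from_config, simulate_alignments

        cfg = SimConfig(
            seed=7,
            chrom_lengths={"chr1": 300_000},
            coverage=100.0,
            cnvs=[PlantedCnv("chr1", 100_000, 110_000, 1.0, 0.0)],
            low_mapq_frac=0.0,
            duplicate_frac=0.0,
        )
        ra, rb, _ = simulate_alignments(cfg)
        cm = chrom_map_from_config(cfg)
        fwd = call_doc(ra, rb, cm, profile="desk")
        rev = call_doc(rb, ra, cm, profile="desk")
        assert [(c.start, c.end) for c in fwd] == [(c.start, c.end) for c in rev]
        for f, r in zip(fwd, rev):
            assert f.direction != r.direction
            assert f.log2_fold_change == pytest.approx(-r.log2_fold_change)

    def test_no_false_positives_under_null(self):
        """Two samples from the same coverage process: expect no calls."""
        from cnvscan import SimConfig, chrom_map_from_config, simulate_alignments

        total_calls = 0
        for seed in range(20):
            cfg = SimConfig(
                seed=seed,
                chrom_lengths={"chr1": 1_000_000},
                coverage=100.0,
                low_mapq_frac=0.0,
                duplicate_frac=0.0,
            )
            ra, rb, _ = simulate_alignments(cfg)
            total_calls += len(
                call_doc(ra, rb, chrom_map_from_config(cfg), profile="desk")
            )
        assert total_calls <= 1
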