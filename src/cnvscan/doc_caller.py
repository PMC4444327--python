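"""Two-sample depth-of-coverage CNV calling.

The caller divides each chromosome into equal-size bins (default
200 bp) and computes, per sample, a coverage count for every bin as the
sum of (i) the number of reads whose aligned span overlaps the bin and
(ii) the number of mate pairs whose inner span (the unsequenced
interval between the two mates) overlaps the bin. Each bin is then
compared between the two samples with a two-sided Fisher exact test
against the remainder of the chromosome, p-values are
Benjamini-Hochberg corrected per chromosome, and candidate CNVs are
segmented with a seed-and-extend rule on the -log10(q) track: a seed is
a run of at least ``window`` consecutive bins above the seed threshold,
extended bin-by-bin in both directions while bins stay above the looser
extension threshold. The minimum callable event is therefore
``window * bin_size`` bp (1,600 bp at the defaults).

Two threshold profiles ship with the package: ``deep`` (seed
-log10(q) > 12, extension > 10, window 8), which requires deep
mate-pair coverage, and ``desk`` (seed > 4, extension > 3), sized for
the coverage the bundled simulator produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment_io import AlignedRead, ChromMap

# -log10 floor for p = 0
_P_FLOOR = 1e-300

#: Threshold profiles: (seed_neglog_q, window, ext_neglog_q)
PROFILES: dict[str, tuple[float, int, float]] = {
    "deep": (12.0, 8, 10.0),
    "desk": (4.0, 8, 3.0),
}

DEFAULT_BIN_SIZE = 200


@dataclass
class BinTrack:
    """Per-bin coverage for two samples on one chromosome."""

    chrom: str
    bin_size: int
    counts_a: np.ndarray
    counts_b: np.ndarray
    total_a: int = field(init=False)
    total_b: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts_a = np.asarray(self.counts_a, dtype=np.int64)
        self.counts_b = np.asarray(self.counts_b, dtype=np.int64)
        if self.counts_a.shape != self.counts_b.shape:
            raise ValueError("count vectors differ in length")
        self.total_a = int(self.counts_a.sum())
        self.total_b = int(self.counts_b.sum())

    @property
    def n_bins(self) -> int:
        return len(self.counts_a)


@dataclass
class QTrack:
    """Per-bin p-values, BH q-values and -log10(q) for one chromosome."""

    chrom: str
    p: np.ndarray
    q: np.ndarray

    @property
    def neglog_q(self) -> np.ndarray:
        return -np.log10(np.maximum(self.q, _P_FLOOR))


@dataclass(frozen=True)
class CnvCall:
    """A called copy-number interval, 0-based half-open.

    ``direction`` and the log2 fold change are oriented to sample A:
    positive fold change / ``gain`` means more copies in A than in B.
    """

    chrom: str
    start: int
    end: int
    n_bins: int
    direction: Literal["gain", "loss"]
    log2_fold_change: float
    min_neglog_q: float
    mean_neglog_q: float

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def _coverage_intervals(reads: Iterable[AlignedRead]) -> dict[str, list[tuple[int, int]]]:
    """Half-open intervals contributing coverage, per chromosome.

    Every read contributes its aligned span. The leftmost mate of a
    proper pair (positive insert) additionally contributes the pair's
    inner span, so each pair's insert is counted once.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        ivs = out.setdefault(r.chrom, [])
        ivs.append((r.start, r.end))
        if r.paired and r.insert_size is not None and r.insert_size > 0:
            inner_start = r.end
            inner_end = r.start + r.insert_size - r.read_length
            if inner_end > inner_start:
                ivs.append((inner_start, inner_end))
    return out


def _bin_counts(
    intervals: Sequence[tuple[int, int]], n_bins: int, bin_size: int
) -> np.ndarray:
    """Number of intervals overlapping each bin, via a difference array."""
    counts = np.zeros(n_bins + 1, dtype=np.int64)
    if intervals:
        arr = np.asarray(intervals, dtype=np.int64)
        first = np.clip(arr[:, 0] // bin_size, 0, n_bins - 1)
        last = np.clip((arr[:, 1] - 1) // bin_size, 0, n_bins - 1)
        np.add.at(counts, first, 1)
        np.add.at(counts, last + 1, -1)
    return np.cumsum(counts)[:n_bins]


def bin_coverage(
    reads_a: Iterable[AlignedRead],
    reads_b: Iterable[AlignedRead],
    chrom_map: ChromMap,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[BinTrack]:
    """Compute the two-sample per-bin coverage tracks.

    Expects reads that are already mapq-filtered and deduplicated. A
    bin's count is the number of read spans plus pair inner spans that
    overlap it. Returns one BinTrack per chromosome in map order.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    by_chrom_a = _coverage_intervals(reads_a)
    by_chrom_b = _coverage_intervals(reads_b)
    tracks = []
    for chrom, length in chrom_map.items():
        n_bins = math.ceil(length / bin_size)
        tracks.append(
            BinTrack(
                chrom=chrom,
                bin_size=bin_size,
                counts_a=_bin_counts(by_chrom_a.get(chrom, []), n_bins, bin_size),
                counts_b=_bin_counts(by_chrom_b.get(chrom, []), n_bins, bin_size),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Per-bin testing
# ---------------------------------------------------------------------------


def bin_fisher(count_a: int, count_b: int, total_a: int, total_b: int) -> float:
    """Two-sided Fisher exact p for [[a, A-a], [b, B-b]].

    Computed as the two-sided hypergeometric tail: the sum, over all
    tables with the observed margins, of probabilities not exceeding
    the observed table's probability.
    """
    _check_fisher_args(count_a, count_b, total_a, total_b)
    return float(
        _fisher_batch(
            np.array([count_a]), np.array([count_b]), total_a, total_b
        )[0]
    )


def _check_fisher_args(a: int, b: int, ta: int, tb: int) -> None:
    if ta <= 0 or tb <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= a <= ta and 0 <= b <= tb):
        raise ValueError("counts must lie within [0, total]")


def _fisher_batch(
    counts_a: np.ndarray, counts_b: np.ndarray, total_a: int, total_b: int
) -> np.ndarray:
    """Vectorized two-sided Fisher exact test with shared margins.

    For fixed margins the table is determined by the top-left cell a,
    which under the null follows Hypergeometric(M=A+B, n=A, K=a+b).
    The support has at most a+b+1 points, so the two-sided tail is an
    explicit sum. Duplicate (a, b) pairs are computed once.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    pairs, inverse = np.unique(
        np.stack([counts_a, counts_b], axis=1), axis=0, return_inverse=True
    )
    M = total_a + total_b
    pvals = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        K = int(a + b)
        lo = max(0, K - total_b)
        hi = min(total_a, K)
        support = np.arange(lo, hi + 1)
        logpmf = stats.hypergeom.logpmf(support, M, K, total_a)
        obs = logpmf[int(a) - lo]
        # relative tolerance guards ties against log-space round-off
        pvals[i] = min(1.0, float(np.exp(logpmf[logpmf <= obs + 1e-7]).sum()))
    return pvals[inverse]


def bh_qvalues(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def qtrack_from_bins(track: BinTrack) -> QTrack:
    """Fisher-test every bin against the rest of its chromosome, then BH."""
    p = _fisher_batch(track.counts_a, track.counts_b, track.total_a, track.total_b)
    return QTrack(chrom=track.chrom, p=p, q=bh_qvalues(p))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _log2_fc(track: BinTrack, lo: int, hi: int) -> float:
    """log2 of total-normalized coverage ratio A/B over bins [lo, hi).

    A 0.5 pseudocount on the interval sums keeps the ratio finite for
    homozygous events.
    """
    sum_a = track.counts_a[lo:hi].sum() + 0.5
    sum_b = track.counts_b[lo:hi].sum() + 0.5
    return float(np.log2((sum_a / track.total_a) / (sum_b / track.total_b)))


def _bin_ratio_sign(track: BinTrack) -> np.ndarray:
    """Sign of the per-bin normalized A/B ratio (pseudocounted)."""
    ra = (track.counts_a + 0.5) / track.total_a
    rb = (track.counts_b + 0.5) / track.total_b
    return np.sign(np.log2(ra / rb))


def segment_cnvs(
    qtrack: QTrack,
    bintrack: BinTrack,
    seed_neglog_q: float = 12.0,
    window: int = 8,
    ext_neglog_q: float = 10.0,
) -> list[CnvCall]:
    """Seed-and-extend segmentation of the -log10(q) track into calls.

    A seed is >= ``window`` consecutive bins with -log10(q) strictly
    above ``seed_neglog_q``; it is extended bin-by-bin outward over
    bins strictly above ``ext_neglog_q``, bridging interior dips of
    fewer than ``window`` consecutive sub-threshold bins (a stretch
    shorter than the caller's own minimum event cannot be confidently
    normal, so it does not terminate the call; the call boundary is
    always an above-threshold bin). Extended candidates that touch,
    overlap, or are separated by less than ``window`` bins are merged
    by the same logic. A merged candidate whose per-bin
    normalized ratio changes sign is split at the sign changes; pieces
    shorter than ``window`` bins are dropped so every emitted call is
    at least ``window * bin_size`` bp.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    score = qtrack.neglog_q
    n = len(score)
    if n != bintrack.n_bins:
        raise ValueError("qtrack and bintrack do not share binning")

    above_seed = score > seed_neglog_q
    above_ext = score > ext_neglog_q

    def _extend_left(mask: np.ndarray, lo: int, w: int) -> int:
        # furthest above-threshold bin reachable leftward without
        # crossing w consecutive below-threshold bins
        while True:
            j = lo - 1
            while j >= 0 and j > lo - 1 - (w - 1) and not mask[j]:
                j -= 1
            if j < 0 or not mask[j]:
                return lo
            lo = j

    def _extend_right(mask: np.ndarray, hi: int, size: int, w: int) -> int:
        # hi is exclusive; the boundary always lands past an
        # above-threshold bin
        while True:
            j = hi
            while j < size and j < hi + (w - 1) and not mask[j]:
                j += 1
            if j >= size or not mask[j]:
                return hi
            hi = j + 1

    # seeds: runs of >= window consecutive bins above the seed threshold
    candidates: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if above_seed[i]:
            j = i
            while j < n and above_seed[j]:
                j += 1
            if j - i >= window:
                candidates.append((_extend_left(above_ext, i, window),
                                   _extend_right(above_ext, j, n, window)))
            i = j
        else:
            i += 1

    # merge extended candidates that touch/overlap or are separated by a
    # gap below the caller's own resolution (window bins): a sub-window
    # stretch between two candidates could never be called normal on
    # its own, so the separation carries no evidence of two events
    merged: list[tuple[int, int]] = []
    for lo, hi in candidates:
        if merged and lo - merged[-1][1] < window:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))

    # split candidates at per-bin ratio sign changes; one direction per call
    signs = _bin_ratio_sign(bintrack)
    pieces: list[tuple[int, int]] = []
    for lo, hi in merged:
        start = lo
        for k in range(lo + 1, hi):
            if signs[k] != signs[start] and signs[k] != 0 and signs[start] != 0:
                pieces.append((start, k))
                start = k
        pieces.append((start, hi))

    calls = []
    for lo, hi in pieces:
        if hi - lo < window:
            continue
        fc = _log2_fc(bintrack, lo, hi)
        seg = score[lo:hi]
        end_bp = hi * bintrack.bin_size
        calls.append(
            CnvCall(
                chrom=qtrack.chrom,
                start=lo * bintrack.bin_size,
                end=end_bp,
                n_bins=hi - lo,
                direction="gain" if fc > 0 else "loss",
                log2_fold_change=fc,
                min_neglog_q=float(seg.min()),
                mean_neglog_q=float(seg.mean()),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def call_doc(
    reads_a: Iterable[AlignedRead],
    reads_b: Iterable[AlignedRead],
    chrom_map: ChromMap,
    bin_size: int = DEFAULT_BIN_SIZE,
    seed_neglog_q: float = 12.0,
    window: int = 8,
    ext_neglog_q: float = 10.0,
    profile: str | None = None,
) -> list[CnvCall]:
    """Full depth-of-coverage pipeline: bin, test, correct, segment.

    ``profile`` ("deep" or "desk") overrides the three thresholds.
    Deterministic for fixed input; calling with A and B swapped yields
    the same intervals with directions flipped.
    """
    if profile is not None:
        seed_neglog_q, window, ext_neglog_q = PROFILES[profile]
    calls: list[CnvCall] = []
    for track in bin_coverage(reads_a, reads_b, chrom_map, bin_size):
        if track.total_a == 0 or track.total_b == 0:
            continue
        qtrack = qtrack_from_bins(track)
        calls.extend(
            segment_cnvs(qtrack, track, seed_neglog_q, window, ext_neglog_q)
        )
    return calls


def calls_to_bed(calls: Iterable[CnvCall]) -> str:
    """Render calls as BED6+ text (0-based half-open)."""
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand\tn_bins\tlog2_fc\tdirection\tmin_neglog_q"]
    for i, c in enumerate(calls, start=1):
        lines.append(
            f"{c.chrom}\t{c.start}\t{c.end}\tcnv_{i}\t"
            f"{min(1000, int(round(c.mean_neglog_q * 10)))}\t.\t"
            f"{c.n_bins}\t{c.log2_fold_change:.4f}\t{c.direction}\t{c.min_neglog_q:.3f}"
        )
    return "\n".join(lines) + "\n"
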