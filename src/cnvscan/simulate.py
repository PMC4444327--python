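"""Synthetic inputs with known truth for every pipeline stage.

Two generators: (1) mate-pair alignments for two samples with planted
copy-number events, emulating deep mate-pair sequencing of two inbred
lines (read pairs from a Poisson process whose local rate scales with
the planted copy ratio; fragment length Normal(2000, 100) truncated
positive, 60 bp reads); (2) a genotyping-array cohort — integer copy
numbers per (sample, region), probe intensities linear in copy number
with Gaussian noise, a block-family kinship, and a phenotype combining
CNV effects, a kinship-structured polygenic term and environmental
noise. Both are pure functions of (config, seed). A truth-based
evaluator scores calls against planted events by reciprocal overlap
and direction.

Coverage is simulated at the read-pair level, not as per-bin counts,
so the depth-of-coverage rule (read spans plus pair inner spans) is
genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import AlignedRead, ChromMap
from .association import KinshipMatrix
from .cnv_unify import reciprocal_overlap
from .doc_caller import CnvCall
from .intensity_hmm import ProbeIntensity


@dataclass(frozen=True)
class PlantedCnv:
    """A planted event: copy ratios are relative to the diploid baseline."""

    chrom: str
    start: int
    end: int
    ratio_a: float = 1.0
    ratio_b: float = 1.0

    @property
    def direction(self) -> str:
        """gain/loss of sample A relative to B."""
        return "gain" if self.ratio_a > self.ratio_b else "loss"


@dataclass
class SimConfig:
    """Study-condition knobs for both generators.

    ``coverage`` is the target mean per-bin coverage count (reads +
    inserts) on a neutral bin; the pair rate is derived from it. The
    2,000 bp mean insert matches long mate-pair libraries. Cohort
    defaults describe a 64-animal array study with litter (family of
    4) kinship structure.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    coverage: float = 100.0
    bin_size: int = 200
    read_length: int = 60
    insert_mean: float = 2_000.0
    insert_sd: float = 100.0
    cnvs: list[PlantedCnv] = field(default_factory=list)
    low_mapq_frac: float = 0.02
    duplicate_frac: float = 0.01
    # cohort settings
    n_samples: int = 64
    n_regions: int = 20
    n_background_probes: int = 200
    probes_per_region: int = 12
    region_length: int = 50_000
    intensity_slope: float = 0.5
    intensity_noise_sd: float = 0.2
    h2: float = 0.4
    family_size: int = 4
    family_coeff: float = 0.5
    causal_regions: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError(f"h2 must be in [0, 1), got {self.h2}")
        for cnv in self.cnvs:
            if cnv.ratio_a < 0 or cnv.ratio_b < 0:
                raise ValueError("copy ratios must be >= 0")
            length = self.chrom_lengths.get(cnv.chrom)
            if length is None or cnv.start < 0 or cnv.end > length:
                raise ValueError(f"planted CNV outside chromosome: {cnv}")


@dataclass
class TruthSet:
    """What was planted: events, causal regions, true heritability."""

    cnvs: list[PlantedCnv] = field(default_factory=list)
    causal_effects: dict[str, float] = field(default_factory=dict)
    h2: float = 0.0
    copy_numbers: np.ndarray | None = None  # regions x samples, cohort only


# ---------------------------------------------------------------------------
# Mate-pair alignment simulation
# ---------------------------------------------------------------------------


def _pair_rate_per_bp(cfg: SimConfig) -> float:
    """Pair left-end rate giving the target mean per-bin coverage.

    A homogeneous Poisson process of pair starts with rate r hits a
    bin with expected count r * (span + bin_size) per contributing
    span: two read spans of length L and one inner span of length
    insert_mean - 2L.
    """
    L, b = cfg.read_length, cfg.bin_size
    inner = max(cfg.insert_mean - 2 * L, 0.0)
    per_pair = 2 * (L + b) + (inner + b if inner > 0 else 0.0)
    return cfg.coverage / per_pair


def _ratio_segments(
    cfg: SimConfig, chrom: str, length: int, sample: str
) -> list[tuple[int, int, float]]:
    """Piecewise-constant copy-ratio segments for one sample/chromosome."""
    points = {0, length}
    for cnv in cfg.cnvs:
        if cnv.chrom == chrom:
            points.update((cnv.start, cnv.end))
    bounds = sorted(points)
    segs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ratio = 1.0
        for cnv in cfg.cnvs:
            if cnv.chrom == chrom and cnv.start <= lo and hi <= cnv.end:
                ratio = cnv.ratio_a if sample == "A" else cnv.ratio_b
        segs.append((lo, hi, ratio))
    return segs


def _simulate_sample(
    cfg: SimConfig, sample: str, rng: np.random.Generator
) -> list[AlignedRead]:
    rate = _pair_rate_per_bp(cfg)
    L = cfg.read_length
    reads: list[AlignedRead] = []
    for chrom, length in cfg.chrom_lengths.items():
        for lo, hi, ratio in _ratio_segments(cfg, chrom, length, sample):
            if ratio <= 0:
                continue
            # fragment abundance follows the copy ratio at the fragment
            # midpoint (symmetric resolution loss of ~insert/2 per side)
            n_pairs = rng.poisson(rate * ratio * (hi - lo))
            mids = rng.integers(lo, hi, size=n_pairs)
            frags = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)
            frags = np.maximum(frags, 2 * L + 1).astype(int)
            starts = np.maximum(mids - frags // 2, 0)
            mapqs = np.where(rng.random(n_pairs) < cfg.low_mapq_frac, 5, 60)
            for s, f, q in zip(starts, frags, mapqs):
                s, f, q = int(s), int(f), int(q)
                right = s + f - L
                if right + L > length:
                    f = length - s
                    right = s + f - L
                    if f < 2 * L + 1:
                        continue
                reads.append(
                    AlignedRead(chrom, s, L, q, True, f, True, sample)
                )
                reads.append(
                    AlignedRead(chrom, right, L, q, True, -f, True, sample)
                )
    # PCR duplicates: re-emit a random subset verbatim
    if reads and cfg.duplicate_frac > 0:
        n_dup = rng.binomial(len(reads), cfg.duplicate_frac)
        for i in rng.integers(0, len(reads), size=n_dup):
            reads.append(reads[int(i)])
    reads.sort(key=lambda r: (r.chrom, r.start))
    return reads


def simulate_alignments(
    cfg: SimConfig,
) -> tuple[list[AlignedRead], list[AlignedRead], TruthSet]:
    """Two-sample mate-pair alignments with planted CNVs.

    Returns unfiltered record lists (including low-mapq records and
    PCR duplicates so the post-processing has work to do) and the
    truth set. Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    reads_a = _simulate_sample(cfg, "A", rng)
    reads_b = _simulate_sample(cfg, "B", rng)
    truth = TruthSet(cnvs=list(cfg.cnvs), h2=0.0)
    return reads_a, reads_b, truth


def chrom_map_from_config(cfg: SimConfig) -> ChromMap:
    return ChromMap(cfg.chrom_lengths)


# ---------------------------------------------------------------------------
# Array cohort simulation
# ---------------------------------------------------------------------------


def _block_kinship(n: int, family_size: int, coeff: float) -> np.ndarray:
    K = np.eye(n)
    for start in range(0, n, family_size):
        stop = min(start + family_size, n)
        K[start:stop, start:stop] = coeff
    np.fill_diagonal(K, 1.0)
    return K


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[ProbeIntensity, KinshipMatrix, pd.DataFrame, TruthSet]:
    """Array cohort: intensities, kinship, phenotype, truth.

    Copy numbers per (region, sample) are integers in {0..3} with a
    diploid mode; probe intensity inside a region is
    slope * (copy - 2) + Normal(0, noise). Background probes between
    regions carry pure noise. The phenotype is
    sum_c beta_c * copy_c + g + e with g ~ N(0, h2 * K) and
    e ~ N(0, 1 - h2); beta for each causal region is set from the
    requested fraction of phenotypic variance it should explain.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_regions
    samples = [f"s{i:03d}" for i in range(n)]

    # region layout on one synthetic chromosome
    gap = cfg.region_length
    regions = [
        (i * (cfg.region_length + gap) + gap, i * (cfg.region_length + gap) + gap + cfg.region_length)
        for i in range(m)
    ]
    chrom_len = regions[-1][1] + gap if regions else 2 * gap

    copies = rng.choice([0, 1, 2, 3], size=(m, n), p=[0.05, 0.2, 0.55, 0.2])

    rows = []
    for i, (start, end) in enumerate(regions):
        pos = np.linspace(start, end - 1, cfg.probes_per_region).astype(int)
        for j, p in enumerate(pos):
            noise = rng.normal(0, cfg.intensity_noise_sd, size=n)
            rows.append(
                {
                    "probe_id": f"r{i:03d}_p{j:02d}",
                    "chrom": "chr1",
                    "pos": int(p),
                    **{
                        s: cfg.intensity_slope * (copies[i, k] - 2) + noise[k]
                        for k, s in enumerate(samples)
                    },
                }
            )
    bg_pos = rng.integers(0, chrom_len, size=cfg.n_background_probes)
    for j, p in enumerate(np.sort(bg_pos)):
        noise = rng.normal(0, cfg.intensity_noise_sd, size=n)
        rows.append(
            {
                "probe_id": f"bg_p{j:03d}",
                "chrom": "chr1",
                "pos": int(p),
                **{s: noise[k] for k, s in enumerate(samples)},
            }
        )
    intensities = ProbeIntensity(pd.DataFrame(rows))

    K = _block_kinship(n, cfg.family_size, cfg.family_coeff)
    kinship = KinshipMatrix(K, samples)

    # phenotype: polygenic + environmental variance sums to 1
    chol = np.linalg.cholesky(K + 1e-9 * np.eye(n))
    g = np.sqrt(cfg.h2) * (chol @ rng.normal(size=n))
    e = np.sqrt(1.0 - cfg.h2) * rng.normal(size=n)
    y = g + e
    causal_effects: dict[str, float] = {}
    for region_idx, var_frac in cfg.causal_regions.items():
        c = copies[region_idx].astype(float)
        vc = c.var()
        if vc == 0:
            continue
        beta = np.sqrt(var_frac / (1.0 - var_frac) / vc)
        y = y + beta * (c - c.mean())
        causal_effects[f"region_{region_idx}"] = float(beta)

    pheno = pd.DataFrame(
        {"sample": samples, "trait": "epm_open_arm_pct", "value": y}
    )
    truth = TruthSet(
        cnvs=[PlantedCnv("chr1", s, e) for s, e in regions],
        causal_effects=causal_effects,
        h2=cfg.h2,
        copy_numbers=copies,
    )
    return intensities, kinship, pheno, truth


#: Event ladder for the standard recovery study: lengths spanning
#: 2-20 kb, alternating homozygous loss (ratio 0) and ratio-2 change,
#: alternating which sample carries the event.
RECOVERY_EVENT_LENGTHS = (2_000, 3_000, 4_000, 6_000, 8_000, 10_000, 14_000, 20_000)
_RECOVERY_RATIOS = ((1.0, 0.0), (2.0, 1.0), (0.0, 1.0), (1.0, 2.0))


def recovery_study_config(seed: int) -> SimConfig:
    """The fixed study conditions for planted-event recovery runs.

    One 1-Mb chromosome at mean bin coverage 100 with eight planted
    events (2-20 kb) separated by 80-kb neutral gaps.
    """
    cnvs = []
    pos = 100_000
    for i, length in enumerate(RECOVERY_EVENT_LENGTHS):
        ra, rb = _RECOVERY_RATIOS[i % 4]
        cnvs.append(PlantedCnv("chr1", pos, pos + length, ra, rb))
        pos += length + 80_000
    return SimConfig(
        seed=seed, chrom_lengths={"chr1": 1_000_000}, coverage=100.0, cnvs=cnvs
    )


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    matches: list[tuple[PlantedCnv, CnvCall]]
    precision_defined: bool = True


def evaluate_recovery(
    calls: list[CnvCall],
    truth: TruthSet,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryReport:
    """Score calls against planted events.

    An event is recovered if some call overlaps it reciprocally at or
    above the threshold with the correct direction (relative to sample
    A). Precision = matched calls / calls; with no calls precision is
    undefined and reported as 1.0 with ``precision_defined=False``.
    """
    events = [c for c in truth.cnvs if c.ratio_a != c.ratio_b]
    matches: list[tuple[PlantedCnv, CnvCall]] = []
    matched_calls: set[int] = set()
    recovered = 0
    for ev in events:
        hit = False
        for i, call in enumerate(calls):
            if call.chrom != ev.chrom or call.direction != ev.direction:
                continue
            if (
                reciprocal_overlap((ev.start, ev.end), (call.start, call.end))
                >= min_reciprocal_overlap
            ):
                matches.append((ev, call))
                matched_calls.add(i)
                hit = True
        if hit:
            recovered += 1
    recall = recovered / len(events) if events else 1.0
    if calls:
        precision = len(matched_calls) / len(calls)
        defined = True
    else:
        precision, defined = 1.0, False
    return RecoveryReport(
        precision=precision, recall=recall, matches=matches, precision_defined=defined
    )
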