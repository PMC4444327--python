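"""Unifying CNV calls across pairwise comparisons and mapping genes.

All-pairs calling produces near-identical intervals with slightly
different breakpoints in different comparisons. Intervals whose
pairwise reciprocal overlap reaches a threshold (default 0.5) are
clustered by transitive closure and each cluster is replaced by its
maximal extent — the unified CNV is defined as large as possible.
Per-sample mean probe intensities inside unified regions feed the
association stage; gene-to-region overlap (any >= 1 bp) feeds the
candidate-gene analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intensity_hmm import ProbeIntensity

#: Total mm9 (NCBI37) mouse genome length in bp, used for genome-fraction
#: arithmetic on CNV spans.
MM9_GENOME_LENGTH = 2_654_895_218


@dataclass
class UnifiedCnv:
    """A merged interval across pairwise comparisons (0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    n_members: int
    mean_intensity: dict[str, float] = field(default_factory=dict)
    n_probes: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene locus."""

    symbol: str
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.symbol}: end must exceed start")


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(shared/len(a), shared/len(b)); 0 when disjoint."""
    shared = min(a[1], b[1]) - max(a[0], b[0])
    if shared <= 0:
        return 0.0
    return min(shared / (a[1] - a[0]), shared / (b[1] - b[0]))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cluster_once(
    ivs: list[tuple[str, int, int, int]], threshold: float
) -> list[tuple[str, int, int, int]]:
    """One transitive-closure pass; ivs are (chrom, start, end, weight)."""
    ivs = sorted(ivs)
    uf = _UnionFind(len(ivs))
    # sorted by start within chrom: once sj >= ei later intervals are disjoint
    for i in range(len(ivs)):
        ci, si, ei, _ = ivs[i]
        for j in range(i + 1, len(ivs)):
            cj, sj, ej, _ = ivs[j]
            if cj != ci or sj >= ei:
                break
            if reciprocal_overlap((si, ei), (sj, ej)) >= threshold:
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(ivs)):
        clusters.setdefault(uf.find(i), []).append(i)
    out = []
    for members in clusters.values():
        chrom = ivs[members[0]][0]
        start = min(ivs[m][1] for m in members)
        end = max(ivs[m][2] for m in members)
        weight = sum(ivs[m][3] for m in members)
        out.append((chrom, start, end, weight))
    return sorted(out)


def unify_breakpoints(
    intervals: Sequence[tuple[str, int, int]],
    min_reciprocal_overlap: float = 0.5,
) -> list[UnifiedCnv]:
    """Cluster intervals by reciprocal overlap and take maximal extents.

    ``intervals`` are (chrom, start, end) from any number of pairwise
    comparisons. Clustering is the transitive closure of the pairwise
    relation "reciprocal overlap >= threshold"; each cluster becomes
    one region spanning min(start)..max(end). Because merging enlarges
    extents, the closure is iterated until a fixpoint so the operation
    is idempotent. Output is sorted by (chrom, start) and ids are
    assigned in that order.
    """
    if not (0.0 < min_reciprocal_overlap <= 1.0):
        raise ValueError(
            f"min_reciprocal_overlap must be in (0, 1], got {min_reciprocal_overlap}"
        )
    current = [(chrom, int(s), int(e), 1) for chrom, s, e in intervals]
    while True:
        merged = _cluster_once(current, min_reciprocal_overlap)
        if len(merged) == len(current):
            break
        current = merged
    merged.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        UnifiedCnv(id=f"cnvr_{k + 1}", chrom=c, start=s, end=e, n_members=m)
        for k, (c, s, e, m) in enumerate(merged)
    ]


def summarize_intensity(
    region: UnifiedCnv, probes: ProbeIntensity
) -> dict[str, float]:
    """Per-sample arithmetic mean intensity of probes inside the region.

    Probe positions are matched half-open: a probe exactly at ``end``
    is excluded. Raises if the region contains no probes (callers flag
    and drop such regions).
    """
    frame = probes.frame
    mask = (
        (frame["chrom"] == region.chrom)
        & (frame["pos"] >= region.start)
        & (frame["pos"] < region.end)
    )
    inside = frame.loc[mask, list(probes.samples)]
    if inside.empty:
        raise ValueError(f"region {region.id} contains no probes")
    means = inside.mean(axis=0)
    region.mean_intensity = {s: float(means[s]) for s in probes.samples}
    region.n_probes = int(mask.sum())
    return region.mean_intensity


def summarize_regions(
    regions: Iterable[UnifiedCnv], probes: ProbeIntensity
) -> tuple[list[UnifiedCnv], list[UnifiedCnv]]:
    """Summarize all regions; returns (kept, probe-less dropped)."""
    kept, dropped = [], []
    for region in regions:
        try:
            summarize_intensity(region, probes)
        except ValueError:
            dropped.append(region)
        else:
            kept.append(region)
    return kept, dropped


def genes_in_regions(
    genes: Sequence[GeneRecord],
    regions: Sequence[UnifiedCnv] | Sequence[tuple[str, int, int]],
) -> list[tuple[GeneRecord, str]]:
    """All (gene, region id) pairs with >= 1 bp overlap.

    A gene overlapping k regions appears k times. Regions may be
    UnifiedCnv objects or bare (chrom, start, end) triples (then the
    region id is "chrom:start-end").
    """
    regs: list[tuple[str, int, int, str]] = []
    for r in regions:
        if isinstance(r, UnifiedCnv):
            regs.append((r.chrom, r.start, r.end, r.id))
        else:
            chrom, s, e = r
            regs.append((chrom, int(s), int(e), f"{chrom}:{s}-{e}"))

    out: list[tuple[GeneRecord, str]] = []
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, rid in regs:
        by_chrom.setdefault(chrom, []).append((s, e, rid))
    for ivs in by_chrom.values():
        ivs.sort()
    for gene in genes:
        ivs = by_chrom.get(gene.chrom, ())
        starts = np.array([s for s, _, _ in ivs])
        # regions starting at/after gene.end cannot overlap
        hi = int(np.searchsorted(starts, gene.end, side="left")) if len(ivs) else 0
        for s, e, rid in ivs[:hi]:
            if e > gene.start:
                out.append((gene, rid))
    return out


def intersect_gene_sets(a: Iterable[str], b: Iterable[str]) -> set[str]:
    """Exact intersection of two gene id sets."""
    return set(a) & set(b)


def genome_fraction(span_bp: float, genome_bp: int = MM9_GENOME_LENGTH) -> float:
    """Fraction (percent) of the genome covered by ``span_bp``."""
    if genome_bp <= 0:
        raise ValueError("genome length must be positive")
    return 100.0 * span_bp / genome_bp


def read_gene_table(path) -> list[GeneRecord]:
    """Load a gene table TSV with columns symbol, id, chrom, start, end."""
    frame = pd.read_csv(path, sep="\t")
    return [
        GeneRecord(
            symbol=str(row["symbol"]),
            gene_id=str(row["id"]),
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
        )
        for _, row in frame.iterrows()
    ]


def regions_to_frame(regions: Sequence[UnifiedCnv]) -> pd.DataFrame:
    """Unified regions as a DataFrame (one intensity column per sample)."""
    rows = []
    for r in regions:
        row = {
            "region": r.id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "n_members": r.n_members,
            "n_probes": r.n_probes,
        }
        row.update(r.mean_intensity)
        rows.append(row)
    return pd.DataFrame(rows)
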