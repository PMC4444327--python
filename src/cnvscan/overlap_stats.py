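"""CNV-expression overlap and agreement statistics.

Four pieces: a pooled two-proportion Z-test for enrichment of
differentially expressed genes inside copy-number-variable regions; a
+-1 status encoding that pairs each gene's copy-number direction with
its expression direction (contradictory evidence duplicates the gene
over both signs); Cohen's weighted kappa for the agreement between the
two status variables; and a Monte-Carlo permutation test for the size
of the intersection of two candidate-gene lists drawn from a common
universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# Two-proportion Z-test and DE-gene enrichment
# ---------------------------------------------------------------------------


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z statistic and two-sided normal p.

    z = (k1/n1 - k2/n2) / sqrt(p*(1-p)*(1/n1 + 1/n2)) with the pooled
    rate p = (k1+k2)/(n1+n2). A degenerate pooled rate (0 or 1) gives
    z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie within [0, n]")
    pooled = (k1 + k2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom == 0:
        return 0.0, 1.0
    z = (k1 / n1 - k2 / n2) / np.sqrt(denom)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def enrichment_test(
    tested_genes: set[str], cnv_genes: set[str], de_genes: set[str]
) -> tuple[float, float]:
    """Are DE genes over-represented inside CNV regions?

    Compares the DE rate among genes inside CNVs against the DE rate
    among tested genes outside CNVs with the pooled two-proportion
    Z-test. All sets are gene ids; cnv_genes and de_genes must be
    subsets of the tested universe.
    """
    if not cnv_genes:
        raise ValueError("cnv_genes is empty")
    if not (cnv_genes <= tested_genes and de_genes <= tested_genes):
        raise ValueError("cnv_genes and de_genes must be subsets of tested_genes")
    outside = tested_genes - cnv_genes
    k1 = len(cnv_genes & de_genes)
    n1 = len(cnv_genes)
    k2 = len(de_genes - cnv_genes)
    n2 = len(outside)
    return two_proportion_z(k1, n1, k2, n2)


# ---------------------------------------------------------------------------
# +-1 status encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatusPair:
    """Per-gene (copy-number status, expression status) in {-1, +1}."""

    gene_id: str
    cnv_status: int
    expr_status: int

    def __post_init__(self) -> None:
        if self.cnv_status not in (-1, 1) or self.expr_status not in (-1, 1):
            raise ValueError("statuses must be -1 or +1")


def encode_status(
    cnv_evidence: Iterable[tuple[str, int]],
    expr_evidence: Iterable[tuple[str, int]],
) -> list[StatusPair]:
    """Pair copy-number and expression directions per gene.

    ``cnv_evidence`` holds (gene id, +-1) rows, possibly several per
    gene from different detection methods; likewise ``expr_evidence``
    from different array probes. A gene contributes one row per
    distinct (cnv sign, expr sign) combination, so contradictory
    evidence on either side duplicates it over both signs. Genes
    lacking either kind of evidence are excluded.
    """
    cnv_signs: dict[str, set[int]] = {}
    for gene, sign in cnv_evidence:
        if sign not in (-1, 1):
            raise ValueError(f"invalid CNV sign {sign} for {gene}")
        cnv_signs.setdefault(gene, set()).add(sign)
    expr_signs: dict[str, set[int]] = {}
    for gene, sign in expr_evidence:
        if sign not in (-1, 1):
            raise ValueError(f"invalid expression sign {sign} for {gene}")
        expr_signs.setdefault(gene, set()).add(sign)

    pairs: list[StatusPair] = []
    for gene in sorted(set(cnv_signs) & set(expr_signs)):
        for c in sorted(cnv_signs[gene]):
            for e in sorted(expr_signs[gene]):
                pairs.append(StatusPair(gene_id=gene, cnv_status=c, expr_status=e))
    return pairs


# ---------------------------------------------------------------------------
# Cohen's weighted kappa
# ---------------------------------------------------------------------------


def weighted_kappa(
    pairs: Sequence[StatusPair] | Sequence[tuple[int, int]],
    weighting: Literal["linear", "quadratic"] = "quadratic",
) -> tuple[float, float]:
    """Cohen's weighted kappa for the +-1 status pairs, with normal p.

    K = 1 - sum(w * O) / sum(w * E) over the ordered categories
    (-1, +1), with disagreement weights w (linear |i-j| or quadratic
    (i-j)^2, identical for two categories), observed proportions O and
    chance-expected proportions E from the margins. The p-value is
    two-sided from K / SE0(K) with the large-sample null standard
    error (Fleiss, Cohen & Everitt). Degenerate margins (either
    variable constant) leave K undefined and return (nan, nan).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 status pairs")
    rows = [
        (p.cnv_status, p.expr_status) if isinstance(p, StatusPair) else tuple(p)
        for p in pairs
    ]
    cats = (-1, 1)
    n = len(rows)
    O = np.zeros((2, 2))
    for c, e in rows:
        O[cats.index(c), cats.index(e)] += 1
    O /= n
    row_m = O.sum(axis=1)
    col_m = O.sum(axis=0)
    if row_m.min() == 0 or col_m.min() == 0:
        # a variable is constant: agreement beyond chance is undefined
        return float("nan"), float("nan")
    E = np.outer(row_m, col_m)

    idx = np.arange(2)
    dist = np.abs(idx[:, None] - idx[None, :])
    w = dist.astype(float) if weighting == "linear" else dist.astype(float) ** 2
    denom = float((w * E).sum())
    if denom == 0:
        return float("nan"), float("nan")
    kappa = 1.0 - float((w * O).sum()) / denom

    # null SE via agreement weights v = 1 - w/max(w)
    v = 1.0 - w / w.max()
    p_e = float((v * E).sum())
    v_row = (v * col_m[None, :]).sum(axis=1)  # E_j[v_ij]
    v_col = (v * row_m[:, None]).sum(axis=0)  # E_i[v_ij]
    var0 = (
        float((E * (v - (v_row[:, None] + v_col[None, :])) ** 2).sum()) - p_e**2
    ) / (n * (1 - p_e) ** 2)
    if var0 <= 0:
        return kappa, float("nan")
    z = kappa / np.sqrt(var0)
    return kappa, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Candidate-gene overlap permutation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    replicates: int
    n_at_least: int
    p: float
    seed: int


def overlap_permutation(
    universe: Sequence[str] | int,
    size_a: int,
    size_b: int,
    observed: int,
    replicates: int = 10_000,
    seed: int = 0,
    mode: Literal["both_random", "fix_a"] = "both_random",
) -> PermutationResult:
    """Monte-Carlo p-value for an overlap of two gene lists.

    Each replicate draws uniform random subsets of the given sizes
    from the universe — both lists in ``both_random`` mode, only list
    B in ``fix_a`` mode — and counts the intersection; the one-sided
    p-value is (#{overlap >= observed} + 1) / (replicates + 1).
    ``universe`` may be the gene id collection or just its size.
    """
    n_universe = universe if isinstance(universe, int) else len(set(universe))
    if size_a > n_universe or size_b > n_universe:
        raise ValueError("list sizes exceed universe size")
    if observed > min(size_a, size_b):
        raise ValueError("observed overlap exceeds the smaller list size")
    if observed < 0 or replicates < 1:
        raise ValueError("observed must be >= 0 and replicates >= 1")

    rng = np.random.default_rng(seed)
    count = 0
    a_fixed = np.arange(size_a)
    for _ in range(replicates):
        b = rng.choice(n_universe, size=size_b, replace=False)
        if mode == "both_random":
            a = rng.choice(n_universe, size=size_a, replace=False)
        else:
            a = a_fixed
        overlap = np.intersect1d(a, b, assume_unique=True).size
        if overlap >= observed:
            count += 1
    p = (count + 1) / (replicates + 1)
    return PermutationResult(
        observed=observed, replicates=replicates, n_at_least=count, p=p, seed=seed
    )


def kappa_by_region(
    status_by_region: Mapping[str, Sequence[StatusPair]],
    weighting: Literal["linear", "quadratic"] = "quadratic",
) -> dict[str, tuple[float, float, float]]:
    """Weighted kappa per brain region with Holm-corrected p-values.

    Returns {region: (kappa, nominal p, Holm p)}; regions with an
    undefined kappa carry nan entries and do not enter the correction.
    """
    from statsmodels.stats.multitest import multipletests

    names, kappas, ps = [], [], []
    out: dict[str, tuple[float, float, float]] = {}
    for region, pairs in status_by_region.items():
        k, p = weighted_kappa(pairs, weighting)
        if np.isnan(p):
            out[region] = (k, p, float("nan"))
        else:
            names.append(region)
            kappas.append(k)
            ps.append(p)
    if ps:
        adj = multipletests(ps, method="holm")[1]
        for name, k, p, a in zip(names, kappas, ps, adj):
            out[name] = (k, p, float(a))
    return out
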