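"""Synthetic stand-in candidate-gene lists for the intersection analysis.

The anxiety candidate-gene analysis intersects two lists: 68 genes
inside copy-number-variable regions of the high/low-anxiety mouse
lines confirmed by all three detection methods, and 78 genes inside
outbred-cohort CNVs best associated with elevated plus-maze open-arm
time. The 15 genes in their intersection (with MGI ids and CD-1 CNV
association p-values) are real published values; the remaining 53 and
63 list members are SYNTHETIC filler identifiers standing in for the
full lists, which are not bundled here — so only the intersection
itself is meaningful.
"""

from __future__ import annotations

#: The 15 intersection genes: symbol -> MGI id.
CANDIDATE_GENES: dict[str, str] = {
    "Sirpb1a": "MGI:2444824",
    "Sirpb1b": "MGI:3779828",
    "Sirpb1c": "MGI:3807521",
    "Skint4": "MGI:2444425",
    "Skint3": "MGI:3045331",
    "Skint9": "MGI:3045341",
    "Skint6": "MGI:3649262",
    "Skint5": "MGI:3650151",
    "Skint11": "MGI:2685415",
    "C230055K05Rik": "MGI:2441896",
    "Tcp10b": "MGI:98542",
    "Gm10512": "MGI:3642173",
    "Smok2a": "MGI:1351487",
    "Smok2b": "MGI:3037705",
    "Gm9880": "MGI:3711246",
}

#: Nominal association p-values of the CD-1 CNVs containing each gene.
CANDIDATE_GENE_CNV_P: dict[str, float] = {
    "Sirpb1a": 0.01213,
    "Sirpb1b": 0.01213,
    "Sirpb1c": 0.01213,
    "Skint4": 0.04514,
    "Skint3": 0.04514,
    "Skint9": 0.04514,
    "Skint6": 0.02412,
    "Skint5": 0.02412,
    "Skint11": 0.02412,
    "C230055K05Rik": 0.03593,
    "Tcp10b": 0.07376,
    "Gm10512": 0.07250,
    "Smok2a": 0.07250,
    "Smok2b": 0.07250,
    "Gm9880": 0.07250,
}


def synthetic_candidate_lists() -> tuple[set[str], set[str]]:
    """Stand-in 68- and 78-gene id lists.

    Both lists contain the 15 real intersection MGI ids; the
    non-shared members are synthetic placeholder ids (``SYN:A...`` /
    ``SYN:B...``), constructed disjoint so the intersection is exactly
    the real candidate set.
    """
    shared = set(CANDIDATE_GENES.values())
    set_a = shared | {f"SYN:A{i:04d}" for i in range(68 - len(shared))}
    set_b = shared | {f"SYN:B{i:04d}" for i in range(78 - len(shared))}
    return set_a, set_b
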