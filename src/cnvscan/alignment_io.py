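"""Reading, filtering and deduplicating aligned mate-pair records.

Supports SAM/BAM (via pysam) and a plain tabular dialect with header
``chrom start0 read_length mapq paired insert_size proper sample_id``.
All coordinates are 0-based half-open internally; SAM/BAM 1-based input
is converted at the boundary.

The post-processing mirrors standard mate-pair CNV workflows: restrict
to confidently mapped records (mapping quality >= 20 by default) and
collapse PCR duplicates, i.e. keep a single record per
(chromosome, start, insert length).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

TSV_COLUMNS = (
    "chrom",
    "start0",
    "read_length",
    "mapq",
    "paired",
    "insert_size",
    "proper",
    "sample_id",
)

DEFAULT_MIN_MAPQ = 20


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One filtered mate-pair alignment record.

    ``start`` is the 0-based leftmost aligned position. ``insert_size``
    is the signed outer distance between mates (positive for the
    leftmost mate) and is defined only for paired records.
    """

    chrom: str
    start: int
    read_length: int
    mapq: int
    paired: bool
    insert_size: int | None
    proper_orientation: bool
    sample_id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.read_length <= 0:
            raise ValueError(f"non-positive read length: {self.read_length}")
        if self.mapq < 0:
            raise ValueError(f"negative mapq: {self.mapq}")
        if self.paired != (self.insert_size is not None):
            raise ValueError("insert_size must be present iff paired")

    @property
    def end(self) -> int:
        """0-based exclusive end of the aligned span."""
        return self.start + self.read_length


class ChromMap:
    """Ordered chromosome names with lengths in bp."""

    def __init__(self, lengths: dict[str, int] | Sequence[tuple[str, int]]):
        items = list(lengths.items()) if isinstance(lengths, dict) else list(lengths)
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")
        self._lengths = dict(items)
        self.names: tuple[str, ...] = tuple(names)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __len__(self) -> int:
        return len(self._lengths)

    def items(self) -> Iterable[tuple[str, int]]:
        return ((name, self._lengths[name]) for name in self.names)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())


def read_alignments(
    path: str | Path,
    sample_id: str,
    chrom_map: ChromMap | None = None,
) -> Iterator[AlignedRead]:
    """Stream AlignedRead records from a SAM/BAM file or the TSV dialect.

    The format is chosen by extension: ``.sam``/``.bam``/``.cram`` go
    through pysam, anything else is parsed as the TSV dialect. Records
    on a chromosome absent from ``chrom_map`` (when given) raise.
    """
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam", ".cram"}:
        yield from _read_sam(path, sample_id, chrom_map)
    else:
        yield from _read_tsv(path, sample_id, chrom_map)


def _check_chrom(chrom: str, chrom_map: ChromMap | None, where: str) -> None:
    if chrom_map is not None and chrom not in chrom_map:
        raise ValueError(f"unknown chromosome {chrom!r} at {where}")


def _read_sam(
    path: Path, sample_id: str, chrom_map: ChromMap | None
) -> Iterator[AlignedRead]:
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as handle:
        for i, rec in enumerate(handle.fetch(until_eof=True)):
            if rec.is_unmapped or rec.reference_name is None:
                continue
            _check_chrom(rec.reference_name, chrom_map, f"record {i}")
            paired = rec.is_paired and not rec.mate_is_unmapped
            insert = rec.template_length if paired else None
            yield AlignedRead(
                chrom=rec.reference_name,
                start=rec.reference_start,  # pysam is already 0-based
                read_length=rec.query_length or rec.infer_query_length() or 0,
                mapq=rec.mapping_quality,
                paired=paired,
                insert_size=insert,
                proper_orientation=bool(rec.is_proper_pair),
                sample_id=sample_id,
            )


def _read_tsv(
    path: Path, sample_id: str, chrom_map: ChromMap | None
) -> Iterator[AlignedRead]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return  # empty file
        missing = set(TSV_COLUMNS[:-1]) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"TSV dialect missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                paired = row["paired"] in ("1", "True", "true")
                raw_insert = row["insert_size"]
                insert = (
                    None if raw_insert in (".", "", "NA") else int(raw_insert)
                )
                rec = AlignedRead(
                    chrom=row["chrom"],
                    start=int(row["start0"]),
                    read_length=int(row["read_length"]),
                    mapq=int(row["mapq"]),
                    paired=paired,
                    insert_size=insert if paired else None,
                    proper_orientation=row["proper"] in ("1", "True", "true"),
                    sample_id=row.get("sample_id") or sample_id,
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"unparseable record at line {lineno}: {exc}") from exc
            _check_chrom(rec.chrom, chrom_map, f"line {lineno}")
            yield rec


def write_alignments_tsv(reads: Iterable[AlignedRead], path: str | Path) -> int:
    """Write records in the TSV dialect; returns the number written."""
    n = 0
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for r in reads:
            writer.writerow(
                (
                    r.chrom,
                    r.start,
                    r.read_length,
                    r.mapq,
                    int(r.paired),
                    r.insert_size if r.insert_size is not None else ".",
                    int(r.proper_orientation),
                    r.sample_id,
                )
            )
            n += 1
    return n


def filter_alignments(
    reads: Iterable[AlignedRead], min_mapq: int = DEFAULT_MIN_MAPQ
) -> Iterator[AlignedRead]:
    """Keep records with mapping quality >= ``min_mapq``, order preserved."""
    return (r for r in reads if r.mapq >= min_mapq)


def dedup_alignments(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse PCR duplicates: one record per (chrom, start, insert length).

    The survivor is the first record in (chrom, start, insert) sort
    order, which makes the result deterministic regardless of input
    order. Unpaired records (insert None) form their own key class.
    """

    def key(r: AlignedRead) -> tuple:
        # None sorts before any int via the (flag, value) trick
        ins = (0, 0) if r.insert_size is None else (1, r.insert_size)
        return (r.chrom, r.start, ins)

    out: list[AlignedRead] = []
    seen: set[tuple] = set()
    for r in sorted(reads, key=key):
        k = key(r)
        if k not in seen:
            seen.add(k)
            out.append(r)
    return out
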