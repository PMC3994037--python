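"""Genomic coordinate primitives shared by every stage of the pipeline.

All coordinates are 0-based, half-open ``[start, end)``: an interval of
length L contains exactly L positions.  1-based formats are converted on
read.  Strand is carried on every interval but deliberately ignored for
overlap queries — ChIP peaks are unstranded; strand matters only for TSS
clustering and gene 5'-end lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Union

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class GenomeLayout:
    """Chromosome name -> length map; validates that intervals fit."""

    chrom_sizes: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def contains(self, iv: GenomicInterval) -> bool:
        size = self.chrom_sizes.get(iv.chrom)
        return size is not None and iv.end <= size

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv} exceeds chromosome length {self.chrom_sizes[iv.chrom]}"
            )


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 base (strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def point_distance(iv: GenomicInterval, pos: int) -> int:
    """Distance in bases from ``pos`` to the nearest base of ``iv``.

    0 when ``pos`` falls inside ``[start, end)``; the caller is responsible
    for restricting queries to the interval's chromosome.
    """
    if pos < 0:
        raise ValueError("pos must be >= 0")
    if iv.start <= pos < iv.end:
        return 0
    return min(abs(pos - iv.start), abs(pos - (iv.end - 1)))


class OverlapIndex:
    """Chromosome-partitioned interval tree answering overlap queries.

    ``query`` returns exactly what a linear scan with
    :func:`intervals_overlap` would return (order not guaranteed).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: Dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval, data: object = None) -> None:
        tree = self._trees.setdefault(iv.chrom, IntervalTree())
        tree.addi(iv.start, iv.end, (iv, data))
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, iv: GenomicInterval) -> List[GenomicInterval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data[0] for hit in tree.overlap(iv.start, iv.end)]

    def query_with_data(self, iv: GenomicInterval) -> List[tuple]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return tree is not None and tree.overlaps(iv.start, iv.end)


def build_index(intervals: Iterable[GenomicInterval]) -> OverlapIndex:
    return OverlapIndex(intervals)


# ---------------------------------------------------------------------------
# Plain-text I/O: BED3/BED6 and two-column chrom.sizes.
# ---------------------------------------------------------------------------

PathLike = Union[str, Path]


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read BED3/BED6 (tab-separated, 0-based half-open) into intervals."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: PathLike,
    names: Optional[Iterable[str]] = None,
) -> None:
    """Write BED6; ``names`` fills column 4 (default '.'), score column is 0."""
    name_iter: Iterator[str] = iter(names) if names is not None else iter(())
    with open(path, "w") as fh:
        for iv in intervals:
            name = next(name_iter, ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_chrom_sizes(path: PathLike) -> GenomeLayout:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return GenomeLayout(sizes)


def write_chrom_sizes(layout: Union[GenomeLayout, Mapping[str, int]], path: PathLike) -> None:
    sizes = layout.chrom_sizes if isinstance(layout, GenomeLayout) else layout
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
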