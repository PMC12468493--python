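"""Genomic intervals and BED input/output.

All intervals are 0-based, half-open ``[start, end)`` — the BED convention.
Conversion to 1-based coordinates happens only at VCF/SAM serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A labelled half-open genomic span: the unit of regions, windows and strata."""

    contig: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file; column 4, when present, becomes the interval label."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 BED columns")
            label = fields[3] if len(fields) > 3 else None
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Per-contig interval trees for fast point/interval membership queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        if len(iv) == 0:
            continue
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, iv.label)
    return trees


def point_in(trees: dict[str, IntervalTree], contig: str, pos: int) -> bool:
    """True if 0-based position ``pos`` lies inside any interval on ``contig``."""
    tree = trees.get(contig)
    return bool(tree is not None and tree.overlaps(pos, pos + 1))


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge adjacent/overlapping same-contig, same-label intervals."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.contig, v.start, v.end)):
        if (
            out
            and out[-1].contig == iv.contig
            and out[-1].label == iv.label
            and iv.start <= out[-1].end
        ):
            prev = out.pop()
            out.append(
                GenomicInterval(prev.contig, prev.start, max(prev.end, iv.end), prev.label)
            )
        else:
            out.append(iv)
    return out
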