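"""Per-base depth tracks from alignments or bedGraph.

A :data:`CoverageTrack` is a plain ``{contig: int32 array}`` mapping, one entry
per reference base. Depth at a base counts reads whose alignment consumes that
base (CIGAR M/=/X); deletions do not add depth, and secondary, supplementary
and duplicate-flagged alignments are excluded.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pysam

CoverageTrack = dict[str, np.ndarray]

_EXCLUDE_FLAGS = 0x100 | 0x200 | 0x400 | 0x800  # secondary, qcfail, dup, supplementary


def empty_track(contig_lengths: Mapping[str, int]) -> CoverageTrack:
    return {c: np.zeros(n, dtype=np.int32) for c, n in contig_lengths.items()}


def coverage_from_sam(path: str | Path, min_mapq: int = 0) -> CoverageTrack:
    """Per-base depth from a SAM/BAM file (primary, non-duplicate alignments).

    Contig names and lengths are taken from the @SQ header lines.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        track = empty_track({sq["SN"]: sq["LN"] for sq in af.header.get("SQ", [])})
        for read in af:
            if read.is_unmapped or (read.flag & _EXCLUDE_FLAGS) or read.mapping_quality < min_mapq:
                continue
            contig = read.reference_name
            if contig not in track:
                raise ValueError(f"alignment contig {contig!r} missing from header @SQ")
            depth = track[contig]
            for start, end in read.get_blocks():  # aligned (M/=/X) blocks, D/I skipped
                depth[start:end] += 1
    return track


def coverage_from_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int]
) -> CoverageTrack:
    """Per-base depth from a bedGraph file (chrom, start, end, value)."""
    track = empty_track(contig_lengths)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            contig, start, end, value = line.split("\t")[:4]
            if contig not in track:
                raise ValueError(f"{path}: line {ln}: unknown contig {contig!r}")
            track[contig][int(start) : int(end)] += np.int32(round(float(value)))
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a depth track as bedGraph, run-length collapsing equal-depth spans."""
    with open(path, "w") as fh:
        for contig in track:
            depth = np.asarray(track[contig])
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                v = int(depth[s])
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{v}\n")


def mean_depth(track: CoverageTrack) -> float:
    total = sum(int(d.sum()) for d in track.values())
    length = sum(d.size for d in track.values())
    return total / length if length else float("nan")
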