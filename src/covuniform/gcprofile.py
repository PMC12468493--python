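"""Genome-wide GC-bias curves: normalized coverage versus window GC.

Depth is averaged in fixed-size windows (default 100 bp), each window gets an
N-excluded GC fraction from the reference, windows are binned by GC percent,
and each replicate's bin depths are divided by that replicate's genome mean
depth before averaging across replicates. A curve pinned at 1.0 across GC
means no GC bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GenomicInterval

__all__ = [
    "WindowRecord",
    "GcBiasCurve",
    "gc_fraction",
    "window_coverage",
    "gc_bias_curve",
]

DEFAULT_WINDOW = 100
DEFAULT_MIN_WINDOWS = 50

_GC_SET = frozenset("GCgc")
_ACGT_SET = frozenset("ACGTacgt")


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); NaN when no A/C/G/T bases at all."""
    n_acgt = sum(1 for b in sequence if b in _ACGT_SET)
    if n_acgt == 0:
        return float("nan")
    return sum(1 for b in sequence if b in _GC_SET) / n_acgt


@dataclass(frozen=True)
class WindowRecord:
    """Fixed-width window with its mean depth and N-excluded GC fraction."""

    interval: GenomicInterval
    gc_fraction: float  # NaN when the window is all N
    mean_depth: float
    full: bool = True  # False for the trailing partial window of a contig


@dataclass
class GcBiasCurve:
    """Per-GC-bin normalized coverage, per replicate and replicate-averaged.

    ``table`` columns: gc_bin (bin-center percent), n_windows (summed over
    replicates), normalized_coverage (mean over replicates of per-replicate
    normalized bin depth), low_confidence (any replicate below min_windows).
    """

    table: pd.DataFrame
    per_replicate: dict[str, pd.DataFrame]
    genome_mean_depth: dict[str, float]
    bin_width_percent: float
    min_windows: int


def _contig_gc_and_depth(
    seq: str, depth: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-window GC fraction, mean depth and GC-denominator count."""
    codes = np.frombuffer(seq.encode("ascii").upper(), dtype=np.uint8)
    is_gc = (codes == ord("G")) | (codes == ord("C"))
    is_acgt = is_gc | (codes == ord("A")) | (codes == ord("T"))
    n = len(seq)
    n_win = (n + window - 1) // window
    pad = n_win * window - n
    if pad:
        is_gc = np.concatenate([is_gc, np.zeros(pad, dtype=bool)])
        is_acgt = np.concatenate([is_acgt, np.zeros(pad, dtype=bool)])
        depth = np.concatenate([depth, np.zeros(pad, dtype=depth.dtype)])
    gc_counts = is_gc.reshape(n_win, window).sum(axis=1)
    acgt_counts = is_acgt.reshape(n_win, window).sum(axis=1)
    depth_sums = depth.reshape(n_win, window).sum(axis=1, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(acgt_counts > 0, gc_counts / np.maximum(acgt_counts, 1), np.nan)
    return gc, depth_sums, acgt_counts


def window_coverage(
    track: CoverageTrack,
    reference: Mapping[str, str],
    window: int = DEFAULT_WINDOW,
) -> list[WindowRecord]:
    """Tile each contig into ``window``-bp windows with mean depth and GC.

    The final partial window of a contig is retained but flagged ``full=False``
    (excluded from curves by default). Mean depth divides by the actual window
    width, so partial windows are not deflated.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    records: list[WindowRecord] = []
    for contig, depth in track.items():
        if contig not in reference:
            raise ValueError(f"coverage contig {contig!r} missing from reference")
        seq = str(reference[contig])
        if len(seq) != len(depth):
            raise ValueError(
                f"length mismatch on {contig!r}: reference {len(seq)}, depth {len(depth)}"
            )
        gc, depth_sums, _ = _contig_gc_and_depth(seq, np.asarray(depth), window)
        n = len(seq)
        for i in range(len(gc)):
            start = i * window
            end = min(start + window, n)
            records.append(
                WindowRecord(
                    interval=GenomicInterval(contig, start, end),
                    gc_fraction=float(gc[i]),
                    mean_depth=float(depth_sums[i] / (end - start)),
                    full=(end - start) == window,
                )
            )
    return records


def gc_bias_curve(
    windows: Sequence[WindowRecord] | Mapping[str, Sequence[WindowRecord]],
    bin_width_percent: float = 1.0,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    include_partial: bool = False,
) -> GcBiasCurve:
    """Bin windows by GC percent and normalize depth per replicate.

    ``windows`` is either one window list (single replicate) or a mapping of
    replicate label to window list. Each replicate is normalized by its own
    genome mean depth (window-weighted mean over usable windows), then bins
    are averaged across replicates. Bins with fewer than ``min_windows``
    windows in any replicate are flagged low-confidence.
    """
    if not isinstance(windows, Mapping):
        windows = {"rep1": list(windows)}
    per_replicate: dict[str, pd.DataFrame] = {}
    genome_means: dict[str, float] = {}
    for rep, wins in windows.items():
        usable = [
            w for w in wins if (w.full or include_partial) and np.isfinite(w.gc_fraction)
        ]
        if not usable:
            raise ValueError(f"replicate {rep!r}: no usable windows (full, defined GC)")
        gc = np.array([w.gc_fraction for w in usable])
        depth = np.array([w.mean_depth for w in usable])
        mean = float(depth.mean())
        if mean <= 0:
            raise ValueError(f"replicate {rep!r}: zero genome mean depth")
        genome_means[rep] = mean
        bins = np.floor(gc * 100.0 / bin_width_percent).astype(int)
        bins[gc >= 1.0] = int(np.floor(100.0 / bin_width_percent)) - 1  # GC=1 edge
        df = (
            pd.DataFrame({"bin": bins, "depth": depth})
            .groupby("bin")
            .agg(n_windows=("depth", "size"), mean_depth=("depth", "mean"))
            .reset_index()
        )
        df["gc_bin"] = (df["bin"] + 0.5) * bin_width_percent
        df["normalized_coverage"] = df["mean_depth"] / mean
        df["low_confidence"] = df["n_windows"] < min_windows
        per_replicate[rep] = df[
            ["gc_bin", "n_windows", "mean_depth", "normalized_coverage", "low_confidence"]
        ]
    merged = pd.concat(per_replicate.values())
    table = (
        merged.groupby("gc_bin")
        .agg(
            n_windows=("n_windows", "sum"),
            normalized_coverage=("normalized_coverage", "mean"),
            low_confidence=("low_confidence", "any"),
        )
        .reset_index()
    )
    return GcBiasCurve(
        table=table,
        per_replicate=per_replicate,
        genome_mean_depth=genome_means,
        bin_width_percent=bin_width_percent,
        min_windows=min_windows,
    )


def write_curve_tsv(curve: GcBiasCurve, path: str | Path) -> None:
    curve.table.to_csv(path, sep="\t", index=False)
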