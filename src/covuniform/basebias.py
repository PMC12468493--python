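"""Read-start base-composition profiles.

Fragmentation chemistry leaves its signature at fragment ends: enzymatic and
tagmentation-based library preps skew the base composition of the first bases
of both mates, while mechanical shearing reproduces the genome's composition.
This module tallies per-position base fractions over the first N bases of R1
or R2 (as stored in the FASTQ — no re-complementing) and reduces the profile
to a scalar deviation score against the genome's base frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._seq import N_CODE, seq_to_codes

__all__ = ["BaseCompositionProfile", "composition_profile", "bias_score"]


@dataclass
class BaseCompositionProfile:
    """Per-position base fractions over the first ``n_positions`` read bases.

    ``counts`` holds integer base tallies (n_positions x 4, A,C,G,T order);
    ``matrix`` the corresponding fractions with N bases excluded from both
    numerator and denominator, so each row is a conditional base distribution.
    """

    read_end: str  # "R1" | "R2"
    counts: np.ndarray  # (n_positions, 4) ints
    n_reads: int

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0]

    @property
    def position_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def matrix(self) -> np.ndarray:
        totals = self.position_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals[:, None] > 0, self.counts / totals[:, None], np.nan)

    def to_frame(self) -> pd.DataFrame:
        frac = self.matrix
        rows = [
            {
                "position": i + 1,
                "base": b,
                "fraction": frac[i, j],
                "read_end": self.read_end,
                "n_reads": self.n_reads,
            }
            for i in range(self.n_positions)
            for j, b in enumerate("ACGT")
        ]
        return pd.DataFrame(rows)


def _iter_seqs(source: str | Path | Iterable[str]) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with pysam.FastxFile(str(source)) as fx:
            for rec in fx:
                if rec.sequence is None:
                    raise ValueError(f"malformed FASTQ record {rec.name!r}")
                yield rec.sequence
    else:
        yield from source


def composition_profile(
    source: str | Path | Iterable[str],
    read_end: str = "R1",
    n_positions: int = 20,
) -> BaseCompositionProfile:
    """Tally base composition over the first ``n_positions`` of each read.

    ``source`` is a FASTQ path (plain or gzip) or an iterable of sequences.
    Reads shorter than ``n_positions`` contribute only to the positions they
    cover; N bases are excluded entirely.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    counts = np.zeros((n_positions, 4), dtype=np.int64)
    n_reads = 0
    for seq in _iter_seqs(source):
        n_reads += 1
        codes = seq_to_codes(seq[:n_positions])
        ok = codes != N_CODE
        np.add.at(counts, (np.flatnonzero(ok), codes[ok]), 1)
    if n_reads == 0:
        raise ValueError("empty read stream")
    return BaseCompositionProfile(read_end=read_end, counts=counts, n_reads=n_reads)


def bias_score(
    profile: BaseCompositionProfile, genome_freqs: Sequence[float]
) -> float:
    """Max absolute deviation of any (position, base) fraction from the genome.

    Zero iff the observed composition matches the genome frequencies at every
    covered position; positions with no non-N bases are ignored.
    """
    freqs = np.asarray(genome_freqs, dtype=float)
    if freqs.shape != (4,):
        raise ValueError("genome_freqs must have 4 entries (A, C, G, T)")
    frac = profile.matrix
    covered = profile.position_totals > 0
    if not covered.any():
        return 0.0
    return float(np.nanmax(np.abs(frac[covered] - freqs)))
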