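"""Synthetic WGS library simulator with controllable fragmentation bias.

This module generates everything the analysis stages consume, with known
ground truth: random (optionally GC-blocked) diploid genomes, fragment
libraries under a mechanical (uniform-breakpoint) or enzymatic
(sequence-preferring) fragmentation model with optional GC-dependent fragment
dropout, planted SNVs/indels with a truth VCF, and error-bearing 2x150 bp
paired-end reads emitted as FASTQ plus a SAM with the true alignment
coordinates (so no aligner is needed downstream).

Fragmentation-bias model
------------------------
Enzymatic chemistries (tagmentation, endonuclease cocktails) prefer particular
sequence contexts at the cut site, which shows up as skewed base composition
at the start of both mates. Breakpoints are drawn uniformly and accepted by
rejection sampling with weight equal to the product, over a +/-k window around
each fragment end, of a position-specific base-weight matrix; the 3' end is
scored on the reverse-complement strand so both mates see the same preference.
A mechanical model has an all-ones matrix (uniform breakpoints). GC dropout
then retains each fragment with probability ``exp(-beta * |GC - 0.5|)``:
symmetric loss of extreme-GC fragments, with ``beta = 0`` recovering the
unbiased library.

All randomness flows from one integer seed, expanded into named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import (
    BASES,
    N_CODE,
    codes_to_seq,
    complement_codes,
    revcomp,
    seq_to_codes,
    substream,
)
from .intervals import GenomicInterval

__all__ = [
    "SyntheticGenome",
    "FragmentationModel",
    "TruthVariant",
    "TruthVariantSet",
    "Haplotype",
    "ReadPair",
    "simulate_genome",
    "simulate_blocked_genome",
    "simulate_gc_graded_chromosomes",
    "simulate_fragments",
    "simulate_multi_contig_fragments",
    "plant_variants",
    "emit_reads",
    "make_gene_panel",
    "pairs_for_coverage",
    "write_fasta",
    "write_fastq",
    "write_sam",
    "write_truth_vcf",
]

HUMAN_LIKE_FREQS = (0.30, 0.20, 0.20, 0.30)  # A, C, G, T — human genome is ~30/20/20/30
MIN_FRAGMENT = 50


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    """A single synthetic contig with known generating base frequencies."""

    name: str
    sequence: str
    base_freqs: tuple[float, float, float, float]
    seed: int

    def __post_init__(self) -> None:
        self._codes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = seq_to_codes(self.sequence)
        return self._codes

    @property
    def gc_fraction(self) -> float:
        codes = self.codes
        acgt = codes != N_CODE
        n = int(acgt.sum())
        return float(((codes == 1) | (codes == 2)).sum() / n) if n else float("nan")


def _check_freqs(base_freqs: Sequence[float]) -> np.ndarray:
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must be 4 nonnegative values summing to 1")
    return freqs


def simulate_genome(
    length: int,
    base_freqs: Sequence[float] = HUMAN_LIKE_FREQS,
    seed: int = 0,
    name: str = "chr1",
) -> SyntheticGenome:
    """i.i.d. random genome of ``length`` bases with the given A,C,G,T frequencies."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    freqs = _check_freqs(base_freqs)
    rng = substream(seed, f"genome:{name}")
    codes = rng.choice(4, size=int(length), p=freqs).astype(np.uint8)
    return SyntheticGenome(name, codes_to_seq(codes), tuple(freqs), seed)


def _gc_to_freqs(gc: float) -> tuple[float, float, float, float]:
    return ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)


def simulate_blocked_genome(
    n_blocks: int,
    block_length: int,
    seed: int = 0,
    name: str = "chr1",
    gc_range: tuple[float, float] = (0.28, 0.80),
    gc_beta_params: tuple[float, float] = (1.5, 3.5),
) -> tuple[SyntheticGenome, list[GenomicInterval]]:
    """Genome of constant-GC blocks whose GC values span ``gc_range``.

    Block GC is drawn from a scaled Beta distribution shaped like the human
    genome's kb-scale GC distribution: right-skewed, most mass near
    0.35-0.50, a floor just below 0.30 and a thinner tail reaching ~0.80
    (CpG-island-like blocks). Returns the genome and per-block intervals
    labelled with the block GC (label ``"gc=<value>"``).
    """
    rng = substream(seed, f"blocked-genome:{name}")
    lo, hi = gc_range
    gcs = lo + (hi - lo) * rng.beta(*gc_beta_params, size=n_blocks)
    parts: list[np.ndarray] = []
    blocks: list[GenomicInterval] = []
    for i, gc in enumerate(gcs):
        codes = rng.choice(4, size=block_length, p=_gc_to_freqs(gc)).astype(np.uint8)
        parts.append(codes)
        blocks.append(
            GenomicInterval(name, i * block_length, (i + 1) * block_length, f"gc={gc:.3f}")
        )
    all_codes = np.concatenate(parts)
    mean_gc = float(np.mean(gcs))
    genome = SyntheticGenome(name, codes_to_seq(all_codes), _gc_to_freqs(mean_gc), seed)
    return genome, blocks


def simulate_gc_graded_chromosomes(
    n_chromosomes: int,
    length: int,
    gc_low: float = 0.35,
    gc_high: float = 0.55,
    seed: int = 0,
) -> dict[str, SyntheticGenome]:
    """Multi-chromosome genome with per-chromosome GC graded from low to high."""
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    gcs = np.linspace(gc_low, gc_high, n_chromosomes)
    out: dict[str, SyntheticGenome] = {}
    for i, gc in enumerate(gcs, 1):
        name = f"chr{i}"
        out[name] = simulate_genome(length, _gc_to_freqs(float(gc)), seed, name=name)
    return out


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------


@dataclass
class FragmentationModel:
    """Parameterized fragmentation chemistry.

    ``cut_preference`` is a (2k+1) x 4 strictly positive weight matrix over a
    window of +/-k bases around each breakpoint (row k is the first retained
    fragment base, columns A,C,G,T). A mechanical model forces all weights
    equal; ``gc_dropout_beta = 0`` disables GC-dependent dropout.
    """

    kind: str = "mechanical"
    cut_preference: np.ndarray | None = None
    gc_dropout_beta: float = 0.0
    insert_mean: float = 350.0
    insert_sd: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("mechanical", "enzymatic"):
            raise ValueError(f"unknown fragmentation kind {self.kind!r}")
        if self.gc_dropout_beta < 0:
            raise ValueError("gc_dropout_beta must be nonnegative")
        if self.cut_preference is None:
            self.cut_preference = np.ones((11, 4))
        self.cut_preference = np.asarray(self.cut_preference, dtype=float)
        rows, cols = self.cut_preference.shape
        if cols != 4 or rows % 2 != 1:
            raise ValueError("cut_preference must be (2k+1) x 4")
        if np.any(self.cut_preference <= 0):
            raise ValueError("cut_preference weights must be strictly positive")
        if self.kind == "mechanical":
            self.cut_preference = np.ones_like(self.cut_preference)

    @property
    def k(self) -> int:
        return self.cut_preference.shape[0] // 2

    @property
    def is_uniform(self) -> bool:
        return bool(np.all(self.cut_preference == self.cut_preference[0, 0]))

    @classmethod
    def mechanical(cls, insert_mean: float = 350.0, insert_sd: float = 50.0,
                   gc_dropout_beta: float = 0.0) -> "FragmentationModel":
        return cls("mechanical", None, gc_dropout_beta, insert_mean, insert_sd)

    @classmethod
    def enzymatic(cls, cut_preference: np.ndarray | None = None,
                  gc_dropout_beta: float = 0.0, insert_mean: float = 350.0,
                  insert_sd: float = 50.0) -> "FragmentationModel":
        if cut_preference is None:
            cut_preference = tagmentation_like_matrix()
        return cls("enzymatic", cut_preference, gc_dropout_beta, insert_mean, insert_sd)


def tagmentation_like_matrix(k: int = 5) -> np.ndarray:
    """An example enzymatic cut-preference: T/G-favoring over the first bases.

    Values are free parameters (no kit is characterized quantitatively in the
    literature this emulates); they are chosen to produce read-start
    composition deviations of the tens-of-percentage-points scale seen in
    tagmentation libraries.
    """
    m = np.ones((2 * k + 1, 4))
    m[k + 0] = (0.6, 0.8, 1.2, 3.0)   # first fragment base: strong T preference
    m[k + 1] = (0.8, 0.9, 1.8, 1.2)
    m[k + 2] = (0.9, 1.3, 1.2, 0.9)
    m[k - 1] = (1.2, 0.9, 0.9, 1.4)
    return m


def _breakpoint_weights(
    codes: np.ndarray, positions: np.ndarray, matrix: np.ndarray, reverse: bool
) -> np.ndarray:
    """Product-of-positions context weight at each breakpoint.

    ``positions`` is the genome index of the first retained fragment base
    (offset 0). ``reverse=True`` scores the reverse-complement strand, for the
    3' fragment end where offsets run leftwards.
    """
    k = matrix.shape[0] // 2
    L = len(codes)
    w = np.ones(len(positions))
    for off in range(-k, k + 1):
        idx = positions - off if reverse else positions + off
        valid = (idx >= 0) & (idx < L)
        base = np.where(valid, codes[np.clip(idx, 0, L - 1)], N_CODE)
        if reverse:
            base = complement_codes(base.astype(np.uint8))
        row = np.append(matrix[off + k], 0.0)  # N gets zero weight
        w *= np.where(valid, row[base], 1.0)
    return w


class _ContigSampler:
    """Precomputed arrays for rejection-sampling fragments on one contig."""

    def __init__(self, genome: SyntheticGenome, model: FragmentationModel):
        self.genome = genome
        self.model = model
        codes = genome.codes
        self.codes = codes
        is_gc = (codes == 1) | (codes == 2)
        acgt = codes != N_CODE
        self.gc_cum = np.concatenate([[0], np.cumsum(is_gc.astype(np.int64))])
        self.acgt_cum = np.concatenate([[0], np.cumsum(acgt.astype(np.int64))])
        self.biased = not model.is_uniform
        matrix = model.cut_preference
        self.w_max = float(np.prod(matrix.max(axis=1))) if self.biased else 1.0

    def batch(self, m: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``m`` candidate fragments; return the accepted (starts, ends)."""
        model = self.model
        L = len(self.genome)
        lens = np.rint(rng.normal(model.insert_mean, model.insert_sd, size=m)).astype(np.int64)
        for _ in range(100):  # truncate by redraw
            bad = (lens < MIN_FRAGMENT) | (lens > L)
            if not bad.any():
                break
            lens[bad] = np.rint(
                rng.normal(model.insert_mean, model.insert_sd, size=int(bad.sum()))
            ).astype(np.int64)
        np.clip(lens, MIN_FRAGMENT, L, out=lens)
        starts = rng.integers(0, L - lens + 1)
        ends = starts + lens
        keep = np.ones(m, dtype=bool)
        if self.biased:
            matrix = model.cut_preference
            w = _breakpoint_weights(self.codes, starts, matrix, reverse=False)
            w *= _breakpoint_weights(self.codes, ends - 1, matrix, reverse=True)
            keep &= rng.random(m) < w / (self.w_max * self.w_max)
        if model.gc_dropout_beta > 0:
            denom = self.acgt_cum[ends] - self.acgt_cum[starts]
            gc = np.where(
                denom > 0, (self.gc_cum[ends] - self.gc_cum[starts]) / np.maximum(denom, 1), 0.5
            )
            keep &= rng.random(m) < np.exp(-model.gc_dropout_beta * np.abs(gc - 0.5))
        return starts[keep], ends[keep]


def simulate_fragments(
    genome: SyntheticGenome,
    model: FragmentationModel,
    n_fragments: int,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Draw ``n_fragments`` fragment intervals under the fragmentation model.

    Lengths ~ Normal(insert_mean, insert_sd) truncated to [50, genome length];
    uniform breakpoints for the mechanical model, context-weighted rejection
    sampling for the enzymatic model, then GC dropout; sampling repeats until
    ``n_fragments`` fragments are retained.
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    L = len(genome)
    if L < MIN_FRAGMENT:
        raise ValueError(f"genome shorter than minimum fragment size {MIN_FRAGMENT}")
    if n_fragments == 0:
        return []
    rng = substream(seed, f"fragments:{genome.name}")
    sampler = _ContigSampler(genome, model)
    starts_out: list[np.ndarray] = []
    ends_out: list[np.ndarray] = []
    n_kept = 0
    while n_kept < n_fragments:
        m = max(2 * (n_fragments - n_kept), 1024)
        starts, ends = sampler.batch(m, rng)
        starts_out.append(starts)
        ends_out.append(ends)
        n_kept += len(starts)
    starts_all = np.concatenate(starts_out)[:n_fragments]
    ends_all = np.concatenate(ends_out)[:n_fragments]
    return [
        GenomicInterval(genome.name, int(s), int(e))
        for s, e in zip(starts_all, ends_all)
    ]


def simulate_multi_contig_fragments(
    genomes: Mapping[str, SyntheticGenome],
    model: FragmentationModel,
    n_fragments: int,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Fragments over a multi-contig genome with genome-level rejection.

    Candidate fragments land on contigs proportional to contig length and are
    then accepted per the model, so contigs whose composition suffers more
    dropout end up with proportionally fewer fragments — the between-
    chromosome coverage signal. (Per-contig :func:`simulate_fragments` would
    instead resample each contig back up to its quota.)
    """
    if n_fragments < 0:
        raise ValueError("n_fragments must be >= 0")
    names = list(genomes)
    rng = substream(seed, "fragments:multi")
    samplers = {n: _ContigSampler(genomes[n], model) for n in names}
    lengths = np.array([len(genomes[n]) for n in names], dtype=float)
    probs = lengths / lengths.sum()
    out: list[GenomicInterval] = []
    while len(out) < n_fragments:
        m = max(2 * (n_fragments - len(out)), 1024)
        counts = rng.multinomial(m, probs)
        for name, c in zip(names, counts):
            if c == 0:
                continue
            starts, ends = samplers[name].batch(int(c), rng)
            out.extend(
                GenomicInterval(name, int(s), int(e)) for s, e in zip(starts, ends)
            )
    return out[:n_fragments]


def pairs_for_coverage(genome_length: int, coverage: float, read_length: int = 150) -> int:
    """Number of read pairs giving approximately ``coverage``-fold read depth."""
    return max(1, round(coverage * genome_length / (2 * read_length)))


# ---------------------------------------------------------------------------
# variants & haplotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant: 1-based position, VCF-style anchored alleles."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # "het" | "hom"

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class TruthVariantSet:
    records: list[TruthVariant]
    confident_regions: list[GenomicInterval]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Haplotype:
    """One parental copy: the reference genome plus VCF-style anchored edits."""

    genome: SyntheticGenome
    edits: list[tuple[int, str, str]] = field(default_factory=list)  # (0-based pos, ref, alt)

    def __post_init__(self) -> None:
        self.edits = sorted(self.edits)

    def splice(self, start: int, end: int) -> tuple[str, list[tuple[str, int]]]:
        """Haplotype sequence over reference span [start, end) plus its CIGAR.

        Edits whose reference footprint is not fully inside the span are left
        unapplied (the fragment carries the reference allele there). Returns
        (sequence, [(op, length), ...]) with ops in {"M", "I", "D"}; SNVs stay
        inside M blocks.
        """
        seq_parts: list[str] = []
        cigar: list[tuple[str, int]] = []

        def push(op: str, n: int) -> None:
            if n <= 0:
                return
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + n)
            else:
                cigar.append((op, n))

        ref = self.genome.sequence
        cur = start
        for pos, vref, valt in self.edits:
            if pos < cur or pos + len(vref) > end:
                continue
            seq_parts.append(ref[cur:pos])
            push("M", pos - cur)
            if len(vref) == 1 and len(valt) == 1:  # SNV
                seq_parts.append(valt)
                push("M", 1)
                cur = pos + 1
            elif len(valt) > len(vref):  # insertion after anchor base
                seq_parts.append(valt)
                push("M", 1)
                push("I", len(valt) - 1)
                cur = pos + 1
            else:  # deletion after anchor base
                seq_parts.append(valt)
                push("M", 1)
                push("D", len(vref) - 1)
                cur = pos + len(vref)
        seq_parts.append(ref[cur:end])
        push("M", end - cur)
        return "".join(seq_parts), cigar


def plant_variants(
    genome: SyntheticGenome,
    n_snp: int,
    n_indel: int,
    seed: int = 0,
    max_indel: int = 3,
) -> tuple[tuple[Haplotype, Haplotype], TruthVariantSet]:
    """Plant SNVs and short indels on a diploid pair with >=50 bp spacing.

    Het variants go to one randomly chosen haplotype, hom variants to both.
    Positions are deterministic under the seed; every ref allele matches the
    genome sequence.
    """
    n_total = n_snp + n_indel
    L = len(genome)
    if n_total > L // 100:
        raise ValueError(
            f"cannot place {n_total} variants with 50 bp spacing in {L} bp "
            f"(capacity {L // 100})"
        )
    rng = substream(seed, f"variants:{genome.name}")
    edge = MIN_FRAGMENT + max_indel + 1
    # 100 bp slots with +/-25 bp jitter guarantee >=50 bp separation
    slots = np.arange(edge, L - edge - 100, 100)
    if len(slots) < n_total:
        raise ValueError("genome too short for requested variant count")
    chosen = np.sort(rng.choice(len(slots), size=n_total, replace=False))
    positions = slots[chosen] + rng.integers(-25, 26, size=n_total)

    seq = genome.sequence
    is_snp = np.zeros(n_total, dtype=bool)
    is_snp[:n_snp] = True
    rng.shuffle(is_snp)

    records: list[TruthVariant] = []
    edits0: list[tuple[int, str, str]] = []
    edits1: list[tuple[int, str, str]] = []
    for pos, snp in zip(positions, is_snp):
        pos = int(pos)
        anchor = seq[pos]
        if anchor == "N":
            continue  # N-free genomes in practice; skip rather than re-jitter
        if snp:
            alt = BASES[(BASES.index(anchor) + int(rng.integers(1, 4))) % 4]
            ref_a, alt_a = anchor, alt
        else:
            ilen = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:  # insertion
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size=ilen))
                ref_a, alt_a = anchor, anchor + ins
            else:  # deletion
                ref_a, alt_a = seq[pos : pos + 1 + ilen], anchor
                if "N" in ref_a:
                    continue
        genotype = "het" if rng.random() < 0.5 else "hom"
        records.append(TruthVariant(genome.name, pos + 1, ref_a, alt_a, genotype))
        if genotype == "hom":
            edits0.append((pos, ref_a, alt_a))
            edits1.append((pos, ref_a, alt_a))
        elif rng.random() < 0.5:
            edits0.append((pos, ref_a, alt_a))
        else:
            edits1.append((pos, ref_a, alt_a))
    truth = TruthVariantSet(records, [GenomicInterval(genome.name, 0, L)])
    return (Haplotype(genome, edits0), Haplotype(genome, edits1)), truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    """One mate, stored in genome (top-strand) orientation."""

    seq: str  # top-strand sequence, errors applied
    ref_start: int  # 0-based
    cigar: list[tuple[str, int]]
    is_reverse: bool

    @property
    def fastq_seq(self) -> str:
        return revcomp(self.seq) if self.is_reverse else self.seq


@dataclass
class ReadPair:
    name: str
    contig: str
    r1: SimRead
    r2: SimRead
    insert_size: int


def _cut_cigar(
    cigar: list[tuple[str, int]], qstart: int, qend: int
) -> tuple[int, list[tuple[str, int]]]:
    """Sub-CIGAR covering query window [qstart, qend).

    Returns (reference offset of the window start, ops). Deletions at the
    window edges are dropped; insertions count as query-consuming.
    """
    out: list[tuple[str, int]] = []
    q = 0
    r = 0
    ref_off: int | None = None
    for op, n in cigar:
        consumes_q = op in ("M", "I")
        consumes_r = op in ("M", "D")
        q_next = q + n if consumes_q else q
        if consumes_q and q_next > qstart and q < qend:
            lo = max(q, qstart)
            hi = min(q_next, qend)
            if ref_off is None:
                ref_off = r + (lo - q if op == "M" else 0)
            out.append((op, hi - lo))
        elif op == "D" and qstart < q < qend and out:
            out.append((op, n))  # interior deletion
        q = q_next
        if consumes_r:
            r += n
    if ref_off is None:
        ref_off = 0
    # merge and strip edge deletions
    while out and out[0][0] == "D":
        out.pop(0)
    while out and out[-1][0] == "D":
        out.pop()
    merged: list[tuple[str, int]] = []
    for op, n in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return ref_off, merged


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0 or not seq:
        return seq
    codes = seq_to_codes(seq).copy()
    hit = np.flatnonzero((rng.random(len(codes)) < error_rate) & (codes != N_CODE))
    if hit.size:
        codes[hit] = (codes[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return codes_to_seq(codes)


def emit_reads(
    fragments: Sequence[GenomicInterval],
    haplotypes: tuple[Haplotype, Haplotype] | Mapping[str, tuple[Haplotype, Haplotype]],
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPair]:
    """Paired reads from fragments: R1 = first bases (top strand), R2 =
    reverse complement of the last bases. Each fragment is drawn from a random
    haplotype; reads shorter than ``read_length`` fragments are truncated.
    Base errors are i.i.d. substitutions at ``error_rate``. For multi-contig
    genomes pass a ``{contig: (hap0, hap1)}`` mapping.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = substream(seed, "reads")
    hap_choice = rng.integers(0, 2, size=len(fragments))
    pairs: list[ReadPair] = []
    for i, frag in enumerate(fragments):
        pair_for_contig = (
            haplotypes[frag.contig] if isinstance(haplotypes, Mapping) else haplotypes
        )
        hap = pair_for_contig[hap_choice[i]]
        fseq, fcig = hap.splice(frag.start, frag.end)
        qlen = len(fseq)
        lr = min(read_length, qlen)
        off1, cig1 = _cut_cigar(fcig, 0, lr)
        off2, cig2 = _cut_cigar(fcig, qlen - lr, qlen)
        s1 = _apply_errors(fseq[:lr], error_rate, rng)
        s2 = _apply_errors(fseq[qlen - lr :], error_rate, rng)
        pairs.append(
            ReadPair(
                name=f"frag{i:08d}",
                contig=frag.contig,
                r1=SimRead(s1, frag.start + off1, cig1, is_reverse=False),
                r2=SimRead(s2, frag.start + off2, cig2, is_reverse=True),
                insert_size=frag.end - frag.start,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------


def make_gene_panel(
    blocks: Sequence[GenomicInterval],
    n_genes: int,
    seed: int = 0,
    regions_per_gene: tuple[int, int] = (1, 4),
    region_length: tuple[int, int] = (150, 400),
    gene_prefix: str = "GENE",
) -> list[GenomicInterval]:
    """Gene-panel-like BED regions: genes assigned to blocks, 1-4 regions each.

    Each gene lives inside one block (so its regions share the block's GC);
    regions within a gene are non-overlapping and ordered.
    """
    if n_genes > len(blocks):
        raise ValueError(f"{n_genes} genes but only {len(blocks)} blocks")
    rng = substream(seed, "panel")
    chosen = rng.choice(len(blocks), size=n_genes, replace=False)
    panel: list[GenomicInterval] = []
    for g, bi in enumerate(np.sort(chosen), 1):
        block = blocks[bi]
        name = f"{gene_prefix}{g:04d}"
        n_regions = int(rng.integers(regions_per_gene[0], regions_per_gene[1] + 1))
        cursor = block.start + int(rng.integers(0, 50))
        for _ in range(n_regions):
            rlen = int(rng.integers(region_length[0], region_length[1] + 1))
            if cursor + rlen > block.end:
                break
            panel.append(GenomicInterval(block.contig, cursor, cursor + rlen, name))
            cursor += rlen + int(rng.integers(20, 120))
    return panel


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _as_genome_dict(
    genomes: SyntheticGenome | Mapping[str, SyntheticGenome],
) -> dict[str, SyntheticGenome]:
    if isinstance(genomes, SyntheticGenome):
        return {genomes.name: genomes}
    return dict(genomes)


def write_fasta(
    genomes: SyntheticGenome | Mapping[str, SyntheticGenome],
    path: str | Path,
    width: int = 60,
) -> None:
    with open(path, "w") as fh:
        for name, g in _as_genome_dict(genomes).items():
            fh.write(f">{name}\n")
            seq = g.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_QUAL33 = chr(30 + 33)  # fixed Q30


def write_fastq(
    pairs: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    """4-line FASTQ, Phred+33 with fixed Q30 qualities."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            s1 = p.r1.fastq_seq
            s2 = p.r2.fastq_seq
            f1.write(f"@{p.name}/1\n{s1}\n+\n{_QUAL33 * len(s1)}\n")
            f2.write(f"@{p.name}/2\n{s2}\n+\n{_QUAL33 * len(s2)}\n")


def _cigar_str(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar) or "*"


def write_sam(
    pairs: Sequence[ReadPair],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Coordinate-sorted SAM with true alignment coordinates.

    Flags 99/147 (R1 forward / R2 reverse, both proper-pair); MAPQ 60.
    """
    rows: list[tuple[str, int, str]] = []
    for p in pairs:
        pos1 = p.r1.ref_start + 1
        pos2 = p.r2.ref_start + 1
        tlen = p.insert_size
        q1 = _QUAL33 * len(p.r1.seq)
        q2 = _QUAL33 * len(p.r2.seq)
        rows.append(
            (p.contig, p.r1.ref_start,
             f"{p.name}\t99\t{p.contig}\t{pos1}\t60\t{_cigar_str(p.r1.cigar)}\t=\t{pos2}\t{tlen}\t{p.r1.seq}\t{q1}")
        )
        rows.append(
            (p.contig, p.r2.ref_start,
             f"{p.name}\t147\t{p.contig}\t{pos2}\t60\t{_cigar_str(p.r2.cigar)}\t=\t{pos1}\t{-tlen}\t{p.r2.seq}\t{q2}")
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for _, _, line in rows:
            fh.write(line + "\n")


def write_truth_vcf(
    truth: TruthVariantSet,
    contig_lengths: Mapping[str, int],
    path: str | Path,
    sample: str = "TRUTH",
) -> None:
    """VCF v4.2 with GT genotypes (het -> 0/1, hom -> 1/1)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(truth.records, key=lambda v: (v.contig, v.pos)):
            gt = "1/1" if v.genotype == "hom" else "0/1"
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n")
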