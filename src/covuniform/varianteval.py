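"""Seeded FASTQ downsampling and GC-stratified variant benchmarking.

Query calls are compared with a truth set inside high-confidence regions
using exact genotype-aware matching on normalized variant keys (multiallelics
split, indels left-aligned and trimmed to minimal representation). A genotype
mismatch at the same site scores one FP plus one FN; SNPs and indels are
scored separately. Stratification evaluates the same comparison independently
inside (confident ∩ stratum) for each GC stratum; strata may overlap, so
per-stratum counts are tallies, not a partition.

This is deliberately simpler than haplotype-aware matchers (hap.py): complex
representation differences that only haplotype playback can reconcile are
counted as FP+FN. Adequate for SNVs and simple planted indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from ._seq import N_CODE, seq_to_codes, substream
from .intervals import GenomicInterval, build_trees, merge_intervals, point_in

__all__ = [
    "VariantKey",
    "VariantComparison",
    "downsample_fastq",
    "normalize_variant",
    "read_vcf",
    "compare_variants",
    "stratify_by_gc",
    "make_gc_strata",
    "naive_pileup_caller",
    "write_vcf",
]


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------


def _read_id(header: str) -> str:
    name = header[1:].split()[0]
    return name[:-2] if name.endswith(("/1", "/2")) else name


def downsample_fastq(
    r1_in: str | Path,
    r2_in: str | Path,
    n_pairs: int,
    seed: int,
    r1_out: str | Path,
    r2_out: str | Path,
) -> int:
    """Uniform sample of read pairs without replacement, order preserved.

    Pair files must be synchronized record-for-record; the first mismatching
    record id raises. Deterministic under ``seed``; returns the number of
    pairs written.
    """
    with open(r1_in) as f1:
        total = sum(1 for _ in f1)
    if total % 4:
        raise ValueError(f"{r1_in}: truncated FASTQ (line count not divisible by 4)")
    total //= 4
    if n_pairs > total:
        raise ValueError(f"requested {n_pairs} pairs but only {total} available")
    rng = substream(seed, "downsample")
    keep = np.zeros(total, dtype=bool)
    keep[rng.choice(total, size=n_pairs, replace=False)] = True
    written = 0
    with open(r1_in) as f1, open(r2_in) as f2, \
            open(r1_out, "w") as o1, open(r2_out, "w") as o2:
        for i in range(total):
            rec1 = [f1.readline() for _ in range(4)]
            rec2 = [f2.readline() for _ in range(4)]
            if not rec2[0]:
                raise ValueError(f"pair files desynchronized: {r2_in} ended at record {i}")
            if _read_id(rec1[0]) != _read_id(rec2[0]):
                raise ValueError(
                    f"pair files desynchronized at record {i}: "
                    f"{_read_id(rec1[0])!r} vs {_read_id(rec2[0])!r}"
                )
            if keep[i]:
                o1.writelines(rec1)
                o2.writelines(rec2)
                written += 1
    return written


# ---------------------------------------------------------------------------
# variant keys & normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized variant identity used for exact matching."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # "het" | "hom"

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def variant_class(self) -> str:
        return "SNP" if self.is_snp else "indel"

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def normalize_variant(
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    genotype: str,
    reference: Mapping[str, str] | None = None,
) -> VariantKey:
    """Left-align and trim to minimal representation (vt-normalize style).

    Left-alignment of indels needs the reference; without it only suffix/prefix
    trimming is applied.
    """
    if ref == alt:
        raise ValueError(f"ref equals alt at {contig}:{pos}")
    seq = str(reference[contig]) if reference is not None and contig in reference else None
    if seq is not None:
        while True:
            changed = False
            if ref and alt and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
                changed = True
            if (not ref or not alt) and pos > 1:
                pos -= 1
                base = seq[pos - 1]
                ref, alt = base + ref, base + alt
                changed = True
            if not changed:
                break
    else:  # no reference: suffix trimming only
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(contig, pos, ref, alt, genotype)


def read_vcf(
    path: str | Path,
    reference: Mapping[str, str] | None = None,
    sample: int | str = 0,
) -> list[VariantKey]:
    """Read and normalize a VCF: multiallelics split, GT-derived genotype.

    Records without a called ALT in the sample's GT are skipped; half-calls
    count as het.
    """
    out: list[VariantKey] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            gt: tuple | None = None
            if rec.samples:
                key = sample if isinstance(sample, str) else list(rec.samples)[sample]
                gt = rec.samples[key].get("GT")
            for ai, alt in enumerate(rec.alts, start=1):
                if alt is None or set(alt) - set("ACGTacgt"):
                    continue
                if gt is not None and all(a is not None for a in gt):
                    count = sum(1 for a in gt if a == ai)
                    if count == 0:
                        continue
                    genotype = "hom" if count == len(gt) and len(gt) > 1 else "het"
                else:
                    genotype = "het"
                out.append(
                    normalize_variant(rec.contig, rec.pos, rec.ref, alt, genotype, reference)
                )
    return out


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


@dataclass
class VariantComparison:
    """TP/FP/FN tallies and derived metrics for one class in one stratum."""

    variant_class: str  # "SNP" | "indel"
    stratum: str = "all"
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn

    @property
    def empty(self) -> bool:
        return self.n_truth == 0 and self.fp == 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "class": self.variant_class,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _confine(keys: Sequence[VariantKey], trees) -> set[VariantKey]:
    return {k for k in keys if point_in(trees, k.contig, k.pos - 1)}


def compare_variants(
    query: Sequence[VariantKey],
    truth: Sequence[VariantKey],
    confident: Sequence[GenomicInterval],
    stratum: str = "all",
    require_truth: bool = True,
) -> dict[str, VariantComparison]:
    """Exact genotype-aware comparison within confident regions.

    Returns one :class:`VariantComparison` per variant class. TP requires an
    exact (contig, pos, ref, alt, genotype) match; a genotype mismatch at the
    same site therefore yields 1 FP + 1 FN.
    """
    if not confident:
        raise ValueError("confident region set is empty")
    trees = build_trees(confident)
    q = _confine(query, trees)
    t = _confine(truth, trees)
    if require_truth and not t:
        raise ValueError("no truth variants inside confident regions")
    out: dict[str, VariantComparison] = {}
    for cls in ("SNP", "indel"):
        qc = {k for k in q if k.variant_class == cls}
        tc = {k for k in t if k.variant_class == cls}
        matched = qc & tc
        out[cls] = VariantComparison(
            variant_class=cls,
            stratum=stratum,
            tp=len(matched),
            fp=len(qc - matched),
            fn=len(tc - matched),
        )
    return out


def stratify_by_gc(
    query: Sequence[VariantKey],
    truth: Sequence[VariantKey],
    confident: Sequence[GenomicInterval],
    strata: Mapping[str, Sequence[GenomicInterval]],
) -> list[VariantComparison]:
    """Per-stratum comparisons within (confident ∩ stratum).

    Strata may overlap (a variant can count in several); variants inside the
    confident set but outside every stratum are reported under
    ``"unstratified"``.
    """
    if len(set(strata)) != len(strata):
        raise ValueError("stratum labels must be unique")
    conf_trees = build_trees(confident)
    query_c = [k for k in query if point_in(conf_trees, k.contig, k.pos - 1)]
    truth_c = [k for k in truth if point_in(conf_trees, k.contig, k.pos - 1)]
    out: list[VariantComparison] = []
    in_any_q: set[VariantKey] = set()
    in_any_t: set[VariantKey] = set()
    for label, intervals in strata.items():
        trees = build_trees(intervals)
        qs = [k for k in query_c if point_in(trees, k.contig, k.pos - 1)]
        ts = [k for k in truth_c if point_in(trees, k.contig, k.pos - 1)]
        in_any_q.update(qs)
        in_any_t.update(ts)
        out.extend(
            compare_variants(qs, ts, confident, stratum=label, require_truth=False).values()
        )
    rest_q = [k for k in query_c if k not in in_any_q]
    rest_t = [k for k in truth_c if k not in in_any_t]
    out.extend(
        compare_variants(
            rest_q, rest_t, confident, stratum="unstratified", require_truth=False
        ).values()
    )
    return out


def make_gc_strata(
    reference: Mapping[str, str],
    window: int = 100,
    edges_percent: Sequence[float] = (0, 25, 30, 40, 55, 65, 75, 85, 100),
) -> dict[str, list[GenomicInterval]]:
    """Label fixed windows by GC-percent bin and merge runs into intervals.

    Bins are ``[edge_i, edge_{i+1})`` (the last bin closed at the top); each
    window falls in exactly one bin, so within one edge list the strata
    partition the genome (all-N windows excepted).
    """
    edges = list(edges_percent)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = [f"gc{a:g}to{b:g}" for a, b in zip(edges, edges[1:])]
    strata: dict[str, list[GenomicInterval]] = {lab: [] for lab in labels}
    from .gcprofile import _contig_gc_and_depth

    for contig, seq in reference.items():
        seq = str(seq)
        gc, _, acgt = _contig_gc_and_depth(seq, np.zeros(len(seq), dtype=np.int32), window)
        for i in range(len(gc)):
            if acgt[i] == 0:
                continue
            pct = gc[i] * 100.0
            j = int(np.searchsorted(edges, pct, side="right")) - 1
            j = min(max(j, 0), len(labels) - 1)
            start = i * window
            end = min(start + window, len(seq))
            strata[labels[j]].append(GenomicInterval(contig, start, end, labels[j]))
    return {lab: merge_intervals(ivs) for lab, ivs in strata.items() if ivs}


# ---------------------------------------------------------------------------
# naive pileup caller
# ---------------------------------------------------------------------------


def naive_pileup_caller(
    sam_path: str | Path,
    reference: Mapping[str, str],
    min_depth: int = 8,
    min_alt_fraction: float = 0.2,
    hom_threshold: float = 0.8,
    call_indels: bool = True,
    min_mapq: int = 0,
) -> list[VariantKey]:
    """Per-column majority caller over a coordinate-sorted SAM/BAM.

    A site is called when depth >= ``min_depth`` and the top non-reference
    allele fraction >= ``min_alt_fraction``; genotype is hom at alt fraction
    >= ``hom_threshold``, else het. Simple insertions/deletions are collected
    from CIGAR I/D events when ``call_indels`` is set. A stand-in for a
    production caller, sufficient to close the simulate -> evaluate loop.
    """
    base_counts: dict[str, np.ndarray] = {}
    indel_counts: dict[tuple[str, int, str, str], int] = {}
    exclude = 0x100 | 0x200 | 0x400 | 0x800
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        lengths = {sq["SN"]: sq["LN"] for sq in af.header.get("SQ", [])}
        for c, n in lengths.items():
            base_counts[c] = np.zeros((n, 4), dtype=np.int32)
        for read in af:
            if read.is_unmapped or (read.flag & exclude) or read.mapping_quality < min_mapq:
                continue
            contig = read.reference_name
            counts = base_counts[contig]
            seq = read.query_sequence
            codes = seq_to_codes(seq)
            rpos = read.reference_start
            qpos = 0
            for op, n in read.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    block = codes[qpos : qpos + n]
                    ok = block != N_CODE
                    if ok.any():
                        idx = np.arange(rpos, rpos + n)[ok]
                        np.add.at(counts, (idx, block[ok]), 1)
                    rpos += n
                    qpos += n
                elif op == 1:  # I — anchored at the base before rpos
                    if call_indels and rpos > 0:
                        anchor = str(reference[contig])[rpos - 1]
                        key = (contig, rpos, anchor, anchor + seq[qpos : qpos + n])
                        indel_counts[key] = indel_counts.get(key, 0) + 1
                    qpos += n
                elif op == 2:  # D
                    if call_indels and rpos > 0:
                        refseq = str(reference[contig])[rpos - 1 : rpos + n]
                        key = (contig, rpos, refseq, refseq[0])
                        indel_counts[key] = indel_counts.get(key, 0) + 1
                    rpos += n
                elif op == 4:  # S
                    qpos += n
                # N/H/P: not emitted by the simulator; ignore

    calls: list[VariantKey] = []
    for contig, counts in base_counts.items():
        refseq = str(reference[contig])
        ref_codes = seq_to_codes(refseq)
        depth = counts.sum(axis=1)
        candidate = depth >= min_depth
        if not candidate.any():
            continue
        masked = counts.copy()
        valid_ref = ref_codes != N_CODE
        idx = np.flatnonzero(valid_ref)
        masked[idx, ref_codes[idx]] = 0
        alt_code = masked.argmax(axis=1)
        alt_count = masked.max(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
        called = candidate & valid_ref & (frac >= min_alt_fraction) & (alt_count > 0)
        for p in np.flatnonzero(called):
            genotype = "hom" if frac[p] >= hom_threshold else "het"
            calls.append(
                VariantKey(contig, int(p) + 1, refseq[p], "ACGT"[alt_code[p]], genotype)
            )
        if call_indels:
            for (c, rpos, ref_a, alt_a), n_ev in indel_counts.items():
                if c != contig:
                    continue
                d = int(depth[rpos - 1]) if rpos - 1 < len(depth) else 0
                d = max(d, n_ev)
                f = n_ev / d
                if d >= min_depth and f >= min_alt_fraction:
                    genotype = "hom" if f >= hom_threshold else "het"
                    calls.append(
                        normalize_variant(c, rpos, ref_a, alt_a, genotype, reference)
                    )
    return sorted(calls)


def write_vcf(
    calls: Sequence[VariantKey],
    contig_lengths: Mapping[str, int],
    path: str | Path,
    sample: str = "CALLS",
) -> None:
    """VCF v4.2 output for a call set (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(calls):
            gt = "1/1" if v.genotype == "hom" else "0/1"
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n")
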