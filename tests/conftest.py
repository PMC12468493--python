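"""Shared fixtures: small simulated libraries, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import covuniform as cv
from covuniform import coverage, simulate

HUMAN_FREQS = (0.30, 0.20, 0.20, 0.30)


@pytest.fixture(scope="session")
def genome_100k():
    """100 kb human-composition genome."""
    return cv.simulate_genome(100_000, HUMAN_FREQS, seed=2)


@pytest.fixture(scope="session")
def diploid_100k(genome_100k):
    """Diploid pair with 50 SNVs + 10 indels planted."""
    return cv.plant_variants(genome_100k, 50, 10, seed=2)


@pytest.fixture(scope="session")
def library_30x(tmp_path_factory, genome_100k, diploid_100k):
    """A 30X mechanical, bias-free library: pairs, SAM path, coverage track."""
    haps, truth = diploid_100k
    model = cv.FragmentationModel.mechanical()
    n = cv.pairs_for_coverage(len(genome_100k), 30)
    frags = cv.simulate_fragments(genome_100k, model, n, seed=2)
    pairs = cv.emit_reads(frags, haps, 150, error_rate=0.001, seed=2)
    d = tmp_path_factory.mktemp("lib30x")
    sam = d / "aln.sam"
    simulate.write_sam(pairs, {genome_100k.name: len(genome_100k)}, sam)
    simulate.write_fastq(pairs, d / "r1.fastq", d / "r2.fastq")
    simulate.write_truth_vcf(truth, {genome_100k.name: len(genome_100k)}, d / "truth.vcf")
    track = coverage.coverage_from_sam(sam)
    return {
        "genome": genome_100k,
        "reference": {genome_100k.name: genome_100k.sequence},
        "haplotypes": haps,
        "truth": truth,
        "fragments": frags,
        "pairs": pairs,
        "dir": d,
        "sam": sam,
        "track": track,
    }


def pileup_oracle(sam_path, contig_lengths):
    """Independent per-base depth: parse SAM text and walk CIGARs by hand."""
    import re

    depth = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.split("\t")
            flag = int(fields[1])
            if flag & (0x4 | 0x100 | 0x200 | 0x400 | 0x800):
                continue
            contig, pos, cigar = fields[2], int(fields[3]) - 1, fields[5]
            for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
                n = int(n)
                if op in "M=X":
                    depth[contig][pos : pos + n] += 1
                    pos += n
                elif op in "DN":
                    pos += n
    return depth
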