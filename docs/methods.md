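# Methods

This note documents the models, statistics and numerical choices behind
`covuniform`, and what the synthetic-data generator does and does not
emulate.

## Fragmentation model

Fragments are sampled on a reference sequence with lengths drawn from
Normal(`insert_mean`, `insert_sd`), truncated by redraw to
[50 bp, genome length], and uniform candidate start positions.

**Cut-context preference.** Enzymatic chemistries (restriction cocktails,
Tn5 tagmentation) cut preferentially in particular sequence contexts, which
appears in real data as skewed base composition over roughly the first 15
bases of both mates. We model this with a strictly positive
(2k+1)×4 weight matrix `cut_preference` (default k = 5; row k is the first
retained fragment base). A candidate fragment is accepted with probability
proportional to the product of per-offset weights at **both** ends; the 3′
end is scored on the reverse-complement strand so R1 and R2 carry the same
signature, as they do in real libraries. The mechanical model is the all-
ones matrix (uniform breakpoints). Rejection sampling uses the exact bound
`w_max = Π_offset max_base(weight)`, so accepted draws follow the target
distribution exactly. The matrix values are free parameters: no kit's
preference is characterized quantitatively in the literature this emulates,
so the shipped `tagmentation_like_matrix()` is an illustrative T/G-favoring
example, not a calibration.

**GC dropout.** After breakpoint acceptance, each fragment is retained with
probability `exp(−β·|GC − 0.5|)` (GC computed over non-N bases; β ≥ 0,
β = 0 disables dropout). The symmetric form loses extreme-GC fragments at
both tails, matching the depressed ends of empirical GC-bias curves;
asymmetric *observable* effects (e.g. a high-GC penalty in variant calling)
arise from the asymmetric GC composition of the genome being sequenced, not
from the retention function. Sampling repeats until the requested fragment
count is retained, which mirrors sequencing a library to a target depth:
dropout reshapes *where* coverage lands, not how much is produced.

For multi-contig genomes, `simulate_multi_contig_fragments` assigns
candidates to contigs proportional to length and applies acceptance
globally, so a contig whose composition suffers more dropout receives
proportionally fewer fragments — the between-chromosome coverage signal.
Per-contig `simulate_fragments` would instead refill each contig to its
quota and erase that signal. Note the direction of the chromosomal
coverage–GC slope under symmetric dropout depends on which side of 50 % GC
the chromosomes lie: retention *rises* toward 0.5, so a 0.35–0.55 grade
gains coverage with GC while a 0.45–0.75 grade loses it. Tests use the
latter, where "high GC loses coverage" genuinely holds.

## Genomes, variants, reads

`simulate_genome` draws i.i.d. bases from given A/C/G/T frequencies
(default 0.30/0.20/0.20/0.30, the human genome's approximate composition).
`simulate_blocked_genome` concatenates constant-GC blocks whose GC is drawn
from `0.28 + 0.52·Beta(1.5, 3.5)` — right-skewed with mode ≈ 0.40, a floor
just below 0.30 and a thin tail to 0.80, emulating the human genome's
kb-scale GC distribution (low-GC extremes are rare; the high tail exists as
CpG-island-like segments). This skew matters: it is what makes high-GC
strata sit farther from 50 % than the variant-bearing low strata, so strong
dropout penalizes them harder.

Variants are planted on 100 bp slots with ±25 bp jitter (guaranteed ≥ 50 bp
separation). SNVs substitute one base; indels insert or delete 1–3 bp with
a VCF-style anchor base. Genotypes are het/hom with probability ½; het
edits go to one randomly chosen haplotype. Reads are emitted from a
randomly chosen haplotype per fragment: R1 is the first `read_length` bases
(top strand), R2 the reverse complement of the last; fragments shorter than
the read length truncate both mates. CIGARs are derived by splicing the
haplotype edits into the fragment and cutting the fragment alignment at the
read's query window, so the emitted SAM carries true coordinates and no
aligner is needed. Base errors are i.i.d. substitutions; qualities are
fixed at Q30. There is no quality decay, adapter read-through, PCR
duplication or FFPE damage chemistry — coverage and genotype effects only.
Consequently, passing tests demonstrate the *analysis chain* is correct and
sensitive to fragmentation/GC effects; they do not certify performance on
real instrument artifacts.

All randomness flows from one integer seed expanded into named substreams
(`(seed, crc32(label))`), so adding a consumer never perturbs existing
draws and every output is bit-reproducible under a fixed seed.

## Depth and GC definitions

Depth at a base counts primary, non-duplicate, non-supplementary alignments
whose CIGAR consumes that reference base (M/=/X; deletions do not add
depth) — per-base read support is the quantity GC dropout acts on. The
MAPQ floor defaults to 0 because the simulator emits perfect mappings; it
is configurable for real BAMs. GC fraction is (G+C)/(A+C+G+T) with N and
other IUPAC codes excluded from numerator and denominator; all-N spans are
flagged undefined. The trailing partial window of each contig is retained
but flagged and excluded from curves by default. Base-composition profiles
likewise exclude N from both sides, keeping each row a conditional base
distribution; R2 is profiled as stored in FASTQ (already instrument-
reverse-complemented).

## Normalization and summaries

The GC-bias curve bins full windows by GC percent (default 1-point bins)
and divides each replicate's bin mean depth by that replicate's genome mean
depth before averaging bins across replicates (normalize-then-average).
Conservation holds by construction: the window-count-weighted mean of
normalized coverage is exactly 1 per replicate. Bins with fewer than 50
windows are flagged low-confidence.

Gene-level analysis averages region depth and region GC **unweighted**
within each gene, then normalizes each (library, sample, replicate) group
by the unweighted mean of gene depths — the gene, not the base pair, is the
unit of the plots this feeds — and averages normalized values across
replicates per (library, sample, gene). Sex-chromosome records are removed
first (default {chrX, chrY, X, Y}), keeping the analysis autosomal.

**Regression.** Ordinary least squares of normalized coverage on GC
fraction via `scipy.stats.linregress`; R² = 1 − SS_res/SS_tot, with the
convention R² = 0 (slope 0) for a constant response to avoid 0/0. Inputs
with n < 3 or a degenerate predictor raise.

**KDE + FWHM.** Gaussian KDE with Silverman's bandwidth (logged and
reported), evaluated on a 512-point grid spanning [min − 3h, max + 3h].
FWHM is the distance between the *outermost* crossings of half the peak
density, located by linear interpolation between grid points — outermost,
rather than peak-local, so multimodal coverage distributions report their
full spread. The KDE convolves the data with the bandwidth kernel, so on
Gaussian data the measured FWHM exceeds the population value
2√(2 ln 2)·σ by ≈ (1 + h²/σ²)^½ − 1 (a few percent at n = 5000); tests use
a 10 % band accordingly. Chromosome-level uniformity treats each
chromosome as one region with the same unweighted normalization and
requires ≥ 3 chromosomes.

## Variant benchmarking

Query and truth VCFs are normalized on read: multiallelic records split,
alleles trimmed and left-aligned against the reference (shared-suffix
truncation with left-extension, then shared-prefix trimming — the standard
vt-normalize loop), genotype classed het/hom from GT. Comparison is exact
on (contig, pos, ref, alt, genotype) within confident regions: unmatched
truth → FN, unmatched query → FP, so a genotype mismatch at one site costs
1 FP + 1 FN. SNVs and indels are scored separately; precision, recall and
F1 use the 0-when-undefined convention. This matcher is deliberately
simpler than haplotype-aware tools (hap.py): representation differences
that only haplotype playback reconciles (MNP decompositions, overlapping
complex events) score as FP+FN. That is adequate for SNVs and the
simulator's isolated indels, and is a documented limitation for real call
sets.

GC strata are built by labelling fixed windows (default 100 bp) with GC-
percent bins (default edges 0/25/30/40/55/65/75/85/100, echoing public
stratification sets that span ~15–85 % with a wide mid-bin) and merging
same-bin runs; one edge list yields a partition, but overlapping strata
from other sources are permitted — per-stratum counts are independent
tallies, never a partition. Variants inside the confident set but outside
all strata report under `unstratified`. The naive pileup caller (depth ≥ 8,
alt fraction ≥ 0.2, hom at ≥ 0.8, CIGAR-derived simple indels) exists to
close the simulate→evaluate loop at desk scale; it is a deliberately
minimal caller, not a production one.

Downsampling selects read pairs uniformly without replacement, preserving
input order and pair synchronization (verified record-by-record), with an
exact pair count rather than an approximate depth target.

## Pipeline and problem sizes

`run_compare` executes base-bias, GC-profile, uniformity and (first
replicate) variant-calling stages per library × replicate on one shared
genome/panel/truth set, and ranks libraries by FWHM and R². The report is
JSON, validated against `docs/run_report.schema.json` by a small structural
checker (type/required/properties), and includes SHA-256 checksums of all
text artifacts; wall-clock timings go to the log, not the report, so
reports are bit-reproducible.

Default study conditions were chosen once as desk-scale versions of a WGS
comparison: 200 kb blocked genomes (40 × 5 kb), 30-gene panels with 1–4
regions of 150–400 bp per gene, 60–120 SNVs + 10–20 indels (well above the
per-stratum counting noise floor), 2×150 bp reads at 10–30X, 350 ± 50 bp
inserts, error rate 10⁻³. Direction-recovery checks (β ∈ {0, 4, 8})
average five seeds. Acceptance anchors run at 1 Mb / 30X / 10⁵ reads,
where binomial noise is comfortably inside the stated bands (e.g. per-
position composition SE ≈ 0.15 points at 10⁵ reads vs a 1.5-point band).

## Known limitations

- Window-level GC only; no fragment-level (insert-based) GC correction
  model à la `computeGCBias`.
- The cut-preference matrix is positional and independent across offsets;
  real enzymes show correlated motifs.
- Retention is symmetric in |GC − 0.5|; chemistry-specific asymmetric
  dropout must be emulated through genome composition.
- The exact matcher under-credits complex variant representations relative
  to haplotype-aware comparison.
- Insert-size and coverage targets are exact counts, not sampled library
  yields.
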