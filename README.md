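# covuniform

Coverage-uniformity and fragmentation-bias analysis for whole-genome
sequencing (WGS) libraries, with a synthetic paired-end library simulator
that supplies ground truth for every stage.

## The problem

How a WGS library is fragmented — mechanical shearing versus enzymatic or
tagmentation chemistry — leaves fingerprints in the data: skewed base
composition at read starts (enzymes prefer particular cut contexts), GC-
dependent loss of fragments, uneven coverage across chromosomes and genes,
and ultimately degraded variant calling in high-GC regions. `covuniform`
implements the full evaluation chain a lab would use to compare library
preparation workflows, for bioinformaticians and sequencing-core scientists:

1. **Read-start base composition** (`covuniform.basebias`): per-position
   fractions of A/C/G/T over the first *N* bases of R1/R2, plus a scalar
   `bias_score` = max deviation from the genome's base frequencies.
2. **GC-bias curve** (`covuniform.gcprofile`): mean depth in 100 bp windows,
   binned by GC percent and normalized per replicate by the genome mean
   depth. A flat curve at 1.0 means no GC bias.
3. **Uniformity statistics** (`covuniform.uniformity`): per-region
   depth/GC from a BED panel, gene-level averaging, per-(library, sample,
   replicate) normalization to mean 1, replicate averaging, then
   - OLS regression of normalized coverage *y* on GC fraction *g*
     (`y = β₁g + β₀`; R² ≈ 0 ⇒ no GC dependence), and
   - a Gaussian-KDE density of the normalized coverage values whose
     **full width at half maximum (FWHM)** measures coverage spread —
     smaller FWHM ⇒ more uniform coverage.
4. **Variant benchmarking** (`covuniform.varianteval`): seeded pair-
   preserving FASTQ downsampling, a naive pileup caller to close the loop
   at desk scale, and genotype-aware exact comparison against a truth VCF
   inside confident regions — overall and stratified by GC-content
   intervals (precision, recall, F1 per stratum).
5. **Simulator** (`covuniform.simulate`): random or GC-blocked genomes,
   fragmentation with a position-specific cut-preference matrix (rejection
   sampling over a ±k window at both fragment ends) and symmetric GC
   dropout `P(retain) = exp(−β·|GC − 0.5|)`, planted SNVs/indels with a
   truth VCF, and 2×150 bp paired reads written as FASTQ plus SAM with
   true coordinates — no aligner required.

The `covuniform run` pipeline executes all stages for each configured
library and ranks libraries by FWHM and R².

## Worked example

```python
import covuniform as cv
from covuniform import simulate, coverage, uniformity

# a 200 kb genome of 5 kb constant-GC blocks (GC 0.28-0.80, human-like skew)
genome, blocks = cv.simulate_blocked_genome(40, 5000, seed=0)
panel = cv.make_gene_panel(blocks, 30, seed=0)
haps, truth = cv.plant_variants(genome, 120, 20, seed=0)

# 15X library with strong GC dropout (beta = 8)
model = cv.FragmentationModel.mechanical(gc_dropout_beta=8.0)
frags = cv.simulate_fragments(genome, model, cv.pairs_for_coverage(len(genome), 15), seed=0)
pairs = cv.emit_reads(frags, haps, 150, error_rate=0.001, seed=0)
simulate.write_sam(pairs, {genome.name: len(genome)}, "aln.sam")

track = coverage.coverage_from_sam("aln.sam")
ref = {genome.name: genome.sequence}
recs = uniformity.region_coverage(track, panel, ref, replicate="r1")
genes = uniformity.normalize_and_average(uniformity.aggregate_genes(recs))
s = uniformity.uniformity_summary(genes)
print(f"slope={s.regression.slope:.2f}  R2={s.regression.r_squared:.3f}  fwhm={s.fwhm:.3f}")
```

prints

```
slope=1.53  R2=0.208  fwhm=1.190
```

— the dropout has coupled coverage to GC (R² = 0.21 instead of ≈ 0) and
spread the normalized-coverage density (FWHM 1.19; the same run with
β = 0 gives R² = 0.017 and FWHM 0.33). The positive slope reflects this
genome's GC distribution: most genes sit below 50 % GC, where retention
rises toward 0.5.

The same comparison from the shell:

```bash
covuniform run --config examples/compare.yaml --out run_out
# run_out/report.json ranks libraries by FWHM and R^2
```

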