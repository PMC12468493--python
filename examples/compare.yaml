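# Example covuniform run configuration.
#
# Compares a mechanical (bias-free) library against an enzymatic library
# with strong GC dropout on one shared synthetic genome, gene panel and
# planted truth set. All randomness derives from `seed`.

libraries:
  - label: mechanical
    fragmentation: mechanical   # uniform breakpoints
    gc_dropout_beta: 0.0        # no GC-dependent fragment loss
    coverage: 15.0              # target read depth (X)
    insert_mean: 350.0          # fragment length mean (bp)
    insert_sd: 50.0
    read_length: 150
    error_rate: 0.001           # per-base substitution rate
  - label: enzymatic
    fragmentation: enzymatic    # T/G-favoring cut-preference matrix
    gc_dropout_beta: 8.0        # retention exp(-beta * |GC - 0.5|)
    coverage: 15.0

sample: synthetic               # sample-type label carried through grouping
replicates: 3                   # technical replicates per library
seed: 1

# shared study conditions
n_blocks: 40                    # genome = n_blocks x block_length bp
block_length: 5000              # constant-GC blocks, GC ~ 0.28-0.80
n_genes: 30                     # gene-panel size (1-4 regions per gene)
n_snp: 60                       # planted heterozygous/homozygous SNVs
n_indel: 10                     # planted 1-3 bp indels
window: 100                     # GC-profile window (bp)
gc_bin_percent: 1.0             # GC-curve bin width (percentage points)
n_positions: 20                 # read-start profile length

out_dir: covuniform_run
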