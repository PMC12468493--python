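"""End-to-end orchestration: simulate -> basebias -> gcprofile -> uniformity
-> varianteval, with a consolidated machine-readable report.

A :class:`RunConfig` declares the libraries to compare (fragmentation kind,
GC-dropout strength, target coverage), the shared synthetic genome/panel/
truth-set conditions, and one master seed from which every stage's randomness
is derived. :func:`run_compare` executes all stages for each
(library, sample, replicate) group, writes per-group artifacts, and returns a
:class:`RunReport` ranking groups by FWHM and GC-regression R^2 — lower is
more uniform. Deterministic stages reproduce bit-identically under the same
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import basebias, gcprofile, simulate, uniformity, varianteval
from .coverage import coverage_from_sam
from .intervals import write_bed

__all__ = ["LibrarySpec", "RunConfig", "RunReport", "run_compare", "validate_report"]

logger = logging.getLogger(__name__)

SCHEMA_PATH = Path(__file__).resolve().parents[2] / "docs" / "run_report.schema.json"


@dataclass
class LibrarySpec:
    """One library-preparation condition to simulate and score."""

    label: str
    fragmentation: str = "mechanical"  # or "enzymatic"
    gc_dropout_beta: float = 0.0
    coverage: float = 20.0
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    read_length: int = 150
    error_rate: float = 0.001

    def model(self) -> simulate.FragmentationModel:
        if self.fragmentation == "mechanical":
            return simulate.FragmentationModel.mechanical(
                self.insert_mean, self.insert_sd, self.gc_dropout_beta
            )
        return simulate.FragmentationModel.enzymatic(
            gc_dropout_beta=self.gc_dropout_beta,
            insert_mean=self.insert_mean,
            insert_sd=self.insert_sd,
        )


@dataclass
class RunConfig:
    """Declarative configuration for a comparison run."""

    libraries: list[LibrarySpec] = field(default_factory=list)
    sample: str = "synthetic"
    replicates: int = 3
    seed: int = 0
    out_dir: str = "covuniform_run"
    # shared synthetic study conditions
    n_blocks: int = 40
    block_length: int = 5000
    n_genes: int = 30
    n_snp: int = 60
    n_indel: int = 10
    window: int = 100
    gc_bin_percent: float = 1.0
    n_positions: int = 20

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        libs = [
            LibrarySpec(**lib) if not isinstance(lib, LibrarySpec) else lib
            for lib in d.pop("libraries", [])
        ]
        cfg = cls(libraries=libs, **d)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        problems = []
        if not self.libraries:
            problems.append("libraries: at least one library is required")
        labels = [lib.label for lib in self.libraries]
        if len(set(labels)) != len(labels):
            problems.append("libraries: labels must be unique")
        for lib in self.libraries:
            if lib.fragmentation not in ("mechanical", "enzymatic"):
                problems.append(f"{lib.label}: unknown fragmentation {lib.fragmentation!r}")
            if lib.gc_dropout_beta < 0:
                problems.append(f"{lib.label}: gc_dropout_beta must be >= 0")
            if lib.coverage <= 0:
                problems.append(f"{lib.label}: coverage must be > 0")
        if self.replicates < 1:
            problems.append("replicates: must be >= 1")
        if self.n_blocks * self.block_length < 10 * self.window:
            problems.append("genome too small for windowed analysis")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


@dataclass
class RunReport:
    config: dict
    version: str
    groups: list[dict]
    rankings: dict
    outputs: dict[str, str]
    checksums: dict[str, str]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_compare(config: RunConfig) -> RunReport:
    """Run the full comparison described by ``config``.

    Stage order per (library, replicate): read simulation, base-composition
    profiling, GC-bias curve, gene-level uniformity, and (on replicate 1)
    variant calling and GC-stratified benchmarking. Any stage failure aborts
    with the stage name and cause; partially written outputs are retained.
    """
    from . import __version__

    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    genome, blocks = simulate.simulate_blocked_genome(
        config.n_blocks, config.block_length, seed=config.seed
    )
    panel = simulate.make_gene_panel(blocks, config.n_genes, seed=config.seed)
    haplotypes, truth = simulate.plant_variants(
        genome, config.n_snp, config.n_indel, seed=config.seed
    )
    reference = {genome.name: genome.sequence}
    contig_lengths = {genome.name: len(genome)}

    simulate.write_fasta(genome, out_root / "genome.fa")
    write_bed(panel, out_root / "panel.bed")
    simulate.write_truth_vcf(truth, contig_lengths, out_root / "truth.vcf")
    write_bed(truth.confident_regions, out_root / "confident.bed")
    strata = varianteval.make_gc_strata(reference, window=config.window)
    strata_dir = out_root / "strata"
    strata_dir.mkdir(exist_ok=True)
    for label, intervals in strata.items():
        write_bed(intervals, strata_dir / f"{label}.bed")

    outputs: dict[str, str] = {
        "genome": str(out_root / "genome.fa"),
        "panel": str(out_root / "panel.bed"),
        "truth_vcf": str(out_root / "truth.vcf"),
    }
    groups: list[dict] = []
    truth_keys = varianteval.read_vcf(out_root / "truth.vcf", reference)

    for lib in config.libraries:
        model = lib.model()
        gene_records_all: list[uniformity.GeneCoverageRecord] = []
        lib_summary: dict[str, Any] = {
            "library": lib.label,
            "sample": config.sample,
            "replicates": [],
        }
        for rep_i in range(1, config.replicates + 1):
            stage = f"{lib.label}/rep{rep_i}"
            t0 = time.perf_counter()
            rep_dir = out_root / lib.label / f"rep{rep_i}"
            rep_dir.mkdir(parents=True, exist_ok=True)
            rep_seed = (
                config.seed * 1000 + zlib.crc32(f"{lib.label}:{rep_i}".encode()) % 997
            ) % (2**31)
            try:
                n_pairs = simulate.pairs_for_coverage(
                    len(genome), lib.coverage, lib.read_length
                )
                frags = simulate.simulate_fragments(genome, model, n_pairs, seed=rep_seed)
                pairs = simulate.emit_reads(
                    frags, haplotypes, lib.read_length, lib.error_rate, seed=rep_seed
                )
                simulate.write_fastq(pairs, rep_dir / "r1.fastq", rep_dir / "r2.fastq")
                simulate.write_sam(pairs, contig_lengths, rep_dir / "aln.sam")

                prof = basebias.composition_profile(
                    rep_dir / "r1.fastq", "R1", config.n_positions
                )
                score = basebias.bias_score(prof, genome.base_freqs)
                prof.to_frame().to_csv(rep_dir / "basebias.tsv", sep="\t", index=False)

                track = coverage_from_sam(rep_dir / "aln.sam")
                windows = gcprofile.window_coverage(track, reference, config.window)
                curve = gcprofile.gc_bias_curve(windows, config.gc_bin_percent)
                gcprofile.write_curve_tsv(curve, rep_dir / "gc_curve.tsv")

                regions = uniformity.region_coverage(
                    track, panel, reference,
                    library=lib.label, sample=config.sample, replicate=f"rep{rep_i}",
                )
                regions = uniformity.filter_autosomal(regions).records
                gene_records_all.extend(uniformity.aggregate_genes(regions))

                rep_entry: dict[str, Any] = {
                    "replicate": f"rep{rep_i}",
                    "seed": rep_seed,
                    "bias_score": score,
                    "mean_depth": float(np.mean(track[genome.name])),
                }
                if rep_i == 1:
                    calls = varianteval.naive_pileup_caller(rep_dir / "aln.sam", reference)
                    varianteval.write_vcf(calls, contig_lengths, rep_dir / "calls.vcf")
                    call_keys = varianteval.read_vcf(rep_dir / "calls.vcf", reference)
                    overall = varianteval.compare_variants(
                        call_keys, truth_keys, truth.confident_regions
                    )
                    stratified = varianteval.stratify_by_gc(
                        call_keys, truth_keys, truth.confident_regions, strata
                    )
                    rep_entry["variant_eval"] = {
                        "overall": [c.to_dict() for c in overall.values()],
                        "stratified": [c.to_dict() for c in stratified],
                    }
                lib_summary["replicates"].append(rep_entry)
                logger.info("%s done in %.2fs", stage, time.perf_counter() - t0)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        averaged = uniformity.normalize_and_average(gene_records_all)
        summary = uniformity.uniformity_summary(averaged)
        lib_summary["uniformity"] = summary.to_dict()
        groups.append(lib_summary)

    rank_fwhm = sorted(groups, key=lambda g: g["uniformity"]["fwhm"])
    rank_r2 = sorted(groups, key=lambda g: g["uniformity"]["r_squared"])
    rankings = {
        "by_fwhm": [g["library"] for g in rank_fwhm],
        "by_r_squared": [g["library"] for g in rank_r2],
    }

    checksums = {
        str(p.relative_to(out_root)): _sha256(p)
        for p in sorted(out_root.rglob("*"))
        if p.is_file() and p.suffix in (".fastq", ".sam", ".vcf", ".bed", ".fa", ".tsv")
    }
    cfg_dict = asdict(config)
    report = RunReport(
        config=cfg_dict,
        version=__version__,
        groups=groups,
        rankings=rankings,
        outputs=outputs,
        checksums=checksums,
    )
    report.to_json(out_root / "report.json")
    return report


# ---------------------------------------------------------------------------
# report schema validation (structural subset of JSON Schema)
# ---------------------------------------------------------------------------

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _validate_node(value: Any, schema: dict, path: str, errors: list[str]) -> None:
    t = schema.get("type")
    if t and not isinstance(value, _TYPES[t]):
        errors.append(f"{path}: expected {t}, got {type(value).__name__}")
        return
    if t == "object":
        for req in schema.get("required", []):
            if req not in value:
                errors.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate_node(value[key], sub, f"{path}.{key}", errors)
    elif t == "array" and "items" in schema:
        for i, item in enumerate(value):
            _validate_node(item, schema["items"], f"{path}[{i}]", errors)


def validate_report(report: dict, schema_path: str | Path = SCHEMA_PATH) -> list[str]:
    """Check a report dict against the published schema; returns problems."""
    with open(schema_path) as fh:
        schema = json.load(fh)
    errors: list[str] = []
    _validate_node(report, schema, "$", errors)
    return errors
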