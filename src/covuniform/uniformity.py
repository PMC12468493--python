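"""Region/gene/chromosome coverage uniformity: normalization, GC regression
and the KDE + FWHM statistic.

The workflow mirrors a targeted-panel coverage QC: mean depth and GC per BED
region, X/Y-chromosome filtering, gene-level averaging of region values,
per-(library, sample, replicate) normalization to mean 1, replicate
averaging, then two summaries of the gene-level normalized coverage
distribution: an OLS regression against GC (slope, R^2 — near 0 means no GC
bias) and the full width at half maximum of a Gaussian KDE (smaller FWHM
means more uniform coverage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .gcprofile import gc_fraction
from .intervals import GenomicInterval

__all__ = [
    "RegionCoverageRecord",
    "GeneCoverageRecord",
    "RegressionResult",
    "KdeFwhm",
    "UniformityResult",
    "region_coverage",
    "filter_autosomal",
    "aggregate_genes",
    "normalize_genes",
    "average_replicates",
    "normalize_and_average",
    "gc_regression",
    "kde_fwhm",
    "uniformity_summary",
    "chromosome_uniformity",
]

logger = logging.getLogger(__name__)

DEFAULT_SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class RegionCoverageRecord:
    """Mean depth + GC for one panel region — the central analysis row."""

    interval: GenomicInterval
    gene: str
    mean_depth: float
    gc_fraction: float
    library: str = ""
    sample: str = ""
    replicate: str = ""


@dataclass(frozen=True)
class GeneCoverageRecord:
    gene: str
    chromosome: str
    mean_depth: float
    gc_fraction: float
    normalized_coverage: float = float("nan")
    library: str = ""
    sample: str = ""
    replicate: str = ""


class RegressionResult(NamedTuple):
    slope: float  # per unit GC fraction
    intercept: float
    r_squared: float


@dataclass
class KdeFwhm:
    fwhm: float
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass
class UniformityResult:
    regression: RegressionResult
    fwhm: float
    kde: KdeFwhm
    n_genes: int

    def to_dict(self) -> dict:
        return {
            "slope": self.regression.slope,
            "intercept": self.regression.intercept,
            "r_squared": self.regression.r_squared,
            "fwhm": self.fwhm,
            "bandwidth": self.kde.bandwidth,
            "n_genes": self.n_genes,
        }


# ---------------------------------------------------------------------------
# region / gene aggregation
# ---------------------------------------------------------------------------


def region_coverage(
    track: CoverageTrack,
    regions: Sequence[GenomicInterval],
    reference: Mapping[str, str],
    library: str = "",
    sample: str = "",
    replicate: str = "",
) -> list[RegionCoverageRecord]:
    """Per-region mean depth (same depth definition as the window profile)
    and N-excluded GC fraction. Region labels are gene names."""
    if not regions:
        raise ValueError("empty region list")
    out: list[RegionCoverageRecord] = []
    for iv in regions:
        if len(iv) == 0:
            raise ValueError(f"zero-length region {iv.contig}:{iv.start}-{iv.end}")
        if iv.contig not in reference:
            raise ValueError(f"region contig {iv.contig!r} missing from reference")
        depth = track[iv.contig][iv.start : iv.end]
        seq = str(reference[iv.contig])[iv.start : iv.end]
        out.append(
            RegionCoverageRecord(
                interval=iv,
                gene=iv.label or f"{iv.contig}:{iv.start}-{iv.end}",
                mean_depth=float(np.mean(depth)),
                gc_fraction=gc_fraction(seq),
                library=library,
                sample=sample,
                replicate=replicate,
            )
        )
    return out


class FilterResult(NamedTuple):
    records: list
    removed_genes: list[str]


def filter_autosomal(
    records: Sequence[RegionCoverageRecord],
    sex_chromosomes: frozenset[str] | set[str] = DEFAULT_SEX_CHROMOSOMES,
) -> FilterResult:
    """Drop records on sex chromosomes; report the removed gene labels."""
    kept = [r for r in records if r.interval.contig not in sex_chromosomes]
    removed = sorted({r.gene for r in records if r.interval.contig in sex_chromosomes})
    if removed:
        logger.info("filtered %d sex-chromosome genes: %s", len(removed), ", ".join(removed))
    return FilterResult(kept, removed)


def aggregate_genes(records: Sequence[RegionCoverageRecord]) -> list[GeneCoverageRecord]:
    """Unweighted mean of region depth and region GC per gene.

    Grouping respects the (library, sample, replicate) keys so records from
    several replicates can be aggregated in one call.
    """
    groups: dict[tuple, list[RegionCoverageRecord]] = {}
    order: list[tuple] = []
    for r in records:
        if not r.gene:
            raise ValueError("record without gene label")
        key = (r.library, r.sample, r.replicate, r.gene)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    out = []
    for key in order:
        rs = groups[key]
        out.append(
            GeneCoverageRecord(
                gene=key[3],
                chromosome=rs[0].interval.contig,
                mean_depth=float(np.mean([r.mean_depth for r in rs])),
                gc_fraction=float(np.mean([r.gc_fraction for r in rs])),
                library=key[0],
                sample=key[1],
                replicate=key[2],
            )
        )
    return out


def normalize_genes(records: Sequence[GeneCoverageRecord]) -> list[GeneCoverageRecord]:
    """Normalize gene depth to the unweighted mean within each
    (library, sample, replicate) group, so each group's mean is exactly 1."""
    groups: dict[tuple, list[GeneCoverageRecord]] = {}
    for r in records:
        groups.setdefault((r.library, r.sample, r.replicate), []).append(r)
    out: list[GeneCoverageRecord] = []
    for key, rs in groups.items():
        mean = float(np.mean([r.mean_depth for r in rs]))
        if mean <= 0:
            raise ValueError(f"group {key}: zero mean depth, cannot normalize")
        out.extend(replace(r, normalized_coverage=r.mean_depth / mean) for r in rs)
    return out


def average_replicates(records: Sequence[GeneCoverageRecord]) -> list[GeneCoverageRecord]:
    """Average normalized coverage (and depth/GC) across replicates per
    (library, sample, gene); the result carries replicate label "mean"."""
    groups: dict[tuple, list[GeneCoverageRecord]] = {}
    order: list[tuple] = []
    for r in records:
        key = (r.library, r.sample, r.gene)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    out = []
    for key in order:
        rs = groups[key]
        out.append(
            GeneCoverageRecord(
                gene=key[2],
                chromosome=rs[0].chromosome,
                mean_depth=float(np.mean([r.mean_depth for r in rs])),
                gc_fraction=float(np.mean([r.gc_fraction for r in rs])),
                normalized_coverage=float(np.mean([r.normalized_coverage for r in rs])),
                library=key[0],
                sample=key[1],
                replicate="mean",
            )
        )
    return out


def normalize_and_average(records: Sequence[GeneCoverageRecord]) -> list[GeneCoverageRecord]:
    """Per-group normalization followed by replicate averaging."""
    return average_replicates(normalize_genes(records))


# ---------------------------------------------------------------------------
# regression & KDE/FWHM
# ---------------------------------------------------------------------------


def gc_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of normalized coverage on GC fraction.

    R^2 = 1 - SS_res/SS_tot, with the convention R^2 = 0 (slope 0) for a
    constant response.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all GC values equal")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0)
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def kde_fwhm(values: Sequence[float], grid_points: int = 512) -> KdeFwhm:
    """Full width at half maximum of a Gaussian KDE (Silverman bandwidth).

    The density is evaluated on a ``grid_points`` grid spanning
    [min - 3h, max + 3h]; the FWHM is the distance between the outermost
    crossings of half the peak density, located by linear interpolation —
    robust to multimodal coverage distributions.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values for a KDE")
    if np.ptp(values) == 0:
        raise ValueError("constant input: zero variance, FWHM undefined")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_points)
    density = kde(grid)
    half = density.max() / 2.0
    above = density >= half
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]

    def _interp_left(i: int) -> float:
        if i == 0:
            return float(grid[0])
        d0, d1 = density[i - 1], density[i]
        return float(grid[i - 1] + (half - d0) / (d1 - d0) * (grid[i] - grid[i - 1]))

    def _interp_right(i: int) -> float:
        if i == len(grid) - 1:
            return float(grid[-1])
        d0, d1 = density[i], density[i + 1]
        return float(grid[i] + (d0 - half) / (d0 - d1) * (grid[i + 1] - grid[i]))

    fwhm = _interp_right(i1) - _interp_left(i0)
    return KdeFwhm(fwhm=float(fwhm), grid=grid, density=density, bandwidth=h)


def uniformity_summary(records: Sequence[GeneCoverageRecord]) -> UniformityResult:
    """Regression of normalized coverage on GC plus the KDE/FWHM statistic."""
    gc = [r.gc_fraction for r in records]
    norm = [r.normalized_coverage for r in records]
    if any(not np.isfinite(v) for v in norm):
        raise ValueError("records must be normalized first (normalized_coverage set)")
    kde = kde_fwhm(norm)
    return UniformityResult(
        regression=gc_regression(gc, norm),
        fwhm=kde.fwhm,
        kde=kde,
        n_genes=len(records),
    )


# ---------------------------------------------------------------------------
# chromosome granularity
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeUniformity:
    table: pd.DataFrame  # chromosome, gc_fraction, mean_depth, normalized_coverage
    regression: RegressionResult


def chromosome_uniformity(
    track: CoverageTrack,
    reference: Mapping[str, str],
    sex_chromosomes: frozenset[str] | set[str] = DEFAULT_SEX_CHROMOSOMES,
) -> ChromosomeUniformity:
    """Whole chromosomes as regions: normalized coverage (unweighted mean over
    chromosomes) regressed on chromosome GC. Needs >= 3 chromosomes."""
    rows = []
    for contig, depth in track.items():
        if contig in sex_chromosomes:
            continue
        seq = str(reference[contig])
        rows.append(
            {
                "chromosome": contig,
                "gc_fraction": gc_fraction(seq),
                "mean_depth": float(np.mean(depth)),
            }
        )
    if len(rows) < 3:
        raise ValueError("need >= 3 (non-sex) chromosomes for a regression")
    df = pd.DataFrame(rows)
    mean = df["mean_depth"].mean()
    if mean <= 0:
        raise ValueError("zero mean depth across chromosomes")
    df["normalized_coverage"] = df["mean_depth"] / mean
    reg = gc_regression(df["gc_fraction"], df["normalized_coverage"])
    return ChromosomeUniformity(table=df, regression=reg)
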