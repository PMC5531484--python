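"""Seeded synthetic panel-sequencing outputs.

Real patient sequencing data for this assay is not public, so every
downstream stage is exercised on synthetic coverage matrices and site
pileups that reproduce the statistical structure the analysis relies on:

* 16-plex capture runs in which >97% of targeted regions exceed the 30x
  diagnostic depth threshold, with ~2.2% designated low-coverage regions
  (region-level mean depth ~5, range 0-25) that are low in every sample,
  matching the observed run-to-run reproducibility of capture efficiency;
* pseudogene-interference regions that retain depth on paper but whose
  reads carry mapping quality 0 (``mq0_fraction`` near 1);
* genomic deletions spiked in as zero-read regions of otherwise
  well-covered genes;
* per-site pileups whose alternate-read counts are binomial in the true
  allele fraction with a small per-base error floor.

All randomness flows from ``SimulationParams.seed``; identical parameters
give bit-identical outputs.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import GenePanel
from .triage import AnnotatedVariant

COVERAGE_COLUMNS = [
    "sample_id",
    "gene",
    "region_label",
    "chrom",
    "start",
    "end",
    "mean_depth",
    "min_depth",
    "mapped_reads",
    "mq0_fraction",
    "region_class",
]


@dataclass(frozen=True)
class SimulationParams:
    """Statistical description of one multiplexed capture run.

    ``target_mean_depth`` is the run-level mean depth of a well-behaved
    region; ``region_dispersion`` and ``sample_dispersion`` are lognormal
    sigmas for the multiplicative region- and sample-level capture effects.
    ``low_coverage_fraction`` of regions are designated poorly-capturing
    (region mean drawn with mean ``low_coverage_mean_depth``, truncated at
    ``low_coverage_max_depth``), and ``mq0_region_fraction`` of regions are
    additionally pseudogene-like (reads present, mapping quality 0).
    ``cell_dispersion`` is run-level library/loading noise applied per
    sample x region cell.
    """

    n_samples: int = 16
    target_mean_depth: float = 200.0
    region_dispersion: float = 0.35
    sample_dispersion: float = 0.10
    cell_dispersion: float = 0.15
    low_coverage_fraction: float = 0.022
    low_coverage_mean_depth: float = 5.0
    low_coverage_max_depth: float = 25.0
    mq0_region_fraction: float = 0.01
    per_base_error: float = 0.001
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("low_coverage_fraction", "mq0_region_fraction", "per_base_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0,1], got {v}")
        if self.target_mean_depth <= 0:
            raise ValueError("target_mean_depth must be positive")
        if self.region_dispersion <= 0:
            raise ValueError("region_dispersion must be positive")


@dataclass(frozen=True)
class PileupSite:
    """Read pileup at a single genomic site in one sample."""

    sample_id: int | str
    gene: str
    position: int
    depth: int
    alt_reads: int
    per_base_error: float

    def __post_init__(self) -> None:
        if self.depth < 0 or not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"invalid pileup: alt_reads {self.alt_reads} / depth {self.depth}"
            )

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0


def simulate_coverage(
    panel: GenePanel,
    params: SimulationParams | None = None,
    sample_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Simulate a sample x region coverage table for one multiplexed run."""
    params = params or SimulationParams()
    if params.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sample_ids is None:
        sample_ids = list(range(1, params.n_samples + 1))
    elif len(sample_ids) != params.n_samples:
        raise ValueError("sample_ids length must equal n_samples")

    rng = np.random.default_rng(params.seed)
    regions = sorted(panel.regions, key=lambda r: (r.gene, r.start))
    n_r, n_s = len(regions), params.n_samples

    # Capture efficiency is a property of the bait design, not of the run:
    # the same regions capture poorly (or map at MQ0) in every multiplexed
    # run, which is what makes between-run coverage highly reproducible.
    # Region-level draws therefore come from a generator seeded by the panel
    # itself; only run-level variation uses params.seed.
    design_key = zlib.crc32(
        "|".join(f"{r.gene}:{r.region_label}" for r in regions).encode()
    )
    design_rng = np.random.default_rng(
        [design_key, int(params.target_mean_depth), int(1e6 * params.low_coverage_fraction)]
    )
    n_low = int(round(params.low_coverage_fraction * n_r))
    low_idx = design_rng.choice(n_r, size=n_low, replace=False)
    # pseudogene-like regions are drawn from the poorly-capturing set: their
    # confidently-mapped depth is low because most reads land at MQ0
    n_mq0 = min(int(round(params.mq0_region_fraction * n_r)), n_low)
    mq0_idx = low_idx[:n_mq0]

    region_mean = params.target_mean_depth * design_rng.lognormal(
        0, params.region_dispersion, n_r
    )
    low_means = np.clip(
        design_rng.gamma(shape=1.2, scale=params.low_coverage_mean_depth / 1.2, size=n_low),
        0.0,
        params.low_coverage_max_depth,
    )
    region_mean[low_idx] = low_means
    sample_effect = rng.lognormal(0, params.sample_dispersion, n_s)

    # run-level library/loading noise on every sample x region cell
    cell_noise = rng.lognormal(0, params.cell_dispersion, (n_s, n_r))
    mean_depth = np.outer(sample_effect, region_mean) * cell_noise  # samples x regions
    min_frac = rng.uniform(0.4, 0.8, size=(n_s, n_r))
    lengths = np.array([r.length for r in regions], dtype=float)
    lam = mean_depth * lengths[None, :] / params.read_length
    mapped = rng.poisson(lam)
    # a region with no confidently mapped reads has, by definition, no depth
    mean_depth = np.where(mapped == 0, 0.0, mean_depth)
    min_depth = mean_depth * min_frac

    mq0 = rng.uniform(0.0, 0.02, size=(n_s, n_r))
    mq0[:, mq0_idx] = rng.uniform(0.92, 1.0, size=(n_s, n_mq0))

    region_class = np.full(n_r, "normal", dtype=object)
    region_class[low_idx] = "low"
    region_class[mq0_idx] = "mq0"

    frames = []
    for si, sid in enumerate(sample_ids):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "gene": [r.gene for r in regions],
                    "region_label": [r.region_label for r in regions],
                    "chrom": [r.chrom for r in regions],
                    "start": [r.start for r in regions],
                    "end": [r.end for r in regions],
                    "mean_depth": mean_depth[si],
                    "min_depth": min_depth[si],
                    "mapped_reads": mapped[si],
                    "mq0_fraction": mq0[si],
                    "region_class": region_class,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[COVERAGE_COLUMNS]


def spike_deletions(
    coverage: pd.DataFrame,
    specs: Iterable[tuple],
) -> pd.DataFrame:
    """Zero out coverage for the given (sample, gene[, region labels]) cells.

    Each spec is ``(sample_id, gene)`` for a whole-gene deletion or
    ``(sample_id, gene, [region_label, ...])`` for specific regions. Unknown
    samples, genes or labels are rejected, listing every offender.
    """
    coverage = coverage.copy()
    samples = set(coverage["sample_id"])
    offenders: list[str] = []
    masks = []
    for spec in specs:
        sample_id, gene = spec[0], spec[1]
        labels = list(spec[2]) if len(spec) > 2 and spec[2] is not None else None
        if sample_id not in samples:
            offenders.append(f"unknown sample {sample_id!r}")
            continue
        gene_mask = (coverage["sample_id"] == sample_id) & (coverage["gene"] == gene)
        if not gene_mask.any():
            offenders.append(f"unknown gene {gene!r}")
            continue
        if labels is None:
            masks.append(gene_mask)
        else:
            known = set(coverage.loc[gene_mask, "region_label"])
            bad = [lb for lb in labels if lb not in known]
            if bad:
                offenders.append(f"unknown regions for {gene}: {bad}")
                continue
            masks.append(gene_mask & coverage["region_label"].isin(labels))
    if offenders:
        raise ValueError("invalid deletion specs: " + "; ".join(offenders))
    for mask in masks:
        coverage.loc[mask, ["mean_depth", "min_depth", "mapped_reads"]] = 0
    return coverage


def simulate_pileup(
    depth: int,
    true_af: float,
    per_base_error: float = 0.001,
    seed: int | np.random.Generator = 0,
    sample_id: int | str = 0,
    gene: str = "NA",
    position: int = 0,
) -> PileupSite:
    """Draw one binomial site pileup.

    The alternate-read probability is ``af*(1-e) + (1-af)*e/3``: a true
    alternate allele is misread with probability ``e``, and a reference
    allele is misread as this particular alternate base a third of the time
    it errors.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= true_af <= 1.0:
        raise ValueError("true_af must be in [0,1]")
    if not 0.0 <= per_base_error <= 1.0:
        raise ValueError("per_base_error must be in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = true_af * (1.0 - per_base_error) + (1.0 - true_af) * per_base_error / 3.0
    alt = int(rng.binomial(depth, p))
    return PileupSite(
        sample_id=sample_id,
        gene=gene,
        position=position,
        depth=int(depth),
        alt_reads=alt,
        per_base_error=per_base_error,
    )


ZYGOSITY_AF = {"het": 0.5, "hom": 1.0, "hemi": 1.0}

DEFAULT_PILEUP_DEPTH = 200


@dataclass
class CohortBundle:
    """Everything the validation harness needs for one synthetic run."""

    panel: GenePanel
    params: SimulationParams
    coverage: pd.DataFrame
    pileups: list[PileupSite]
    variants: list[AnnotatedVariant]
    truth: list

    @property
    def sample_ids(self) -> list:
        if self.coverage.empty:
            return []
        return sorted(self.coverage["sample_id"].unique())


def build_cohort_from_truth(
    truth: Sequence,
    panel: GenePanel,
    params: SimulationParams | None = None,
) -> CohortBundle:
    """Materialise a truth set as a synthetic sequencing run.

    Sequence-variant truth records become pileups at their recorded read
    depths (germline allele fraction by zygosity, mosaic fraction for
    mosaics) and rows of the annotated variant table; records falling
    outside the panel's captured design are omitted from the variant table
    but stay in the truth list. Deletion records become zero-read regions
    spiked into the simulated coverage matrix.
    """
    from .panel import in_capture  # local import to keep module load cheap

    params = params or SimulationParams()
    truth = list(truth)
    if not truth:
        return CohortBundle(panel, params, pd.DataFrame(columns=COVERAGE_COLUMNS), [], [], [])

    patients = sorted({r.patient_id for r in truth})
    params = replace(params, n_samples=len(patients))
    coverage = simulate_coverage(panel, params, sample_ids=patients)

    specs = []
    for r in truth:
        if r.is_deletion:
            labels = None if r.region_label == "whole_gene" else [r.region_label]
            specs.append((r.patient_id, r.gene, labels))
    coverage = spike_deletions(coverage, specs)

    pileup_rng = np.random.default_rng([params.seed, 0x9E3779B9])
    pileups: list[PileupSite] = []
    variants: list[AnnotatedVariant] = []
    for r in sorted(truth, key=lambda t: (t.patient_id, t.gene, t.cdna_change)):
        if r.is_deletion:
            continue
        if not in_capture(panel, r.chrom, r.position, r.gene):
            continue  # not captured: never reaches the variant table
        depth = r.read_depth
        if depth is None:
            warnings.warn(
                f"truth record {r.gene} {r.cdna_change} lacks a read depth; "
                f"using cohort default {DEFAULT_PILEUP_DEPTH}",
                stacklevel=2,
            )
            depth = DEFAULT_PILEUP_DEPTH
        af = (
            r.mosaic_fraction
            if r.mosaic_fraction is not None
            else ZYGOSITY_AF.get(r.zygosity, 0.5)
        )
        site = simulate_pileup(
            depth,
            af,
            params.per_base_error,
            seed=pileup_rng,
            sample_id=r.patient_id,
            gene=r.gene,
            position=r.position,
        )
        pileups.append(site)
        variants.append(
            AnnotatedVariant(
                patient_id=r.patient_id,
                gene=r.gene,
                cdna_change=r.cdna_change,
                protein_change=r.protein_change,
                consequence=r.consequence or "missense",
                zygosity="het" if r.zygosity == "n/a" else r.zygosity,
                read_depth=site.depth,
                alt_reads=site.alt_reads,
                maf_by_db=dict(r.maf_by_db),
            )
        )
    return CohortBundle(panel, params, coverage, pileups, variants, truth)
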