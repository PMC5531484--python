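"""Depth-of-coverage QC: the 30x rule, low-coverage flagging, run concordance.

A region is "low coverage" when any single base falls below the 30x
diagnostic threshold; with per-region summary records this is
operationalised as ``min_depth < threshold``. Because the 2.2%
low-region figure can be read either per sample x region or on cohort-mean
depths, the summary reports both granularities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

REGION_KEY = ["gene", "region_label"]


def _check_coverage(coverage: pd.DataFrame) -> None:
    if coverage is None or len(coverage) == 0:
        raise ValueError("coverage table is empty")


def flag_low_coverage(
    coverage: pd.DataFrame, threshold: float = 30.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag regions below the diagnostic depth threshold.

    Returns ``(per_cell, per_region)``: the input plus a boolean
    ``low_coverage`` column (``min_depth < threshold``, strict), and a
    per-region aggregate with ``flagged_any_sample`` and
    ``flagged_by_cohort_mean`` (cohort mean of min depth below threshold).
    """
    _check_coverage(coverage)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    per_cell = coverage.copy()
    per_cell["low_coverage"] = per_cell["min_depth"] < threshold
    grouped = per_cell.groupby(REGION_KEY, sort=True)
    per_region = grouped.agg(
        flagged_any_sample=("low_coverage", "any"),
        mean_min_depth=("min_depth", "mean"),
        mean_depth=("mean_depth", "mean"),
    ).reset_index()
    per_region["flagged_by_cohort_mean"] = per_region["mean_min_depth"] < threshold
    return per_cell, per_region


@dataclass
class CoverageSummary:
    threshold: float
    n_regions: int
    fraction_regions_above: float  # cohort-mean depth strictly above threshold
    fraction_flagged_by_mean: float  # complement of the above
    fraction_flagged_any_sample: float  # any-single-base rule, any sample
    fraction_cells_flagged: float  # per sample x region granularity
    per_gene: pd.DataFrame
    mq0_genes: list[str]


def coverage_summary(
    coverage: pd.DataFrame, threshold: float = 30.0, mq0_cutoff: float = 0.9
) -> CoverageSummary:
    """Cohort-level coverage QC summary.

    ``fraction_regions_above`` and ``fraction_flagged_by_mean`` partition
    the region set on cohort-mean depth. Genes with a region whose mean
    MQ0 fraction exceeds ``mq0_cutoff`` are listed separately: their reads
    map ambiguously (pseudogene interference) and their depth figures are
    not trustworthy for deletion calling.
    """
    per_cell, per_region = flag_low_coverage(coverage, threshold)
    above = per_region["mean_depth"] > threshold
    region_mq0 = (
        per_cell.groupby(REGION_KEY, sort=True)["mq0_fraction"].mean().reset_index()
    )
    mq0_genes = sorted(
        region_mq0.loc[region_mq0["mq0_fraction"] > mq0_cutoff, "gene"].unique()
    )
    per_gene = (
        per_cell.groupby("gene", sort=True)
        .agg(
            mean_depth=("mean_depth", "mean"),
            n_regions=("region_label", "nunique"),
            n_cells_flagged=("low_coverage", "sum"),
        )
        .reset_index()
    )
    return CoverageSummary(
        threshold=threshold,
        n_regions=len(per_region),
        fraction_regions_above=float(above.mean()),
        fraction_flagged_by_mean=float(1.0 - above.mean()),
        fraction_flagged_any_sample=float(per_region["flagged_any_sample"].mean()),
        fraction_cells_flagged=float(per_cell["low_coverage"].mean()),
        per_gene=per_gene,
        mq0_genes=mq0_genes,
    )


@dataclass
class ConcordanceResult:
    n_regions: int
    pearson: float
    spearman: float
    per_region: pd.DataFrame


def run_concordance(
    coverage_a: pd.DataFrame, coverage_b: pd.DataFrame
) -> ConcordanceResult:
    """Between-run reproducibility of per-region cohort-mean depth.

    Both runs must cover the same region set (same underlying panel);
    the result is symmetric in its arguments.
    """
    _check_coverage(coverage_a)
    _check_coverage(coverage_b)
    mean_a = coverage_a.groupby(REGION_KEY, sort=True)["mean_depth"].mean()
    mean_b = coverage_b.groupby(REGION_KEY, sort=True)["mean_depth"].mean()
    only_a = sorted(set(mean_a.index) - set(mean_b.index))
    only_b = sorted(set(mean_b.index) - set(mean_a.index))
    if only_a or only_b:
        raise ValueError(
            f"region sets differ: {len(only_a)} only in A (e.g. {only_a[:3]}), "
            f"{len(only_b)} only in B (e.g. {only_b[:3]})"
        )
    merged = pd.DataFrame({"run_a": mean_a, "run_b": mean_b}).reset_index()
    pearson = float(stats.pearsonr(merged["run_a"], merged["run_b"]).statistic)
    spearman = float(stats.spearmanr(merged["run_a"], merged["run_b"]).statistic)
    return ConcordanceResult(
        n_regions=len(merged), pearson=pearson, spearman=spearman, per_region=merged
    )
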