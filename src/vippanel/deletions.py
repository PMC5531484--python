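"""Coverage-based deletion calling.

A genomic deletion on a capture panel manifests as a region with zero
confidently mapped reads in one sample while the rest of the cohort covers
the same region well. The caller therefore flags (sample, region) cells
with at most ``max_sample_reads`` reads whose leave-one-out cohort mean
depth is at least ``min_cohort_mean``; the cohort guard excludes regions
that capture poorly in everyone (those are low-coverage regions, not
deletions), and regions dominated by mapping-quality-0 reads are excluded
outright (pseudogene interference, not deletion).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coverage import REGION_KEY


@dataclass(frozen=True)
class DeletionCall:
    sample_id: int | str
    gene: str
    region_labels: tuple[str, ...]
    kind: str  # "whole_gene" | "exon"
    cohort_mean: float  # leave-one-out mean depth over the called regions


def call_deletions(
    coverage: pd.DataFrame,
    min_cohort_mean: float = 30.0,
    max_sample_reads: int = 0,
    mq0_cutoff: float = 0.9,
) -> list[DeletionCall]:
    """Call candidate deletions from zero-read regions.

    Requires >= 2 samples: the cohort mean for a cell is estimated from the
    other samples, so a single-sample matrix has no cohort to compare with.
    Called regions of one gene in one sample are merged into a single call,
    labelled ``whole_gene`` when every covered region of the gene is called.
    """
    if coverage is None or len(coverage) == 0:
        return []
    samples = coverage["sample_id"].unique()
    if len(samples) < 2:
        raise ValueError("cohort required: deletion calling needs >= 2 samples")

    depth = coverage.pivot_table(
        index=REGION_KEY, columns="sample_id", values="mean_depth"
    )
    reads = coverage.pivot_table(
        index=REGION_KEY, columns="sample_id", values="mapped_reads"
    )
    mq0 = coverage.groupby(REGION_KEY)["mq0_fraction"].mean()
    starts = coverage.groupby(REGION_KEY)["start"].first()

    n = depth.shape[1]
    loo_mean = (depth.sum(axis=1).to_numpy()[:, None] - depth.to_numpy()) / (n - 1)
    loo = pd.DataFrame(loo_mean, index=depth.index, columns=depth.columns)

    called = (
        (reads <= max_sample_reads)
        & (loo >= min_cohort_mean)
        & (mq0 <= mq0_cutoff).to_numpy()[:, None]
    )

    # a call spans the "whole gene" when every region the caller can assess
    # (cohort supports the comparison, not pseudogene-dominated) is called;
    # regions that capture poorly in everyone carry no deletion information
    assessable = (loo >= min_cohort_mean) & (mq0 <= mq0_cutoff).to_numpy()[:, None]
    genes_of_regions = depth.index.get_level_values("gene")
    calls: list[DeletionCall] = []
    for sample in called.columns:
        hits = called[sample]
        if not hits.any():
            continue
        hit_idx = depth.index[hits]
        by_gene: dict[str, list[str]] = {}
        for gene, label in hit_idx:
            by_gene.setdefault(gene, []).append(label)
        n_assessable = (
            assessable[sample].groupby(genes_of_regions).sum()
        )
        for gene in sorted(by_gene):
            labels = sorted(by_gene[gene], key=lambda lb: starts.loc[(gene, lb)])
            kind = "whole_gene" if len(labels) == int(n_assessable[gene]) else "exon"
            cohort_mean = float(
                loo.loc[[(gene, lb) for lb in labels], sample].mean()
            )
            calls.append(
                DeletionCall(
                    sample_id=sample,
                    gene=gene,
                    region_labels=tuple(labels),
                    kind=kind,
                    cohort_mean=cohort_mean,
                )
            )
    calls.sort(key=lambda c: (str(c.sample_id), c.gene))
    return calls
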