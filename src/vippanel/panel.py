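"""Capture-panel model: target regions, gene annotation, membership queries.

A panel is a set of captured intervals (exons plus at least 10 bp of flanking
intronic sequence, BED-style 0-based half-open) together with per-gene
annotation: inheritance mode (AR / AD / XL / other) and one of eleven disease
subgroups used to organise the gene list. Two panel versions exist: VIP1
(113 genes) and a broadened successor VIP2 (166 genes, adding among other
things the regulatory intron 1 of UNC13D).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import pandas as pd

VALID_INHERITANCE = frozenset({"AR", "AD", "XL", "other"})

PANEL_VERSIONS = ("VIP1", "VIP2")


class PanelError(ValueError):
    """Raised when panel sources are malformed or internally inconsistent."""


class CaptureStatus(enum.Enum):
    """Outcome of a capture-membership query.

    ``GENE_NOT_ON_PANEL`` is deliberately distinct from ``OUT_OF_CAPTURE``:
    "this panel does not target the gene at all" must never be conflated with
    "the gene is targeted but this position falls outside the baited design".
    """

    IN_CAPTURE = "in_capture"
    OUT_OF_CAPTURE = "out_of_capture"
    GENE_NOT_ON_PANEL = "gene_not_on_panel"

    def __bool__(self) -> bool:
        return self is CaptureStatus.IN_CAPTURE


@dataclass(frozen=True)
class TargetRegion:
    """One captured interval (typically an exon) with its intronic flank."""

    gene: str
    region_label: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    flank_bp: int = 10
    boosted: bool = False  # regions given additional baits to lift coverage

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"malformed interval {self.gene}/{self.region_label}: "
                f"start {self.start} >= end {self.end}"
            )
        if self.flank_bp < 0:
            raise PanelError(f"negative flank_bp for {self.gene}/{self.region_label}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, position: int) -> bool:
        """True iff ``position`` lies within the flanked interval.

        The flank extends the captured half-open interval symmetrically:
        [start - flank_bp, end + flank_bp).
        """
        return (
            chrom == self.chrom
            and self.start - self.flank_bp <= position < self.end + self.flank_bp
        )


@dataclass
class GenePanel:
    version: str
    regions: list[TargetRegion]
    inheritance: dict[str, str]
    subgroup: dict[str, str]
    _regions_by_gene: dict[str, list[TargetRegion]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if self.version not in PANEL_VERSIONS:
            raise PanelError(f"unknown panel version {self.version!r}")
        self._regions_by_gene = {}
        for region in self.regions:
            self._regions_by_gene.setdefault(region.gene, []).append(region)
        for gene in self._regions_by_gene:
            if gene not in self.subgroup:
                raise PanelError(f"gene {gene} has regions but no subgroup")

    @property
    def genes(self) -> list[str]:
        return sorted(self._regions_by_gene)

    @property
    def gene_count(self) -> int:
        return len(self._regions_by_gene)

    def regions_of(self, gene: str) -> list[TargetRegion]:
        try:
            return list(self._regions_by_gene[gene])
        except KeyError:
            raise PanelError(f"gene {gene} not on panel {self.version}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._regions_by_gene


def load_panel(
    regions_source: pd.DataFrame, annotation_source: pd.DataFrame, version: str = "VIP1"
) -> GenePanel:
    """Build a validated :class:`GenePanel` from BED-like tables.

    Parameters
    ----------
    regions_source
        Columns ``chrom, start, end, gene`` and optionally ``region_label``,
        ``flank_bp``, ``boosted``. Intervals are 0-based half-open.
    annotation_source
        Columns ``gene, inheritance, subgroup``; every gene appearing in
        ``regions_source`` must be annotated. Unknown inheritance strings are
        recorded as ``"other"`` with a warning rather than rejected.
    """
    if len(regions_source) == 0:
        raise PanelError("no regions")
    required = {"chrom", "start", "end", "gene"}
    missing = required - set(regions_source.columns)
    if missing:
        raise PanelError(f"regions table missing columns: {sorted(missing)}")

    ann = annotation_source.set_index("gene")
    unknown = sorted(set(regions_source["gene"]) - set(ann.index))
    if unknown:
        raise PanelError(f"genes missing from annotation: {unknown}")

    regions: list[TargetRegion] = []
    for idx, row in enumerate(regions_source.itertuples(index=False), start=1):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise PanelError(f"malformed interval at line {idx}: start {start} >= end {end}")
        regions.append(
            TargetRegion(
                gene=str(row.gene),
                region_label=str(getattr(row, "region_label", f"region {idx}")),
                chrom=str(row.chrom),
                start=start,
                end=end,
                flank_bp=int(getattr(row, "flank_bp", 10)),
                boosted=bool(getattr(row, "boosted", False)),
            )
        )

    inheritance: dict[str, str] = {}
    subgroup: dict[str, str] = {}
    for gene, row in ann.iterrows():
        mode = str(row["inheritance"])
        if mode not in VALID_INHERITANCE:
            warnings.warn(
                f"gene {gene}: unknown inheritance {mode!r} recorded as 'other'",
                stacklevel=2,
            )
            mode = "other"
        inheritance[str(gene)] = mode
        subgroup[str(gene)] = str(row["subgroup"])

    return GenePanel(
        version=version, regions=regions, inheritance=inheritance, subgroup=subgroup
    )


def in_capture(panel: GenePanel, chrom: str, position: int, gene: str) -> CaptureStatus:
    """Is ``position`` inside the flanked capture design of ``gene``?

    Returns :class:`CaptureStatus`, which is truthy only for ``IN_CAPTURE``.
    A gene absent from the panel yields ``GENE_NOT_ON_PANEL``, never a bare
    "outside capture" answer.
    """
    if gene not in panel:
        return CaptureStatus.GENE_NOT_ON_PANEL
    for region in panel.regions_of(gene):
        if region.contains(chrom, position):
            return CaptureStatus.IN_CAPTURE
    return CaptureStatus.OUT_OF_CAPTURE


def subgroup_totals(panel: GenePanel) -> tuple[dict[str, int], int]:
    """Per-disease-subgroup gene counts plus the panel total.

    The subgroups partition the gene set (each gene carries exactly one
    label), so the counts sum to ``panel.gene_count``.
    """
    counts: dict[str, int] = {}
    for gene in panel.genes:
        counts[panel.subgroup[gene]] = counts.get(panel.subgroup[gene], 0) + 1
    return counts, sum(counts.values())
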