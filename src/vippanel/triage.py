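"""Variant prioritisation: MAF cascade, whitelist, rescue re-scan, inheritance
consistency, and ACGS class 1-5 assignment.

The cascade mirrors clinical practice for rare monogenic inflammatory
disease: synonymous changes are dropped first, then anything with a
population minor-allele frequency above 1% in any of 1000G / ESP6500 / ExAC
— except a short whitelist of relatively common but disease-relevant
low-penetrance alleles (PRF1 p.A91V, TNFRSF1A p.R92Q, NLRP3 p.V198M).
A recessive "single heterozygote" rescue pass then re-admits same-gene
variants from the unfiltered list, because a rare pathogenic allele paired
with a commoner reduced-penetrance allele (e.g. the 5'UTR CECR1 variant at
MAF 7%) can cause recessive disease and would otherwise be lost to the MAF
filter.

Classification applies a deterministic, auditable rule table rather than
free expert judgement: the evidence that an expert would weigh (a published
pathogenic report, phenotype concordance, ACMG evidence codes) is explicit
input on each variant, and the mapping from evidence to ACGS class 1-5 is
fixed and ordered, so replaying the same table always yields the same class.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .panel import GenePanel

CONSEQUENCES = frozenset(
    {
        "synonymous",
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splice_site",
        "UTR",
        "intronic",
        "regulatory",
    }
)

EVIDENCE_CODES = frozenset({"VS", "S", "M"})

#: The three low-penetrance MAF-filter exceptions, keyed (gene, protein change).
DEFAULT_WHITELIST = frozenset(
    {("PRF1", "A91V"), ("TNFRSF1A", "R92Q"), ("NLRP3", "V198M")}
)


def _norm_protein(p: str | None) -> str | None:
    if p is None:
        return None
    return p[2:] if p.startswith("p.") else p


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant with the annotation the cascade consumes."""

    patient_id: int
    gene: str
    cdna_change: str
    protein_change: str | None = None
    consequence: str = "missense"
    zygosity: str = "het"  # het | hom | hemi
    read_depth: int | None = None
    alt_reads: int | None = None
    maf_by_db: Mapping[str, float] = field(default_factory=dict)
    predictions: tuple[str, str, str] | None = None
    published_pathogenic_ref: bool = False
    phenotype_concordant: bool = False
    evidence_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for db, maf in self.maf_by_db.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF out of range for {db}: {maf}")
        if not self.evidence_codes <= EVIDENCE_CODES:
            raise ValueError(f"unknown evidence codes {set(self.evidence_codes)}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.cdna_change)


@dataclass(frozen=True)
class TriageConfig:
    maf_cutoff: float = 0.01
    whitelist: frozenset[tuple[str, str]] = DEFAULT_WHITELIST
    drop_synonymous: bool = True
    min_depth: int = 30  # diagnostic depth expected at a reportable site
    flank_bp: int = 10

    def is_whitelisted(self, variant: AnnotatedVariant) -> bool:
        return (variant.gene, _norm_protein(variant.protein_change)) in {
            (g, _norm_protein(p)) for g, p in self.whitelist
        }


def aggregate_maf(variant: AnnotatedVariant) -> float:
    """Worst-case population frequency: maximum over the databases that
    report the allele; absent everywhere counts as 0 (novel)."""
    if not variant.maf_by_db:
        return 0.0
    return max(variant.maf_by_db.values())


@dataclass(frozen=True)
class RemovedVariant:
    variant: AnnotatedVariant
    reason: str  # "synonymous" | "common"
    audit_class: int  # 1 for synonymous, 2 for common: audit bookkeeping only


@dataclass
class CascadeResult:
    retained: list[AnnotatedVariant]
    removed: list[RemovedVariant]

    @property
    def audit(self) -> dict[tuple[str, str], str]:
        return {rm.variant.key: rm.reason for rm in self.removed}


def filter_cascade(
    variants: Iterable[AnnotatedVariant], config: TriageConfig | None = None
) -> CascadeResult:
    """Synonymous filter, then the MAF>cutoff filter with whitelist exceptions.

    Every input variant lands in exactly one of ``retained`` / ``removed``.
    """
    config = config or TriageConfig()
    retained: list[AnnotatedVariant] = []
    removed: list[RemovedVariant] = []
    for v in variants:
        if config.drop_synonymous and v.consequence == "synonymous":
            removed.append(RemovedVariant(v, "synonymous", audit_class=1))
        elif aggregate_maf(v) > config.maf_cutoff and not config.is_whitelisted(v):
            removed.append(RemovedVariant(v, "common", audit_class=2))
        else:
            retained.append(v)
    return CascadeResult(retained=retained, removed=removed)


def rescue_scan(
    all_variants: Iterable[AnnotatedVariant],
    retained: Iterable[AnnotatedVariant],
    panel: GenePanel,
) -> list[AnnotatedVariant]:
    """Recessive single-heterozygote rescue.

    For each autosomal-recessive gene in which a patient retains exactly one
    heterozygous rare variant, re-admit that patient's other variants in the
    same gene from the unfiltered list (whatever their MAF), since a second,
    commoner hit may complete a biallelic genotype. Synonymous variants stay
    out; dominant and X-linked genes are unaffected.
    """
    retained = list(retained)
    retained_keys = {(v.patient_id, v.key) for v in retained}
    het_count: Counter[tuple[int, str]] = Counter(
        (v.patient_id, v.gene) for v in retained if v.zygosity == "het"
    )
    rescued: list[AnnotatedVariant] = []
    for v in all_variants:
        if (v.patient_id, v.key) in retained_keys or v.consequence == "synonymous":
            continue
        if v.gene in panel and panel.inheritance.get(v.gene) == "AR":
            if het_count[(v.patient_id, v.gene)] == 1:
                rescued.append(v)
    return rescued


class InheritanceResult(enum.Enum):
    CONSISTENT = "consistent"
    CARRIER_ONLY = "carrier_only"
    INCONSISTENT = "inconsistent"
    FLAGGED_FOR_REVIEW = "flagged_for_review"


def inheritance_check(
    variant: AnnotatedVariant,
    panel: GenePanel,
    patient_sex: str = "unknown",
    same_gene_het_count: int = 1,
) -> InheritanceResult:
    """Does the zygosity fit the gene's mode of inheritance?

    ``same_gene_het_count`` is the number of retained heterozygous variants
    the patient carries in this gene (two rare hets in an AR gene are a
    candidate compound heterozygote). Unknown inheritance is flagged for
    review, never silently passed.
    """
    if variant.gene not in panel:
        return InheritanceResult.FLAGGED_FOR_REVIEW
    mode = panel.inheritance.get(variant.gene, "other")
    zyg = variant.zygosity
    if mode == "AR":
        if zyg == "hom":
            return InheritanceResult.CONSISTENT
        if zyg == "het":
            return (
                InheritanceResult.CONSISTENT
                if same_gene_het_count >= 2
                else InheritanceResult.CARRIER_ONLY
            )
        return InheritanceResult.FLAGGED_FOR_REVIEW
    if mode == "AD":
        return InheritanceResult.CONSISTENT
    if mode == "XL":
        if patient_sex in ("M", "male"):
            if zyg in ("hemi", "hom"):
                return InheritanceResult.CONSISTENT
            return InheritanceResult.FLAGGED_FOR_REVIEW
        if patient_sex in ("F", "female"):
            if zyg == "hom":
                return InheritanceResult.CONSISTENT
            if zyg == "het":
                # symptomatic female carriers of X-linked disease are reported
                return InheritanceResult.FLAGGED_FOR_REVIEW
            return InheritanceResult.INCONSISTENT
        return InheritanceResult.FLAGGED_FOR_REVIEW
    return InheritanceResult.FLAGGED_FOR_REVIEW


@dataclass(frozen=True)
class Classification:
    variant: AnnotatedVariant
    assigned_class: int  # ACGS 1-5
    evidence_codes: frozenset[str]
    rule_fired: str
    rationale: str


#: Ordered classification rule table (documented in the methods note).
RULE_TABLE = (
    ("R1", "published pathogenic report -> class 5"),
    ("R2", "whitelisted low-penetrance allele with concordant phenotype -> class 4"),
    ("R3", "concordant phenotype with AR-biallelic genotype or ACMG evidence -> class 4"),
    ("R4", "retained rare non-synonymous variant -> class 3 (VUS)"),
)


def classify_variant(
    variant: AnnotatedVariant,
    inheritance_result: InheritanceResult,
    config: TriageConfig | None = None,
    gene_inheritance: str | None = None,
) -> Classification:
    """Apply the ordered rule table; every retained variant gets one class."""
    config = config or TriageConfig()
    ar_biallelic = (
        gene_inheritance == "AR" and inheritance_result is InheritanceResult.CONSISTENT
    )
    if variant.published_pathogenic_ref:
        return Classification(
            variant,
            5,
            variant.evidence_codes or frozenset({"S"}),
            "R1",
            "published pathogenic report",
        )
    if config.is_whitelisted(variant) and variant.phenotype_concordant:
        return Classification(
            variant,
            4,
            frozenset({"S"}),
            "R2",
            "low-penetrance whitelist allele, concordant phenotype",
        )
    if variant.phenotype_concordant and (ar_biallelic or variant.evidence_codes):
        return Classification(
            variant,
            4,
            variant.evidence_codes,
            "R3",
            "concordant phenotype with supporting genotype/evidence",
        )
    return Classification(variant, 3, frozenset(), "R4", "rare variant of unknown significance")


@dataclass
class PatientReport:
    patient_id: int
    retained: list[AnnotatedVariant]
    rescued: list[AnnotatedVariant]
    removed: list[RemovedVariant]
    classifications: list[Classification]
    inheritance: dict[tuple[str, str], InheritanceResult]
    flags: list[str]
    partial: bool = False

    @property
    def headline_class(self) -> int | None:
        if not self.classifications:
            return None
        return max(c.assigned_class for c in self.classifications)

    @property
    def headline(self) -> str:
        if self.headline_class is None:
            return "no rare variants"
        return f"class {self.headline_class}"

    def classes_present(self) -> set[int]:
        return {c.assigned_class for c in self.classifications}


def triage_patient(
    variants: Iterable[AnnotatedVariant],
    panel: GenePanel,
    config: TriageConfig | None = None,
    patient_sex: str = "unknown",
    patient_id: int | None = None,
) -> PatientReport:
    """Full per-patient pipeline: cascade, rescue, inheritance, classification.

    Every input variant appears exactly once across the report's
    retained / rescued / removed categories; the patient headline is the
    highest assigned class.
    """
    config = config or TriageConfig()
    variants = sorted(variants, key=lambda v: (v.gene, v.cdna_change))
    if patient_id is None:
        patient_id = variants[0].patient_id if variants else -1
    cascade = filter_cascade(variants, config)
    rescued = rescue_scan(variants, cascade.retained, panel)
    rescued_keys = {v.key for v in rescued}
    removed = [rm for rm in cascade.removed if rm.variant.key not in rescued_keys]

    final = cascade.retained + rescued
    het_count: Counter[str] = Counter(v.gene for v in final if v.zygosity == "het")
    inheritance: dict[tuple[str, str], InheritanceResult] = {}
    classifications: list[Classification] = []
    flags: list[str] = []
    for v in final:
        res = inheritance_check(v, panel, patient_sex, het_count[v.gene])
        inheritance[v.key] = res
        mode = panel.inheritance.get(v.gene) if v.gene in panel else None
        classifications.append(classify_variant(v, res, config, mode))
        if res is InheritanceResult.FLAGGED_FOR_REVIEW:
            flags.append(f"flagged_for_review: {v.gene} {v.cdna_change}")
        elif res is InheritanceResult.CARRIER_ONLY:
            flags.append(f"carrier_only: {v.gene} {v.cdna_change}")
    return PatientReport(
        patient_id=patient_id,
        retained=cascade.retained,
        rescued=rescued,
        removed=removed,
        classifications=classifications,
        inheritance=inheritance,
        flags=flags,
    )
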