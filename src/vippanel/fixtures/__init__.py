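"""Machine-readable encodings of the printed study tables.

Three fixtures are packaged as plain TSV and validated on every load:

* the positive-control truth set (22 patients; the first 16 carry the 21
  previously Sanger-validated mutations used for the blinded panel
  validation, including three mosaics and three genomic deletions);
* the prospective cohort of 50 undiagnosed patients — full variant rows for
  patients 23-39, the two variant-negative patients 40-41, and per-patient
  "class 3 only" summary stubs for patients 42-72 whose individual variant
  lists were published only in supplementary material (stubs are flagged
  ``partial``);
* the synthetic stand-in capture panels (see :mod:`._panelgen`).

Load-time invariant checks guard against fixture corruption: a packaged
table that no longer matches the printed counts raises ``FixtureError``
rather than silently feeding wrong ground truth to the test harnesses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from ..panel import GenePanel
from ._panelgen import (
    SUBGROUP_TOTALS,
    _gene_position,
    _read_tsv,
    build_panel,
    unc13d_intron1_locus,
)

__all__ = [
    "FixtureError",
    "TruthRecord",
    "CohortVariantRecord",
    "PatientStub",
    "ProspectiveCohort",
    "load_positive_controls",
    "load_prospective_cohort",
    "vip1_panel",
    "vip2_panel",
    "SUBGROUP_TOTALS",
    "BLINDED_VALIDATION_PATIENTS",
]

#: Patients used in the formal blinded validation of VIP1.
BLINDED_VALIDATION_PATIENTS = frozenset(range(1, 17))

MOSAIC_PATIENTS = {14: 0.07, 15: 0.20, 16: 0.03}

DELETION_TYPES = frozenset({"gene_deletion", "exon_deletion"})


class FixtureError(RuntimeError):
    """Packaged fixture data failed its printed-table invariants."""


def vip1_panel() -> GenePanel:
    return build_panel("VIP1")


def vip2_panel() -> GenePanel:
    return build_panel("VIP2")


@dataclass(frozen=True)
class TruthRecord:
    """One previously validated positive-control mutation."""

    patient_id: int
    diagnosis: str
    gene: str
    cdna_change: str
    protein_change: str | None
    mutation_type: str  # SNV | small_indel | splice | gene_deletion | exon_deletion | regulatory
    consequence: str | None
    zygosity: str  # het | hom | hemi | n/a
    read_depth: int | None
    mosaic_fraction: float | None
    maf_by_db: dict[str, float]
    in_capture_vip1: bool
    region_label: str | None
    chrom: str
    position: int

    @property
    def is_deletion(self) -> bool:
        return self.mutation_type in DELETION_TYPES

    @property
    def is_sequence_variant(self) -> bool:
        return not self.is_deletion


def _maf_dict(row) -> dict[str, float]:
    out = {}
    for col, db in (("maf_1000g", "1000G"), ("maf_esp6500", "ESP6500"), ("maf_exac", "ExAC")):
        v = row[col]
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            out[db] = float(v)
    return out


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return str(v)


@lru_cache(maxsize=1)
def _positive_controls() -> tuple[TruthRecord, ...]:
    df = _read_tsv("positive_controls.tsv")
    vip1 = vip1_panel()
    records: list[TruthRecord] = []
    per_gene_offset: dict[str, int] = {}
    for _, row in df.iterrows():
        gene = row["gene"]
        if row["cdna_change"] == "c.118-308C>T" and gene == "UNC13D":
            chrom, pos = unc13d_intron1_locus()
        else:
            # distinct in-exon positions per record of the same gene
            off = per_gene_offset.get(gene, 0)
            per_gene_offset[gene] = off + 3
            chrom, pos = _gene_position(vip1, gene, offset=20 + off)
        depth = row["read_depth"]
        records.append(
            TruthRecord(
                patient_id=int(row["patient_id"]),
                diagnosis=str(row["diagnosis"]),
                gene=str(gene),
                cdna_change=str(row["cdna_change"]),
                protein_change=_opt_str(row["protein_change"]),
                mutation_type=str(row["mutation_type"]),
                consequence=_opt_str(row["consequence"]),
                zygosity=str(row["zygosity"]),
                read_depth=None if pd.isna(depth) else int(depth),
                mosaic_fraction=None
                if pd.isna(row["mosaic_fraction"])
                else float(row["mosaic_fraction"]),
                maf_by_db=_maf_dict(row),
                in_capture_vip1=bool(int(row["in_capture_vip1"])),
                region_label=_opt_str(row["region_label"]),
                chrom=chrom,
                position=pos,
            )
        )
    _check_truth_invariants(records)
    return tuple(records)


def _check_truth_invariants(records: list[TruthRecord]) -> None:
    patients = {r.patient_id for r in records}
    if patients != set(range(1, 23)):
        raise FixtureError("positive controls must cover patients 1-22")
    blinded = [r for r in records if r.patient_id in BLINDED_VALIDATION_PATIENTS]
    if len(blinded) != 21:
        raise FixtureError(f"expected 21 blinded truth mutations, got {len(blinded)}")
    genes = {r.gene for r in blinded}
    if len(genes) != 11:
        raise FixtureError(f"expected 11 distinct genes in blinded set, got {len(genes)}")
    mosaic = {r.patient_id: r.mosaic_fraction for r in records if r.mosaic_fraction is not None}
    if mosaic != MOSAIC_PATIENTS:
        raise FixtureError(f"mosaic fractions {mosaic} do not match printed values")
    for r in records:
        if r.is_deletion and r.read_depth is not None:
            raise FixtureError(f"deletion record {r.gene} must not carry a read depth")
    n_del_samples = len({r.patient_id for r in blinded if r.is_deletion})
    if n_del_samples != 3:
        raise FixtureError("expected genomic deletions in exactly 3 blinded samples")


def load_positive_controls() -> list[TruthRecord]:
    """The 22-patient positive-control truth set (Table 2 encoding)."""
    return list(_positive_controls())


@dataclass(frozen=True)
class CohortVariantRecord:
    """One printed variant row for a prospective-cohort patient."""

    patient_id: int
    sex: str
    gene: str
    cdna_change: str
    protein_change: str | None
    consequence: str
    predictions: tuple[str, str, str] | None  # (PolyPhen2, SIFT, MutationTaster)
    zygosity: str
    maf_by_db: dict[str, float]
    published_pathogenic_ref: bool
    low_penetrance_whitelisted: bool
    phenotype_concordant: bool
    evidence_codes: frozenset[str]
    printed_class: int


@dataclass(frozen=True)
class PatientStub:
    """Summary for a patient whose class-3-only variant list is unpublished."""

    patient_id: int
    n_class3: int
    note: str = ""
    partial: bool = True


@dataclass
class ProspectiveCohort:
    """The 50-patient prospective cohort: full rows plus partial stubs."""

    variants: dict[int, list[CohortVariantRecord]]  # patients 23-41
    stubs: dict[int, PatientStub] = field(default_factory=dict)  # patients 42-72
    sex: dict[int, str] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[int]:
        return sorted(self.variants) + sorted(self.stubs)

    @property
    def n_patients(self) -> int:
        return len(self.variants) + len(self.stubs)


def _parse_predictions(s) -> tuple[str, str, str] | None:
    s = _opt_str(s)
    if s is None:
        return None
    parts = tuple(s.split("/"))
    if len(parts) != 3:
        raise FixtureError(f"malformed prediction triple {s!r}")
    return parts  # type: ignore[return-value]


def _parse_codes(s) -> frozenset[str]:
    s = _opt_str(s)
    if s is None:
        return frozenset()
    codes = frozenset(c.strip() for c in s.split("+"))
    if not codes <= {"VS", "S", "M"}:
        raise FixtureError(f"unknown evidence codes {s!r}")
    return codes


@lru_cache(maxsize=1)
def _prospective() -> ProspectiveCohort:
    df = _read_tsv("prospective_variants.tsv")
    variants: dict[int, list[CohortVariantRecord]] = {pid: [] for pid in range(23, 42)}
    sex: dict[int, str] = {40: "M", 41: "M"}
    for _, row in df.iterrows():
        pid = int(row["patient_id"])
        sex[pid] = str(row["sex"])
        variants[pid].append(
            CohortVariantRecord(
                patient_id=pid,
                sex=str(row["sex"]),
                gene=str(row["gene"]),
                cdna_change=str(row["cdna_change"]),
                protein_change=_opt_str(row["protein_change"]),
                consequence=str(row["consequence"]),
                predictions=_parse_predictions(row["predictions"]),
                zygosity=str(row["zygosity"]),
                maf_by_db=_maf_dict(row),
                published_pathogenic_ref=bool(int(row["published_pathogenic_ref"])),
                low_penetrance_whitelisted=bool(int(row["low_penetrance_whitelisted"])),
                phenotype_concordant=bool(int(row["phenotype_concordant"])),
                evidence_codes=_parse_codes(row["evidence_codes"]),
                printed_class=int(row["printed_class"]),
            )
        )
    stub_df = _read_tsv("prospective_stubs.tsv")
    stubs = {
        int(r["patient_id"]): PatientStub(
            patient_id=int(r["patient_id"]),
            n_class3=int(r["n_class3"]),
            note=_opt_str(r.get("note")) or "",
        )
        for _, r in stub_df.iterrows()
    }
    cohort = ProspectiveCohort(variants=variants, stubs=stubs, sex=sex)
    _check_cohort_invariants(cohort)
    return cohort


def _check_cohort_invariants(cohort: ProspectiveCohort) -> None:
    if cohort.n_patients != 50:
        raise FixtureError(f"expected 50 prospective patients, got {cohort.n_patients}")
    if cohort.variants[40] or cohort.variants[41]:
        raise FixtureError("patients 40 and 41 must carry no rare variants")
    class5 = [r for recs in cohort.variants.values() for r in recs if r.printed_class == 5]
    # Table 3 prints one class-5 row for each of patients 23-28
    if len(class5) != 6 or {r.patient_id for r in class5} != set(range(23, 29)):
        raise FixtureError("class-5 rows must be the 6 printed rows of patients 23-28")
    if not all(r.published_pathogenic_ref for r in class5):
        raise FixtureError("all printed class-5 rows carry a published reference")
    class4_patients = {
        r.patient_id for recs in cohort.variants.values() for r in recs if r.printed_class == 4
    }
    if class4_patients != set(range(29, 40)):
        raise FixtureError("class-4 rows must occur in exactly patients 29-39")
    whitelisted = {
        (r.gene, r.protein_change)
        for recs in cohort.variants.values()
        for r in recs
        if r.low_penetrance_whitelisted
    }
    if whitelisted != {("TNFRSF1A", "R92Q"), ("NLRP3", "V198M")}:
        raise FixtureError(f"unexpected low-penetrance rows: {whitelisted}")


def load_prospective_cohort() -> ProspectiveCohort:
    """The 50-patient prospective cohort (Tables 3/4 encoding plus stubs)."""
    return _prospective()
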