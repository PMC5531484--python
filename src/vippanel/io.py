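"""File-format plumbing: BED target regions, coverage TSVs, variant tables
(merged TSV dialect or minimal VCF + sidecar annotation TSV), YAML config,
and report writers."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .triage import AnnotatedVariant, PatientReport

BED_COLUMNS = ["chrom", "start", "end", "gene", "region_label"]

VARIANT_TSV_COLUMNS = [
    "patient_id",
    "gene",
    "cdna_change",
    "protein_change",
    "consequence",
    "zygosity",
    "read_depth",
    "alt_reads",
    "maf_1000g",
    "maf_esp6500",
    "maf_exac",
    "predictions",
    "published_pathogenic_ref",
    "phenotype_concordant",
    "evidence_codes",
]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read target regions from BED (0-based half-open; 4th column gene
    symbol, optional 5th region label)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED needs >= 4 columns (chrom,start,end,gene)")
    df = df.iloc[:, :5] if df.shape[1] >= 5 else df
    df.columns = BED_COLUMNS[: df.shape[1]]
    if "region_label" not in df.columns:
        df["region_label"] = [f"region {i + 1}" for i in range(len(df))]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV with header: gene, inheritance, subgroup."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "inheritance", "subgroup"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene", "region_label", "mean_depth", "min_depth", "mapped_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing coverage columns {sorted(missing)}")
    if "mq0_fraction" not in df.columns:
        df["mq0_fraction"] = 0.0
    return df


def write_coverage(coverage: pd.DataFrame, path: str | Path) -> None:
    coverage.to_csv(path, sep="\t", index=False)


def _nan_to_none(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def _row_to_variant(row: dict) -> AnnotatedVariant:
    maf = {}
    for col, db in (("maf_1000g", "1000G"), ("maf_esp6500", "ESP6500"), ("maf_exac", "ExAC")):
        v = _nan_to_none(row.get(col))
        if v is not None and str(v) != "":
            maf[db] = float(v)
    pred = _nan_to_none(row.get("predictions"))
    predictions = tuple(str(pred).split("/")) if pred else None
    if predictions is not None and len(predictions) != 3:
        raise ValueError(f"prediction triple must have 3 fields: {pred!r}")
    codes = _nan_to_none(row.get("evidence_codes"))
    depth = _nan_to_none(row.get("read_depth"))
    alt = _nan_to_none(row.get("alt_reads"))
    return AnnotatedVariant(
        patient_id=int(row["patient_id"]),
        gene=str(row["gene"]),
        cdna_change=str(row["cdna_change"]),
        protein_change=_nan_to_none(row.get("protein_change")),
        consequence=str(row.get("consequence", "missense")),
        zygosity=str(row.get("zygosity", "het")),
        read_depth=None if depth is None else int(depth),
        alt_reads=None if alt is None else int(alt),
        maf_by_db=maf,
        predictions=predictions,  # type: ignore[arg-type]
        published_pathogenic_ref=bool(int(row.get("published_pathogenic_ref", 0) or 0)),
        phenotype_concordant=bool(int(row.get("phenotype_concordant", 0) or 0)),
        evidence_codes=frozenset(str(codes).split("+")) if codes else frozenset(),
    )


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    """Read the merged TSV variant dialect."""
    df = pd.read_csv(path, sep="\t")
    missing = {"patient_id", "gene", "cdna_change"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing variant columns {sorted(missing)}")
    return [_row_to_variant(row) for row in df.to_dict("records")]


def write_variant_table(variants: list[AnnotatedVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "patient_id": v.patient_id,
                "gene": v.gene,
                "cdna_change": v.cdna_change,
                "protein_change": v.protein_change,
                "consequence": v.consequence,
                "zygosity": v.zygosity,
                "read_depth": v.read_depth,
                "alt_reads": v.alt_reads,
                "maf_1000g": v.maf_by_db.get("1000G"),
                "maf_esp6500": v.maf_by_db.get("ESP6500"),
                "maf_exac": v.maf_by_db.get("ExAC"),
                "predictions": "/".join(v.predictions) if v.predictions else None,
                "published_pathogenic_ref": int(v.published_pathogenic_ref),
                "phenotype_concordant": int(v.phenotype_concordant),
                "evidence_codes": "+".join(sorted(v.evidence_codes)) or None,
            }
        )
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_vcf_variants(
    vcf_path: str | Path, annotation_path: str | Path
) -> list[AnnotatedVariant]:
    """Read a minimal VCF (CHROM, POS, REF, ALT; FORMAT GT:AD:DP) plus a
    sidecar annotation TSV keyed by ``chrom:pos:ref:alt``."""
    import pysam

    ann = pd.read_csv(annotation_path, sep="\t").set_index("variant_key")
    variants: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                if key not in ann.index:
                    continue
                meta = ann.loc[key].to_dict()
                for sample in sample_names:
                    call = rec.samples[sample]
                    gt = call.get("GT")
                    if gt is None or not any(g for g in gt if g):
                        continue
                    zygosity = "hom" if all(g == 1 for g in gt if g is not None) else "het"
                    ad = call.get("AD")
                    dp = call.get("DP")
                    row = dict(meta)
                    row.setdefault("patient_id", sample)
                    row["zygosity"] = zygosity
                    row["read_depth"] = dp
                    row["alt_reads"] = ad[1] if ad is not None and len(ad) > 1 else None
                    variants.append(_row_to_variant(row))
    return variants


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_json(obj: Any, path: str | Path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict("records")
        if hasattr(o, "item"):
            return o.item()
        return str(o)

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def write_patient_reports(reports: list[PatientReport], path: str | Path) -> None:
    """Per-variant audit TSV: one row per input variant per patient."""
    rows = []
    for rep in reports:
        class_by_key = {c.variant.key: c for c in rep.classifications}
        rescued_keys = {v.key for v in rep.rescued}
        for v in rep.retained + rep.rescued:
            c = class_by_key[v.key]
            rows.append(
                {
                    "patient_id": rep.patient_id,
                    "gene": v.gene,
                    "cdna_change": v.cdna_change,
                    "status": "rescued" if v.key in rescued_keys else "retained",
                    "assigned_class": c.assigned_class,
                    "evidence_codes": "+".join(sorted(c.evidence_codes)) or None,
                    "rule_fired": c.rule_fired,
                    "inheritance": rep.inheritance[v.key].value,
                }
            )
        for rm in rep.removed:
            rows.append(
                {
                    "patient_id": rep.patient_id,
                    "gene": rm.variant.gene,
                    "cdna_change": rm.variant.cdna_change,
                    "status": f"removed:{rm.reason}",
                    "assigned_class": rm.audit_class,
                    "evidence_codes": None,
                    "rule_fired": "cascade",
                    "inheritance": None,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
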