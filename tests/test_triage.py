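"""Variant triage: MAF aggregation, cascade, rescue, inheritance, classes."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vippanel.triage import (
    AnnotatedVariant,
    InheritanceResult,
    TriageConfig,
    aggregate_maf,
    classify_variant,
    filter_cascade,
    inheritance_check,
    rescue_scan,
    triage_patient,
)


def v(gene="NLRP3", cdna="1G>A", protein=None, consequence="missense", zygosity="het",
      maf=None, patient=1, **kwargs):
    return AnnotatedVariant(
        patient_id=patient,
        gene=gene,
        cdna_change=cdna,
        protein_change=protein,
        consequence=consequence,
        zygosity=zygosity,
        maf_by_db=maf or {},
        **kwargs,
    )


class TestAggregateMaf:
    def test_maximum_across_databases(self):
        prf1 = v("PRF1", "c.C272T", "A91V",
                 maf={"1000G": 0.02, "ESP6500": 0.034, "ExAC": 0.0311})
        assert aggregate_maf(prf1) == pytest.approx(0.034)

    def test_absent_everywhere_is_novel(self):
        assert aggregate_maf(v()) == 0.0

    def test_single_database(self):
        assert aggregate_maf(v(maf={"1000G": 0.0008})) == pytest.approx(0.0008)


class TestFilterCascade:
    def test_whitelisted_common_variant_retained(self):
        prf1 = v("PRF1", "c.C272T", "A91V", maf={"1000G": 0.02})
        res = filter_cascade([prf1], TriageConfig())
        assert res.retained == [prf1]

    def test_common_variant_removed_without_whitelist(self):
        intronic = v("UNC13D", "c.118-308C>T", consequence="intronic",
                     maf={"1000G": 0.28})
        res = filter_cascade([intronic], TriageConfig(whitelist=frozenset()))
        assert res.retained == []
        assert res.removed[0].reason == "common"

    def test_synonymous_removed_first_even_when_rare(self):
        syn = v(consequence="synonymous")
        res = filter_cascade([syn], TriageConfig())
        assert res.removed[0].reason == "synonymous"
        assert res.removed[0].audit_class == 1

    def test_protein_change_prefix_normalised(self):
        cfg = TriageConfig()
        assert cfg.is_whitelisted(v("NLRP3", "598G>A", "p.V198M"))
        assert cfg.is_whitelisted(v("NLRP3", "598G>A", "V198M"))


# --- randomized property checks -------------------------------------------

_GENES = ["NLRP3", "PRF1", "UNC13D", "MEFV", "TNFRSF1A", "CECR1"]

variant_strategy = st.builds(
    lambda gene, idx, consequence, maf_val, has_maf: v(
        gene=gene,
        cdna=f"{idx}G>A",
        consequence=consequence,
        maf={"ExAC": maf_val} if has_maf else {},
    ),
    gene=st.sampled_from(_GENES),
    idx=st.integers(1, 5000),
    consequence=st.sampled_from(["missense", "synonymous", "intronic", "frameshift"]),
    maf_val=st.floats(0, 0.5),
    has_maf=st.booleans(),
)


@settings(max_examples=60, derandomize=True)
@given(st.lists(variant_strategy, max_size=25))
def test_cascade_conserves_variants_with_unique_reasons(variants):
    res = filter_cascade(variants, TriageConfig())
    assert len(res.retained) + len(res.removed) == len(variants)
    retained_ids = {id(x) for x in res.retained}
    removed_ids = {id(rm.variant) for rm in res.removed}
    assert retained_ids.isdisjoint(removed_ids)
    assert all(rm.reason in ("synonymous", "common") for rm in res.removed)


@settings(max_examples=60, derandomize=True)
@given(st.lists(variant_strategy, max_size=25))
def test_whitelist_only_ever_adds_retained_variants(variants):
    with_wl = filter_cascade(variants, TriageConfig())
    without_wl = filter_cascade(variants, TriageConfig(whitelist=frozenset()))
    assert {id(x) for x in without_wl.retained} <= {id(x) for x in with_wl.retained}


class TestRescueScan:
    def test_recessive_second_hit_readmitted(self, vip1):
        exonic = v("CECR1", "C752T", "P251L", maf={"1000G": 0.0002}, patient=11)
        utr = v("CECR1", "-12233delC", consequence="UTR", maf={"1000G": 0.07}, patient=11)
        res = filter_cascade([exonic, utr], TriageConfig())
        assert res.retained == [exonic]
        rescued = rescue_scan([exonic, utr], res.retained, vip1)
        assert rescued == [utr]

    def test_biallelic_gene_needs_no_rescue(self, vip1):
        two = [v("LPIN2", "1876C>T", patient=29), v("LPIN2", "608C>T", patient=29)]
        common = v("LPIN2", "99G>A", maf={"ExAC": 0.05}, patient=29)
        assert rescue_scan(two + [common], two, vip1) == []

    def test_dominant_gene_single_het_not_rescued(self, vip1):
        kept = v("NLRP3", "1G>A", patient=1)
        common = v("NLRP3", "2G>A", maf={"ExAC": 0.05}, patient=1)
        assert rescue_scan([kept, common], [kept], vip1) == []


class TestInheritanceCheck:
    def test_xl_het_female_flagged_for_review(self, vip1):
        was = v("WAS", "391G>A", "E131K")
        res = inheritance_check(was, vip1, patient_sex="F")
        assert res is InheritanceResult.FLAGGED_FOR_REVIEW

    def test_ar_hom_consistent(self, vip1):
        stxbp2 = v("STXBP2", "c.1247-1G>C", consequence="splice_site", zygosity="hom")
        assert inheritance_check(stxbp2, vip1) is InheritanceResult.CONSISTENT

    def test_ar_single_het_is_carrier_only(self, vip1):
        unc = v("UNC13D", "2896C>T", "R966W")
        res = inheritance_check(unc, vip1, same_gene_het_count=1)
        assert res is InheritanceResult.CARRIER_ONLY

    def test_ar_compound_het_consistent(self, vip1):
        unc = v("UNC13D", "2896C>T", "R966W")
        res = inheritance_check(unc, vip1, same_gene_het_count=2)
        assert res is InheritanceResult.CONSISTENT

    def test_unknown_gene_never_silently_passes(self, vip1):
        res = inheritance_check(v("NOTAGENE", "1G>A"), vip1)
        assert res is InheritanceResult.FLAGGED_FOR_REVIEW


class TestClassifyVariant:
    def test_published_report_gives_class5_with_codes(self):
        tnfaip3 = v("TNFAIP3", "811C>T", "R271X", consequence="nonsense",
                    published_pathogenic_ref=True, phenotype_concordant=True,
                    evidence_codes=frozenset({"VS", "S"}))
        c = classify_variant(tnfaip3, InheritanceResult.CONSISTENT, gene_inheritance="AD")
        assert c.assigned_class == 5
        assert c.evidence_codes == {"VS", "S"}
        assert c.rule_fired == "R1"

    def test_whitelisted_low_penetrance_gives_class4(self):
        r92q = v("TNFRSF1A", "362G>A", "R92Q", phenotype_concordant=True)
        c = classify_variant(r92q, InheritanceResult.CONSISTENT, gene_inheritance="AD")
        assert (c.assigned_class, c.evidence_codes, c.rule_fired) == (4, {"S"}, "R2")

    def test_concordant_with_evidence_gives_class4(self):
        lyn = v("LYN", "1523A>T", "Y508F", phenotype_concordant=True,
                evidence_codes=frozenset({"S"}))
        c = classify_variant(lyn, InheritanceResult.CONSISTENT, gene_inheritance="AD")
        assert (c.assigned_class, c.rule_fired) == (4, "R3")

    def test_plain_rare_variant_is_class3(self):
        c5 = v("C5", "715G>A", "G239S")
        c = classify_variant(c5, InheritanceResult.CARRIER_ONLY, gene_inheritance="AR")
        assert (c.assigned_class, c.rule_fired) == (3, "R4")


class TestTriagePatient:
    def test_empty_patient_reports_no_rare_variants(self, vip1):
        report = triage_patient([], vip1, patient_id=40)
        assert report.headline == "no rare variants"
        assert report.headline_class is None

    def test_compound_het_recessive_headline_class4(self, vip1):
        variants = [
            v("LPIN2", "1876C>T", "P626S", patient=29, phenotype_concordant=True,
              evidence_codes=frozenset({"S"})),
            v("LPIN2", "608C>T", "S203F", patient=29, phenotype_concordant=True,
              evidence_codes=frozenset({"S"})),
        ]
        report = triage_patient(variants, vip1, patient_sex="F")
        assert report.headline_class == 4
        assert all(
            r is InheritanceResult.CONSISTENT for r in report.inheritance.values()
        )

    def test_every_variant_accounted_exactly_once(self, vip1):
        variants = [
            v("CECR1", "C752T", patient=11, maf={"1000G": 0.0002}),
            v("CECR1", "-12233delC", consequence="UTR", patient=11, maf={"1000G": 0.07}),
            v("PRF1", "1G>A", consequence="synonymous", patient=11),
        ]
        report = triage_patient(variants, vip1)
        keys = (
            [x.key for x in report.retained]
            + [x.key for x in report.rescued]
            + [rm.variant.key for rm in report.removed]
        )
        assert sorted(keys) == sorted(x.key for x in variants)
        assert len(keys) == len(set(keys))

    def test_input_order_never_changes_assigned_classes(self, vip1, cohort):
        records = cohort.variants[33]
        from vippanel.validation import replay_prospective

        base = {
            c.variant.key: c.assigned_class
            for r in replay_prospective()
            if r.patient_id == 33
            for c in r.classifications
        }
        variants = [
            v(r.gene, r.cdna_change, r.protein_change, r.consequence, r.zygosity,
              dict(r.maf_by_db), patient=33,
              published_pathogenic_ref=r.published_pathogenic_ref,
              phenotype_concordant=r.phenotype_concordant,
              evidence_codes=r.evidence_codes)
            for r in records
        ]
        rng = random.Random(5)
        for _ in range(5):
            rng.shuffle(variants)
            report = triage_patient(variants, vip1, patient_sex="F")
            got = {c.variant.key: c.assigned_class for c in report.classifications}
            assert got == base
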