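"""Fusion prioritization and TP53 status rules."""

import pytest

from pedcan.config import RuleConfig
from pedcan.fusion import annotate_oncogenic, cohort_fusion_counts, retain_fusions
from pedcan.tp53 import Tp53Evidence, Tp53Variant, classify_tp53
from pedcan.types import FusionCall


def fusion(g5, g3, callers=("arriba",), sample="S1", group="LGG"):
    return FusionCall(gene5=g5, gene3=g3, callers=frozenset(callers),
                      sample_id=sample, cancer_group=group)


GENE_LISTS = {
    "kinase": {"BRAF", "ALK"},
    "oncogene": {"MYCN"},
    "tsg": set(),
    "tf": set(),
    "cosmic_cgc": set(),
    "tcga_observed": {"TCGAGENE"},
}


class TestAnnotateOncogenic:
    def test_kinase_partner_is_oncogenic(self):
        assert annotate_oncogenic(fusion("KIAA1549", "BRAF"), GENE_LISTS)

    def test_unlisted_partners_not_oncogenic(self):
        assert not annotate_oncogenic(fusion("GENEX", "GENEY"), GENE_LISTS)

    def test_tcga_observed_counts(self):
        assert annotate_oncogenic(fusion("TCGAGENE", "GENEY"), GENE_LISTS)


class TestRetention:
    def test_both_callers_retained(self, cfg):
        f = fusion("GENEX", "GENEY", callers=("arriba", "starfusion"))
        (out,) = retain_fusions([f], {}, GENE_LISTS, cfg)
        assert "both_callers" in out.retained_reason

    def test_single_caller_oncogenic_retained(self, cfg):
        f = fusion("GENEX", "MYCN")
        counts = {("GENEX::MYCN", "LGG"): 1, ("GENEX::MYCN", "HGG"): 1}
        (out,) = retain_fusions([f], counts, GENE_LISTS, cfg)
        assert out.putative_oncogenic
        assert "oncogenic" in out.retained_reason

    def test_single_caller_unannotated_multigroup_dropped(self, cfg):
        f = fusion("GENEX", "GENEY")
        counts = {("GENEX::GENEY", "LGG"): 1, ("GENEX::GENEY", "HGG"): 1}
        assert retain_fusions([f], counts, GENE_LISTS, cfg) == []

    def test_recurrent_in_group_retained(self, cfg):
        f = fusion("GENEX", "GENEY")
        counts = {("GENEX::GENEY", "LGG"): 3, ("GENEX::GENEY", "HGG"): 1}
        (out,) = retain_fusions([f], counts, GENE_LISTS, cfg)
        assert "recurrent" in out.retained_reason

    def test_panel_fusions_pass_through(self, cfg):
        f = fusion("GENEX", "GENEY", callers=("dgd_panel",))
        counts = {("GENEX::GENEY", "LGG"): 1, ("GENEX::GENEY", "HGG"): 1}
        (out,) = retain_fusions([f], counts, GENE_LISTS, cfg)
        assert out.retained_reason == {"panel_passthrough"}

    def test_adding_gene_to_list_is_monotone(self, cfg):
        fusions = [
            fusion("GENEX", "GENEY"),
            fusion("KIAA1549", "BRAF", callers=("arriba", "starfusion")),
        ]
        counts = {("GENEX::GENEY", "LGG"): 1, ("GENEX::GENEY", "HGG"): 1}
        before = {(p.fusion.name, p.fusion.sample_id)
                  for p in retain_fusions(fusions, counts, GENE_LISTS, cfg)}
        bigger = {**GENE_LISTS, "oncogene": GENE_LISTS["oncogene"] | {"GENEX"}}
        after = {(p.fusion.name, p.fusion.sample_id)
                 for p in retain_fusions(fusions, counts, bigger, cfg)}
        assert before <= after

    def test_counts_deduplicate_patients(self):
        fusions = [fusion("A", "B", sample=s) for s in ("S1", "S2", "S3")]
        counts = cohort_fusion_counts(fusions, {"S1": "P1", "S2": "P1", "S3": "P2"})
        assert counts[("A::B", "LGG")] == 2


def evidence(**kw):
    return Tp53Evidence(sample_id="S1", **kw)


class TestTp53:
    def test_gain_of_function_is_activated(self):
        e = evidence(tp53_variants=[Tp53Variant("p.R273C", "somatic")])
        assert classify_tp53(e) == "activated"

    def test_activation_precedes_loss(self):
        e = evidence(
            tp53_variants=[Tp53Variant("p.R273C", "somatic"),
                           Tp53Variant("p.R175H", "somatic", hotspot_db_member=True)],
        )
        assert classify_tp53(e) == "activated"

    def test_hotspot_db_member_is_lost(self):
        e = evidence(tp53_variants=[Tp53Variant("p.R175H", "somatic",
                                                hotspot_db_member=True)])
        assert classify_tp53(e) == "lost"

    def test_two_distinct_alterations_lost(self):
        e = evidence(tp53_variants=[Tp53Variant("p.C135F", "somatic")],
                     tp53_cnv_deleted=True)
        assert classify_tp53(e) == "lost"

    def test_somatic_plus_lfs_germline_lost(self):
        e = evidence(tp53_variants=[
            Tp53Variant("p.C135F", "somatic"),
            Tp53Variant("p.R337H", "germline", lfs_associated=True),
        ])
        assert classify_tp53(e) == "lost"

    def test_lfs_germline_with_classifier_above_half_lost(self):
        e = evidence(tp53_variants=[Tp53Variant("p.R337H", "germline",
                                                lfs_associated=True)],
                     classifier_score=0.6)
        assert classify_tp53(e) == "lost"

    def test_classifier_exactly_half_is_not_lost(self):
        e = evidence(tp53_variants=[Tp53Variant("p.R337H", "germline",
                                                lfs_associated=True)],
                     classifier_score=0.5)
        assert classify_tp53(e) == "none"

    def test_no_evidence_is_none(self):
        assert classify_tp53(evidence()) == "none"

    def test_loss_monotone_in_evidence(self):
        base = evidence(tp53_variants=[Tp53Variant("p.C135F", "somatic")],
                        tp53_cnv_deleted=True)
        assert classify_tp53(base) == "lost"
        more = evidence(tp53_variants=base.tp53_variants, tp53_cnv_deleted=True,
                        tp53_sv_disrupted=True)
        assert classify_tp53(more) == "lost"
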