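"""Subtyping rule engine: per-histology rules, dominance, concordance."""

import pytest

from pedcan.config import RuleConfig
from pedcan.subtyping import (
    LABELS,
    SmallVariant,
    TumorEventEvidence,
    concordance_table,
    high_conf_methyl,
    mb_consensus_group,
    run_subtyping,
    subtype_atrt,
    subtype_epn,
    subtype_hgg,
    subtype_ihg,
    subtype_mb,
    subtype_mb_shh,
    subtype_nbl,
)
from pedcan.simulate import table1_fixture
from pedcan.types import FusionCall, HistologyRecord, MethylationCall


def make_event(diagnosis="High-grade glioma", age=8.0, free_text="", cns_region="",
               **channels):
    hist = HistologyRecord(
        participant_id="PT1", biospecimen_id="BS1", tumor_event_id="EV1",
        pathology_diagnosis=diagnosis, pathology_free_text_diagnosis=free_text,
        age_at_diagnosis_years=age, cns_region=cns_region,
        experimental_strategy="WGS",
        germline_pathogenic=frozenset(channels.pop("germline", ())),
    )
    return TumorEventEvidence(histology=hist, **channels)


def methyl(subclass, score=0.9):
    return MethylationCall(classifier="dkfz_v12", subclass=subclass, score=score,
                           sample_id="BS1")


def fus(g5, g3):
    return FusionCall(gene5=g5, gene3=g3, callers=frozenset({"arriba"}),
                      sample_id="BS1")


class TestHighConfMethyl:
    def test_match_above_threshold(self, cfg):
        e = make_event(methylation=[methyl("ATRT_MYC", 0.85)])
        assert high_conf_methyl(e, lambda s: s.startswith("ATRT"), cfg) is not None

    def test_score_below_threshold_is_none(self, cfg):
        e = make_event(methylation=[methyl("ATRT_MYC", 0.79)])
        assert high_conf_methyl(e, lambda s: True, cfg) is None

    def test_nonmatching_subclass_is_none(self, cfg):
        e = make_event(methylation=[methyl("MB_WNT", 0.9)])
        assert high_conf_methyl(e, lambda s: s.startswith("ATRT"), cfg) is None


class TestHgg:
    def test_k28m_variant_calls_dmg(self, cfg):
        e = make_event(variants=[SmallVariant("H3F3A", "p.K28M", "Missense_Mutation")])
        assert subtype_hgg(e, cfg).molecular_subtype == "DMG, H3 K28"

    def test_pxa_requires_full_conjunction(self, cfg):
        full = make_event(
            free_text="pxa",
            variants=[SmallVariant("BRAF", "p.V600E", "Missense_Mutation")],
            gene_cn={"CDKN2A": "deep_deletion"},
        )
        assert subtype_hgg(full, cfg).molecular_subtype == "PXA"
        no_del = make_event(
            free_text="pxa",
            variants=[SmallVariant("BRAF", "p.V600E", "Missense_Mutation")],
            gene_cn={"CDKN2A": "neutral"},
        )
        assert subtype_hgg(no_del, cfg).molecular_subtype == "HGG, To be classified"

    def test_wildtype_methylation_token(self, cfg):
        e = make_event(methylation=[methyl("GBM_MES_TYPICAL")])
        assert subtype_hgg(e, cfg).molecular_subtype == "HGG, H3 wild-type"


class TestIhg:
    def test_alk_fusion(self, cfg):
        e = make_event(methylation=[methyl("IHG")], fusions=[fus("EML4", "ALK")])
        assert subtype_ihg(e, cfg).molecular_subtype == "IHG, ALK-altered"

    def test_no_rtk_fusion_to_be_classified(self, cfg):
        e = make_event(methylation=[methyl("IHG")])
        assert subtype_ihg(e, cfg).molecular_subtype == "IHG, To be classified"


class TestAtrt:
    def test_shh_high_conf(self, cfg):
        e = make_event(diagnosis="ATRT", methylation=[methyl("ATRT_SHH")])
        assert subtype_atrt(e, cfg).molecular_subtype == "ATRT, SHH"

    def test_low_conf_to_be_classified(self, cfg):
        e = make_event(diagnosis="ATRT", methylation=[methyl("ATRT_SHH", 0.5)])
        assert subtype_atrt(e, cfg).molecular_subtype == "ATRT, To be classified"


class TestNbl:
    def test_genomic_amplification_wins(self, cfg):
        e = make_event(diagnosis="Neuroblastoma", gene_cn={"MYCN": "amplification"})
        assert subtype_nbl(e, cfg).molecular_subtype == "NBL, MYCN amplified"

    @pytest.mark.parametrize("tpm,expected", [
        (150.0, "NBL, MYCN amplified"),
        (140.83, "NBL, MYCN amplified"),
        (140.82, "NBL, MYCN non-amplified"),
    ])
    def test_rna_only_tpm_boundary(self, cfg, tpm, expected):
        e = make_event(diagnosis="Neuroblastoma", expr_tpm={"MYCN": tpm})
        assert subtype_nbl(e, cfg).molecular_subtype == expected

    def test_conflict_without_rna_unclassified(self, cfg):
        e = make_event(diagnosis="Neuroblastoma", free_text="nbl, mycn amplified",
                       gene_cn={"MYCN": "neutral"})
        assert subtype_nbl(e, cfg).molecular_subtype == "NBL, To be classified"


class TestEpn:
    def test_zfta_fusion(self, cfg):
        e = make_event(diagnosis="Ependymoma", fusions=[fus("ZFTA", "RELA")])
        assert subtype_epn(e, cfg).molecular_subtype == "EPN, ST ZFTA"

    def test_1q_gain_tktl1_overexpression(self, cfg):
        e = make_event(diagnosis="Ependymoma", arms={"1q": "gain"},
                       expr_z={"TKTL1": 2.5})
        assert subtype_epn(e, cfg).molecular_subtype == "EPN, PF A"

    def test_rule_order_zfta_before_pfa(self, cfg):
        e = make_event(diagnosis="Ependymoma", fusions=[fus("ZFTA", "RELA")],
                       expr_z={"EZHIP": 3.0})
        assert subtype_epn(e, cfg).molecular_subtype == "EPN, ST ZFTA"

    def test_no_rule_matches(self, cfg):
        e = make_event(diagnosis="Ependymoma")
        assert subtype_epn(e, cfg).molecular_subtype == "EPN, To be classified"


class TestMbShh:
    def test_methylation_dominates_molecular_evidence(self, cfg):
        e = make_event(diagnosis="Medulloblastoma", age=12.0,
                       methylation=[methyl("MB_SHH_1")],
                       variants=[SmallVariant("DDX3X", "p.R276*", "Nonsense_Mutation")])
        # molecular evidence says delta; high-conf MB_SHH_1 forces beta
        assert subtype_mb_shh(e, cfg).molecular_subtype == "MB, SHH beta"

    def test_age_gate_blocks_alpha(self, cfg):
        e = make_event(diagnosis="Medulloblastoma", age=1.0,
                       methylation=[methyl("MB_SHH")],
                       gene_cn={"GLI2": "amplification"})
        assert subtype_mb_shh(e, cfg).molecular_subtype == "MB, SHH"

    def test_2p_only_goes_gamma_2q_goes_beta(self, cfg):
        gamma = make_event(diagnosis="Medulloblastoma", age=3.0,
                           methylation=[methyl("MB_SHH")], arms={"2p": "gain"})
        assert subtype_mb_shh(gamma, cfg).molecular_subtype == "MB, SHH gamma"
        beta = make_event(diagnosis="Medulloblastoma", age=3.0,
                          methylation=[methyl("MB_SHH")],
                          arms={"2p": "gain", "2q": "gain"})
        assert subtype_mb_shh(beta, cfg).molecular_subtype == "MB, SHH beta"

    def test_rna_classifier_fallback_when_no_methylation(self, cfg):
        e = make_event(diagnosis="Medulloblastoma", rna_mb_class="Group4")
        assert subtype_mb(e, cfg).molecular_subtype == "MB, Group4"


class TestEngineProperties:
    def test_all_emitted_labels_in_closed_vocabulary(self, noiseless_evidence, cfg):
        events, _ = noiseless_evidence
        for call in run_subtyping(events, cfg):
            assert call.molecular_subtype in LABELS

    def test_cohort_permutation_invariance(self, noiseless_evidence, cfg):
        events, _ = noiseless_evidence
        a = run_subtyping(events, cfg)
        b = run_subtyping(list(reversed(events)), cfg)
        assert a == b

    def test_methylation_high_conf_dominates_channel_removal(self, cfg):
        e = make_event(diagnosis="Ependymoma", methylation=[methyl("EPN, MPE")],
                       arms={"1q": "gain"}, expr_z={"TKTL1": 5.0})
        with_all = subtype_epn(e, cfg)
        stripped = make_event(diagnosis="Ependymoma",
                              methylation=[methyl("EPN, MPE")])
        # PF A fires first on molecular evidence, but once the non-methylation
        # channels are removed the methylation call alone still yields a label
        assert subtype_epn(stripped, cfg).molecular_subtype == "EPN, MPE"
        assert with_all.molecular_subtype in LABELS


class TestConcordance:
    def test_published_fixture_single_discordant_pair(self):
        pairs = table1_fixture()
        assert len(pairs) == 150
        table, mismatches = concordance_table(*zip(*pairs))
        assert mismatches == 1
        assert table.loc["MB_G34_VII", "Group4"] == 30
        assert table.loc["MB_WNT", "WNT"] == 18
        assert table.loc["MB_G34_III", "Group3"] == 17
        assert table.loc["MB_SHH_1", "SHH"] == 11

    def test_identical_mapped_labels_concordant(self):
        meth = ["MB_WNT", "MB_SHH_2", "MB_G34_II"]
        rna = ["WNT", "SHH", "Group3"]
        _, mismatches = concordance_table(meth, rna)
        assert mismatches == 0

    def test_marginals_conserve_input_counts(self):
        pairs = table1_fixture()
        table, _ = concordance_table(*zip(*pairs))
        assert int(table.to_numpy().sum()) == len(pairs)
        meth_counts = table.sum(axis=1)
        assert int(meth_counts["MB_G34_VIII"]) == 34

    def test_subclass_mapping(self):
        assert mb_consensus_group("MB_SHH_4") == "SHH"
        assert mb_consensus_group("MB_G34_V") == "Group4"
        assert mb_consensus_group("MB_MYO") == "MYO"
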