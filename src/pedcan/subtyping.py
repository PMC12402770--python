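"""WHO-2021-aligned molecular subtyping rule engine.

Each tumor event carries all of its molecular and clinical evidence in a
:class:`TumorEventEvidence`; histology-specific rule functions evaluate
ordered rules (first match wins) and return a :class:`SubtypeCall` whose
label is drawn from the closed vocabulary shipped in
``rules/subtyping.yaml``. Methylation-classifier calls with a score of at
least 0.8 ("high confidence") dominate molecular evidence wherever a rule
admits both.

The mapping tables (methylation subclass -> label, fusion partner -> label,
gene lists) are data, loaded from the YAML rule file, so the label strings
and correspondences are auditable and versioned without touching code; the
conjunctive logic that combines evidence channels is implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .config import RuleConfig
from .types import FusionCall, HistologyRecord, MethylationCall

logger = logging.getLogger(__name__)


def load_rules() -> dict:
    """Load the shipped subtyping rule tables."""
    text = resources.files("pedcan").joinpath("rules/subtyping.yaml").read_text()
    return yaml.safe_load(text)


_RULES = load_rules()
LABELS = set(_RULES["labels"])


@dataclass(frozen=True)
class SmallVariant:
    """A consensus small variant as seen by the subtyping rules."""

    gene: str
    hgvsp: str = ""
    classification: str = ""
    origin: str = "somatic"
    hotspot: bool = False


@dataclass
class TumorEventEvidence:
    """All evidence channels for one tumor event."""

    histology: HistologyRecord
    variants: List[SmallVariant] = field(default_factory=list)
    gene_cn: Dict[str, str] = field(default_factory=dict)
    arms: Dict[str, str] = field(default_factory=dict)
    fusions: List[FusionCall] = field(default_factory=list)
    expr_z: Dict[str, float] = field(default_factory=dict)
    expr_tpm: Dict[str, float] = field(default_factory=dict)
    methylation: List[MethylationCall] = field(default_factory=list)
    tp53_status: str = "none"
    rna_mb_class: Optional[str] = None  # WNT / SHH / Group3 / Group4
    u1_snrna_hotspot: bool = False

    @property
    def tumor_event_id(self) -> str:
        return self.histology.tumor_event_id

    # -- convenience predicates used across rule sets -----------------------
    def has_variant(self, gene: str, hgvsp: str | None = None) -> bool:
        return any(
            v.gene == gene and (hgvsp is None or v.hgvsp == hgvsp) for v in self.variants
        )

    def has_lof(self, gene: str, cfg: RuleConfig) -> bool:
        return any(
            v.gene == gene and v.classification in cfg.lof_classes for v in self.variants
        )

    def cn_status(self, gene: str) -> Optional[str]:
        return self.gene_cn.get(gene)

    def arm(self, arm: str) -> str:
        return self.arms.get(arm, "neutral")

    def overexpressed(self, gene: str, cfg: RuleConfig) -> bool:
        return self.expr_z.get(gene, 0.0) >= cfg.expr_z_high

    def fusion_partners(self) -> set:
        return {g for f in self.fusions for g in (f.gene5, f.gene3)}

    def has_fusion(self, name: str) -> bool:
        return any(f.name == name for f in self.fusions)


@dataclass(frozen=True)
class SubtypeCall:
    tumor_event_id: str
    molecular_subtype: str
    evidence_used: Tuple[str, ...] = ()
    confidence_basis: str = "molecular"  # methylation_high_conf/molecular/clinical_text/fallback

    def __post_init__(self):
        if self.molecular_subtype not in LABELS:
            raise ValueError(f"label not in rule vocabulary: {self.molecular_subtype!r}")


def high_conf_methyl(
    e: TumorEventEvidence,
    wanted: Callable[[str], bool],
    cfg: RuleConfig | None = None,
) -> Optional[MethylationCall]:
    """Best high-confidence methylation call whose subclass satisfies ``wanted``."""
    cfg = cfg or RuleConfig()
    matches = [
        m
        for m in e.methylation
        if m.score >= cfg.methyl_high_confidence and wanted(m.subclass)
    ]
    if not matches:
        return None
    # prefer the DKFZ classifier, then the higher score
    return max(matches, key=lambda m: (m.classifier == "dkfz_v12", m.score))


def _call(e, label, evidence, basis) -> SubtypeCall:
    return SubtypeCall(e.tumor_event_id, label, tuple(evidence), basis)


def _has_h3_k28(e: TumorEventEvidence) -> bool:
    return any(
        e.has_variant(g, c)
        for g in _RULES["h3_k28_genes"]
        for c in _RULES["h3_k28_changes"]
    )


# ---------------------------------------------------------------------------
# High-grade glioma (incl. DMG / PXA) and infant-type hemispheric glioma
# ---------------------------------------------------------------------------

def subtype_hgg(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    """Ordered HGG rules: DMG, IDH-mutant entities, PXA, DHG, HGG-IDH,
    H3 wild-type, then the fallback."""
    cfg = cfg or RuleConfig()
    free_text = e.histology.pathology_free_text_diagnosis.lower()

    def methyl_rule(label):
        rule = next(r for r in _RULES["hgg_methyl_rules"] if r["label"] == label)
        return high_conf_methyl(
            e,
            lambda s: s in rule.get("equals", ())
            or any(token in s for token in rule.get("contains", ())),
            cfg,
        )

    if _has_h3_k28(e):
        return _call(e, "DMG, H3 K28", ["h3_k28_variant"], "molecular")
    m = methyl_rule("DMG, H3 K28")
    if m is not None:
        return _call(e, "DMG, H3 K28", [f"methylation:{m.subclass}"], "methylation_high_conf")

    for label in ("Oligodendroglioma, IDH-mutant", "Oligosarcoma, IDH-mutant"):
        m = methyl_rule(label)
        if m is not None:
            return _call(e, label, [f"methylation:{m.subclass}"], "methylation_high_conf")

    pxa = _try_pxa(e, cfg, free_text)
    if pxa is not None:
        return pxa

    for label in ("DHG, H3 G35", "HGG, IDH", "HGG, H3 wild-type"):
        m = methyl_rule(label)
        if m is not None:
            return _call(e, label, [f"methylation:{m.subclass}"], "methylation_high_conf")

    return _call(e, "HGG, To be classified", [], "fallback")


def _try_pxa(e: TumorEventEvidence, cfg: RuleConfig, free_text: str) -> Optional[SubtypeCall]:
    """PXA requires (methylation or free text) AND BRAF V600E AND CDKN2A/B
    homozygous deletion."""
    named = high_conf_methyl(e, lambda s: s == "PXA", cfg) is not None or (
        "pleomorphic xanthoastrocytoma" in free_text or "pxa" in free_text
    )
    braf = e.has_variant("BRAF", "p.V600E")
    cdkn = e.cn_status("CDKN2A") == "deep_deletion" or e.cn_status("CDKN2B") == "deep_deletion"
    if named and braf and cdkn:
        return _call(e, "PXA", ["pxa_diagnosis", "BRAF_V600E", "CDKN2A/B_deep_deletion"],
                     "molecular")
    return None


def ihg_eligible(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> bool:
    free_text = e.histology.pathology_free_text_diagnosis.lower()
    has_methyl = any(m.subclass == "IHG" for m in e.methylation)
    return has_methyl or "infant type hemispheric glioma" in free_text


def subtype_ihg(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    cfg = cfg or RuleConfig()
    rtk_map = _RULES["ihg_rtk_map"]
    for partner in sorted(e.fusion_partners()):
        if partner in rtk_map:
            return _call(e, rtk_map[partner], [f"fusion_partner:{partner}"], "molecular")
    return _call(e, "IHG, To be classified", [], "fallback")


# ---------------------------------------------------------------------------
# ATRT, NBL, CRANIO
# ---------------------------------------------------------------------------

def subtype_atrt(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    cfg = cfg or RuleConfig()
    for subclass, label in _RULES["atrt_map"].items():
        m = high_conf_methyl(e, lambda s, sub=subclass: s == sub, cfg)
        if m is not None:
            return _call(e, label, [f"methylation:{m.subclass}"], "methylation_high_conf")
    return _call(e, "ATRT, To be classified", [], "fallback")


def subtype_nbl(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    cfg = cfg or RuleConfig()
    free_text = e.histology.pathology_free_text_diagnosis.lower()
    text_says_amplified = "mycn amplified" in free_text and "non-amplified" not in free_text
    dna_status = e.cn_status("MYCN")
    tpm = e.expr_tpm.get("MYCN")

    if dna_status == "amplification":
        return _call(e, "NBL, MYCN amplified", ["MYCN_CN_amplification"], "molecular")
    if dna_status is not None:
        # genomic non-amplified; free-text conflict routes to RNA expression
        if text_says_amplified:
            if tpm is not None:
                label = (
                    "NBL, MYCN amplified"
                    if tpm >= cfg.mycn_tpm_cutoff
                    else "NBL, MYCN non-amplified"
                )
                return _call(e, label, [f"MYCN_TPM:{tpm}"], "molecular")
            return _call(e, "NBL, To be classified", ["freetext_genomic_conflict_no_rna"],
                         "fallback")
        return _call(e, "NBL, MYCN non-amplified", ["MYCN_CN_not_amplified"], "molecular")
    if tpm is not None:
        label = (
            "NBL, MYCN amplified" if tpm >= cfg.mycn_tpm_cutoff else "NBL, MYCN non-amplified"
        )
        return _call(e, label, [f"MYCN_TPM:{tpm}"], "molecular")
    return _call(e, "NBL, To be classified", [], "fallback")


def subtype_cranio(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    cfg = cfg or RuleConfig()
    for token, label in _RULES["cranio_contains_map"].items():
        m = high_conf_methyl(e, lambda s, t=token: t in s, cfg)
        if m is not None:
            return _call(e, label, [f"methylation:{m.subclass}"], "methylation_high_conf")
    return _call(e, "CRANIO, To be classified", [], "fallback")


# ---------------------------------------------------------------------------
# Ependymoma
# ---------------------------------------------------------------------------

def subtype_epn(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    cfg = cfg or RuleConfig()
    region = e.histology.cns_region.lower()
    spinal = "spinal" in region
    posterior_fossa = "posterior fossa" in region

    def methyl(label):
        return high_conf_methyl(e, lambda s, lab=label: s == lab, cfg)

    # (1) spinal + MYCN amplification
    if (spinal and e.cn_status("MYCN") == "amplification") or methyl("EPN, SP-MYCN"):
        return _call(e, "EPN, SP-MYCN", ["spinal_MYCN"], "molecular")
    # (2) YAP1 fusions
    if any(e.has_fusion(f) for f in _RULES["epn_yap1_fusions"]) or methyl("EPN, ST YAP1"):
        return _call(e, "EPN, ST YAP1", ["YAP1_fusion"], "molecular")
    # (3) ZFTA fusions
    if any(e.has_fusion(f) for f in _RULES["epn_zfta_fusions"]) or methyl("EPN, ST ZFTA"):
        return _call(e, "EPN, ST ZFTA", ["ZFTA_fusion"], "molecular")
    # (4) PF A
    if (
        (e.arm("1q") == "gain" and e.overexpressed("TKTL1", cfg))
        or e.overexpressed("EZHIP", cfg)
        or (posterior_fossa and _has_h3_k28(e))
        or methyl("EPN, PF A")
    ):
        return _call(e, "EPN, PF A", ["pf_a_evidence"], "molecular")
    # (5) PF B
    if (
        (e.arm("6p") == "loss" or e.arm("6q") == "loss")
        and (e.overexpressed("GPBP1", cfg) or e.overexpressed("IFT46", cfg))
    ) or methyl("EPN, PF B"):
        return _call(e, "EPN, PF B", ["pf_b_evidence"], "molecular")
    # (6)-(9) direct methylation labels
    for label in ("EPN, MPE", "EPN, PF SE", "EPN, SP SE", "EPN, SP"):
        m = methyl(label)
        if m is not None:
            return _call(e, label, [f"methylation:{m.subclass}"], "methylation_high_conf")
    return _call(e, "EPN, To be classified", [], "fallback")


# ---------------------------------------------------------------------------
# Low-grade glioma (methylation mapping)
# ---------------------------------------------------------------------------

def subtype_lgg_methyl(
    e: TumorEventEvidence, cfg: RuleConfig | None = None
) -> Optional[SubtypeCall]:
    """Methylation-based LGG labels; ``None`` when no mapped subclass."""
    cfg = cfg or RuleConfig()
    lgg_map = _RULES["lgg_map"]
    m = high_conf_methyl(e, lambda s: s in lgg_map, cfg)
    if m is None:
        return None
    return _call(e, lgg_map[m.subclass], [f"methylation:{m.subclass}"], "methylation_high_conf")


# ---------------------------------------------------------------------------
# Medulloblastoma
# ---------------------------------------------------------------------------

def mb_group_label(subclass: str) -> Optional[str]:
    """Methylation subclass -> MB group label (MB_SHH_* -> 'MB, SHH')."""
    if "MB_SHH" in subclass:
        return "MB, SHH"
    return _RULES["mb_group_map"].get(subclass)


def subtype_mb(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    cfg = cfg or RuleConfig()
    for m in sorted(e.methylation, key=lambda m: -m.score):
        label = mb_group_label(m.subclass)
        if label is not None:
            if label == "MB, SHH":
                return subtype_mb_shh(e, cfg)
            return _call(e, label, [f"methylation:{m.subclass}"], "methylation_high_conf")
    if e.rna_mb_class is not None:
        label = {
            "WNT": "MB, WNT",
            "SHH": "MB, SHH",
            "Group3": "MB, Group3",
            "Group4": "MB, Group4",
        }.get(e.rna_mb_class)
        if label == "MB, SHH":
            return subtype_mb_shh(e, cfg)
        if label is not None:
            return _call(e, label, [f"rna_classifier:{e.rna_mb_class}"], "molecular")
    return _call(e, "MB, To be classified", [], "fallback")


def subtype_mb_shh(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    """Assign the SHH subgroup (alpha/beta/gamma/delta) for an MB, SHH event.

    High-confidence methylation (MB_SHH_1..4) decides when present.
    Otherwise age-gated molecular features decide; because the beta and
    gamma rules overlap on young age + 2p gain, beta requires a
    beta-specific feature (KMT2D loss of function, a PTEN lesion, or 2q
    gain), and 2p-gain-only young events go to gamma.
    """
    cfg = cfg or RuleConfig()
    shh_map = _RULES["mb_shh_map"]
    m = high_conf_methyl(e, lambda s: s in shh_map, cfg)
    if m is not None:
        return _call(e, shh_map[m.subclass], [f"methylation:{m.subclass}"],
                     "methylation_high_conf")

    age = e.histology.age_at_diagnosis_years
    germline = e.histology.germline_pathogenic

    if age is not None and age >= cfg.shh_alpha_min_age:
        alpha_features = []
        for gene in ("MYCN", "GLI2", "CCND2"):
            if e.cn_status(gene) == "amplification" or e.overexpressed(gene, cfg):
                alpha_features.append(f"{gene}_amplified_or_overexpressed")
        if germline & {"ELP1", "TP53"}:
            alpha_features.append("germline_ELP1_or_TP53")
        if any(v.gene == "TP53" and v.hotspot and v.origin == "somatic" for v in e.variants):
            alpha_features.append("TP53_somatic_hotspot")
        if e.arm("9p") == "gain":
            alpha_features.append("9p_gain")
        if e.arm("17p") == "loss":
            alpha_features.append("17p_loss")
        if alpha_features:
            return _call(e, "MB, SHH alpha", alpha_features, "molecular")

    if age is not None and age < cfg.shh_beta_gamma_max_age:
        beta_features = []
        if e.has_lof("KMT2D", cfg):
            beta_features.append("KMT2D_lof")
        if (
            e.cn_status("PTEN") in ("loss", "deep_deletion")
            or e.expr_z.get("PTEN", 0.0) < cfg.expr_z_low
        ):
            beta_features.append("PTEN_loss")
        if e.arm("2q") == "gain":
            beta_features.append("2q_gain")
        if beta_features:
            return _call(e, "MB, SHH beta", beta_features, "molecular")
        if e.arm("2p") == "gain":
            return _call(e, "MB, SHH gamma", ["2p_gain"], "molecular")

    if age is not None and age >= cfg.shh_delta_min_age:
        delta_features = []
        if e.has_lof("DDX3X", cfg) or e.has_lof("SMO", cfg):
            delta_features.append("DDX3X_or_SMO_lof")
        if any(v.gene == "TERT" and v.hotspot for v in e.variants) or e.u1_snrna_hotspot:
            delta_features.append("TERT_or_U1_hotspot")
        if e.arm("14q") == "loss":
            delta_features.append("14q_loss")
        if delta_features:
            return _call(e, "MB, SHH delta", delta_features, "molecular")

    return _call(e, "MB, SHH", [], "molecular")


# ---------------------------------------------------------------------------
# Pineoblastoma, ETMR
# ---------------------------------------------------------------------------

def subtype_pb(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    cfg = cfg or RuleConfig()
    pb_map = _RULES["pb_map"]
    m = high_conf_methyl(e, lambda s: s in pb_map, cfg)
    if m is not None:
        return _call(e, pb_map[m.subclass], [f"methylation:{m.subclass}"],
                     "methylation_high_conf")
    return _call(e, "PB, To be classified", [], "fallback")


def subtype_etmr(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> SubtypeCall:
    cfg = cfg or RuleConfig()
    ttyh1 = any("TTYH1" in (f.gene5, f.gene3) for f in e.fusions)
    chr19_amp = e.arm("19p") == "gain" or e.arm("19q") == "gain" or any(
        e.cn_status(g) == "amplification" for g in ("MIR371", "C19MC")
    )
    lin28a = e.overexpressed("LIN28A", cfg)
    m = high_conf_methyl(e, lambda s: s == "ETMR_C19MC", cfg)
    if m is not None or (ttyh1 and (chr19_amp or lin28a)):
        basis = "methylation_high_conf" if m is not None else "molecular"
        return _call(e, "ETMR, C19MC-altered", ["c19mc_evidence"], basis)
    if lin28a and not ttyh1:
        return _call(e, "ETMR, NOS", ["LIN28A_overexpressed"], "molecular")
    return _call(e, "ETMR, To be classified", [], "fallback")


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

_DISPATCH: Sequence[Tuple[Tuple[str, ...], Callable]] = (
    (("medulloblastoma",), subtype_mb),
    (("atypical teratoid", "atrt"), subtype_atrt),
    (("neuroblastoma", "ganglioneuroblastoma", "ganglioneuroma"), subtype_nbl),
    (("craniopharyngioma",), subtype_cranio),
    (("ependymoma",), subtype_epn),
    (("pineoblastoma",), subtype_pb),
    (("embryonal tumor", "etmr"), subtype_etmr),
    (("low-grade glioma", "pilocytic astrocytoma", "low grade glioma"), None),  # LGG
    (("high-grade glioma", "high grade glioma", "glioblastoma", "diffuse midline glioma"),
     None),  # HGG/IHG
)


def route_event(e: TumorEventEvidence, cfg: RuleConfig | None = None) -> Optional[SubtypeCall]:
    """Dispatch one event to its histology rule set; None when unmatched."""
    cfg = cfg or RuleConfig()
    diagnosis = e.histology.pathology_diagnosis.lower()
    for tokens, handler in _DISPATCH:
        if any(t in diagnosis for t in tokens):
            if handler is not None:
                return handler(e, cfg)
            if tokens[0].startswith("low"):
                call = subtype_lgg_methyl(e, cfg)
                return call or _call(e, "LGG, To be classified", [], "fallback")
            if ihg_eligible(e, cfg):
                return subtype_ihg(e, cfg)
            return subtype_hgg(e, cfg)
    return None


def run_subtyping(
    cohort: Sequence[TumorEventEvidence], cfg: RuleConfig | None = None
) -> List[SubtypeCall]:
    """Subtype every event in the cohort; unmatched histologies emit no call."""
    cfg = cfg or RuleConfig()
    calls = []
    for e in sorted(cohort, key=lambda e: e.tumor_event_id):
        call = route_event(e, cfg)
        if call is not None:
            calls.append(call)
        else:
            logger.info("no subtyping rule set for diagnosis %r (event %s)",
                        e.histology.pathology_diagnosis, e.tumor_event_id)
    return calls


# ---------------------------------------------------------------------------
# Methylation-vs-RNA concordance (medulloblastoma)
# ---------------------------------------------------------------------------

def mb_consensus_group(subclass: str) -> Optional[str]:
    """Methylation subclass -> consensus group (WNT/SHH/Group3/Group4/MYO)."""
    if subclass.startswith("MB_SHH"):
        return "SHH"
    return _RULES["mb_concordance_map"].get(subclass)


def concordance_table(
    meth_labels: Sequence[str], rna_labels: Sequence[str]
) -> Tuple[pd.DataFrame, int]:
    """Cross-tabulate methylation subclass x RNA group; count discordant pairs.

    A pair is discordant when the methylation subclass's mapped consensus
    group differs from the RNA group.
    """
    if len(meth_labels) != len(rna_labels):
        raise ValueError("paired label lists must have equal length")
    table = pd.crosstab(
        pd.Series(meth_labels, name="methylation"), pd.Series(rna_labels, name="rna")
    )
    mismatches = sum(
        1 for m, r in zip(meth_labels, rna_labels) if mb_consensus_group(m) != r
    )
    return table, mismatches
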