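"""Fusion prioritization: annotate putative oncogenic fusions and retain calls.

A fusion is putatively oncogenic when either partner is a known kinase,
oncogene, tumor suppressor, curated transcription factor, on the COSMIC
Cancer Gene Census list, or observed in TCGA. A call is retained when it was
made by both RNA callers, is recurrent within a cancer group, is specific to
exactly one cancer group, or is putatively oncogenic. Targeted-panel (DGD)
fusions bypass filtering and are released as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

from .config import RuleConfig
from .types import RNA_FUSION_CALLERS, FusionCall

ONCOGENIC_LISTS = ("kinase", "oncogene", "tsg", "tf", "cosmic_cgc", "tcga_observed")


@dataclass(frozen=True)
class PrioritizedFusion:
    fusion: FusionCall
    putative_oncogenic: bool
    retained_reason: FrozenSet[str]

    def __post_init__(self):
        if not self.retained_reason:
            raise ValueError("retained fusions must have a nonempty retained_reason")


def annotate_oncogenic(f: FusionCall, gene_lists: Mapping[str, Set[str]]) -> bool:
    """True iff either partner appears in any curated cancer-gene list."""
    return any(
        f.gene5 in genes or f.gene3 in genes
        for name, genes in gene_lists.items()
    )


def cohort_fusion_counts(
    fusions: Iterable[FusionCall],
    sample_to_patient: Mapping[str, str] | None = None,
) -> Dict[Tuple[str, str], int]:
    """Independent-patient counts per (fusion name, cancer group)."""
    patients: Dict[Tuple[str, str], Set[str]] = {}
    for f in fusions:
        patient = (sample_to_patient or {}).get(f.sample_id, f.sample_id)
        patients.setdefault((f.name, f.cancer_group), set()).add(patient)
    return {k: len(v) for k, v in patients.items()}


def retain_fusions(
    fusions: List[FusionCall],
    cohort_counts: Mapping[Tuple[str, str], int],
    gene_lists: Mapping[str, Set[str]],
    cfg: RuleConfig | None = None,
) -> List[PrioritizedFusion]:
    """Apply the four retention rules; dropped fusions are absent from output."""
    cfg = cfg or RuleConfig()
    groups_by_fusion: Dict[str, Set[str]] = {}
    for (name, group), n in cohort_counts.items():
        if n > 0:
            groups_by_fusion.setdefault(name, set()).add(group)
    for f in fusions:
        groups_by_fusion.setdefault(f.name, set()).add(f.cancer_group)

    out: List[PrioritizedFusion] = []
    for f in fusions:
        if "dgd_panel" in f.callers:
            # panel fusions are clinical calls released untouched
            out.append(
                PrioritizedFusion(
                    fusion=f,
                    putative_oncogenic=annotate_oncogenic(f, gene_lists),
                    retained_reason=frozenset({"panel_passthrough"}),
                )
            )
            continue
        reasons = set()
        if set(RNA_FUSION_CALLERS) <= f.callers:
            reasons.add("both_callers")
        if cohort_counts.get((f.name, f.cancer_group), 0) >= cfg.fusion_recurrent_min_patients:
            reasons.add("recurrent")
        if len(groups_by_fusion.get(f.name, set())) == 1:
            reasons.add("cancer_group_specific")
        oncogenic = annotate_oncogenic(f, gene_lists)
        if oncogenic:
            reasons.add("oncogenic")
        if reasons:
            out.append(
                PrioritizedFusion(
                    fusion=f, putative_oncogenic=oncogenic, retained_reason=frozenset(reasons)
                )
            )
    return out
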