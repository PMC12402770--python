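"""Pipeline configuration: every numeric threshold and label list in one place.

All rule constants used across the consensus callers, TMB, TP53 annotation
and the subtyping engine live on :class:`RuleConfig` so that a single,
versionable object documents the pipeline's behaviour. Defaults follow the
OpenPedCan conventions; any field may be overridden per run or loaded from
YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

# Consequence classes counted as nonsynonymous for TMB (high/moderate impact).
NONSYN_CLASSES: tuple[str, ...] = (
    "Missense_Mutation",
    "Frame_Shift_Del",
    "In_Frame_Ins",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Nonsense_Mutation",
    "In_Frame_Del",
    "Nonstop_Mutation",
    "Translation_Start_Site",
)

# Friends-of-Cancer-Research TMB harmonization variant and classes (optional
# alternate numerator filter; adds silent-adjacent coding classes).
NONSYN_CLASSES_FOCR: tuple[str, ...] = NONSYN_CLASSES + (
    "Start_Codon_Ins",
    "Start_Codon_Del",
    "Stop_Codon_Ins",
    "Stop_Codon_Del",
)

# Variant classes treated as loss-of-function evidence by the subtyping rules.
LOF_CLASSES: tuple[str, ...] = (
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Translation_Start_Site",
)


@dataclass
class RuleConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    Attributes
    ----------
    min_callers_consensus : int
        Minimum number of SNV callers that must report a variant for it
        to enter the consensus without a hotspot rescue.
    germline_max_n_depth : int
        Normal depth at or below which a non-hotspot variant with elevated
        population frequency is considered a likely germline leak.
    germline_min_gnomad_af : float
        gnomAD allele frequency strictly above which the germline filter
        applies (conjunction with the depth condition).
    tumor_only_min_t_depth : int
        Tumor-only calls with total depth below this are removed.
    cnv_denoise_max : int
        A per-sample, per-caller segment file with more than this many
        CNVs is dropped entirely (noise heuristic).
    cnv_reciprocal_min, cnv_containment_min : float
        Reciprocal-overlap and one-way coverage fractions for CNV consensus.
    cnv_merge_gap_bp : int
        Same-direction consensus regions within this gap are merged.
    cnv_min_len_bp : int
        Consensus regions shorter than this are filtered out.
    cnv_blacklist_overlap : float
        Regions with at least this fraction of their length in blacklist
        intervals are filtered out.
    ploidy : int
        Assumed baseline copy number for mapping integer CN to status labels.
    amplification_gain_over_ploidy : int
        CN >= ploidy + this is labelled amplification.
    methyl_high_confidence : float
        Classifier score at or above which a methylation subclass call is
        treated as high confidence by the subtyping rules.
    mycn_tpm_cutoff : float
        MYCN TPM cutoff for RNA-based neuroblastoma MYCN-amplification calls.
    tp53_classifier_cutoff : float
        RNA inactivation-classifier score strictly above which germline-LFS
        evidence counts toward TP53 lost status.
    expr_z_high, expr_z_low : float
        Cohort z-score cutoffs defining over-/under-expression.
    shh_alpha_min_age, shh_beta_gamma_max_age, shh_delta_min_age : float
        Age gates (years) of the medulloblastoma SHH subgroup rules.
    arm_coverage_min : float
        Fraction of a chromosome arm that same-direction regions must cover
        for an arm-level gain/loss call.
    fusion_recurrent_min_patients : int
        Patients within one cancer group needed to call a fusion recurrent.
    tmb_scale : float
        Multiplier converting mutations/bp to the reported burden unit
        (1e6 -> mutations per megabase).
    """

    min_callers_consensus: int = 2
    germline_max_n_depth: int = 7
    germline_min_gnomad_af: float = 0.001
    tumor_only_min_t_depth: int = 4
    cnv_denoise_max: int = 2500
    cnv_reciprocal_min: float = 0.50
    cnv_containment_min: float = 0.90
    cnv_merge_gap_bp: int = 10_000
    cnv_min_len_bp: int = 3_000
    cnv_blacklist_overlap: float = 0.50
    ploidy: int = 2
    amplification_gain_over_ploidy: int = 3
    methyl_high_confidence: float = 0.8
    mycn_tpm_cutoff: float = 140.83
    tp53_classifier_cutoff: float = 0.5
    expr_z_high: float = 2.0
    expr_z_low: float = -2.0
    shh_alpha_min_age: float = 2.0
    shh_beta_gamma_max_age: float = 5.0
    shh_delta_min_age: float = 10.0
    arm_coverage_min: float = 0.5
    fusion_recurrent_min_patients: int = 3
    tmb_scale: float = 1e6
    nonsyn_classes: Sequence[str] = NONSYN_CLASSES
    nonsynfilter_focr: Sequence[str] = NONSYN_CLASSES_FOCR
    lof_classes: Sequence[str] = LOF_CLASSES

    def __post_init__(self) -> None:
        for name in (
            "min_callers_consensus",
            "tumor_only_min_t_depth",
            "cnv_denoise_max",
            "cnv_merge_gap_bp",
            "cnv_min_len_bp",
            "tmb_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"RuleConfig.{name} must be positive")
        if not self.nonsyn_classes:
            raise ValueError("nonsyn_classes must be nonempty")

    def cn_to_status(self, copy_number: int | None) -> str:
        """Map an integer copy number to a status label under the ploidy model.

        CN 0 -> deep_deletion, CN < ploidy -> loss, CN == ploidy -> neutral,
        ploidy < CN < ploidy + amplification_gain_over_ploidy -> gain,
        larger -> amplification. ``None`` maps to neutral.
        """
        if copy_number is None:
            return "neutral"
        if copy_number == 0:
            return "deep_deletion"
        if copy_number < self.ploidy:
            return "loss"
        if copy_number == self.ploidy:
            return "neutral"
        if copy_number >= self.ploidy + self.amplification_gain_over_ploidy:
            return "amplification"
        return "gain"

    @classmethod
    def from_yaml(cls, path) -> "RuleConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
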