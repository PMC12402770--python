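"""Domain types shared across the pipeline stages.

Coordinate conventions: :class:`VariantCall` and :class:`CnvSegment` use
1-based inclusive positions (MAF/SEG convention); interval sets
(:class:`~pedcan.intervals.GenomeIntervals`) use 0-based half-open (BED).
Conversion happens only where a record is tested against an interval set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, List, Optional, Tuple

from .intervals import normalize_chrom

SNV_CALLERS = ("strelka2", "mutect2", "lancet", "vardict")
CNV_CALLERS = ("controlfreec", "cnvkit", "gatk", "mantasv")
RNA_FUSION_CALLERS = ("arriba", "starfusion")

VariantKey = Tuple[str, str, int, str, str]  # sample, chrom, pos, ref, alt


@dataclass(frozen=True)
class VariantCall:
    """One somatic small-variant record from one caller (MAF semantics)."""

    caller: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    t_depth: Optional[int] = None
    t_alt_count: Optional[int] = None
    n_depth: Optional[int] = None
    gnomad_af: Optional[float] = None
    hotspot: bool = False
    variant_classification: str = ""
    hugo_symbol: str = ""
    hgvsp_short: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be nonempty")
        if (
            self.t_depth is not None
            and self.t_alt_count is not None
            and not (self.t_depth >= self.t_alt_count >= 0)
        ):
            raise ValueError(
                f"require t_depth >= t_alt_count >= 0, got {self.t_depth}/{self.t_alt_count}"
            )
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"gnomad_af outside [0,1]: {self.gnomad_af}")

    @property
    def key(self) -> VariantKey:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_mnp(self) -> bool:
        return len(self.ref) == len(self.alt) > 1

    @property
    def end(self) -> int:
        """Last reference base covered (1-based inclusive)."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class ConsensusVariant:
    """A consensus variant with caller provenance."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    caller_support: FrozenSet[str]
    hotspot: bool = False
    hotspot_rescued: bool = False
    mnp_reconstructed: bool = False
    t_depth: Optional[int] = None
    t_alt_count: Optional[int] = None
    n_depth: Optional[int] = None
    gnomad_af: Optional[float] = None
    variant_classification: str = ""
    hugo_symbol: str = ""
    hgvsp_short: str = ""

    @property
    def key(self) -> VariantKey:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConsensusMaf:
    """Consensus small-variant set: every record has >=2 supporters or is a hotspot."""

    records: List[ConsensusVariant] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (sample, chrom, pos, ref, alt) in consensus")

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def restrict_to_sample(self, sample_id: str) -> "ConsensusMaf":
        return ConsensusMaf([r for r in self.records if r.sample_id == sample_id])


@dataclass(frozen=True)
class CnvSegment:
    """One raw copy-number segment from one caller (1-based inclusive)."""

    caller: str
    chrom: str
    start: int
    end: int
    sample_id: str
    copy_number: Optional[int] = None
    status: Optional[str] = None  # gain/loss/neutral/amplification/deep_deletion

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def direction(self) -> Optional[str]:
        """gain / loss / None(neutral) collapsed from the status label."""
        if self.status in ("gain", "amplification"):
            return "gain"
        if self.status in ("loss", "deep_deletion"):
            return "loss"
        return None


@dataclass(frozen=True)
class ConsensusCnvRegion:
    """A consensus copy-number region (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    direction: str  # gain or loss, never neutral
    supporting_callers: FrozenSet[str]
    sample_id: str
    copy_number: Optional[int] = None
    from_containment: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("region end < start")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain or loss, got {self.direction!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FusionCall:
    """An RNA fusion call with caller provenance and oncogenic annotations."""

    gene5: str
    gene3: str
    callers: FrozenSet[str]
    sample_id: str
    cancer_group: str = ""
    annotations: FrozenSet[str] = frozenset()

    def __post_init__(self):
        if not self.callers:
            raise ValueError("fusion must have at least one caller")
        if not self.gene5 or not self.gene3:
            raise ValueError("fusion partners must be nonempty")

    @property
    def name(self) -> str:
        return f"{self.gene5}::{self.gene3}"


@dataclass(frozen=True)
class MethylationCall:
    """A methylation-classifier output (subclass label + confidence score)."""

    classifier: str  # dkfz_v12 or nih_v2
    subclass: str
    score: float
    sample_id: str
    mgmt_status: Optional[str] = None
    mgmt_estimated: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"methylation score outside [0,1]: {self.score}")


@dataclass(frozen=True)
class HistologyRecord:
    """Harmonized clinical metadata for one biospecimen (Kids First model)."""

    participant_id: str
    biospecimen_id: str
    tumor_event_id: str
    pathology_diagnosis: str = ""
    pathology_free_text_diagnosis: str = ""
    age_at_diagnosis_years: Optional[float] = None
    tumor_descriptor: str = ""
    cns_region: str = ""
    experimental_strategy: str = ""
    composition: str = ""
    germline_pathogenic: FrozenSet[str] = frozenset()

    def __post_init__(self):
        if not self.participant_id or not self.biospecimen_id:
            raise ValueError("participant_id and biospecimen_id must be nonempty")
        if self.age_at_diagnosis_years is not None and self.age_at_diagnosis_years < 0:
            raise ValueError("age_at_diagnosis_years must be >= 0")


@dataclass(frozen=True)
class GeneCnStatus:
    """Resolved per-gene copy-number status for one sample."""

    gene: str
    sample_id: str
    status: str
    overlap_fraction: float = 0.0
    dominant_segment: Optional[Tuple[str, int, int]] = None


@dataclass(frozen=True)
class ArmStatus:
    """Chromosome-arm-level gain/loss call for one sample."""

    sample_id: str
    arm: str
    status: str  # gain / loss / neutral
    covered_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.covered_fraction <= 1.0):
            raise ValueError("covered_fraction outside [0,1]")
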