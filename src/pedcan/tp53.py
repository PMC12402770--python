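"""TP53 status annotation: activated, lost, or neither.

A tumor is TP53 *activated* when it carries either of the two known
gain-of-function substitutions p.R273C or p.R248W. Otherwise it is TP53
*lost* under any of: (i) a hotspot TP53 mutation from the IARC/MSKCC
databases; (ii) two distinct TP53 alterations among SNV, CNV deletion and
SV disruption (consistent with biallelic inactivation); (iii) a single
somatic variant together with a Li-Fraumeni-associated pathogenic germline
variant; (iv) an LFS germline variant together with an RNA inactivation
classifier score strictly above 0.5. The activation check runs first; a
sample meeting both is labelled activated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .config import RuleConfig

GAIN_OF_FUNCTION = ("p.R273C", "p.R248W")


@dataclass(frozen=True)
class Tp53Variant:
    hgvsp: str
    origin: str  # somatic or germline
    hotspot_db_member: bool = False
    lfs_associated: bool = False


@dataclass
class Tp53Evidence:
    sample_id: str
    tp53_variants: List[Tp53Variant] = field(default_factory=list)
    tp53_cnv_deleted: bool = False
    tp53_sv_disrupted: bool = False
    classifier_score: Optional[float] = None

    def __post_init__(self):
        if self.classifier_score is not None and not (0.0 <= self.classifier_score <= 1.0):
            raise ValueError("classifier_score outside [0,1]")


def classify_tp53(e: Tp53Evidence, cfg: RuleConfig | None = None) -> str:
    """Return 'activated', 'lost' or 'none' for one tumor event."""
    cfg = cfg or RuleConfig()
    somatic = [v for v in e.tp53_variants if v.origin == "somatic"]
    germline_lfs = [
        v for v in e.tp53_variants if v.origin == "germline" and v.lfs_associated
    ]

    if any(v.hgvsp in GAIN_OF_FUNCTION for v in somatic):
        return "activated"

    # (i) hotspot-database mutation
    if any(v.hotspot_db_member for v in e.tp53_variants):
        return "lost"

    # (ii) two distinct alterations across SNV / CNV / SV channels; two SNVs
    # with different protein changes also count as two distinct alterations
    n_alterations = (
        len({v.hgvsp for v in somatic})
        + int(e.tp53_cnv_deleted)
        + int(e.tp53_sv_disrupted)
    )
    if n_alterations >= 2:
        return "lost"

    # (iii) single somatic variant plus an LFS-associated germline variant
    if somatic and germline_lfs:
        return "lost"

    # (iv) LFS germline variant with inactivation classifier score > 0.5
    if germline_lfs and e.classifier_score is not None:
        if e.classifier_score > cfg.tp53_classifier_cutoff:
            return "lost"

    return "none"
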