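"""Synthetic-cohort generator with planted ground truth.

Emits a complete miniature cohort — per-caller MAFs, per-caller SEG files,
fusion and methylation tables, a TPM matrix, a clinical histologies table —
plus a YAML manifest of the planted truth (true variants, true copy-number
regions, expected TMB, expected molecular subtype per event), so that every
pipeline stage is exercisable end to end without any data download.

The genome is a toy reference: one short contig per chromosome the
subtyping rules reference, with miniature gene, CDS, arm and blacklist
models, plus a sandbox contig (``chrS``) that carries the randomly placed
variants and copy-number segments used for consensus-calling and TMB
experiments. Subtyping evidence is planted noiselessly (all callers agree);
the sandbox channels honour the cohort's caller-agreement probability and
breakpoint jitter so consensus behaviour under noise is measurable against
the manifest truth.

The generator's defaults are the study conditions the rest of the package
is tested under; they are not tuned per test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .config import RuleConfig
from .intervals import GenomeIntervals
from .types import (
    CnvSegment,
    FusionCall,
    HistologyRecord,
    MethylationCall,
    VariantCall,
)

# ---------------------------------------------------------------------------
# Toy reference
# ---------------------------------------------------------------------------

ARM_LEN = 100_000  # every toy chromosome is two 100-kb arms

TOY_CONTIGS: Dict[str, int] = {
    c: 2 * ARM_LEN
    for c in (
        "chr1", "chr2", "chr5", "chr6", "chr7", "chr9", "chr10", "chr12",
        "chr14", "chr17", "chr19", "chrX", "chrS",
    )
}

# gene -> (chrom, start, end), 1-based inclusive; spans are miniature and the
# placement is synthetic (arm membership matters, real coordinates do not)
TOY_GENES: Dict[str, Tuple[str, int, int]] = {
    "MYCN": ("chr2", 20_001, 25_000),
    "GLI2": ("chr2", 150_001, 155_000),
    "CCND2": ("chr12", 20_001, 25_000),
    "PTEN": ("chr10", 120_001, 125_000),
    "KMT2D": ("chr12", 150_001, 155_000),
    "DDX3X": ("chrX", 20_001, 25_000),
    "SMO": ("chr7", 150_001, 155_000),
    "TERT": ("chr5", 20_001, 25_000),
    "TP53": ("chr17", 20_001, 25_000),
    "ELP1": ("chr9", 150_001, 155_000),
    "BRAF": ("chr7", 20_001, 25_000),
    "CDKN2A": ("chr9", 20_001, 25_000),
    "CDKN2B": ("chr9", 30_001, 35_000),
    "H3F3A": ("chr1", 150_001, 155_000),
    "HIST1H3B": ("chr6", 20_001, 25_000),
    "TKTL1": ("chrX", 150_001, 155_000),
    "EZHIP": ("chrX", 60_001, 65_000),
    "GPBP1": ("chr5", 150_001, 155_000),
    "IFT46": ("chr14", 20_001, 25_000),
    "LIN28A": ("chr1", 20_001, 25_000),
    "TTYH1": ("chr19", 150_001, 155_000),
}

SANDBOX_CHROM = "chrS"
# surveyed-region files per SNV caller on the sandbox contig (0-based half-open)
SANDBOX_SURVEYED: Dict[str, Tuple[int, int]] = {
    "strelka2": (0, 190_000),
    "mutect2": (5_000, 200_000),
    "vardict": (2_000, 195_000),
}
SANDBOX_CDS: Tuple[int, int] = (10_000, 110_000)  # 100 kb of coding sequence


def toy_gene_models() -> Dict[str, Tuple[str, int, int]]:
    return dict(TOY_GENES)


def toy_arm_models() -> Dict[str, Tuple[str, int, int]]:
    arms = {}
    for chrom in TOY_CONTIGS:
        if chrom == SANDBOX_CHROM:
            continue
        name = chrom[3:]
        arms[f"{name}p"] = (chrom, 1, ARM_LEN)
        arms[f"{name}q"] = (chrom, ARM_LEN + 1, 2 * ARM_LEN)
    return arms


def toy_surveyed(caller: str) -> GenomeIntervals:
    start, end = SANDBOX_SURVEYED[caller]
    return GenomeIntervals([(SANDBOX_CHROM, start, end)], name=f"surveyed_{caller}")


def toy_cds() -> GenomeIntervals:
    intervals = [(SANDBOX_CHROM, SANDBOX_CDS[0], SANDBOX_CDS[1])]
    intervals += [(c, s - 1, e) for c, s, e in TOY_GENES.values()]
    return GenomeIntervals(intervals, name="CDS")


def toy_blacklist() -> GenomeIntervals:
    # telomere-like margins of the sandbox contig
    return GenomeIntervals(
        [(SANDBOX_CHROM, 195_000, 200_000), (SANDBOX_CHROM, 0, 1_000)], name="blacklist"
    )


# ---------------------------------------------------------------------------
# Subtyping scenario catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One planted subtyping case: clinical context + evidence + expected label."""

    id: str
    group: str
    diagnosis: str
    expected: str
    free_text: str = ""
    age: Optional[float] = 8.0
    cns_region: str = ""
    has_dna: bool = True
    has_rna: bool = True
    variants: Tuple[Tuple[str, str, str, bool], ...] = ()  # gene, hgvsp, class, hotspot
    germline: Tuple[str, ...] = ()
    gene_cnv: Tuple[Tuple[str, int], ...] = ()  # gene symbol, copy number
    arm_cnv: Tuple[Tuple[str, int], ...] = ()  # arm label, copy number
    fusions: Tuple[str, ...] = ()  # "GENE5::GENE3"
    overexpress: Tuple[str, ...] = ()
    underexpress: Tuple[str, ...] = ()
    tpm_override: Tuple[Tuple[str, float], ...] = ()
    methylation: Tuple[Tuple[str, float], ...] = ()  # subclass, score
    rna_mb_class: Optional[str] = None
    u1_hotspot: bool = False


_MIS = "Missense_Mutation"
_NON = "Nonsense_Mutation"


def subtyping_scenarios() -> List[Scenario]:
    """Every rule branch of the subtyping engine, one planted case each,
    including a dedicated negative case per "To be classified" fallback."""
    s: List[Scenario] = []
    add = s.append

    hgg = dict(group="HGG", diagnosis="High-grade glioma/astrocytoma")
    add(Scenario("hgg_dmg_k28m", expected="DMG, H3 K28",
                 variants=(("H3F3A", "p.K28M", _MIS, False),), **hgg))
    add(Scenario("hgg_dmg_k28i", expected="DMG, H3 K28",
                 variants=(("HIST1H3B", "p.K28I", _MIS, False),), **hgg))
    add(Scenario("hgg_dmg_methyl", expected="DMG, H3 K28",
                 methylation=(("DMG_K27", 0.92),), **hgg))
    add(Scenario("hgg_oligo_idh", expected="Oligodendroglioma, IDH-mutant",
                 methylation=(("O_IDH", 0.9),), **hgg))
    add(Scenario("hgg_oligosarc", expected="Oligosarcoma, IDH-mutant",
                 methylation=(("OLIGOSARC_IDH", 0.9),), **hgg))
    add(Scenario("hgg_pxa", expected="PXA", free_text="consistent with pxa",
                 variants=(("BRAF", "p.V600E", _MIS, False),),
                 gene_cnv=(("CDKN2A", 0),), **hgg))
    add(Scenario("hgg_pxa_negative", expected="HGG, To be classified",
                 free_text="consistent with pxa",
                 variants=(("BRAF", "p.V600E", _MIS, False),), **hgg))
    add(Scenario("hgg_dhg_g35", expected="DHG, H3 G35",
                 methylation=(("DHG_G34", 0.9),), **hgg))
    add(Scenario("hgg_idh", expected="HGG, IDH",
                 methylation=(("GBM_IDH", 0.9),), **hgg))
    add(Scenario("hgg_wildtype", expected="HGG, H3 wild-type",
                 methylation=(("GBM_RTK_II", 0.9),), **hgg))
    add(Scenario("hgg_tbc", expected="HGG, To be classified", **hgg))
    add(Scenario("ihg_alk", expected="IHG, ALK-altered",
                 methylation=(("IHG", 0.9),), fusions=("EML4::ALK",), **hgg))
    add(Scenario("ihg_ntrk", expected="IHG, NTRK-altered",
                 free_text="infant type hemispheric glioma",
                 fusions=("ETV6::NTRK3",), **hgg))
    add(Scenario("ihg_ros1", expected="IHG, ROS1-altered",
                 methylation=(("IHG", 0.9),), fusions=("GOPC::ROS1",), **hgg))
    add(Scenario("ihg_met", expected="IHG, MET-altered",
                 methylation=(("IHG", 0.9),), fusions=("CAPZA2::MET",), **hgg))
    add(Scenario("ihg_tbc", expected="IHG, To be classified",
                 methylation=(("IHG", 0.9),), **hgg))

    atrt = dict(group="ATRT", diagnosis="Atypical Teratoid Rhabdoid Tumor (ATRT)")
    add(Scenario("atrt_myc", expected="ATRT, MYC", methylation=(("ATRT_MYC", 0.85),), **atrt))
    add(Scenario("atrt_shh", expected="ATRT, SHH", methylation=(("ATRT_SHH", 0.9),), **atrt))
    add(Scenario("atrt_tyr", expected="ATRT, TYR", methylation=(("ATRT_TYR", 0.95),), **atrt))
    add(Scenario("atrt_tbc", expected="ATRT, To be classified",
                 methylation=(("ATRT_SHH", 0.5),), **atrt))

    nbl = dict(group="NBL", diagnosis="Neuroblastoma")
    add(Scenario("nbl_amp", expected="NBL, MYCN amplified", gene_cnv=(("MYCN", 8),), **nbl))
    add(Scenario("nbl_nonamp", expected="NBL, MYCN non-amplified", **nbl))
    add(Scenario("nbl_conflict_rna_high", expected="NBL, MYCN amplified",
                 free_text="nbl, mycn amplified", tpm_override=(("MYCN", 150.0),), **nbl))
    add(Scenario("nbl_conflict_rna_low", expected="NBL, MYCN non-amplified",
                 free_text="nbl, mycn amplified", tpm_override=(("MYCN", 140.82),), **nbl))
    add(Scenario("nbl_rna_only_high", expected="NBL, MYCN amplified",
                 has_dna=False, tpm_override=(("MYCN", 140.83),), **nbl))
    add(Scenario("nbl_rna_only_low", expected="NBL, MYCN non-amplified",
                 has_dna=False, tpm_override=(("MYCN", 90.0),), **nbl))
    add(Scenario("nbl_tbc", expected="NBL, To be classified",
                 has_dna=False, has_rna=False, **nbl))

    cranio = dict(group="CRANIO", diagnosis="Craniopharyngioma")
    add(Scenario("cranio_pap", expected="CRANIO, PAP",
                 methylation=(("CPH_PAP", 0.95),), **cranio))
    add(Scenario("cranio_adam", expected="CRANIO, ADAM",
                 methylation=(("CPH_ADM", 0.95),), **cranio))
    add(Scenario("cranio_tbc", expected="CRANIO, To be classified",
                 methylation=(("CPH_PAP", 0.6),), **cranio))

    epn = dict(group="EPN", diagnosis="Ependymoma")
    add(Scenario("epn_spmycn", expected="EPN, SP-MYCN", cns_region="Spinal",
                 gene_cnv=(("MYCN", 8),), **epn))
    add(Scenario("epn_styap1", expected="EPN, ST YAP1", fusions=("YAP1::MAMLD1",), **epn))
    add(Scenario("epn_stzfta", expected="EPN, ST ZFTA", fusions=("ZFTA::RELA",), **epn))
    add(Scenario("epn_pfa_1q", expected="EPN, PF A",
                 arm_cnv=(("1q", 3),), overexpress=("TKTL1",), **epn))
    add(Scenario("epn_pfa_ezhip", expected="EPN, PF A", overexpress=("EZHIP",), **epn))
    add(Scenario("epn_pfa_h3", expected="EPN, PF A", cns_region="Posterior fossa",
                 variants=(("H3F3A", "p.K28M", _MIS, False),), **epn))
    add(Scenario("epn_pfa_methyl", expected="EPN, PF A",
                 methylation=(("EPN, PF A", 0.9),), **epn))
    add(Scenario("epn_pfb", expected="EPN, PF B",
                 arm_cnv=(("6q", 1),), overexpress=("GPBP1",), **epn))
    add(Scenario("epn_mpe", expected="EPN, MPE", methylation=(("EPN, MPE", 0.9),), **epn))
    add(Scenario("epn_pfse", expected="EPN, PF SE",
                 methylation=(("EPN, PF SE", 0.9),), **epn))
    add(Scenario("epn_spse", expected="EPN, SP SE",
                 methylation=(("EPN, SP SE", 0.9),), **epn))
    add(Scenario("epn_sp", expected="EPN, SP", methylation=(("EPN, SP", 0.9),), **epn))
    add(Scenario("epn_tbc", expected="EPN, To be classified", **epn))

    lgg = dict(group="LGG", diagnosis="Low-grade glioma/astrocytoma")
    add(Scenario("lgg_plnty", expected="LGG, other MAPK-altered",
                 methylation=(("PLNTY", 0.9),), **lgg))
    add(Scenario("lgg_pamid", expected="LGG, other MAPK-altered",
                 methylation=(("PA_MID", 0.9),), **lgg))
    add(Scenario("lgg_fgfr", expected="LGG, FGFR-altered",
                 methylation=(("PA_INF_FGFR", 0.9),), **lgg))
    add(Scenario("lgg_idh", expected="LGG, IDH-altered",
                 methylation=(("A_IDH_LG", 0.9),), **lgg))
    add(Scenario("lgg_myb", expected="LGG, MYB/MYBL1 fusion",
                 methylation=(("LGG_MYB", 0.9),), **lgg))
    add(Scenario("lgg_mapk", expected="LGG, MAPK-altered",
                 methylation=(("LGG, MAPK", 0.9),), **lgg))
    add(Scenario("lgg_braf_mapk", expected="LGG, BRAF- and MAPK-altered",
                 methylation=(("LGG, BRAF/MAPK", 0.9),), **lgg))
    add(Scenario("lgg_sega", expected="SEGA, To be classified",
                 methylation=(("SEGA, To be classified", 0.9),), **lgg))
    add(Scenario("lgg_tbc", expected="LGG, To be classified",
                 methylation=(("PA_CORT", 0.9),), **lgg))

    mb = dict(group="MB", diagnosis="Medulloblastoma")
    add(Scenario("mb_wnt", expected="MB, WNT", methylation=(("MB_WNT", 0.9),), **mb))
    add(Scenario("mb_g3", expected="MB, Group3", methylation=(("MB_G34_II", 0.9),), **mb))
    add(Scenario("mb_g4", expected="MB, Group4", methylation=(("MB_G34_VII", 0.9),), **mb))
    add(Scenario("mb_myo", expected="MB, MYO", methylation=(("MB_MYO", 0.9),), **mb))
    add(Scenario("mb_rna_group3", expected="MB, Group3", rna_mb_class="Group3", **mb))
    add(Scenario("mb_shh_alpha_methyl", expected="MB, SHH alpha",
                 methylation=(("MB_SHH_3", 0.9),), **mb))
    add(Scenario("mb_shh_beta_methyl", expected="MB, SHH beta",
                 methylation=(("MB_SHH_1", 0.9),), **mb))
    add(Scenario("mb_shh_gamma_methyl", expected="MB, SHH gamma",
                 methylation=(("MB_SHH_2", 0.9),), **mb))
    add(Scenario("mb_shh_delta_methyl", expected="MB, SHH delta",
                 methylation=(("MB_SHH_4", 0.9),), **mb))
    add(Scenario("mb_shh_alpha_gli2", expected="MB, SHH alpha", age=3.0,
                 methylation=(("MB_SHH", 0.9),), gene_cnv=(("GLI2", 8),), **mb))
    add(Scenario("mb_shh_alpha_germline", expected="MB, SHH alpha", age=4.0,
                 methylation=(("MB_SHH", 0.9),), germline=("TP53",), **mb))
    add(Scenario("mb_shh_alpha_17p", expected="MB, SHH alpha", age=6.0,
                 methylation=(("MB_SHH", 0.9),), arm_cnv=(("17p", 1),), **mb))
    add(Scenario("mb_shh_beta_kmt2d", expected="MB, SHH beta", age=3.0,
                 methylation=(("MB_SHH", 0.9),),
                 variants=(("KMT2D", "p.Q100*", _NON, False),), **mb))
    add(Scenario("mb_shh_beta_pten", expected="MB, SHH beta", age=2.0,
                 methylation=(("MB_SHH", 0.9),), gene_cnv=(("PTEN", 0),), **mb))
    add(Scenario("mb_shh_gamma_2p", expected="MB, SHH gamma", age=3.0,
                 methylation=(("MB_SHH", 0.9),), arm_cnv=(("2p", 3),), **mb))
    add(Scenario("mb_shh_delta_ddx3x", expected="MB, SHH delta", age=12.0,
                 methylation=(("MB_SHH", 0.9),),
                 variants=(("DDX3X", "p.R276*", _NON, False),), **mb))
    add(Scenario("mb_shh_delta_tert", expected="MB, SHH delta", age=11.0,
                 methylation=(("MB_SHH", 0.9),),
                 variants=(("TERT", "p.=", "5'Flank", True),), **mb))
    add(Scenario("mb_shh_delta_u1", expected="MB, SHH delta", age=14.0,
                 methylation=(("MB_SHH", 0.9),), u1_hotspot=True, **mb))
    add(Scenario("mb_shh_delta_14q", expected="MB, SHH delta", age=15.0,
                 methylation=(("MB_SHH", 0.9),), arm_cnv=(("14q", 1),), **mb))
    add(Scenario("mb_shh_unsub", expected="MB, SHH", age=7.0,
                 methylation=(("MB_SHH", 0.9),), **mb))
    add(Scenario("mb_tbc", expected="MB, To be classified", **mb))

    pb = dict(group="PB", diagnosis="Pineoblastoma")
    add(Scenario("pb_foxr2", expected="PB, MYC/FOXR2-activated",
                 methylation=(("PB_FOXR2", 0.9),), **pb))
    add(Scenario("pb_rb1", expected="PB, RB1-altered", methylation=(("PB_RB1", 0.9),), **pb))
    add(Scenario("pb_grp1", expected="PB, group 1", methylation=(("PB_GRP1B", 0.9),), **pb))
    add(Scenario("pb_grp2", expected="PB, group 2", methylation=(("PB_GRP2", 0.9),), **pb))
    add(Scenario("pb_tbc", expected="PB, To be classified",
                 methylation=(("PB_FOXR2", 0.5),), **pb))

    etmr = dict(group="ETMR", diagnosis="Embryonal tumor with multilayer rosettes")
    add(Scenario("etmr_methyl", expected="ETMR, C19MC-altered",
                 methylation=(("ETMR_C19MC", 0.9),), **etmr))
    add(Scenario("etmr_fusion_chr19", expected="ETMR, C19MC-altered",
                 fusions=("TTYH1::MIR371",), arm_cnv=(("19q", 3),), **etmr))
    add(Scenario("etmr_fusion_lin28a", expected="ETMR, C19MC-altered",
                 fusions=("TTYH1::MIR371",), overexpress=("LIN28A",), **etmr))
    add(Scenario("etmr_nos", expected="ETMR, NOS", overexpress=("LIN28A",), **etmr))
    add(Scenario("etmr_tbc", expected="ETMR, To be classified", **etmr))
    return s


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``histology_mix`` gives proportions over the subtyped histology groups;
    ``None`` means deterministic full coverage of the scenario catalog
    (``n_participants`` is then the catalog size). ``caller_agreement`` is
    the independent per-caller inclusion probability for the sandbox
    variants and copy-number segments; subtyping evidence is always planted
    in every caller.
    """

    n_participants: Optional[int] = None
    histology_mix: Optional[Dict[str, float]] = None
    caller_agreement: float = 1.0
    n_variants_per_sample: int = 20
    hotspot_fraction: float = 0.05
    n_cnvs_per_sample: int = 3
    breakpoint_jitter_sd: float = 0.0
    methyl_score_sd: float = 0.0
    expression_dispersion: float = 0.25
    baseline_tpm: float = 10.0
    overexpressed_tpm: float = 5_000.0
    underexpressed_tpm: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.caller_agreement <= 1.0):
            raise ValueError("caller_agreement must be in [0,1]")
        if self.histology_mix is not None:
            total = sum(self.histology_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"histology_mix proportions sum to {total}, not 1")
            if self.n_participants is None:
                raise ValueError("n_participants required with an explicit histology_mix")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

SNV_CALLER_FILES = ("strelka2", "mutect2", "lancet", "vardict")
CNV_CALLER_FILES = ("controlfreec", "cnvkit", "gatk")

_BASES = ("A", "C", "G", "T")


def _choose_scenarios(spec: CohortSpec, rng: np.random.Generator) -> List[Scenario]:
    catalog = subtyping_scenarios()
    if spec.histology_mix is None:
        n = spec.n_participants or len(catalog)
        return [catalog[i % len(catalog)] for i in range(n)]
    by_group: Dict[str, List[Scenario]] = {}
    for sc in catalog:
        by_group.setdefault(sc.group, []).append(sc)
    unknown = set(spec.histology_mix) - set(by_group)
    if unknown:
        raise ValueError(f"histology_mix names unknown groups: {sorted(unknown)}")
    groups = sorted(spec.histology_mix)
    probs = np.array([spec.histology_mix[g] for g in groups])
    counters = {g: 0 for g in groups}
    chosen = []
    for _ in range(spec.n_participants):
        g = groups[rng.choice(len(groups), p=probs)]
        chosen.append(by_group[g][counters[g] % len(by_group[g])])
        counters[g] += 1
    return chosen


def _sandbox_variants(
    sample_id: str, spec: CohortSpec, rng: np.random.Generator
) -> List[dict]:
    """Random nonsynonymous SNVs uniformly in the sandbox CDS ∩ surveyed region."""
    lo = max(SANDBOX_CDS[0], *(s for s, _ in SANDBOX_SURVEYED.values()))
    hi = min(SANDBOX_CDS[1], *(e for _, e in SANDBOX_SURVEYED.values()))
    positions = rng.choice(np.arange(lo, hi), size=spec.n_variants_per_sample, replace=False)
    out = []
    for pos0 in sorted(int(p) for p in positions):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        out.append(
            {
                "chrom": SANDBOX_CHROM,
                "pos": pos0 + 1,
                "ref": str(ref),
                "alt": str(alt),
                "sample": sample_id,
                "hotspot": bool(rng.random() < spec.hotspot_fraction),
                "classification": "Missense_Mutation",
                "gene": "SANDBOX",
            }
        )
    return out


def _sandbox_cnvs(sample_id: str, spec: CohortSpec, rng: np.random.Generator) -> List[dict]:
    out = []
    for _ in range(spec.n_cnvs_per_sample):
        start = int(rng.integers(5_000, 150_000))
        length = int(rng.integers(5_000, 30_000))
        cn = int(rng.choice([0, 1, 3, 6]))
        out.append(
            {
                "chrom": SANDBOX_CHROM,
                "start": start,
                "end": start + length - 1,
                "cn": cn,
                "sample": sample_id,
            }
        )
    return out


def _pad_span(start: int, end: int, min_len: int = 20_000) -> Tuple[int, int]:
    """Grow a span symmetrically to a minimum length (stays >= 1)."""
    if end - start + 1 >= min_len:
        return start, end
    pad = (min_len - (end - start + 1) + 1) // 2
    return max(1, start - pad), end + pad


def generate_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write the full synthetic cohort to ``out_dir`` and return the manifest.

    Files emitted: ``<caller>.maf.tsv`` (4 SNV callers), ``<caller>.seg.tsv``
    (3 CNV callers), ``fusions.tsv``, ``methylation.tsv``, ``tpm.tsv``,
    ``histologies.tsv``, ``rna_classifier.tsv``, ``flags.tsv``, BED files for
    the toy surveyed/CDS/blacklist models, and ``manifest.yaml``.
    """
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    cfg = RuleConfig()
    scenarios = _choose_scenarios(spec, rng)

    maf_rows: Dict[str, List[VariantCall]] = {c: [] for c in SNV_CALLER_FILES}
    seg_rows: Dict[str, List[CnvSegment]] = {c: [] for c in CNV_CALLER_FILES}
    fusion_rows: List[FusionCall] = []
    methyl_rows: List[MethylationCall] = []
    histology_rows: List[HistologyRecord] = []
    rna_class_rows: List[dict] = []
    flag_rows: List[dict] = []
    tpm_cols: Dict[str, Dict[str, float]] = {}
    manifest_samples: Dict[str, dict] = {}

    arms = toy_arm_models()
    genes = toy_gene_models()
    surveyed_isect = toy_surveyed("strelka2")
    for c in ("mutect2", "vardict"):
        surveyed_isect = surveyed_isect.intersect(toy_surveyed(c))
    denom_all = surveyed_isect.total_length()
    denom_coding = surveyed_isect.intersect(toy_cds()).total_length()

    for i, sc in enumerate(scenarios):
        pid = f"PT_{i:04d}"
        bsid = f"BS_{i:04d}"
        event = f"{bsid}_event"
        histology_rows.append(
            HistologyRecord(
                participant_id=pid,
                biospecimen_id=bsid,
                tumor_event_id=event,
                pathology_diagnosis=sc.diagnosis,
                pathology_free_text_diagnosis=sc.free_text,
                age_at_diagnosis_years=sc.age,
                tumor_descriptor="Initial CNS Tumor",
                cns_region=sc.cns_region,
                experimental_strategy="WGS" if sc.has_dna else (
                    "RNA-Seq" if sc.has_rna else "Methylation"
                ),
                germline_pathogenic=frozenset(sc.germline),
            )
        )

        entry: dict = {
            "participant": pid,
            "scenario": sc.id,
            "expected_subtype": sc.expected,
            "has_dna": sc.has_dna,
            "true_variants": [],
            "true_cnvs": [],
        }

        # -- subtyping evidence (noiseless: planted in every caller) --------
        if sc.has_dna:
            for gene, hgvsp, vclass, hotspot in sc.variants:
                chrom, gstart, _ = genes[gene]
                call = dict(
                    chrom=chrom, pos=gstart + 100, ref="C", alt="T", sample_id=bsid,
                    t_depth=100, t_alt_count=40, n_depth=30, hotspot=hotspot,
                    variant_classification=vclass, hugo_symbol=gene, hgvsp_short=hgvsp,
                )
                for caller in SNV_CALLER_FILES:
                    maf_rows[caller].append(VariantCall(caller=caller, **call))
            for gene, cn in sc.gene_cnv:
                chrom, gstart, gend = genes[gene]
                start, end = _pad_span(gstart, gend)
                for caller in CNV_CALLER_FILES:
                    seg_rows[caller].append(
                        CnvSegment(caller=caller, chrom=chrom, start=start, end=end,
                                   sample_id=bsid, copy_number=cn,
                                   status=cfg.cn_to_status(cn))
                    )
                entry["true_cnvs"].append(
                    {"chrom": chrom, "start": start, "end": end, "cn": cn, "planted": "gene"}
                )
            for arm, cn in sc.arm_cnv:
                chrom, astart, aend = arms[arm]
                span = int(0.6 * (aend - astart + 1))
                start, end = astart, astart + span - 1
                for caller in CNV_CALLER_FILES:
                    seg_rows[caller].append(
                        CnvSegment(caller=caller, chrom=chrom, start=start, end=end,
                                   sample_id=bsid, copy_number=cn,
                                   status=cfg.cn_to_status(cn))
                    )
                entry["true_cnvs"].append(
                    {"chrom": chrom, "start": start, "end": end, "cn": cn, "planted": "arm"}
                )

        if sc.has_rna:
            for fusion in sc.fusions:
                g5, g3 = fusion.split("::")
                fusion_rows.append(
                    FusionCall(gene5=g5, gene3=g3,
                               callers=frozenset({"arriba", "starfusion"}),
                               sample_id=bsid, cancer_group=sc.group)
                )
            col: Dict[str, float] = {}
            for gene in genes:
                col[gene] = float(
                    spec.baseline_tpm
                    * rng.lognormal(mean=0.0, sigma=spec.expression_dispersion)
                )
            for gene in sc.overexpress:
                col[gene] = spec.overexpressed_tpm
            for gene in sc.underexpress:
                col[gene] = spec.underexpressed_tpm
            for gene, value in sc.tpm_override:
                col[gene] = value
            tpm_cols[bsid] = col
            if sc.rna_mb_class is not None:
                rna_class_rows.append({"Sample": bsid, "rna_mb_class": sc.rna_mb_class})

        for subclass, score in sc.methylation:
            if spec.methyl_score_sd > 0:
                score = float(np.clip(rng.normal(score, spec.methyl_score_sd), 0.0, 1.0))
            methyl_rows.append(
                MethylationCall(classifier="dkfz_v12", subclass=subclass,
                                score=score, sample_id=bsid)
            )
        if sc.u1_hotspot:
            flag_rows.append({"Sample": bsid, "u1_snrna_hotspot": 1})

        # -- sandbox channels (consensus / TMB experiments, with noise) -----
        if sc.has_dna:
            truths = _sandbox_variants(bsid, spec, rng)
            for t in truths:
                included = []
                for caller in SNV_CALLER_FILES:
                    if rng.random() < spec.caller_agreement:
                        included.append(caller)
                        maf_rows[caller].append(
                            VariantCall(
                                caller=caller, chrom=t["chrom"], pos=t["pos"],
                                ref=t["ref"], alt=t["alt"], sample_id=bsid,
                                t_depth=100, t_alt_count=30, n_depth=30,
                                hotspot=t["hotspot"],
                                variant_classification=t["classification"],
                                hugo_symbol=t["gene"],
                            )
                        )
                entry["true_variants"].append({**t, "callers": included})
            cnv_truths = _sandbox_cnvs(bsid, spec, rng)
            for t in cnv_truths:
                for caller in CNV_CALLER_FILES:
                    if rng.random() < spec.caller_agreement:
                        jitter = (
                            int(round(rng.normal(0, spec.breakpoint_jitter_sd)))
                            if spec.breakpoint_jitter_sd > 0
                            else 0
                        )
                        start = max(1, t["start"] + jitter)
                        seg_rows[caller].append(
                            CnvSegment(caller=caller, chrom=t["chrom"], start=start,
                                       end=max(start, t["end"] + jitter), sample_id=bsid,
                                       copy_number=t["cn"],
                                       status=cfg.cn_to_status(t["cn"]))
                        )
                entry["true_cnvs"].append({**t, "planted": "sandbox"})
            if spec.caller_agreement >= 1.0:
                n = len(truths)
                # subtyping variants count toward the all-mutation numerator
                # when nonsynonymous; they sit outside the surveyed region so
                # never toward the coding numerator
                n_all = n + sum(
                    1 for _, _, vclass, _ in sc.variants if vclass in cfg.nonsyn_classes
                )
                entry["expected_tmb"] = {
                    "n_all": n_all,
                    "denom_all_bp": denom_all,
                    "tmb_all": n_all / denom_all * cfg.tmb_scale,
                    "n_coding": n,
                    "denom_coding_bp": denom_coding,
                    "tmb_coding": n / denom_coding * cfg.tmb_scale,
                }
        manifest_samples[bsid] = entry

    # -- write files ---------------------------------------------------------
    for caller in SNV_CALLER_FILES:
        pio.write_maf(maf_rows[caller], out / f"{caller}.maf.tsv")
    for caller in CNV_CALLER_FILES:
        pio.write_seg(seg_rows[caller], out / f"{caller}.seg.tsv")
    pio.write_fusions(fusion_rows, out / "fusions.tsv")
    pio.write_methylation(methyl_rows, out / "methylation.tsv")
    pio.write_histologies(histology_rows, out / "histologies.tsv")
    pd.DataFrame(rna_class_rows, columns=["Sample", "rna_mb_class"]).to_csv(
        out / "rna_classifier.tsv", sep="\t", index=False
    )
    pd.DataFrame(flag_rows, columns=["Sample", "u1_snrna_hotspot"]).to_csv(
        out / "flags.tsv", sep="\t", index=False
    )
    tpm = pd.DataFrame(tpm_cols).fillna(0.0)
    tpm.index.name = "gene_symbol"
    pio.write_expression(tpm.sort_index(), out / "tpm.tsv")
    for caller in SNV_CALLER_FILES:
        if caller in SANDBOX_SURVEYED:
            pio.write_bed(toy_surveyed(caller), out / f"surveyed_{caller}.bed")
    pio.write_bed(toy_cds(), out / "cds.bed")
    pio.write_bed(toy_blacklist(), out / "blacklist.bed")

    manifest = {
        "seed": spec.seed,
        "spec": {
            k: v for k, v in dataclasses.asdict(spec).items() if v is not None
        },
        "genome": {"contigs": dict(TOY_CONTIGS)},
        "denominators": {"all_bp": denom_all, "coding_bp": denom_coding},
        "samples": manifest_samples,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Evidence loading (files -> subtyping inputs, via the real pipeline)
# ---------------------------------------------------------------------------

def expression_z(tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores of log2(TPM+1) across the cohort's samples."""
    logged = np.log2(tpm + 1.0)
    mu = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1).replace(0.0, np.nan)
    return logged.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def load_cohort_evidence(cohort_dir, cfg: RuleConfig | None = None):
    """Rebuild per-event subtyping evidence from a generated cohort directory.

    Runs the package's own consensus SNV and CNV pipelines on the emitted
    caller files, projects consensus regions onto the toy gene and arm
    models, and assembles one :class:`TumorEventEvidence` per tumor event.
    """
    from . import io as pio
    from .consensus_cnv import run_consensus_cnv
    from .consensus_snv import run_consensus_snv
    from .focal_cn import arm_status, assign_gene_status
    from .subtyping import SmallVariant, TumorEventEvidence

    cfg = cfg or RuleConfig()
    d = Path(cohort_dir)
    histologies = pio.read_histologies(d / "histologies.tsv")
    calls_by_caller = {
        c: pio.read_maf(d / f"{c}.maf.tsv", default_caller=c) for c in SNV_CALLER_FILES
    }
    consensus = run_consensus_snv(calls_by_caller, cfg)
    segs_by_caller = {
        c: pio.read_seg(d / f"{c}.seg.tsv", default_caller=c) for c in CNV_CALLER_FILES
    }
    blacklist = pio.read_bed(d / "blacklist.bed", name="blacklist")
    by_sample: Dict[str, Dict[str, List[CnvSegment]]] = {}
    for caller, segs in segs_by_caller.items():
        for s in segs:
            by_sample.setdefault(s.sample_id, {c: [] for c in CNV_CALLER_FILES})[
                caller
            ].append(s)
    regions = []
    for sample in sorted(by_sample):
        r, _ = run_consensus_cnv(by_sample[sample], blacklist, cfg, has_gatk_pon=True)
        regions.extend(r)
    gene_models = toy_gene_models()
    gene_rows = assign_gene_status(regions, gene_models, cfg) if regions else []
    arm_rows = arm_status(regions, toy_arm_models(), cfg) if regions else []
    gene_cn: Dict[str, Dict[str, str]] = {}
    for row in gene_rows:
        gene_cn.setdefault(row.sample_id, {})[row.gene] = row.status
    arms: Dict[str, Dict[str, str]] = {}
    for row in arm_rows:
        arms.setdefault(row.sample_id, {})[row.arm] = row.status

    fusions = pio.read_fusions(d / "fusions.tsv")
    methylation = pio.read_methylation(d / "methylation.tsv")
    tpm = pio.read_expression(d / "tpm.tsv")
    z = expression_z(tpm) if not tpm.empty else tpm
    rna_class = pd.read_csv(d / "rna_classifier.tsv", sep="\t", dtype=str)
    rna_class_map = dict(zip(rna_class["Sample"], rna_class["rna_mb_class"]))
    flags = pd.read_csv(d / "flags.tsv", sep="\t", dtype=str)
    u1_samples = set(flags["Sample"]) if not flags.empty else set()

    events = []
    neutral_base = {g: "neutral" for g in gene_models}
    neutral_arms = {a: "neutral" for a in toy_arm_models()}
    for h in histologies:
        bsid = h.biospecimen_id
        has_dna = h.experimental_strategy in ("WGS", "WXS")
        sample_variants = [
            SmallVariant(
                gene=r.hugo_symbol,
                hgvsp=r.hgvsp_short,
                classification=r.variant_classification,
                hotspot=r.hotspot,
            )
            for r in consensus
            if r.sample_id == bsid
        ]
        events.append(
            TumorEventEvidence(
                histology=h,
                variants=sample_variants,
                gene_cn=(
                    {**neutral_base, **gene_cn.get(bsid, {})} if has_dna else {}
                ),
                arms={**neutral_arms, **arms.get(bsid, {})} if has_dna else {},
                fusions=[f for f in fusions if f.sample_id == bsid],
                expr_z=dict(z[bsid]) if bsid in getattr(z, "columns", []) else {},
                expr_tpm=dict(tpm[bsid]) if bsid in tpm.columns else {},
                methylation=[m for m in methylation if m.sample_id == bsid],
                rna_mb_class=rna_class_map.get(bsid),
                u1_snrna_hotspot=bsid in u1_samples,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Published medulloblastoma concordance fixture
# ---------------------------------------------------------------------------

# (methylation subclass, RNA group) -> number of paired samples; the published
# methylation-vs-RNA contingency table for medulloblastoma (150 pairs).
TABLE1_CELLS: Tuple[Tuple[str, str, int], ...] = (
    ("MB_G34_II", "Group3", 8),
    ("MB_G34_III", "Group3", 17),
    ("MB_G34_IV", "Group3", 8),
    ("MB_G34_V", "Group4", 6),
    ("MB_G34_VI", "Group4", 4),
    ("MB_G34_VII", "Group4", 30),
    ("MB_G34_VIII", "Group4", 34),
    ("MB_MYO", "Group3", 1),
    ("MB_SHH_1", "SHH", 11),
    ("MB_SHH_2", "SHH", 4),
    ("MB_SHH_3", "SHH", 2),
    ("MB_SHH_4", "SHH", 7),
    ("MB_WNT", "WNT", 18),
)


def table1_fixture() -> List[Tuple[str, str]]:
    """The published medulloblastoma concordance cells expanded into the
    multiset of 150 (methylation subclass, RNA group) pairs."""
    pairs: List[Tuple[str, str]] = []
    for subclass, rna, count in TABLE1_CELLS:
        pairs.extend([(subclass, rna)] * count)
    return pairs
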