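"""Tumor mutation burden (all-mutation and coding-only).

TMB = qualifying consensus mutations / effectively surveyed bases x scale
(default 1e6, i.e. mutations per megabase). For WGS the denominator is the
intersection of the callers' surveyed-region files; for WXS it is the
capture BED. The coding-only variant restricts both numerator positions and
the denominator to the surveyed-region intersection with coding sequence.
MNVs are decomposed into their constituent SNVs first and sample-level
duplicates removed, so a di-nucleotide substitution counts as two mutations
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

from .config import RuleConfig
from .intervals import GenomeIntervals
from .types import ConsensusMaf, ConsensusVariant


@dataclass(frozen=True)
class TmbResult:
    sample_id: str
    strategy: str  # WGS or WXS
    n_all: int = 0
    denom_all_bp: int = 0
    tmb_all: Optional[float] = None
    n_coding: int = 0
    denom_coding_bp: int = 0
    tmb_coding: Optional[float] = None


def prepare_snv_input(consensus: ConsensusMaf) -> ConsensusMaf:
    """Decompose MNVs into SNVs and drop sample-level duplicate calls."""
    seen = set()
    out: List[ConsensusVariant] = []
    for r in consensus:
        if len(r.ref) == len(r.alt) > 1:
            parts = [
                ConsensusVariant(
                    chrom=r.chrom,
                    pos=r.pos + i,
                    ref=r.ref[i],
                    alt=r.alt[i],
                    sample_id=r.sample_id,
                    caller_support=r.caller_support,
                    hotspot=r.hotspot,
                    t_depth=r.t_depth,
                    t_alt_count=r.t_alt_count,
                    n_depth=r.n_depth,
                    gnomad_af=r.gnomad_af,
                    variant_classification=r.variant_classification,
                    hugo_symbol=r.hugo_symbol,
                    hgvsp_short=r.hgvsp_short,
                )
                for i in range(len(r.ref))
            ]
        else:
            parts = [r]
        for p in parts:
            if p.key not in seen:
                seen.add(p.key)
                out.append(p)
    out.sort(key=lambda r: (r.sample_id, r.chrom, r.pos, r.alt))
    return ConsensusMaf(out)


def select_nonsyn_filter(mode: str, cfg: RuleConfig | None = None) -> Sequence[str]:
    """Active consequence-class list for the TMB numerator."""
    cfg = cfg or RuleConfig()
    if mode == "default":
        return tuple(cfg.nonsyn_classes)
    if mode == "focr":
        return tuple(cfg.nonsynfilter_focr)
    raise ValueError(f"unknown nonsynonymous filter mode: {mode!r}")


def _surveyed_denominator(
    surveyed: Sequence[GenomeIntervals], strategy: str
) -> GenomeIntervals:
    if not surveyed:
        raise ValueError("at least one surveyed-region interval set is required")
    if strategy == "WXS":
        # capture BED is the denominator region; if several given, intersect
        region = surveyed[0]
        for s in surveyed[1:]:
            region = region.intersect(s)
        return region
    region = surveyed[0]
    for s in surveyed[1:]:
        region = region.intersect(s)
    return region


def tmb_all(
    consensus: ConsensusMaf,
    surveyed: Sequence[GenomeIntervals],
    strategy: str,
    cfg: RuleConfig | None = None,
    nonsyn_mode: str = "default",
) -> List[TmbResult]:
    """All-mutation TMB per sample over the surveyed-region denominator."""
    cfg = cfg or RuleConfig()
    classes = set(select_nonsyn_filter(nonsyn_mode, cfg))
    region = _surveyed_denominator(surveyed, strategy)
    denom = region.total_length()
    if denom == 0:
        raise ValueError("surveyed-region denominator is zero")
    prepared = prepare_snv_input(consensus)
    counts: dict = {}
    for r in prepared:
        counts.setdefault(r.sample_id, 0)
        if r.variant_classification in classes:
            counts[r.sample_id] += 1
    return [
        TmbResult(
            sample_id=s,
            strategy=strategy,
            n_all=n,
            denom_all_bp=denom,
            tmb_all=n / denom * cfg.tmb_scale,
        )
        for s, n in sorted(counts.items())
    ]


def tmb_coding(
    consensus: ConsensusMaf,
    surveyed: Sequence[GenomeIntervals],
    cds: GenomeIntervals,
    strategy: str,
    cfg: RuleConfig | None = None,
    nonsyn_mode: str = "default",
) -> List[TmbResult]:
    """Coding-only TMB: numerator and denominator restricted to surveyed ∩ CDS."""
    cfg = cfg or RuleConfig()
    classes = set(select_nonsyn_filter(nonsyn_mode, cfg))
    region = _surveyed_denominator(surveyed, strategy).intersect(cds)
    denom = region.total_length()
    if denom == 0:
        raise ValueError("surveyed ∩ CDS denominator is zero")
    prepared = prepare_snv_input(consensus)
    counts: dict = {}
    for r in prepared:
        counts.setdefault(r.sample_id, 0)
        if r.variant_classification in classes and region.contains_point(r.chrom, r.pos - 1):
            counts[r.sample_id] += 1
    return [
        TmbResult(
            sample_id=s,
            strategy=strategy,
            n_coding=n,
            denom_coding_bp=denom,
            tmb_coding=n / denom * cfg.tmb_scale,
        )
        for s, n in sorted(counts.items())
    ]


def compute_tmb(
    consensus: ConsensusMaf,
    surveyed: Sequence[GenomeIntervals],
    cds: GenomeIntervals,
    strategy: str,
    cfg: RuleConfig | None = None,
    nonsyn_mode: str = "default",
) -> List[TmbResult]:
    """Combined all-mutation + coding-only TMB per sample."""
    all_res = {r.sample_id: r for r in tmb_all(consensus, surveyed, strategy, cfg, nonsyn_mode)}
    cod_res = {
        r.sample_id: r for r in tmb_coding(consensus, surveyed, cds, strategy, cfg, nonsyn_mode)
    }
    return [
        TmbResult(
            sample_id=s,
            strategy=strategy,
            n_all=all_res[s].n_all,
            denom_all_bp=all_res[s].denom_all_bp,
            tmb_all=all_res[s].tmb_all,
            n_coding=cod_res[s].n_coding,
            denom_coding_bp=cod_res[s].denom_coding_bp,
            tmb_coding=cod_res[s].tmb_coding,
        )
        for s in sorted(all_res)
    ]
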