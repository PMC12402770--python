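"""Consensus somatic small-variant calling across four callers.

A variant enters the consensus when at least two of the callers (Strelka2,
Mutect2, Lancet, VarDict) report it, or when any caller flags it as a known
hotspot allele. Strelka2 decomposes multi-nucleotide substitutions into
consecutive SNVs; those are re-assembled into MNP records first whenever
another caller provides the MNP evidence, so that the consensus preserves
the predicted protein change. Two depth-based filters follow: a germline
leak filter for matched tumor/normal calls, and a minimal-depth filter for
tumor-only calls.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional

from .config import RuleConfig
from .types import SNV_CALLERS, ConsensusMaf, ConsensusVariant, VariantCall

logger = logging.getLogger(__name__)

# Caller precedence for the consensus record's numeric fields.
CALLER_PRECEDENCE = ("strelka2", "mutect2", "lancet", "vardict")


def reconstruct_mnps(
    strelka_calls: Iterable[VariantCall], other_calls: Iterable[VariantCall]
) -> List[VariantCall]:
    """Re-assemble Strelka2's consecutive SNVs into MNPs supported elsewhere.

    For every MNP reported by another caller at positions ``p..p+k``, if
    Strelka2 reports SNVs at exactly those consecutive positions whose
    concatenated ref/alt alleles equal the MNP alleles (same sample), the
    SNVs are replaced by a single MNP record. Overlapping but
    allele-inconsistent evidence triggers no merge and a warning.
    """
    strelka = list(strelka_calls)
    by_locus: Dict[tuple, VariantCall] = {}
    for v in strelka:
        if len(v.ref) == len(v.alt) == 1:
            by_locus[(v.sample_id, v.chrom, v.pos)] = v

    consumed: set = set()
    reconstructed: List[VariantCall] = []
    seen_mnp_keys: set = set()
    for mnp in other_calls:
        if not mnp.is_mnp:
            continue
        key = (mnp.sample_id, mnp.chrom, mnp.pos, mnp.ref, mnp.alt)
        if key in seen_mnp_keys:
            continue
        seen_mnp_keys.add(key)
        span = [
            by_locus.get((mnp.sample_id, mnp.chrom, mnp.pos + i))
            for i in range(len(mnp.ref))
        ]
        if any(v is None for v in span):
            continue
        ref = "".join(v.ref for v in span)
        alt = "".join(v.alt for v in span)
        if ref != mnp.ref or alt != mnp.alt:
            logger.warning(
                "MNP %s:%d %s>%s overlaps Strelka2 SNVs with inconsistent alleles; not merged",
                mnp.chrom, mnp.pos, mnp.ref, mnp.alt,
            )
            continue
        if any(id(v) in consumed for v in span):
            continue
        consumed.update(id(v) for v in span)
        first = span[0]
        reconstructed.append(
            VariantCall(
                caller=first.caller,
                chrom=mnp.chrom,
                pos=mnp.pos,
                ref=mnp.ref,
                alt=mnp.alt,
                sample_id=mnp.sample_id,
                t_depth=first.t_depth,
                t_alt_count=first.t_alt_count,
                n_depth=first.n_depth,
                gnomad_af=first.gnomad_af,
                hotspot=any(v.hotspot for v in span),
                variant_classification=first.variant_classification,
                hugo_symbol=first.hugo_symbol,
                hgvsp_short=mnp.hgvsp_short or first.hgvsp_short,
            )
        )

    out = [v for v in strelka if id(v) not in consumed]
    out.extend(reconstructed)
    return out


def call_consensus(
    calls_by_caller: Mapping[str, Iterable[VariantCall]], cfg: RuleConfig | None = None
) -> ConsensusMaf:
    """Retain variants seen by >= ``min_callers_consensus`` callers or hotspots.

    Input calls are keyed by (sample, chrom, pos, ref, alt); MNP
    reconstruction is assumed already applied. Numeric fields of the
    consensus record come from the highest-precedence supporting caller
    (strelka2 > mutect2 > lancet > vardict).
    """
    cfg = cfg or RuleConfig()
    grouped: Dict[tuple, Dict[str, VariantCall]] = defaultdict(dict)
    for caller, calls in calls_by_caller.items():
        for v in calls:
            grouped[v.key][caller] = v

    records: List[ConsensusVariant] = []
    for key in sorted(grouped):
        support = grouped[key]
        hotspot = any(v.hotspot for v in support.values())
        if len(support) < cfg.min_callers_consensus and not hotspot:
            continue
        order = [c for c in CALLER_PRECEDENCE if c in support] + sorted(
            c for c in support if c not in CALLER_PRECEDENCE
        )
        rep = support[order[0]]
        sample, chrom, pos, ref, alt = key
        records.append(
            ConsensusVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                sample_id=sample,
                caller_support=frozenset(support),
                hotspot=hotspot,
                hotspot_rescued=hotspot and len(support) < cfg.min_callers_consensus,
                mnp_reconstructed=len(ref) == len(alt) > 1,
                t_depth=rep.t_depth,
                t_alt_count=rep.t_alt_count,
                n_depth=rep.n_depth,
                gnomad_af=_first_not_none(support[c].gnomad_af for c in order),
                variant_classification=rep.variant_classification,
                hugo_symbol=rep.hugo_symbol,
                hgvsp_short=rep.hgvsp_short,
            )
        )
    records.sort(key=lambda r: (r.sample_id, r.chrom, r.pos, r.alt))
    return ConsensusMaf(records)


def _first_not_none(values) -> Optional[float]:
    for v in values:
        if v is not None:
            return v
    return None


def filter_germline(consensus: ConsensusMaf, cfg: RuleConfig | None = None) -> ConsensusMaf:
    """Remove likely germline leaks from matched tumor/normal consensus calls.

    A non-hotspot record is removed when BOTH the normal depth is at most
    ``germline_max_n_depth`` (too shallow to exclude a germline allele) AND
    the gnomAD allele frequency exceeds ``germline_min_gnomad_af``
    (population-common). Missing gnomAD frequency is treated as 0, so rare
    or unobserved alleles are kept. Hotspot records are never removed.
    """
    cfg = cfg or RuleConfig()

    def is_germline(r) -> bool:
        if r.hotspot:
            return False
        af = r.gnomad_af if r.gnomad_af is not None else 0.0
        return (
            r.n_depth is not None
            and r.n_depth <= cfg.germline_max_n_depth
            and af > cfg.germline_min_gnomad_af
        )

    return ConsensusMaf([r for r in consensus if not is_germline(r)])


def filter_tumor_only(
    calls: Iterable[VariantCall], cfg: RuleConfig | None = None
) -> List[VariantCall]:
    """Drop tumor-only calls with no alt reads or total depth below minimum."""
    cfg = cfg or RuleConfig()
    return [
        v
        for v in calls
        if not (
            (v.t_alt_count is not None and v.t_alt_count == 0)
            or (v.t_depth is not None and v.t_depth < cfg.tumor_only_min_t_depth)
        )
    ]


def run_consensus_snv(
    calls_by_caller: Mapping[str, Iterable[VariantCall]],
    cfg: RuleConfig | None = None,
    mode: str = "tn",
) -> ConsensusMaf:
    """Full consensus pipeline: MNP reconstruction, voting, germline filter.

    ``mode='tumor-only'`` instead applies the tumor-only depth filter to the
    single caller's calls before voting (tumor-only runs use one caller, so
    hotspot-or-multicaller voting degenerates to hotspot retention there).
    """
    cfg = cfg or RuleConfig()
    calls_by_caller = {c: list(v) for c, v in calls_by_caller.items()}
    if mode == "tumor-only":
        calls_by_caller = {
            c: filter_tumor_only(v, cfg) for c, v in calls_by_caller.items()
        }
        grouped = call_consensus(calls_by_caller, cfg)
        return grouped
    strelka = calls_by_caller.get("strelka2", [])
    others = [v for c, vs in calls_by_caller.items() if c != "strelka2" for v in vs]
    calls_by_caller["strelka2"] = reconstruct_mnps(strelka, others)
    consensus = call_consensus(calls_by_caller, cfg)
    return filter_germline(consensus, cfg)
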