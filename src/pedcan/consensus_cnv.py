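"""Consensus copy-number calling by reciprocal overlap and containment.

Per WGS sample, segments from Control-FREEC, CNVkit and GATK (or MantaSV
when no GATK panel of normals exists) are combined: a span is consensus if
two callers' same-direction segments reciprocally overlap by at least 50%
(the intersected span is kept), or if one caller's segment is at least 90%
covered by another caller's same-direction segments (the contained
segment's own span is kept). Per-caller files with more than 2,500 segments
are dropped as noise first. Pooled consensus spans of the same direction are
unioned where they overlap, merged across gaps of up to 10 kb, and finally
filtered for minimum length and blacklist overlap. WXS samples bypass
consensus: their single-caller CNVkit segments are appended unchanged.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .config import RuleConfig
from .intervals import GenomeIntervals
from .types import CnvSegment, ConsensusCnvRegion

logger = logging.getLogger(__name__)


def denoise_caller_set(
    segments: List[CnvSegment], cfg: RuleConfig | None = None
) -> List[CnvSegment]:
    """Drop the whole per-sample caller file when it has > 2,500 segments."""
    cfg = cfg or RuleConfig()
    if len(segments) > cfg.cnv_denoise_max:
        if segments:
            logger.warning(
                "dropping %d segments for sample %s caller %s (noise threshold %d)",
                len(segments), segments[0].sample_id, segments[0].caller, cfg.cnv_denoise_max,
            )
        return []
    return segments


def reciprocal_overlap(a: CnvSegment, b: CnvSegment) -> Tuple[float, float]:
    """Overlap length divided by each segment's own length; (0, 0) if disjoint."""
    if a.chrom != b.chrom:
        raise ValueError(f"segments on different chromosomes: {a.chrom} vs {b.chrom}")
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return (0.0, 0.0)
    return (ov / a.length, ov / b.length)


def apply_manta_fallback(
    by_caller: Mapping[str, List[CnvSegment]], has_gatk_pon: bool
) -> Dict[str, List[CnvSegment]]:
    """Select the caller trio: {freec, cnvkit, gatk} with a PoN, else MantaSV."""
    wanted = (
        ("controlfreec", "cnvkit", "gatk")
        if has_gatk_pon
        else ("controlfreec", "cnvkit", "mantasv")
    )
    if not has_gatk_pon and "mantasv" not in by_caller:
        raise ValueError("MantaSV-derived CNV calls required when no GATK panel of normals")
    return {c: list(by_caller[c]) for c in wanted if c in by_caller}


def _coverage_fraction(seg: CnvSegment, others: Iterable[CnvSegment]) -> float:
    """Fraction of ``seg`` covered by the union of ``others`` (same chrom)."""
    cover = GenomeIntervals(
        [(o.chrom, o.start - 1, o.end) for o in others if o.chrom == seg.chrom],
        name="cover",
    )
    return cover.overlap_bp(seg.chrom, seg.start - 1, seg.end) / seg.length


def consensus_regions(
    by_caller: Mapping[str, List[CnvSegment]], cfg: RuleConfig | None = None
) -> List[ConsensusCnvRegion]:
    """Pairwise reciprocal-overlap and containment consensus across callers.

    Produces raw (unmerged) consensus regions; callers' neutral segments
    never contribute direction support, and a span whose supporters carry
    conflicting or missing copy numbers gets copy_number ``None``.
    """
    cfg = cfg or RuleConfig()
    callers = [c for c in by_caller if by_caller[c]]
    if len(callers) < 2:
        logger.warning("fewer than 2 caller sets available; no consensus regions")
        return []

    raw: List[ConsensusCnvRegion] = []

    def emit(chrom, start, end, direction, supporters, segs, from_containment=False):
        cns = {s.copy_number for s in segs}
        neutral_overlap = any(s.direction is None for s in segs)
        cn = cns.pop() if len(cns) == 1 and not neutral_overlap else None
        raw.append(
            ConsensusCnvRegion(
                chrom=chrom,
                start=start,
                end=end,
                direction=direction,
                supporting_callers=frozenset(supporters),
                sample_id=segs[0].sample_id,
                copy_number=cn,
                from_containment=from_containment,
            )
        )

    # Rule (i): intersected spans of reciprocally overlapping pairs.
    for ca, cb in combinations(callers, 2):
        for a in by_caller[ca]:
            if a.direction is None:
                continue
            for b in by_caller[cb]:
                if (
                    b.direction != a.direction
                    or b.chrom != a.chrom
                    or b.sample_id != a.sample_id
                ):
                    continue
                fa, fb = reciprocal_overlap(a, b)
                if fa >= cfg.cnv_reciprocal_min and fb >= cfg.cnv_reciprocal_min:
                    emit(
                        a.chrom,
                        max(a.start, b.start),
                        min(a.end, b.end),
                        a.direction,
                        {ca, cb},
                        [a, b],
                    )

    # Rule (ii): segments >= 90% covered by another caller's same-direction set.
    for ca in callers:
        for a in by_caller[ca]:
            if a.direction is None:
                continue
            for cb in callers:
                if cb == ca:
                    continue
                others = [
                    b
                    for b in by_caller[cb]
                    if b.direction == a.direction
                    and b.chrom == a.chrom
                    and b.sample_id == a.sample_id
                ]
                if not others:
                    continue
                if _coverage_fraction(a, others) >= cfg.cnv_containment_min:
                    touching = [
                        b for b in others if min(a.end, b.end) >= max(a.start, b.start)
                    ]
                    emit(
                        a.chrom, a.start, a.end, a.direction, {ca, cb},
                        [a] + touching, from_containment=True,
                    )

    return _union_overlapping(raw)


def _union_overlapping(regions: List[ConsensusCnvRegion]) -> List[ConsensusCnvRegion]:
    """Union overlapping same-direction pooled regions (gap 0 merge)."""
    return _merge(regions, max_gap=0)


def merge_adjacent(
    regions: List[ConsensusCnvRegion], cfg: RuleConfig | None = None
) -> List[ConsensusCnvRegion]:
    """Merge same-direction regions within ``cnv_merge_gap_bp`` of each other."""
    cfg = cfg or RuleConfig()
    return _merge(regions, max_gap=cfg.cnv_merge_gap_bp)


def _merge(regions: List[ConsensusCnvRegion], max_gap: int) -> List[ConsensusCnvRegion]:
    grouped: Dict[tuple, List[ConsensusCnvRegion]] = defaultdict(list)
    for r in regions:
        grouped[(r.sample_id, r.chrom, r.direction)].append(r)

    out: List[ConsensusCnvRegion] = []
    for key in sorted(grouped):
        block: List[ConsensusCnvRegion] = []
        for r in sorted(grouped[key], key=lambda r: (r.start, r.end)):
            if block and r.start - block[-1].end - 1 <= max_gap:
                block.append(r)
            else:
                if block:
                    out.append(_collapse(block))
                block = [r]
        if block:
            out.append(_collapse(block))
    out.sort(key=lambda r: (r.sample_id, r.chrom, r.start, r.direction))
    return out


def _collapse(block: List[ConsensusCnvRegion]) -> ConsensusCnvRegion:
    if len(block) == 1:
        return block[0]
    cns = {r.copy_number for r in block}
    return ConsensusCnvRegion(
        chrom=block[0].chrom,
        start=min(r.start for r in block),
        end=max(r.end for r in block),
        direction=block[0].direction,
        supporting_callers=frozenset().union(*(r.supporting_callers for r in block)),
        sample_id=block[0].sample_id,
        copy_number=cns.pop() if len(cns) == 1 else None,
        from_containment=all(r.from_containment for r in block),
    )


def filter_regions(
    regions: List[ConsensusCnvRegion],
    blacklist: GenomeIntervals,
    cfg: RuleConfig | None = None,
) -> List[ConsensusCnvRegion]:
    """Drop regions shorter than 3 kb or with >= 50% blacklist overlap."""
    cfg = cfg or RuleConfig()
    kept = []
    for r in regions:
        if r.length < cfg.cnv_min_len_bp:
            continue
        if blacklist.overlap_bp(r.chrom, r.start - 1, r.end) / r.length >= cfg.cnv_blacklist_overlap:
            continue
        kept.append(r)
    return kept


def run_consensus_cnv(
    by_caller: Mapping[str, List[CnvSegment]],
    blacklist: GenomeIntervals,
    cfg: RuleConfig | None = None,
    has_gatk_pon: bool = True,
    wxs_cnvkit: Optional[List[CnvSegment]] = None,
) -> Tuple[List[ConsensusCnvRegion], List[CnvSegment]]:
    """Full per-sample consensus CNV pipeline.

    Returns the filtered consensus regions plus any WXS CNVkit segments
    appended unchanged (they bypass consensus).
    """
    cfg = cfg or RuleConfig()
    selected = apply_manta_fallback(by_caller, has_gatk_pon)
    selected = {c: denoise_caller_set(v, cfg) for c, v in selected.items()}
    regions = consensus_regions(selected, cfg)
    regions = merge_adjacent(regions, cfg)
    regions = filter_regions(regions, blacklist, cfg)
    return regions, list(wxs_cnvkit or [])
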