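"""Project consensus CNV regions onto genes and chromosome arms.

Gene-level status resolution follows a three-step precedence when several
regions overlap the same gene in the same sample: (1) non-neutral status
beats neutral; (2) among the remaining candidates the dominant segment is
the one with the largest base-pair overlap with the gene (ties: longer
segment, then leftmost start); (3) when the dominant tie still remains,
amplification beats gain and deep deletion beats loss. The result is
exactly one status row per (gene, sample).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from intervaltree import IntervalTree

from .config import RuleConfig
from .intervals import GenomeIntervals, normalize_chrom
from .types import ArmStatus, ConsensusCnvRegion, GeneCnStatus

Span = Tuple[str, int, int]  # chrom, start, end (1-based inclusive)

_SEVERITY = {"deep_deletion": 2, "amplification": 2, "loss": 1, "gain": 1, "neutral": 0}


def region_status(region: ConsensusCnvRegion, cfg: RuleConfig) -> str:
    """Status label for a consensus region: from its integer CN when known,
    else its direction."""
    if region.copy_number is not None:
        return cfg.cn_to_status(region.copy_number)
    return region.direction


def _gene_trees(gene_models: Mapping[str, Span]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene, (chrom, start, end) in gene_models.items():
        trees[normalize_chrom(chrom)][start : end + 1] = (gene, start, end)
    return trees


def assign_gene_status(
    regions: Iterable[ConsensusCnvRegion],
    gene_models: Mapping[str, Span],
    cfg: RuleConfig | None = None,
) -> List[GeneCnStatus]:
    """Resolve one copy-number status per (gene, sample).

    Genes with no overlapping region are reported neutral for every sample
    present in ``regions``.
    """
    cfg = cfg or RuleConfig()
    if not gene_models:
        raise ValueError("gene_models must be nonempty")
    trees = _gene_trees(gene_models)

    # (gene, sample) -> list of (overlap_bp, seg_length, seg_start, status, region)
    candidates: Dict[Tuple[str, str], list] = defaultdict(list)
    samples = set()
    for r in regions:
        samples.add(r.sample_id)
        for hit in trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end + 1):
            gene, gstart, gend = hit.data
            overlap = min(r.end, gend) - max(r.start, gstart) + 1
            candidates[(gene, r.sample_id)].append(
                (overlap, r.length, r.start, region_status(r, cfg), r, gend - gstart + 1)
            )

    out: List[GeneCnStatus] = []
    for sample in sorted(samples):
        for gene in sorted(gene_models):
            cands = candidates.get((gene, sample), [])
            nonneutral = [c for c in cands if c[3] != "neutral"]
            pool = nonneutral or cands
            if not pool:
                out.append(GeneCnStatus(gene=gene, sample_id=sample, status="neutral"))
                continue
            # dominant segment: largest overlap; remaining ties resolved by
            # status severity, then longer segment, then leftmost start
            best_overlap = max(c[0] for c in pool)
            dominant = [c for c in pool if c[0] == best_overlap]
            chosen = max(dominant, key=lambda c: (_SEVERITY[c[3]], c[1], -c[2]))
            overlap, _, _, status, region, gene_len = chosen
            out.append(
                GeneCnStatus(
                    gene=gene,
                    sample_id=sample,
                    status=status,
                    overlap_fraction=min(1.0, overlap / gene_len),
                    dominant_segment=(region.chrom, region.start, region.end),
                )
            )
    return out


def arm_status(
    regions: Iterable[ConsensusCnvRegion],
    arm_models: Mapping[str, Span],
    cfg: RuleConfig | None = None,
) -> List[ArmStatus]:
    """Call arm-level gain/loss when same-direction regions cover >= the
    configured fraction of the arm (default 0.5); otherwise neutral."""
    cfg = cfg or RuleConfig()
    by_sample_dir: Dict[Tuple[str, str], List[ConsensusCnvRegion]] = defaultdict(list)
    samples = set()
    for r in regions:
        samples.add(r.sample_id)
        by_sample_dir[(r.sample_id, r.direction)].append(r)

    out: List[ArmStatus] = []
    for sample in sorted(samples):
        for arm in sorted(arm_models):
            chrom, start, end = arm_models[arm]
            chrom = normalize_chrom(chrom)
            arm_len = end - start + 1
            fractions = {}
            for direction in ("gain", "loss"):
                cover = GenomeIntervals(
                    [
                        (r.chrom, r.start - 1, r.end)
                        for r in by_sample_dir.get((sample, direction), [])
                        if r.chrom == chrom
                    ]
                )
                fractions[direction] = cover.overlap_bp(chrom, start - 1, end) / arm_len
            direction = max(fractions, key=lambda d: fractions[d])
            if fractions[direction] >= cfg.arm_coverage_min:
                out.append(
                    ArmStatus(
                        sample_id=sample,
                        arm=arm,
                        status=direction,
                        covered_fraction=fractions[direction],
                    )
                )
            else:
                out.append(
                    ArmStatus(
                        sample_id=sample,
                        arm=arm,
                        status="neutral",
                        covered_fraction=fractions[direction],
                    )
                )
    return out
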