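"""Consensus CNV calling vs a brute-force per-base oracle."""

import random

import pytest

from pedcan.config import RuleConfig
from pedcan.consensus_cnv import (
    apply_manta_fallback,
    consensus_regions,
    denoise_caller_set,
    filter_regions,
    merge_adjacent,
    reciprocal_overlap,
)
from pedcan.intervals import GenomeIntervals
from pedcan.types import CnvSegment, ConsensusCnvRegion


def seg(caller, start, end, status, chrom="chr1", sample="S1", cn=None):
    return CnvSegment(caller=caller, chrom=chrom, start=start, end=end,
                      sample_id=sample, copy_number=cn, status=status)


def region(start, end, direction="gain", chrom="chr1", sample="S1",
           callers=("controlfreec", "cnvkit")):
    return ConsensusCnvRegion(chrom=chrom, start=start, end=end, direction=direction,
                              supporting_callers=frozenset(callers), sample_id=sample)


class TestDenoise:
    def test_2501_segments_dropped(self, cfg):
        segs = [seg("cnvkit", i * 10 + 1, i * 10 + 5, "gain") for i in range(2501)]
        assert denoise_caller_set(segs, cfg) == []

    def test_2500_segments_kept(self, cfg):
        segs = [seg("cnvkit", i * 10 + 1, i * 10 + 5, "gain") for i in range(2500)]
        assert denoise_caller_set(segs, cfg) == segs

    def test_empty_unchanged(self, cfg):
        assert denoise_caller_set([], cfg) == []


class TestReciprocalOverlap:
    def test_half_overlap(self):
        a, b = seg("a", 1001, 2000, "gain"), seg("b", 1501, 2500, "gain")
        assert reciprocal_overlap(a, b) == (0.5, 0.5)

    def test_identical_segments(self):
        a = seg("a", 1, 100, "gain")
        assert reciprocal_overlap(a, a) == (1.0, 1.0)

    def test_disjoint(self):
        assert reciprocal_overlap(
            seg("a", 1, 100, "gain"), seg("b", 200, 300, "gain")
        ) == (0.0, 0.0)

    def test_different_chromosomes_error(self):
        with pytest.raises(ValueError):
            reciprocal_overlap(seg("a", 1, 10, "gain"),
                               seg("b", 1, 10, "gain", chrom="chr2"))


class TestConsensusRules:
    def test_reciprocal_pair_yields_intersected_span(self, cfg):
        out = consensus_regions(
            {"controlfreec": [seg("controlfreec", 1001, 2000, "gain")],
             "cnvkit": [seg("cnvkit", 1501, 2500, "gain")]},
            cfg,
        )
        assert [(r.start, r.end) for r in out] == [(1501, 2000)]
        assert out[0].supporting_callers == {"controlfreec", "cnvkit"}

    def test_containment_keeps_contained_span(self, cfg):
        out = consensus_regions(
            {"controlfreec": [seg("controlfreec", 1001, 1200, "gain")],
             "cnvkit": [seg("cnvkit", 1, 10000, "gain")]},
            cfg,
        )
        assert any(r.start == 1001 and r.end == 1200 for r in out)

    def test_direction_mismatch_no_consensus(self, cfg):
        out = consensus_regions(
            {"controlfreec": [seg("controlfreec", 1001, 2000, "gain")],
             "cnvkit": [seg("cnvkit", 1001, 2000, "loss")]},
            cfg,
        )
        assert out == []

    def test_single_caller_gives_empty(self, cfg):
        assert consensus_regions({"cnvkit": [seg("cnvkit", 1, 100, "gain")]}, cfg) == []

    def test_neutral_supporter_gives_na_copy_number(self, cfg):
        out = consensus_regions(
            {"controlfreec": [seg("controlfreec", 1001, 2000, "gain", cn=3)],
             "cnvkit": [seg("cnvkit", 1001, 2000, "gain", cn=4)]},
            cfg,
        )
        assert out[0].copy_number is None  # disagreeing CNs -> NA


class TestMergeAndFilter:
    def test_gap_below_threshold_merges(self, cfg):
        out = merge_adjacent([region(1, 1000), region(6001, 9000)], cfg)
        assert [(r.start, r.end) for r in out] == [(1, 9000)]

    def test_opposite_directions_not_merged(self, cfg):
        out = merge_adjacent([region(1, 1000, "gain"), region(2001, 3000, "loss")], cfg)
        assert len(out) == 2

    def test_merge_idempotent_and_order_independent(self, cfg):
        regions = [region(1, 1000), region(6001, 9000), region(50_000, 60_000)]
        once = merge_adjacent(regions, cfg)
        assert merge_adjacent(once, cfg) == once
        assert merge_adjacent(list(reversed(regions)), cfg) == once

    @pytest.mark.parametrize(
        "length,bl_overlap,kept",
        [(2999, 0, False), (10_000, 5_000, False), (10_000, 4_900, True), (3_000, 0, True)],
    )
    def test_length_and_blacklist_boundaries(self, cfg, length, bl_overlap, kept):
        r = region(10_001, 10_000 + length)
        blacklist = GenomeIntervals(
            [("chr1", 10_000, 10_000 + bl_overlap)] if bl_overlap else [], name="bl"
        )
        assert (filter_regions([r], blacklist, cfg) == [r]) is kept


class TestMantaFallback:
    def test_gatk_with_pon(self):
        by = {"controlfreec": [], "cnvkit": [], "gatk": [seg("gatk", 1, 10, "gain")],
              "mantasv": []}
        assert "gatk" in apply_manta_fallback(by, has_gatk_pon=True)
        assert "mantasv" not in apply_manta_fallback(by, has_gatk_pon=True)

    def test_manta_without_pon(self):
        by = {"controlfreec": [], "cnvkit": [], "mantasv": []}
        assert "mantasv" in apply_manta_fallback(by, has_gatk_pon=False)

    def test_missing_manta_errors(self):
        with pytest.raises(ValueError):
            apply_manta_fallback({"controlfreec": [], "cnvkit": []}, has_gatk_pon=False)


# ---------------------------------------------------------------------------
# Brute-force per-base oracle: the same published rules, computed naively on
# explicit base sets, independent of the package's interval arithmetic.
# ---------------------------------------------------------------------------

def bases(start, end):
    return set(range(start, end + 1))


def oracle_consensus(by_caller, blacklist_pairs, cfg):
    callers = [c for c, v in by_caller.items() if 0 < len(v) <= cfg.cnv_denoise_max]
    spans = {}  # direction -> set of covered bases
    for i, ca in enumerate(callers):
        for cb in callers[i + 1:]:
            for a in by_caller[ca]:
                for b in by_caller[cb]:
                    if a.direction is None or a.direction != b.direction:
                        continue
                    if a.chrom != b.chrom:
                        continue
                    ov = bases(a.start, a.end) & bases(b.start, b.end)
                    if len(ov) / a.length >= cfg.cnv_reciprocal_min and \
                       len(ov) / b.length >= cfg.cnv_reciprocal_min:
                        spans.setdefault(a.direction, set()).update(ov)
    for ca in callers:
        for a in by_caller[ca]:
            if a.direction is None:
                continue
            for cb in callers:
                if cb == ca:
                    continue
                cover = set()
                for b in by_caller[cb]:
                    if b.direction == a.direction and b.chrom == a.chrom:
                        cover |= bases(b.start, b.end) & bases(a.start, a.end)
                if len(cover) / a.length >= cfg.cnv_containment_min:
                    spans.setdefault(a.direction, set()).update(bases(a.start, a.end))
    out = []
    for direction, covered in spans.items():
        runs = runs_from(covered)
        merged = []
        for start, end in runs:
            if merged and start - merged[-1][1] - 1 <= cfg.cnv_merge_gap_bp:
                merged[-1] = (merged[-1][0], end)
            else:
                merged.append((start, end))
        bl = set()
        for s, e in blacklist_pairs:
            bl |= bases(s, e)
        for start, end in merged:
            length = end - start + 1
            if length < cfg.cnv_min_len_bp:
                continue
            if len(bases(start, end) & bl) / length >= cfg.cnv_blacklist_overlap:
                continue
            out.append((start, end, direction))
    return sorted(out)


def runs_from(covered):
    runs, block = [], None
    for p in sorted(covered):
        if block and p == block[1] + 1:
            block = (block[0], p)
        else:
            if block:
                runs.append(block)
            block = (p, p)
    if block:
        runs.append(block)
    return runs


class TestPerBaseOracle:
    def test_pipeline_matches_oracle_on_random_toy_genomes(self, cfg):
        from pedcan.consensus_cnv import run_consensus_cnv

        rng = random.Random(2024)
        for trial in range(8):
            by_caller = {}
            for caller in ("controlfreec", "cnvkit", "gatk"):
                segs = []
                for _ in range(rng.randrange(1, 7)):
                    start = rng.randrange(1, 900_000)
                    length = rng.randrange(500, 60_000)
                    status = rng.choice(["gain", "loss", "neutral"])
                    segs.append(seg(caller, start, start + length - 1, status))
                by_caller[caller] = segs
            blacklist_pairs = [(700_001, 720_000)]
            blacklist = GenomeIntervals(
                [("chr1", s - 1, e) for s, e in blacklist_pairs], name="bl"
            )
            got, _ = run_consensus_cnv(by_caller, blacklist, cfg, has_gatk_pon=True)
            got_spans = sorted((r.start, r.end, r.direction) for r in got)
            assert got_spans == oracle_consensus(by_caller, blacklist_pairs, cfg), (
                f"trial {trial}"
            )

    def test_output_regions_non_overlapping_per_direction(self, cfg):
        from pedcan.consensus_cnv import run_consensus_cnv

        rng = random.Random(5)
        by_caller = {
            caller: [
                seg(caller, s, s + rng.randrange(3_000, 50_000), "gain")
                for s in sorted(rng.sample(range(1, 500_000), 5))
            ]
            for caller in ("controlfreec", "cnvkit")
        }
        got, _ = run_consensus_cnv(
            by_caller, GenomeIntervals([], name="bl"), cfg, has_gatk_pon=True
        )
        spans = sorted((r.start, r.end) for r in got if r.direction == "gain")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
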