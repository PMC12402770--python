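"""Consensus SNV calling: MNP reconstruction, voting, filters, oracle match."""

import random

import pytest

from pedcan.config import RuleConfig
from pedcan.consensus_snv import (
    call_consensus,
    filter_germline,
    filter_tumor_only,
    reconstruct_mnps,
    run_consensus_snv,
)
from pedcan.types import ConsensusMaf, VariantCall


def vc(caller, pos, ref, alt, sample="S1", chrom="chr1", **kw):
    return VariantCall(caller=caller, chrom=chrom, pos=pos, ref=ref, alt=alt,
                       sample_id=sample, **kw)


class TestMnpReconstruction:
    def test_adjacent_snvs_merge_into_mnp(self):
        strelka = [vc("strelka2", 100, "C", "A"), vc("strelka2", 101, "G", "T")]
        mutect = [vc("mutect2", 100, "CG", "AT")]
        out = reconstruct_mnps(strelka, mutect)
        assert len(out) == 1
        assert (out[0].pos, out[0].ref, out[0].alt) == (100, "CG", "AT")

    def test_no_mnp_evidence_leaves_snvs_unchanged(self):
        strelka = [vc("strelka2", 100, "C", "A")]
        assert reconstruct_mnps(strelka, []) == strelka

    def test_nonconsecutive_snvs_do_not_merge(self):
        strelka = [vc("strelka2", 100, "C", "A"), vc("strelka2", 102, "G", "T")]
        mutect = [vc("mutect2", 100, "CNG", "ANT")]
        out = reconstruct_mnps(strelka, mutect)
        assert sorted(v.pos for v in out) == [100, 102]
        assert all(len(v.ref) == 1 for v in out)

    def test_allele_inconsistent_evidence_not_merged(self):
        strelka = [vc("strelka2", 100, "C", "A"), vc("strelka2", 101, "G", "C")]
        mutect = [vc("mutect2", 100, "CG", "AT")]
        out = reconstruct_mnps(strelka, mutect)
        assert sorted(v.pos for v in out) == [100, 101]

    def test_reconstructed_mnp_counts_with_donor_as_two_supporters(self):
        calls = {
            "strelka2": reconstruct_mnps(
                [vc("strelka2", 100, "C", "A"), vc("strelka2", 101, "G", "T")],
                [vc("mutect2", 100, "CG", "AT")],
            ),
            "mutect2": [vc("mutect2", 100, "CG", "AT")],
        }
        consensus = call_consensus(calls)
        assert len(consensus) == 1
        rec = consensus.records[0]
        assert rec.caller_support == {"strelka2", "mutect2"}
        assert rec.mnp_reconstructed


class TestVoting:
    def test_two_callers_retained(self):
        consensus = call_consensus(
            {"strelka2": [vc("strelka2", 10, "A", "G")],
             "lancet": [vc("lancet", 10, "A", "G")]}
        )
        assert len(consensus) == 1
        assert consensus.records[0].caller_support == {"strelka2", "lancet"}
        assert not consensus.records[0].hotspot_rescued

    def test_single_caller_hotspot_rescued(self):
        consensus = call_consensus(
            {"vardict": [vc("vardict", 10, "A", "G", hotspot=True)]}
        )
        assert len(consensus) == 1
        assert consensus.records[0].hotspot_rescued

    def test_single_caller_non_hotspot_dropped(self):
        assert len(call_consensus({"mutect2": [vc("mutect2", 10, "A", "G")]})) == 0

    def test_empty_input_gives_empty_consensus(self):
        assert len(call_consensus({})) == 0


class TestGermlineFilter:
    @pytest.mark.parametrize(
        "n_depth,af,hotspot,kept",
        [
            (7, 0.002, False, False),   # shallow normal AND common -> removed
            (10, 0.002, False, True),   # deep normal -> kept
            (7, 0.001, False, True),    # af not strictly above cutoff -> kept
            (7, 0.0005, False, True),
            (3, 0.05, True, True),      # hotspots never removed
            (7, None, False, True),     # missing af treated as 0
        ],
    )
    def test_truth_table(self, n_depth, af, hotspot, kept):
        consensus = call_consensus(
            {
                "strelka2": [vc("strelka2", 10, "A", "G", n_depth=n_depth,
                                gnomad_af=af, hotspot=hotspot)],
                "mutect2": [vc("mutect2", 10, "A", "G", n_depth=n_depth,
                               gnomad_af=af, hotspot=hotspot)],
            }
        )
        assert (len(filter_germline(consensus)) == 1) is kept


class TestTumorOnlyFilter:
    @pytest.mark.parametrize(
        "t_alt,t_depth,kept",
        [(0, 100, False), (3, 4, True), (2, 3, False), (1, 100, True)],
    )
    def test_depth_boundaries(self, t_alt, t_depth, kept):
        calls = [vc("mutect2", 10, "A", "G", t_depth=t_depth, t_alt_count=t_alt)]
        assert (len(filter_tumor_only(calls)) == 1) is kept


def brute_force_consensus(calls_by_caller, cfg):
    """Independent set-based oracle: >=2 callers or hotspot, then the
    germline filter over the two quoted conditions."""
    support, hotspot, meta = {}, {}, {}
    for caller, calls in calls_by_caller.items():
        for v in calls:
            support.setdefault(v.key, set()).add(caller)
            hotspot[v.key] = hotspot.get(v.key, False) or v.hotspot
            meta.setdefault(v.key, v)
    kept = set()
    for key, callers in support.items():
        if len(callers) >= cfg.min_callers_consensus or hotspot[key]:
            v = meta[key]
            af = v.gnomad_af if v.gnomad_af is not None else 0.0
            germline = (
                not hotspot[key]
                and v.n_depth is not None
                and v.n_depth <= cfg.germline_max_n_depth
                and af > cfg.germline_min_gnomad_af
            )
            if not germline:
                kept.add(key)
    return kept


def random_caller_calls(n_variants, seed, n_samples=4):
    rng = random.Random(seed)
    calls = {c: [] for c in ("strelka2", "mutect2", "lancet", "vardict")}
    truth = []
    for i in range(n_variants):
        sample = f"S{rng.randrange(n_samples)}"
        pos = rng.randrange(1, 10**6)
        ref, alt = rng.sample("ACGT", 2)
        hotspot = rng.random() < 0.1
        n_depth = rng.choice([3, 7, 8, 30, None])
        af = rng.choice([None, 0.0, 0.0005, 0.001, 0.002, 0.05])
        callers = [c for c in calls if rng.random() < 0.5]
        for c in callers:
            calls[c].append(
                VariantCall(caller=c, chrom="chr1", pos=pos, ref=ref, alt=alt,
                            sample_id=sample, hotspot=hotspot, n_depth=n_depth,
                            gnomad_af=af)
            )
        truth.append((sample, pos, ref, alt, callers))
    return calls, truth


class TestOracleEquivalence:
    def test_matches_set_based_oracle_on_1000_variants(self, cfg):
        calls, _ = random_caller_calls(1000, seed=42)
        got = {r.key for r in filter_germline(call_consensus(calls, cfg), cfg)}
        assert got == brute_force_consensus(calls, cfg)

    def test_consensus_subset_of_inputs(self, cfg):
        calls, _ = random_caller_calls(300, seed=7)
        input_keys = {v.key for vs in calls.values() for v in vs}
        consensus = call_consensus(calls, cfg)
        assert {r.key for r in consensus} <= input_keys


class TestDeterminismAndRestriction:
    def test_shuffled_inputs_identical_output(self, cfg):
        calls, _ = random_caller_calls(500, seed=3)
        shuffled = {c: list(reversed(v)) for c, v in calls.items()}
        a = run_consensus_snv(calls, cfg)
        b = run_consensus_snv(shuffled, cfg)
        assert a.records == b.records

    def test_filter_commutes_with_sample_restriction(self, cfg):
        calls, _ = random_caller_calls(500, seed=9)
        pooled = filter_germline(call_consensus(calls, cfg), cfg)
        per_sample = pooled.restrict_to_sample("S1")
        restricted_calls = {
            c: [v for v in vs if v.sample_id == "S1"] for c, vs in calls.items()
        }
        direct = filter_germline(call_consensus(restricted_calls, cfg), cfg)
        assert per_sample.records == direct.records
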