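# pedcan

Downstream analysis toolkit for harmonized pediatric cancer cohorts:
consensus somatic variant calling, consensus copy-number calling, tumor
mutation burden, fusion prioritization, TP53 status annotation, and a
WHO-2021-aligned molecular-subtyping rule engine for CNS tumors — with a
synthetic-cohort generator so every stage runs end to end without any data
download.

## Who this is for

Groups analyzing multi-caller somatic outputs from pediatric cancer
cohorts (e.g. Kids First / PBTA-style data): per-caller MAFs from Strelka2,
Mutect2, Lancet and VarDict; per-caller SEG files from Control-FREEC,
CNVkit, GATK or MantaSV-derived calls; RNA fusion tables from Arriba and
STAR-Fusion; DNA-methylation classifier outputs; expression matrices; and a
harmonized clinical histologies table.

## What it computes

**Consensus SNVs.** A variant is retained when called by ≥ 2 of the 4
callers or flagged `HotSpotAllele` by any caller. Strelka2's decomposed
multi-nucleotide substitutions are first re-assembled into MNPs wherever
another caller supplies the MNP allele. Non-hotspot calls with normal depth
≤ 7 **and** gnomAD AF > 0.001 are removed as germline leaks; tumor-only
calls with `alt_depth == 0 or t_depth < 4` are removed.

**Consensus CNVs.** Per sample, caller files with > 2,500 segments are
dropped as noise; a span is consensus when two callers' same-direction
segments reciprocally overlap ≥ 50 % (intersected span) or one segment is
≥ 90 % covered by another caller's same-direction calls (contained span).
Same-direction regions within 10 kb merge; regions < 3 kb or with ≥ 50 %
blacklist overlap are filtered. Gene-, cytoband-arm-level status is then
resolved with non-neutral > neutral, dominant-segment, and
amplification/deep-deletion precedence, yielding exactly one status per
(gene, sample).

**TMB.** Mutations per megabase:

```
TMB = n_nonsynonymous / L_surveyed × 10⁶
```

where `n` counts the nine high/moderate-consequence classes
(Missense_Mutation, Frame_Shift_Del, In_Frame_Ins, Frame_Shift_Ins,
Splice_Site, Nonsense_Mutation, In_Frame_Del, Nonstop_Mutation,
Translation_Start_Site) and `L` is the intersection of the callers'
surveyed regions (WGS) or the capture BED (WXS); the coding-only variant
restricts both numerator and denominator to the CDS intersection. MNVs are
decomposed into SNVs and de-duplicated first.

**Molecular subtyping.** Per tumor event, histology-specific ordered rules
over integrated evidence (consensus variants, gene/arm copy-number status,
fusions, expression z-scores and TPM, methylation-classifier calls, clinical
fields) assign WHO-2021-aligned labels for HGG (incl. DMG, PXA, IHG), ATRT,
neuroblastoma (MYCN status, TPM cutoff 140.83), craniopharyngioma,
ependymoma (10 ordered rules), LGG, medulloblastoma (WNT / SHH / Group3 /
Group4 plus SHH α/β/γ/δ), pineoblastoma, and ETMR. Methylation subclass
calls with score ≥ 0.8 are high-confidence and dominate. TP53 status
(activated / lost / none) integrates gain-of-function variants
(p.R273C/p.R248W), hotspot-database membership, biallelic-inactivation
evidence, Li-Fraumeni germline variants and an RNA inactivation-classifier
score (> 0.5).

## Worked example

Generate a synthetic cohort with planted ground truth, then subtype it and
compute TMB, all from the shell:

```
$ pedcan simulate --seed 7 -o demo
wrote 83 samples to demo

$ pedcan subtype --cohort-dir demo -o demo/subtypes.tsv
83 subtype calls -> demo/subtypes.tsv

$ head -4 demo/subtypes.tsv
tumor_event_id  molecular_subtype               confidence_basis        evidence
BS_0000_event   DMG, H3 K28                     molecular               h3_k28_variant
BS_0001_event   DMG, H3 K28                     molecular               h3_k28_variant
BS_0002_event   DMG, H3 K28                     methylation_high_conf   methylation:DMG_K27

$ pedcan consensus-snv --strelka demo/strelka2.maf.tsv --mutect demo/mutect2.maf.tsv \
    --lancet demo/lancet.maf.tsv --vardict demo/vardict.maf.tsv -o demo/consensus.maf.tsv
1608 consensus variants -> demo/consensus.maf.tsv

$ pedcan tmb --maf demo/consensus.maf.tsv --strategy WGS \
    --surveyed demo/surveyed_strelka2.bed --surveyed demo/surveyed_mutect2.bed \
    --surveyed demo/surveyed_vardict.bed --cds demo/cds.bed -o demo/tmb.tsv
TMB for 80 samples -> demo/tmb.tsv

$ head -2 demo/tmb.tsv
sample_id  strategy  n_all  denom_all_bp  tmb_all             n_coding  denom_coding_bp  tmb_coding
BS_0000    WGS       21     185000        113.51351351351352  20        100000           200.0
```

Each synthetic sample carries 20 planted coding mutations in a 100-kb toy
CDS ∩ surveyed region, so its coding TMB is exactly 20/100,000 × 10⁶ = 200
mutations/Mb; the all-mutation denominator is the 185-kb intersection of the
three surveyed-region files, and sample `BS_0000` additionally carries its
planted H3F3A K28M subtyping variant (21 total). The subtype labels match
the cohort manifest's planted truth for all 83 events.

## Layout

- `src/pedcan/` — library: `io`, `intervals`, `consensus_snv`,
  `consensus_cnv`, `focal_cn`, `tmb`, `fusion`, `tp53`, `subtyping` (rule
  tables in `rules/subtyping.yaml`), `cohort`, `simulate`, `cli`.
- `docs/methods.md` — the models, rules, defaults and limitations in detail.
- `tests/` — unit, property and end-to-end acceptance tests.
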