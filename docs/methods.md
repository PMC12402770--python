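# Methods

This note documents the models and procedures pedcan implements, the
defaults that matter, the design choices made where the procedure was
genuinely open, and what the synthetic cohorts do and do not demonstrate.

## Coordinate conventions

Variants and copy-number segments are 1-based inclusive (MAF/SEG
convention); interval sets (`GenomeIntervals`) are 0-based half-open (BED
convention). Conversion happens only at type boundaries — when a variant
position or a segment span is tested against an interval set. Chromosome
names are normalized to the `chr`-prefixed form on construction.

## Consensus SNV calling

Input is one MAF per caller (Strelka2, Mutect2, Lancet, VarDict), assumed
post-annotation and left-aligned upstream; no re-normalization is
performed. Variant identity is `(sample, chrom, pos, ref, alt)`.

1. **MNP reconstruction.** Strelka2 emits multi-nucleotide substitutions as
   consecutive SNVs. For every MNP reported by another caller, if Strelka2
   has SNVs at exactly those consecutive positions whose concatenated
   ref/alt alleles equal the MNP alleles, they are replaced by one MNP
   record. Allele-inconsistent overlaps are left unmerged with a warning.
   The reconstructed record shares the donor MNP's identity key, so the
   pair counts as two supporters — the two callers describe the same
   allele.
2. **Voting.** Retain keys supported by ≥ `min_callers_consensus` (2)
   callers, or flagged as hotspot by any caller (hotspot membership is an
   input annotation, never computed here). The consensus record's numeric
   fields come from a fixed caller precedence (strelka2 > mutect2 > lancet
   > vardict) for reproducibility.
3. **Germline filter** (matched tumor/normal): remove non-hotspot records
   with normal depth ≤ 7 **and** gnomAD AF > 0.001. The conjunction is
   deliberate: a shallow normal cannot exclude a germline allele, and a
   population-common allele is the likely explanation. Missing gnomAD AF is
   treated as 0 (kept) — the filter targets population-common variants,
   and an unobserved allele is not one.
4. **Tumor-only filter**: remove calls with zero alt reads or total depth
   < 4.

Output ordering is fixed (sample, chrom, pos, alt), so identical inputs in
any order produce byte-identical output.

## Consensus CNV calling

Caller trio per WGS sample: Control-FREEC, CNVkit and GATK when a GATK
panel of normals exists (≥ 30 male and 30 female platform-matched normals);
MantaSV-derived calls substitute for GATK otherwise. WXS samples bypass
consensus entirely and their CNVkit segments are appended unchanged.

- A per-sample caller file with more than 2,500 segments is dropped whole
  (noise heuristic).
- Rule (i): two callers' same-direction segments with reciprocal overlap
  ≥ 0.50 contribute their **intersected** span. Intersection (rather than
  union) guarantees every supporter covers the emitted span.
- Rule (ii): a segment ≥ 90 % covered by another caller's same-direction
  segments contributes its **own** span (the contained segment's
  coordinates, not the container's).
- Pooled same-direction spans that touch are unioned, then same-direction
  regions within 10,000 bp merge into one spanning region with supporters
  unioned. Finally, regions shorter than 3,000 bp, or with ≥ 50 % of their
  length in blacklist intervals (immunoglobulin / telomeric / centromeric /
  segmental-duplication regions, supplied as one BED), are removed.
- Consensus copy number is the callers' shared integer CN when all
  supporters agree and none is neutral; otherwise NA. Direction (gain/loss)
  always requires same-direction non-neutral supporters.

Neutral segments never contribute direction support. Pairwise consensus
across three callers pools all pair results and unions overlaps, which
reproduces "at least 2 of the callers" without triple-wise enumeration.

## Focal copy number

Gene status resolution per (gene, sample), in order: (1) non-neutral
status calls beat neutral ones; (2) the dominant segment is the one with
the largest base-pair overlap with the gene; (3) on a dominant tie,
amplification beats gain and deep deletion beats loss; residual ties go to
the longer, then leftmost segment (an arbitrary but deterministic
tie-break). Genes with no overlapping region are neutral. The result is
exactly one row per (gene, sample) — asserted, not merely "> 99 %".

Integer CN maps to status under a configurable ploidy model (default
ploidy 2): CN 0 → deep_deletion, CN < ploidy → loss, CN = ploidy → neutral,
ploidy < CN < ploidy + 3 → gain, CN ≥ ploidy + 3 → amplification. A region
whose integer CN equals ploidy therefore projects as neutral even if its
(merged) direction label differs. The cutoffs are explicit configuration,
not inferred caller intent.

Arm-level status: an arm is gain/loss when same-direction regions cover
≥ 50 % of its span (`arm_coverage_min`, configurable); else neutral.

## Tumor mutation burden

`TMB = n / L × scale`, default scale 10⁶ (mutations per megabase — the
community convention; set scale to 1 for a raw ratio). The numerator counts
consensus mutations whose consequence class is one of the nine
high/moderate classes; an alternate class list (`nonsynfilter_focr`,
TMB-harmonization style) is selectable. MNVs are decomposed to SNVs and
sample-level duplicates removed first, so a dinucleotide substitution
counts as two mutations exactly once.

Denominators: WGS all-mutation — the intersection of **all provided**
surveyed-region files (the file list is an input: pass Strelka2 ∩ Mutect2,
or include VarDict, as your pipeline defines "effectively surveyed");
WXS — the capture BED. Coding-only restricts numerator positions and the
denominator to surveyed ∩ CDS. A zero denominator is an error, never a
silent zero.

## Fusion prioritization

A fusion is putatively oncogenic when either partner is in any provided
gene list (kinase, oncogene, tumor suppressor, curated transcription
factor, COSMIC Cancer Gene Census, observed-in-TCGA). Retention requires
any of: called by both RNA callers; recurrent in a cancer group (≥ 3
independent patients — a conventional default, configurable); specific to
exactly one cancer group; or putatively oncogenic. Targeted-panel (DGD)
fusions pass through unfiltered. Artifact flags (read-through, homolog) are
accepted as upstream annotations, not recomputed.

## TP53 status

Activated: any somatic p.R273C or p.R248W (the activation check precedes
the loss checks; a sample meeting both is labelled activated). Lost: a
hotspot-database TP53 mutation; or ≥ 2 distinct alterations among SNV, CNV
deletion and SV disruption (two SNVs with different protein changes count
as distinct); or a single somatic variant plus an LFS-associated pathogenic
germline variant; or an LFS germline variant with RNA inactivation
classifier score strictly > 0.5 (a score of exactly 0.5 does not qualify).
The classifier itself is consumed as a precomputed score.

## Subtyping engine

One `TumorEventEvidence` per tumor event aggregates clinical fields,
consensus variants, gene/arm CN status, fusions, expression (TPM and
cohort z-scores), methylation-classifier calls, TP53 status and the RNA
medulloblastoma classifier output. Dispatch is by pathology diagnosis;
within each histology, rules evaluate in a fixed order and the first match
wins. Methylation subclass calls with score ≥ 0.8 are high-confidence and
dominate molecular evidence wherever a rule admits both.

Design choices worth knowing:

- **Rules as data.** Label vocabulary, methylation-subclass mappings,
  fusion-partner maps and gene lists live in `rules/subtyping.yaml`;
  conjunctive logic (e.g. PXA = (methylation or free-text naming) AND BRAF
  V600E AND CDKN2A/B deep deletion; the MB SHH age gates) is code that
  reads those tables. A full condition-DSL interpreter was judged
  disproportionate to the auditability it would add.
- **Overexpression** = per-cohort z-score of log2(TPM+1) ≥ 2, computed
  within RNA library-type strata when applicable; **loss-of-function** =
  classification in {Nonsense, Frame_Shift_Ins/Del, Splice_Site,
  Translation_Start_Site}; both lists configurable.
- **MB SHH β vs γ overlap** (both rules can fire on age < 5 + 2p gain):
  high-confidence methylation decides when present; otherwise β requires a
  β-specific feature (KMT2D LoF, a PTEN lesion, or 2q gain) and
  2p-gain-only young events go to γ.
- **Neuroblastoma conflicts**: genomic MYCN amplification always wins; a
  free-text "amplified" against genomic non-amplified routes to the MYCN
  TPM cutoff (≥ 140.83); with no RNA available the event is left "NBL, To
  be classified".
- **Ependymoma** "spinal"/"posterior fossa" are read from the harmonized
  CNS region field, not free text; chromosome 19 amplification for ETMR is
  read from 19p/19q arm gain. U1 snRNA hotspot status is a boolean evidence
  flag, since it has no natural MAF representation.
- The IHG eligibility check accepts an "IHG" classifier call at any score
  (the source procedure states no threshold there); all other methylation
  clauses require high confidence.

Medulloblastoma methylation-vs-RNA concordance maps subclasses to consensus
groups (MB_G34_I–IV → Group3, MB_G34_V–VIII → Group4, MB_SHH_* → SHH,
MB_WNT → WNT, MB_MYO → MYO) and counts pairs whose mapped group differs
from the RNA group. Subclass names of the form "MB_G334_*" appearing in
some renderings of the source tables are treated as typos for "MB_G34_*".

## Cohort utilities

Symbol liftover replaces outdated HGNC symbols (unknown symbols pass
through). Expression-matrix collapse drops all-zero rows, then keeps the
row with the maximum mean across samples per duplicate symbol (ties by
Ensembl-id sort). Independent-sample selection picks one biospecimen per
participant under ordered tumor-descriptor and experimental-strategy
preferences with a lexicographic biospecimen-id tie-break; it is invariant
to input order.

## Synthetic cohorts

The generator plants a complete miniature cohort on a toy reference: one
200-kb contig per chromosome the rules reference (two 100-kb arms each),
miniature gene spans for the rule-relevant genes, and a sandbox contig
(`chrS`) carrying the surveyed-region files (185-kb three-way
intersection), a 100-kb CDS window, a blacklist, and the randomly placed
variants and segments used for consensus and TMB experiments.

Per event, one scenario from an 83-case catalog plants exactly the
antecedents of one rule branch (subtyping evidence is written to **every**
caller file, i.e. noiselessly); each "To be classified" fallback has a
dedicated negative case. Sandbox variants (default 20 per WGS sample, 5 %
hotspot-flagged) and CNV segments (3 per sample) are included per caller
independently with the cohort's agreement probability and optional
breakpoint jitter. All randomness derives from a single seeded generator;
identical seeds give byte-identical output files. The manifest records the
planted truth — true variants with their caller draws, true regions,
expected TMB (noiseless case only), and the expected subtype label per
event — so tests read expectations from the manifest, not the generator's
internals.

Defaults were chosen once as plausible study conditions: agreement 1.0
(noiseless) for rule-recovery cohorts, log-normal baseline expression
(TPM ~ 10, dispersion 0.25) with planted outliers at TPM 5,000 / 0.01 so a
single outlier among ≥ 10 samples clears |z| = 2, and methylation scores
planted at the values each scenario requires.

**What passing does not show.** The toy genome has no sequence, no
realistic mutational spectrum, no breakpoint microhomology, and gene
placement is synthetic; caller errors are modelled as independent Bernoulli
drops plus Gaussian breakpoint jitter, not as the correlated, context-
dependent errors of real callers. Recovery of planted subtypes shows the
rule engine implements the rules faithfully — not that the rules are
clinically sufficient, nor how the pipeline behaves on discordant or
borderline real-world evidence beyond the planted conflict cases.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen as sufficient for
their statistical purpose: 10³ variants for the set-oracle equivalence,
500 variants at agreement 0.6 for the binomial recall check (normal
approximation to the 95 % interval), ≤ 10⁶-bp toy genomes for the per-base
CNV oracle, and the 83-scenario cohort for rule recovery. Interval
arithmetic is exact integer arithmetic throughout; TMB values are exact
rational arithmetic in floating point (numerator and denominator are also
reported as integers). Known limitation: `consensus_regions` is
O(pairs × segments²) per sample and intended for post-denoising segment
counts, not for raw caller output at tens of thousands of segments.
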