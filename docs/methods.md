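# Methods

## Model and procedure

The pipeline treats each species as one diploid individual genotyped at
base-pair resolution on a shared chromosome frame. Heterozygosity He in a
window is the count of heterozygous sites divided by the window length
(50 kb, non-overlapping); no window is excluded for missingness at this
stage, but the missing proportion is carried so that ROH calling can apply
its own cap. The per-window missing proportion is exact because QC filtering
converts failing genotypes to missing instead of deleting records, and
positions absent from the input are themselves counted as missing — a
conservative choice, since an absent position could also be
reference-homozygous.

Site QC follows the GATK-style recipe for single-sample gVCFs: keep MQ ≥ 30,
8 ≤ depth ≤ 2× mean coverage, biallelic variants only; variant sites inside
repeat-mask intervals become missing. Boundaries are inclusive on the keep
side (depth exactly 8, MQ exactly 30 and depth exactly 2× the mean are
retained), reading the removal rules as strict inequalities.

ROH: a window is low-He when He < genome-mean/5 (strict) and its missing
proportion is ≤ 0.7. Maximal runs of adjacent low windows with ≥ 10 members
spanning ≥ 500 kb become segments; both minima are enforced independently so
truncated terminal windows cannot produce sub-500-kb ten-window calls.
High-missingness windows break runs by default — the conservative reading of
"adjacent" — with an optional bridge mode that spans them without counting
them. FROH divides total segment bp by the summed length of the analysed
chromosome frame (not a full assembly) and decomposes by segment length into
half-open bins [0.5–1), [1–2), [2–5), ≥ 5 Mb; the per-class fractions sum to
the total by construction. The threshold mean is total-het/total-length,
identical to the window mean when windows tile fully.

Genetic distance: interspecific single variants per aligned bp in 10-kb
windows, on the reference species' coordinates. The denominator is aligned
bp rather than raw window length, reflecting that alignment coverage defines
where variants can be observed; windows with aligned fraction below 0.5 are
masked rather than reported with an unstable denominator
(`min_aligned_fraction=0` recovers a raw-length denominator). Per-chromosome
means are total variants over total aligned bp across unmasked windows.

Hotspots: the two metrics live on different grids, and the joint rule is
evaluated on the 50-kb grid — a window is flagged iff its normalised He
strictly exceeds 4 and at least one overlapping unmasked 10-kb window
strictly exceeds 2 in normalised distance. Flagged windows separated by
≤ 100 kb merge into regions (so a single sub-threshold window does not split
a biological region); cross-species consensus votes window-by-window on the
shared grid and requires every cohort member by default. Normalisation is
the ratio to the length-weighted chromosome mean; zero-mean chromosomes are
flagged degenerate and report 0.

Enrichment: genes are reduced to the span of their longest isoform
(gene-line fallback), classified by case-insensitive keyword matching with
fixed precedence MHC > OR > GPCR > ZNF > IMMUNE (the specific class wins
when vocabularies overlap: ORs are GPCRs, MHC genes are immune genes), and
tested family-by-family with a one-sided (greater) Fisher exact test on
(in-region × family) against all other annotated genes genome-wide, a ≥ 1-bp
overlap defining membership. BH correction is applied jointly across all
tests of a run; per-chromosome scoping and a two-sided test are available as
options. The shipped keyword lists are a synthetic stand-in for a curated
annotation vocabulary and are user-replaceable.

Macro/micro contrast: classes split at a length threshold with strict >
(an exactly-threshold chromosome is micro); the contrast is an exact
two-sided Wilcoxon rank-sum on per-chromosome values. With ties the exact
null is unavailable and the normal approximation is used; an all-identical
input reports p = 1 with direction 0.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| window size (He) | 50 000 | bp | resolves sub-chromosomal hotspots while keeping ≥ ~50 het sites per window at 1e-3 He |
| window size (distance) | 10 000 | bp | matches alignment-coverage window granularity |
| ROH threshold fraction | 1/5 | — | separates ROH windows from background at typical He |
| ROH min windows / length | 10 / 500 000 | — / bp | suppresses single-window noise calls |
| ROH missing cap | 0.7 | fraction | excludes windows whose He is undefined in practice |
| hotspot folds | 4 (He), 2 (distance) | — | strict ("exceeding") inequalities |
| merge gap | 100 000 | bp | two windows; reported in output metadata |
| min aligned fraction | 0.5 | fraction | masks windows dominated by alignment gaps |
| macro threshold | 50 000 000 | bp | reptile macro/microchromosome convention |

## The synthetic cohort

The generator emulates the *statistical* structure of a multi-species
genome comparison, not sequences: each position is independently
heterozygous with probability baseline × chromosome-class multiplier ×
hotspot multiplier × ROH factor, and independently missing; pairwise variant
tracks use the same hotspot geometry with their own multiplier, restricted
to a deterministic aligned-block pattern; genes draw their positions from a
two-component mixture (inside/outside hotspots) with family-specific
weights. Emission is sparse — informative sites plus a per-window count of
unmaterialised missing positions — with a dense mode for oracle tests.
Sampling is multinomial per window-stratum, which is exactly equivalent to
per-position categorical draws.

The scaled default represents a 7-species, 28-chromosome cohort at roughly
1/70 linear scale: 11 macrochromosomes of 2 Mb, 17 microchromosomes of
0.5 Mb, macro threshold 1 Mb, baseline He 1e-3 with micro multiplier 3,
missing rate 0.05, 2% repeat mask, 2% low-MQ sites, mean depth 30×, baseline
divergence 0.02/bp with 80% aligned fraction. One 50-kb hotspot is planted
on each of chromosomes 13, 14 and 24, shared across species, with He
multiplier 8 and distance multiplier 3. The He multiplier is 8 rather than
the calling fold of 4 because the hotspot occupies 10% of its chromosome and
inflates the chromosome mean: the expected normalised He is
8/(1 + 7·0.1) ≈ 4.7, comfortably but not trivially above the threshold,
while a multiplier of 6 would put the expectation exactly at the strict
boundary. ROH plans give one species FROH 0.20 (tracts of 2.0, 1.5, 0.8,
0.7, 0.6 and 0.5 Mb, populating three length classes), one species none, and
the rest 0.052; the within-ROH He factor is 1/50. Genes number 2000 —
denser per Mb than a real genome, deliberately, so that 2×2 tables at this
genome size remain informative — with the olfactory-receptor family (300
genes) placed at 10× density inside hotspots and all other families
unclustered as negative controls.

Window-stratum margins under these conditions are wide: a hotspot window's
normalised He is ≈ 4.7 with ≈ 3% sampling noise, ROH windows sit ~15
standard deviations below the ROH threshold, and background windows cannot
approach the 4× fold. Tract boundaries are window-aligned, so FROH recovery
is exact up to stray window misclassification, which has negligible
probability at these rates.

## What passing tests do and do not show

The generator's independence assumptions (no linkage, no mutation-rate
heterogeneity beyond the planted structure, missingness independent of
genotype, a deterministic alignment pattern, one shared coordinate frame
with no lift-over error) make recovery tests clean but idealised. Passing
them demonstrates that the window accounting, run-calling, masking,
consensus and testing machinery is correct and deterministic — not that the
thresholds would behave identically on real data with correlated noise,
reference bias, or alignment artefacts. Conversely the statistical tests
(rank-sum, Fisher) are exercised at realistic granularity: the null
calibration run confirms the macro/micro contrast rejects at ≈ the nominal
5% when no class difference is planted.

## Numerical choices and degenerate inputs

All intervals are 0-based half-open internally; VCF/GFF3 coordinates are
converted at the boundary, and one shared interval-arithmetic implementation
serves masking, ROH, hotspot and gene overlap so boundary semantics cannot
drift between stages. Normalisation guards zero-mean chromosomes with a
degenerate flag instead of dividing; all-masked chromosomes are excluded
from distance means with a warning; Fisher tables with an empty margin
report p = 1 and a degenerate flag; the sample odds ratio reports inf/0
explicitly on zero cells. Determinism comes from a single SeedSequence spawn
tree with a fixed stream layout (mask, genes, species…, tracks…), so
identical (config, seed) pairs give byte-identical files on any platform.

## Problem sizes

The shipped tests run the full pipeline on the 30.5-Mb scaled cohort
(seconds per run), brute-force oracles on ≤ 200-kb chromosomes and ≤ 60-gene
tables, and a 100-seed single-species null calibration; these sizes were
chosen so the whole suite stays interactive while every stage is exercised
at full depth.

## Known limitations

One individual per species (no multi-sample VCF handling); no model-based
(HMM) ROH calling; no statistical null for hotspot calls (the fold
thresholds are descriptive, as defined); no lift-over — all species must
share one coordinate frame; no coalescent realism in the generator; the
default family keyword lists are illustrative, not curated.
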