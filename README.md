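# divscan

Windowed genome scans of intraspecific diversity and interspecific
divergence for multi-species cohorts, built for comparative-genomics designs
like the sea-turtle clade: one reference individual per species, a shared
chromosome frame, and whole-genome-alignment variant tracks projected onto
one reference genome. The package locates *hotspots* — regions where both
within-species heterozygosity and between-species genetic distance are
elevated far above their chromosomal background — and characterises the
multicopy gene families (MHC, olfactory receptors, other GPCRs, zinc
fingers, immune genes) that cluster inside them.

## What it computes

* **Windowed heterozygosity.** From a base-pair-resolution genotype table
  (gVCF-derived), sites are QC-filtered (MQ ≥ 30, 8 ≤ depth ≤ 2× mean
  coverage, biallelic only; failing genotypes become missing, never
  dropped) and repeat-masked variants removed. He is counted in
  non-overlapping 50-kb windows with no missing-data exclusion, and
  normalised per window as He / chromosome mean.
* **ROH and FROH.** A window is low-He when He < (1/5) × genome-wide mean;
  runs of ≥ 10 adjacent low windows spanning ≥ 500 kb (windows with > 0.7
  missing data are ineligible) are runs of homozygosity. FROH = fraction of
  the chromosome frame in ROH, decomposed into [0.5–1), [1–2), [2–5), ≥ 5 Mb
  length classes.
* **Windowed genetic distance.** Interspecific single variants per aligned
  bp in 10-kb windows from a pairwise alignment track (variant positions +
  aligned-coverage intervals, as produced by halSnps / halAlignmentDepth),
  normalised by the chromosome mean; poorly aligned windows are masked.
* **Hotspots.** A 50-kb window is flagged when normalised He > 4 and an
  overlapping unmasked 10-kb window has normalised distance > 2; flagged
  windows merge into regions, and regions flagged in ≥ *k* species (default:
  all) form the cross-species consensus.
* **Gene density and family enrichment.** Genes per Mb, keyword-based
  multicopy-family classification, and a one-sided Fisher exact test per
  family on the 2×2 (in-hotspot × family) table against all other annotated
  genes, with Benjamini–Hochberg correction across tests.
* **Macro/microchromosome contrast.** Chromosomes above/below a length
  threshold (50 Mb at full scale) are compared with an exact two-sided
  Wilcoxon rank-sum test on per-chromosome values.
* **Synthetic cohorts.** A seeded generator plants all of the above
  structures — hotspot intervals, ROH tracts, chromosome-class diversity
  differences, clustered gene families — and records them in a truth ledger,
  so every stage can be validated end to end at desk scale.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/05_hotspot_consensus.py` simulates the scaled 7-species
cohort (28 chromosomes, 30.5 Mb, seed 42), runs the full analysis, and
prints:

```
consensus hotspot regions (all 7 species):
  chr13:200000-250000  species=7  max norm He=4.79  max norm dist=2.64
  chr14:300000-350000  species=7  max norm He=4.77  max norm dist=2.77
  chr24:100000-150000  species=7  max norm He=4.88  max norm dist=2.72
```

Each line is one consensus hotspot: every species' 50-kb window at that
position exceeded 4× its chromosome-mean heterozygosity while an overlapping
10-kb divergence window exceeded 2× — exactly the three regions the
generator planted, and nothing else. `examples/06_gene_family_enrichment.py`
then tests gene families inside these regions:

```
  family   in   out     odds          p          q
     MHC    1    59     0.95   6.59e-01   9.40e-01
      OR   19   281     7.12   5.40e-08   2.70e-07
    GPCR    0   150     0.00   1.00e+00   1.00e+00
     ZNF    3   197     0.84   6.96e-01   9.40e-01
  IMMUNE    2   148     0.74   7.52e-01   9.40e-01
```

The olfactory-receptor family, planted with 10× hotspot clustering, is the
only one that reaches significance (q ≪ 0.05); the unclustered control
families stay flat.

## Command-line pipeline

The same stages run file-to-file for inspection and scripting:

```sh
divscan simulate   --outdir run --seed 42
divscan filter     --outdir run
divscan windows    --outdir run
divscan roh        --outdir run
divscan divergence --outdir run
divscan hotspots   --outdir run
divscan enrich     --outdir run
divscan report     --outdir run
```

Every primary output (TSV/BED/JSON) gets a `.meta.json` sidecar with the
stage parameters, input checksums, version and seed; reruns with unchanged
inputs are byte-identical.

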