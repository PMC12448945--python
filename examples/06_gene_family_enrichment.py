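"""Gene density and multicopy-family enrichment inside consensus hotspots.

Genes are classified into families (MHC/OR/GPCR/ZNF/IMMUNE) from their
functional-annotation terms; each family is tested for over-representation
inside the hotspot regions with a one-sided Fisher exact test, BH-corrected
across the five tests.
"""

import divscan as d

cfg = d.scaled_default_config()
cohort = d.simulate_cohort(cfg, seed=42)
res = d.analyze_cohort(cohort)

density_windows, per_chrom = d.gene_density(res.genes, cohort.index)
print(f"genes: {len(res.genes)} total; "
      f"density chr1 {per_chrom['chr1']:.1f} vs chr13 {per_chrom['chr13']:.1f} genes/Mb")

print("\nfamily enrichment in consensus hotspots:")
print(f"{'family':>8s} {'in':>4s} {'out':>5s} {'odds':>8s} {'p':>10s} {'q':>10s}")
for row in res.enrichment.itertuples(index=False):
    print(f"{row.family:>8s} {row.a:>4d} {row.c:>5d} {row.odds_ratio:>8.2f} "
          f"{row.p_value:>10.2e} {row.q_value:>10.2e}")
# Only the olfactory-receptor family was planted with 10x hotspot clustering;
# its q-value falls far below 0.05 while the unclustered control families
# stay non-significant.
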