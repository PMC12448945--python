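"""End-to-end orchestration of the analysis on an in-memory cohort.

Stage order mirrors the file-based CLI: per-species site QC and masking,
50-kb heterozygosity windows with normalisation, ROH/FROH, per-pair 10-kb
divergence windows with normalisation, joint hotspot flagging, cross-species
consensus, and gene-family enrichment inside the consensus regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotation, divergence, hotspots, roh, site_io, window_stats
from .genome import GenomeIndex
from .intervals import IntervalSet
from .simulate import Cohort


@dataclass
class CohortResults:
    index: GenomeIndex
    het_windows: dict[str, pd.DataFrame]
    genome_mean_het: dict[str, float]
    roh_segments: dict[str, pd.DataFrame]
    froh: dict[str, roh.FROHReport]
    div_windows: dict[str, pd.DataFrame]
    flagged: dict[str, pd.DataFrame]
    consensus: pd.DataFrame
    chrom_summary: dict[str, pd.DataFrame]
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)


def species_track_label(cohort: Cohort, species: str) -> str:
    """Divergence track used when flagging a species' windows: its pair with
    the reference-frame species; the reference itself borrows the first pair
    (hotspot elevation is shared across pairs by construction)."""
    ref = cohort.config.species[0]
    if species == ref:
        other = cohort.config.species[1]
        return f"{ref}__{other}"
    return f"{ref}__{species}"


def analyze_cohort(
    cohort: Cohort,
    filter_params: site_io.FilterParams | None = None,
    roh_params: roh.ROHParams | None = None,
    hotspot_params: hotspots.HotspotParams | None = None,
    apply_qc: bool = True,
) -> CohortResults:
    cfg = cohort.config
    index = cohort.index
    filter_params = filter_params or site_io.FilterParams()
    roh_params = roh_params or roh.ROHParams(window_size=cfg.window_size)
    hotspot_params = hotspot_params or hotspots.HotspotParams()

    grid = window_stats.make_windows(index, size=cfg.window_size)

    het_windows, gmeans, roh_segments, froh_reports, summaries = {}, {}, {}, {}, {}
    for sp in cfg.species:
        sites = cohort.sites[sp]
        if apply_qc:
            sites = site_io.filter_sites(sites, filter_params)
            sites = site_io.apply_mask(sites, cohort.mask)
        win = window_stats.window_heterozygosity(sites, grid,
                                                 implicit_missing=cohort.implicit_missing[sp])
        win = window_stats.normalize_windows(win)
        het_windows[sp] = win
        gmean = window_stats.genome_mean_het(win)
        gmeans[sp] = gmean
        threshold = roh.roh_threshold(gmean, roh_params.het_threshold_fraction)
        segs = roh.call_roh(win, threshold, roh_params)
        roh_segments[sp] = segs
        froh_reports[sp] = roh.froh(segs, index)
        summaries[sp] = window_stats.chromosome_summary(index, win, cfg.macro_threshold)

    div_windows = {}
    for label, track in cohort.tracks.items():
        dwin = divergence.window_distance(track, index, size=cfg.div_window_size)
        div_windows[label] = divergence.normalize_distance(dwin)

    flagged = {}
    if div_windows:
        for sp in cfg.species:
            dwin = div_windows[species_track_label(cohort, sp)]
            flagged[sp] = hotspots.flag_windows(het_windows[sp], dwin, hotspot_params)
        consensus = hotspots.consensus_hotspots(flagged, hotspot_params)
    else:
        consensus = pd.DataFrame(
            columns=["chrom", "start", "end", "supporting_species",
                     "max_norm_het", "max_norm_distance"])

    results = CohortResults(
        index=index,
        het_windows=het_windows,
        genome_mean_het=gmeans,
        roh_segments=roh_segments,
        froh=froh_reports,
        div_windows=div_windows,
        flagged=flagged,
        consensus=consensus,
        chrom_summary=summaries,
    )

    if cohort.genes_gff3:
        import tempfile, os

        with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
            fh.write(cohort.genes_gff3)
            gff_path = fh.name
        try:
            genes = annotation.read_genes(gff_path)
        finally:
            os.unlink(gff_path)
        results.genes = genes
        if len(consensus):
            regions = IntervalSet.from_pairs(
                (r.chrom, r.start, r.end) for r in consensus.itertuples(index=False)
            )
            results.enrichment = annotation.enrichment_table(genes, regions)
    return results
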