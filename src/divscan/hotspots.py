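"""Diversity/divergence hotspot calling and cross-species colocalisation.

A 50-kb heterozygosity window is flagged when its normalised He strictly
exceeds ``het_fold`` (default 4x the chromosome mean) AND at least one
overlapping unmasked 10-kb divergence window strictly exceeds ``dist_fold``
(default 2x). Flagged windows are merged into regions when separated by at
most ``merge_gap``; consensus hotspots across a cohort are called by voting
on the shared 50-kb grid and merging windows supported by at least
``min_species`` species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HotspotParams:
    het_fold: float = 4.0
    dist_fold: float = 2.0
    merge_gap: int = 100_000
    min_species: int | None = None  # None = all species in the cohort

    def __post_init__(self):
        if self.het_fold <= 0 or self.dist_fold <= 0:
            raise ValueError("fold thresholds must be > 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


def flag_windows(
    het_windows: pd.DataFrame,
    div_windows: pd.DataFrame,
    params: HotspotParams = HotspotParams(),
) -> pd.DataFrame:
    """Evaluate the joint elevation rule on the heterozygosity grid.

    Adds ``max_norm_distance`` (max over overlapping unmasked divergence
    windows, NaN when none overlap) and the boolean ``flagged`` column.
    Both window sets must live on the same chromosome frame.
    """
    het_chroms = set(het_windows["chrom"])
    div_chroms = set(div_windows["chrom"])
    if not div_chroms <= het_chroms:
        unknown = sorted(div_chroms - het_chroms)[0]
        raise ValueError(f"divergence frame has unknown chromosome {unknown!r}")

    out = het_windows.copy()
    max_nd = np.full(len(out), np.nan)
    div_by_chrom = {c: g for c, g in div_windows.groupby("chrom", sort=False)}
    for chrom, grp in out.groupby("chrom", sort=False):
        d = div_by_chrom.get(chrom)
        if d is None:
            continue
        unmasked = d[~d["masked"].values]
        if unmasked.empty:
            continue
        d_start = unmasked["start"].values
        d_end = unmasked["end"].values
        d_norm = unmasked["norm_distance"].values
        for row, s, e in zip(grp.index.values, grp["start"].values, grp["end"].values):
            lo = np.searchsorted(d_end, s, side="right")
            hi = np.searchsorted(d_start, e, side="left")
            if hi > lo:
                max_nd[row] = np.nanmax(d_norm[lo:hi])
    out["max_norm_distance"] = max_nd
    with np.errstate(invalid="ignore"):
        out["flagged"] = (out["norm_het"].values > params.het_fold) & (max_nd > params.dist_fold)
    return out


def merge_flagged(flagged_windows: pd.DataFrame, merge_gap: int = 100_000) -> pd.DataFrame:
    """Merge flagged windows whose gaps are <= merge_gap into maximal regions.

    Region bounds snap to window bounds. Carries max_norm_het and
    max_norm_distance over member windows.
    """
    hits = flagged_windows[flagged_windows["flagged"]]
    regions = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start - cur["end"] <= merge_gap:
                cur["end"] = row.end
                cur["max_norm_het"] = max(cur["max_norm_het"], row.norm_het)
                cur["max_norm_distance"] = np.nanmax([cur["max_norm_distance"], row.max_norm_distance])
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "max_norm_het": float(row.norm_het),
                    "max_norm_distance": float(row.max_norm_distance),
                }
        if cur is not None:
            regions.append(cur)
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "max_norm_het", "max_norm_distance"])


def consensus_hotspots(
    per_species_flagged: dict[str, pd.DataFrame],
    params: HotspotParams = HotspotParams(),
) -> pd.DataFrame:
    """Window-grid voting across species.

    Every species' flagged table must share one window grid (same chrom,
    start, end rows in the same order). A grid window enters the consensus
    when flagged in >= min_species species (default: all); consensus windows
    are merged with merge_gap and annotated with the union of supporting
    species over member windows.
    """
    if not per_species_flagged:
        raise ValueError("empty cohort")
    species = sorted(per_species_flagged)
    min_species = params.min_species if params.min_species is not None else len(species)
    if not 1 <= min_species <= len(species):
        raise ValueError("min_species out of range")

    ref = per_species_flagged[species[0]]
    grid = ref[["chrom", "start", "end"]].reset_index(drop=True)
    votes = np.zeros(len(grid), dtype=int)
    supporters: list[set[str]] = [set() for _ in range(len(grid))]
    max_nh = np.zeros(len(grid))
    max_nd = np.full(len(grid), np.nan)
    for sp in species:
        tab = per_species_flagged[sp].reset_index(drop=True)
        if not (tab["chrom"].equals(grid["chrom"]) and tab["start"].equals(grid["start"])
                and tab["end"].equals(grid["end"])):
            raise ValueError(f"species {sp!r} window grid differs from the shared frame")
        fl = tab["flagged"].values.astype(bool)
        votes += fl
        for i in np.flatnonzero(fl):
            supporters[i].add(sp)
            max_nh[i] = max(max_nh[i], tab["norm_het"].values[i])
            max_nd[i] = np.nanmax([max_nd[i], tab["max_norm_distance"].values[i]])

    keep = votes >= min_species
    regions = []
    for chrom, grp in grid[keep].groupby("chrom", sort=False):
        idxs = grp.index.values
        cur = None
        for i in idxs:
            s, e = int(grid["start"][i]), int(grid["end"][i])
            if cur is not None and s - cur["end"] <= params.merge_gap:
                cur["end"] = e
                cur["supporting_species"] |= supporters[i]
                cur["max_norm_het"] = max(cur["max_norm_het"], max_nh[i])
                cur["max_norm_distance"] = np.nanmax([cur["max_norm_distance"], max_nd[i]])
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "supporting_species": set(supporters[i]),
                    "max_norm_het": max_nh[i],
                    "max_norm_distance": max_nd[i],
                }
        if cur is not None:
            regions.append(cur)
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "supporting_species",
                                        "max_norm_het", "max_norm_distance"])
    if len(df):
        df["supporting_species"] = df["supporting_species"].map(lambda s: ",".join(sorted(s)))
    return df


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    cols = [c for c in ("supporting_species", "max_norm_het", "max_norm_distance") if c in regions]
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            extra = "\t".join(
                f"{getattr(row, c):.4g}" if isinstance(getattr(row, c), float) else str(getattr(row, c))
                for c in cols
            )
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}" + (f"\t{extra}" if extra else "") + "\n")
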