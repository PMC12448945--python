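"""Windowed interspecific genetic distance.

Input is a pairwise alignment track — the variant positions and aligned-
coverage intervals produced by whole-genome-alignment SNP callers (for HAL
alignments, the halSnps and halAlignmentDepth outputs) projected onto one
reference species' coordinate frame. Distance in a window (default 10 kb) is
the number of interspecific single variants divided by the aligned base
pairs in the window; windows whose aligned fraction falls below a cutoff are
masked rather than reported with an unstable denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .genome import GenomeIndex
from .intervals import IntervalSet

DIVERGENCE_COLUMNS = [
    "chrom", "start", "end", "n_variants", "aligned_bp",
    "distance", "masked", "norm_distance", "degenerate",
]


@dataclass
class PairwiseTrack:
    """Variant positions + aligned intervals for one species pair, on the
    reference species' coordinates."""

    species_a: str
    species_b: str
    variants: pd.DataFrame  # columns: chrom, pos (1-based), sorted per chrom
    aligned: IntervalSet
    validated: bool = field(default=False, repr=False)

    @property
    def label(self) -> str:
        return f"{self.species_a}__{self.species_b}"

    def validate(self) -> "PairwiseTrack":
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            inside = self.aligned.contains(chrom, grp["pos"].values - 1)
            if not inside.all():
                bad = grp["pos"].values[~inside][0]
                raise ValueError(
                    f"{self.label}: variant {chrom}:{bad} outside aligned intervals"
                )
        self.validated = True
        return self

    # ------------------------------------------------------------------- I/O
    def write(self, variants_path, aligned_bed_path, chrom_order=None) -> None:
        with open(variants_path, "w") as fh:
            fh.write("chrom\tpos\n")
            for chrom, pos in zip(self.variants["chrom"], self.variants["pos"]):
                fh.write(f"{chrom}\t{pos}\n")
        self.aligned.to_bed(aligned_bed_path, chrom_order=chrom_order)

    @classmethod
    def read(cls, species_a, species_b, variants_path, aligned_bed_path) -> "PairwiseTrack":
        df = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str, "pos": np.int64})
        return cls(species_a, species_b, df, IntervalSet.from_bed(aligned_bed_path)).validate()


def window_distance(
    track: PairwiseTrack,
    index: GenomeIndex,
    size: int = 10_000,
    min_aligned_fraction: float = 0.5,
) -> pd.DataFrame:
    """Tile the genome at ``size`` and compute per-window variant density.

    distance = n_variants / aligned_bp where the window's aligned fraction is
    at least ``min_aligned_fraction``; otherwise the window is masked
    (distance NaN). ``min_aligned_fraction=0`` with a fully aligned track
    reduces to a raw-window-length denominator.
    """
    if not track.validated:
        track.validate()
    from .window_stats import make_windows

    windows = make_windows(index, size=size)[["chrom", "start", "end", "window_len"]]
    n = len(windows)
    n_variants = np.zeros(n, dtype=np.int64)
    aligned_bp = np.zeros(n, dtype=np.int64)

    win_by_chrom = {c: g for c, g in windows.groupby("chrom", sort=False)}
    for chrom, w in win_by_chrom.items():
        starts = w["start"].values
        ends = w["end"].values
        rows = w.index.values
        # variant counts
        grp = track.variants[track.variants["chrom"] == chrom]
        if len(grp):
            pos0 = grp["pos"].values - 1
            if (pos0 < 0).any() or (pos0 >= ends[-1]).any():
                raise ValueError(f"variant position outside chromosome {chrom}")
            idx = np.searchsorted(starts, pos0, side="right") - 1
            np.add.at(n_variants, rows[idx], 1)
        # aligned bp per window: clip each aligned interval to each window it spans
        for s, e in track.aligned.restricted_to(chrom):
            lo = np.searchsorted(ends, s, side="right")
            hi = np.searchsorted(starts, e, side="left")
            for k in range(lo, hi):
                aligned_bp[rows[k]] += min(e, ends[k]) - max(s, starts[k])

    wl = windows["window_len"].values
    masked = aligned_bp < min_aligned_fraction * wl
    with np.errstate(divide="ignore", invalid="ignore"):
        distance = np.where(masked, np.nan, n_variants / np.where(aligned_bp == 0, 1, aligned_bp))
    windows = windows.copy()
    windows["n_variants"] = n_variants
    windows["aligned_bp"] = aligned_bp
    windows["distance"] = distance
    windows["masked"] = masked
    return windows


def chromosome_mean_distance(windows: pd.DataFrame) -> pd.Series:
    """Per-chromosome mean distance over unmasked windows: total variants over
    total aligned bp. Chromosomes with every window masked are excluded with
    a warning."""
    out = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        ok = ~grp["masked"].values
        if not ok.any():
            warnings.warn(f"chromosome {chrom}: all windows masked; mean distance undefined")
            continue
        out[chrom] = grp["n_variants"].values[ok].sum() / grp["aligned_bp"].values[ok].sum()
    return pd.Series(out, dtype=float)


def normalize_distance(windows: pd.DataFrame, chrom_means: pd.Series | None = None) -> pd.DataFrame:
    """norm_distance = distance / chromosome mean; masked windows stay masked
    (NaN); zero-mean chromosomes get 0 with the degenerate flag."""
    if chrom_means is None:
        chrom_means = chromosome_mean_distance(windows)
    windows = windows.copy()
    means = windows["chrom"].map(chrom_means).values.astype(float)
    degenerate = means == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(degenerate, 0.0, windows["distance"].values / means)
    windows["norm_distance"] = norm
    windows["degenerate"] = degenerate
    return windows
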