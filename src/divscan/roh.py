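"""Runs of homozygosity (ROH) and the inbreeding coefficient FROH.

A 50-kb window is "low heterozygosity" when its He falls strictly below
one-fifth of the genome-wide mean; maximal runs of at least 10 adjacent low
windows spanning at least 500 kb become ROH segments. Windows with more than
70% missing data are ineligible and, by default, break runs (a bridge mode
lets them be spanned without counting). FROH is the fraction of the analysed
chromosome set covered by ROH, decomposed into half-open length classes
(0.5-1, 1-2, 2-5, >=5 Mb): long runs indicate recent shared ancestry of the
parental lineages, short runs older background relatedness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeIndex

DEFAULT_BINS = ((500_000, 1_000_000), (1_000_000, 2_000_000), (2_000_000, 5_000_000), (5_000_000, math.inf))


def _bin_label(lo: float, hi: float) -> str:
    if math.isinf(hi):
        return f">={lo / 1e6:g}Mb"
    return f"{lo / 1e6:g}-{hi / 1e6:g}Mb"


@dataclass(frozen=True)
class ROHParams:
    het_threshold_fraction: float = 0.2
    min_windows: int = 10
    min_length: int = 500_000
    max_missing_prop: float = 0.7
    window_size: int = 50_000
    bridge_high_missing: bool = False

    def __post_init__(self):
        if min(self.het_threshold_fraction, self.min_windows, self.min_length,
               self.max_missing_prop, self.window_size) <= 0:
            raise ValueError("all ROH parameters must be positive")
        if self.min_windows * self.window_size < self.min_length:
            raise ValueError("min_windows x window_size must cover min_length")


def roh_threshold(genome_mean_het: float, fraction: float = 0.2) -> float:
    """Low-He cutoff: the given fraction (default one-fifth) of the mean."""
    return fraction * genome_mean_het


def call_roh(windows: pd.DataFrame, threshold: float, params: ROHParams = ROHParams()) -> pd.DataFrame:
    """Call ROH segments from the tiled window table.

    A window is eligible-low iff ``het < threshold`` (strict) and
    ``missing_prop <= max_missing_prop``. Maximal runs of adjacent
    eligible-low windows with >= min_windows members and a span >= min_length
    are reported. High-missingness windows break runs unless
    ``bridge_high_missing`` is set, in which case they are spanned but do not
    count toward min_windows.
    """
    segments = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        starts = grp["start"].values
        ends = grp["end"].values
        if not (np.all(np.diff(starts) > 0) and np.all(starts[1:] == ends[:-1])):
            raise ValueError(f"windows on {chrom} are unsorted or do not tile")
        low = (grp["het"].values < threshold) & (grp["missing_prop"].values <= params.max_missing_prop)
        high_missing = grp["missing_prop"].values > params.max_missing_prop

        run: list[int] = []

        def flush(run):
            if len(run) >= params.min_windows:
                s, e = int(starts[run[0]]), int(ends[run[-1]])
                if e - s >= params.min_length:
                    het_vals = grp["n_het"].values[run]
                    segments.append(
                        {
                            "chrom": chrom,
                            "start": s,
                            "end": e,
                            "n_windows": len(run),
                            "mean_het": float(het_vals.sum() / (e - s)),
                        }
                    )

        for i in range(len(grp)):
            if low[i]:
                run.append(i)
            elif params.bridge_high_missing and high_missing[i] and run:
                continue  # spanned, not counted; trailing bridges trimmed by end index
            else:
                flush(run)
                run = []
        flush(run)
    return pd.DataFrame(segments, columns=["chrom", "start", "end", "n_windows", "mean_het"])


@dataclass
class FROHReport:
    froh_total: float
    froh_by_class: dict[str, float]
    denominator: int
    n_segments: int = 0
    bins: tuple = DEFAULT_BINS
    segment_bp_by_class: dict[str, int] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "froh_total": self.froh_total,
            "froh_by_class": self.froh_by_class,
            "denominator": self.denominator,
            "n_segments": self.n_segments,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def froh(segments: pd.DataFrame, index: GenomeIndex, bins=DEFAULT_BINS) -> FROHReport:
    """Genome fraction in ROH, decomposed by segment length class.

    The denominator is the summed length of the analysed chromosome frame.
    Bins are half-open [lo, hi); a catch-all lower bin is added when custom
    ROH parameters produce segments shorter than the lowest edge. The class
    fractions sum exactly to froh_total.
    """
    denom = index.total_bp
    lengths = (segments["end"] - segments["start"]).values if len(segments) else np.array([], dtype=np.int64)

    # overlap check (call_roh guarantees this; defend file-loaded input)
    if len(segments):
        for chrom, grp in segments.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError(f"overlapping ROH segments on {chrom}")

    bins = tuple(bins)
    lowest = bins[0][0]
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    bp_by_class = dict.fromkeys(labels, 0)
    if len(lengths) and (lengths < lowest).any():
        under = _bin_label(0, lowest).replace("0-", "<").replace("Mb", "Mb")
        under = f"<{lowest / 1e6:g}Mb"
        labels = [under] + labels
        bp_by_class = {under: 0, **bp_by_class}
        bins = ((0, lowest),) + bins
    for length in lengths:
        for (lo, hi), label in zip(bins, labels):
            if lo <= length < hi:
                bp_by_class[label] += int(length)
                break
    fractions = {label: bp / denom for label, bp in bp_by_class.items()}
    total = sum(fractions.values())
    return FROHReport(
        froh_total=total,
        froh_by_class=fractions,
        denominator=denom,
        n_segments=int(len(segments)),
        bins=bins,
        segment_bp_by_class=bp_by_class,
    )


def write_roh_bed(segments: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in segments.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.n_windows}\t{row.mean_het:.6g}\n")
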