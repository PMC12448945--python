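"""Non-overlapping heterozygosity windows and chromosome summaries.

Heterozygosity (He) is computed in fixed-width non-overlapping windows
(default 50 kb) without excluding windows for missing data; the missing
proportion is carried alongside so downstream stages (notably ROH calling)
can apply their own missingness rules. Normalised heterozygosity divides a
window's per-bp He by the length-weighted mean of its chromosome, which
highlights within-chromosome hotspots rather than overall diversity.

Chromosomes are split into macro- and microchromosomes at a length
threshold (50 Mb for turtle-sized genomes) and class-level contrasts use an
exact two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeIndex
from .site_io import HET, MISSING

MACRO, MICRO = "MACRO", "MICRO"

WINDOW_COLUMNS = [
    "chrom", "start", "end", "window_len", "n_het", "n_missing",
    "het", "missing_prop", "norm_het", "degenerate",
]


def make_windows(index: GenomeIndex, size: int = 50_000) -> pd.DataFrame:
    """Tile every chromosome with [0,size), [size,2*size), ...; the final
    window is truncated at the chromosome end. Every bp is covered once."""
    if size <= 0:
        raise ValueError("window size must be >= 1")
    chroms, starts, ends = [], [], []
    for name, length in index:
        s = np.arange(0, length, size, dtype=np.int64)
        e = np.minimum(s + size, length)
        chroms.extend([name] * len(s))
        starts.append(s)
        ends.append(e)
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
        }
    )
    df["window_len"] = df["end"] - df["start"]
    return df


def window_heterozygosity(
    sites: pd.DataFrame,
    windows: pd.DataFrame,
    implicit_missing: np.ndarray | None = None,
) -> pd.DataFrame:
    """Count HET sites and missing bp per window.

    Two accounting modes:

    * dense (default): the site table covers every callable position, so
      ``n_missing = window_len - (# non-missing records in the window)``;
      positions absent from the table count as missing.
    * sparse + sidecar: only informative records (HET/HOM_ALT/MISSING) are
      materialised and ``implicit_missing`` (one count per window row) gives
      the number of missing positions that were never materialised; then
      ``n_missing = implicit + (# materialised MISSING records)``.
    """
    windows = windows.copy()
    n = len(windows)
    if implicit_missing is not None:
        implicit_missing = np.asarray(implicit_missing, dtype=np.int64)
        if implicit_missing.shape != (n,):
            raise ValueError("implicit_missing must have one entry per window")

    n_het = np.zeros(n, dtype=np.int64)
    n_nonmissing = np.zeros(n, dtype=np.int64)
    n_materialised_missing = np.zeros(n, dtype=np.int64)

    win_by_chrom = {c: g for c, g in windows.groupby("chrom", sort=False)}
    for chrom, grp in sites.groupby("chrom", sort=False):
        if chrom not in win_by_chrom:
            raise ValueError(f"site on chromosome {chrom!r} outside the window frame")
        w = win_by_chrom[chrom]
        starts = w["start"].values
        chrom_end = int(w["end"].values[-1])
        pos0 = grp["pos"].values - 1
        if (pos0 < 0).any() or (pos0 >= chrom_end).any():
            raise ValueError(f"site position outside any window on {chrom}")
        idx = np.searchsorted(starts, pos0, side="right") - 1
        rows = w.index.values[idx]
        gt = grp["gt"].values
        np.add.at(n_het, rows, gt == HET)
        np.add.at(n_nonmissing, rows, gt != MISSING)
        np.add.at(n_materialised_missing, rows, gt == MISSING)

    wl = windows["window_len"].values
    if implicit_missing is None:
        n_missing = wl - n_nonmissing
    else:
        n_missing = implicit_missing + n_materialised_missing
    if (n_het + n_missing > wl).any():
        raise ValueError("window accounting exceeds window length")

    windows["n_het"] = n_het
    windows["n_missing"] = n_missing
    windows["het"] = n_het / wl
    windows["missing_prop"] = n_missing / wl
    return windows


def chromosome_mean_het(windows: pd.DataFrame, weighted: bool = True) -> pd.Series:
    """Per-chromosome mean He. Length-weighted (total het sites over
    chromosome length) by default; ``weighted=False`` averages window rates."""
    if windows.empty:
        raise ValueError("no windows")
    g = windows.groupby("chrom", sort=False)
    if weighted:
        return g["n_het"].sum() / g["window_len"].sum()
    return g["het"].mean()


def genome_mean_het(windows: pd.DataFrame) -> float:
    return float(windows["n_het"].sum() / windows["window_len"].sum())


def normalize_windows(windows: pd.DataFrame, chrom_means: pd.Series | None = None) -> pd.DataFrame:
    """Fill norm_het = het / chromosome mean; zero-mean chromosomes get
    norm_het 0 with the ``degenerate`` flag set."""
    if chrom_means is None:
        chrom_means = chromosome_mean_het(windows)
    windows = windows.copy()
    means = windows["chrom"].map(chrom_means).values.astype(float)
    degenerate = means == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(degenerate, 0.0, windows["het"].values / means)
    windows["norm_het"] = norm
    windows["degenerate"] = degenerate
    return windows


def classify_chromosomes(index: GenomeIndex, macro_threshold: int = 50_000_000) -> pd.DataFrame:
    """MACRO iff length strictly exceeds the threshold (an exactly-threshold
    chromosome is MICRO)."""
    return pd.DataFrame(
        {
            "chrom": list(index.names),
            "length": list(index.lengths),
            "size_class": [MACRO if l > macro_threshold else MICRO for l in index.lengths],
        }
    )


@dataclass(frozen=True)
class MacroMicroResult:
    statistic: float
    p_value: float
    direction: int  # sign of (micro median - macro median)
    n_macro: int
    n_micro: int


def compare_macro_micro(values: pd.Series, classes: pd.DataFrame) -> MacroMicroResult:
    """Exact two-sided Wilcoxon rank-sum contrast of per-chromosome values.

    ``values`` is indexed by chromosome name; ``classes`` comes from
    :func:`classify_chromosomes`. With ties present the exact null is not
    available and the normal approximation is used; the fully degenerate
    all-identical case reports p = 1, direction 0.
    """
    cls = classes.set_index("chrom")["size_class"]
    macro = values[cls.reindex(values.index) == MACRO].astype(float)
    micro = values[cls.reindex(values.index) == MICRO].astype(float)
    if len(macro) == 0 or len(micro) == 0:
        raise ValueError("both chromosome classes must be non-empty")
    direction = int(np.sign(np.median(micro) - np.median(macro)))
    if np.unique(np.concatenate([macro.values, micro.values])).size == 1:
        return MacroMicroResult(np.nan, 1.0, 0, len(macro), len(micro))
    has_ties = len(np.unique(np.concatenate([macro.values, micro.values]))) < len(macro) + len(micro)
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(micro.values, macro.values, alternative="two-sided", method=method)
    return MacroMicroResult(float(res.statistic), float(min(res.pvalue, 1.0)), direction,
                            len(macro), len(micro))


def chromosome_summary(
    index: GenomeIndex,
    het_windows: pd.DataFrame,
    macro_threshold: int = 50_000_000,
) -> pd.DataFrame:
    """Assemble the per-chromosome summary (mean het + size class); gene
    density and mean divergence columns are merged in by their own modules."""
    summary = classify_chromosomes(index, macro_threshold)
    means = chromosome_mean_het(het_windows)
    summary["mean_het"] = summary["chrom"].map(means)
    return summary
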