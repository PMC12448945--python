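"""Per-site genotype I/O, QC filtering and repeat masking.

The atom of the diversity analysis is one genomic position with a diploid
genotype class. Genotypes live in a pandas DataFrame with columns

    chrom   chromosome name (must be in the GenomeIndex)
    pos     1-based position
    gt      int8 genotype class: 0=HOM_REF, 1=HET, 2=HOM_ALT, -1=MISSING
    depth   read depth (float; NaN when absent)
    mq      mapping quality (float; NaN when absent)
    biallelic  bool, False for sites with >1 ALT allele

Filtering follows the GATK-style recipe used for base-pair-resolution gVCFs:
sites are kept when MQ >= 30, depth is at least 8 and at most twice the
sample's mean coverage, and variant sites are biallelic; genotypes failing any
rule are converted to missing rather than dropped, so window-level missingness
accounting stays exact. Variant sites inside repeat-masked intervals are also
set to missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeIndex
from .intervals import IntervalSet

logger = logging.getLogger(__name__)

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_GT_TO_TEXT = {HOM_REF: "0", HET: "1", HOM_ALT: "2", MISSING: "."}
_TEXT_TO_GT = {v: k for k, v in _GT_TO_TEXT.items()}

SITE_COLUMNS = ["chrom", "pos", "gt", "depth", "mq", "biallelic"]


@dataclass(frozen=True)
class FilterParams:
    """Site-level QC thresholds.

    Boundaries are inclusive on the keep side: depth exactly 8 and exactly
    2x the mean, and MQ exactly 30, are retained.
    """

    min_mq: float = 30.0
    min_depth: float = 8.0
    max_depth_factor: float = 2.0
    mean_depth: float | None = None
    require_biallelic: bool = True

    def __post_init__(self):
        if self.min_mq < 0 or self.min_depth < 0:
            raise ValueError("min_mq and min_depth must be >= 0")
        if self.max_depth_factor <= 0:
            raise ValueError("max_depth_factor must be > 0")


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "gt": pd.Series(dtype=np.int8),
            "depth": pd.Series(dtype=float),
            "mq": pd.Series(dtype=float),
            "biallelic": pd.Series(dtype=bool),
        }
    )


def make_sites(chrom, pos, gt, depth=None, mq=None, biallelic=None) -> pd.DataFrame:
    """Assemble a site table from columns, filling absent QC fields."""
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "gt": np.asarray(gt, dtype=np.int8),
            "depth": np.full(n, np.nan) if depth is None else np.asarray(depth, dtype=float),
            "mq": np.full(n, np.nan) if mq is None else np.asarray(mq, dtype=float),
            "biallelic": np.ones(n, dtype=bool) if biallelic is None else np.asarray(biallelic, dtype=bool),
        }
    )


def validate_sites(sites: pd.DataFrame, index: GenomeIndex) -> None:
    """Check positions lie on index chromosomes within their lengths."""
    for chrom, grp in sites.groupby("chrom", sort=False):
        if chrom not in index:
            raise ValueError(f"chromosome {chrom!r} not in genome index")
        if (grp["pos"].values < 1).any() or (grp["pos"].values > index.length_of(chrom)).any():
            raise ValueError(f"position outside chromosome {chrom}")


# --------------------------------------------------------------------- VCF in
def read_vcf_sites(path, index: GenomeIndex) -> pd.DataFrame:
    """Read one-sample VCF/gVCF records into a site table.

    Records on contigs absent from the index are dropped (a count is logged).
    Positions never mentioned in the file are simply absent from the table;
    downstream window accounting treats absent positions as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    if len(vcf.samples) > 1:
        raise ValueError(f"{path}: expected a single-sample VCF, found {len(vcf.samples)} samples")

    chroms, poss, gts, depths, mqs, bis = [], [], [], [], [], []
    dropped = 0
    for rec in vcf:
        if rec.CHROM not in index:
            dropped += 1
            continue
        # cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
        code = rec.gt_types[0]
        gt = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}[int(code)]
        alts = [a for a in rec.ALT if a not in (".", "<NON_REF>")]
        dp = rec.format("DP")
        depth = float(dp[0][0]) if dp is not None else float(rec.gt_depths[0])
        mq = rec.INFO.get("MQ")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        gts.append(gt)
        depths.append(depth if depth >= 0 else np.nan)
        mqs.append(float(mq) if mq is not None else np.nan)
        bis.append(len(alts) <= 1)
    if dropped:
        logger.warning("%s: dropped %d records on contigs absent from the index", path, dropped)
    if not chroms:
        return _empty_sites()
    sites = make_sites(chroms, poss, gts, depths, mqs, bis)
    validate_sites(sites, index)
    return sites


# ----------------------------------------------------------------- filtering
def filter_sites(sites: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Apply QC rules; failing genotypes become MISSING, no row is removed.

    ``mean_depth`` is taken from ``params`` or computed over non-missing
    sites with a recorded depth. QC fields that are absent (NaN) cannot fail
    their rule.
    """
    mean_depth = params.mean_depth
    if mean_depth is None:
        nonmissing = sites["gt"].values != MISSING
        depths = sites.loc[nonmissing, "depth"]
        mean_depth = float(depths.mean()) if depths.notna().any() else np.nan
    if not np.isnan(mean_depth) and mean_depth <= 0:
        raise ValueError(f"mean_depth must be > 0, got {mean_depth}")

    gt = sites["gt"].values
    depth = sites["depth"].values
    mq = sites["mq"].values
    fail = np.zeros(len(sites), dtype=bool)
    with np.errstate(invalid="ignore"):
        fail |= mq < params.min_mq
        fail |= depth < params.min_depth
        if not np.isnan(mean_depth):
            fail |= depth > params.max_depth_factor * mean_depth
    if params.require_biallelic:
        variant = (gt == HET) | (gt == HOM_ALT)
        fail |= variant & ~sites["biallelic"].values

    out = sites.copy()
    out.loc[fail, "gt"] = MISSING
    return out


def apply_mask(sites: pd.DataFrame, mask: IntervalSet) -> pd.DataFrame:
    """Set variant genotypes (HET/HOM_ALT) inside masked intervals to MISSING.

    Mask intervals are 0-based half-open; site positions are 1-based.
    Non-variant sites are untouched.
    """
    out = sites.copy()
    if not mask or out.empty:
        return out
    gt = out["gt"].values
    variant = (gt == HET) | (gt == HOM_ALT)
    if not variant.any():
        return out
    hit = np.zeros(len(out), dtype=bool)
    for chrom, rows in out.loc[variant].groupby("chrom", sort=False):
        inside = mask.contains(chrom, rows["pos"].values - 1)
        hit[rows.index[inside]] = True
    out.loc[hit, "gt"] = MISSING
    return out


# ----------------------------------------------------------------------- TSV
def write_site_table(sites: pd.DataFrame, path) -> None:
    """Write the callable table: chrom, pos (1-based), gt in {0,1,2,.}."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tgt\n")
        for chrom, pos, gt in zip(sites["chrom"], sites["pos"], sites["gt"]):
            fh.write(f"{chrom}\t{pos}\t{_GT_TO_TEXT[int(gt)]}\n")


def write_site_table_qc(sites: pd.DataFrame, path) -> None:
    """Site table with QC columns (depth, mq, biallelic) for filter input."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tgt\tdepth\tmq\tbiallelic\n")
        for row in sites.itertuples(index=False):
            depth = "." if np.isnan(row.depth) else f"{row.depth:g}"
            mq = "." if np.isnan(row.mq) else f"{row.mq:g}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t{_GT_TO_TEXT[int(row.gt)]}\t{depth}\t{mq}\t"
                f"{int(row.biallelic)}\n"
            )


def read_site_table_qc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64, "gt": str},
                     keep_default_na=False, na_values={"depth": ["."], "mq": ["."]})
    gt = df["gt"].map(_TEXT_TO_GT)
    if gt.isna().any():
        bad = df.loc[gt.isna(), "gt"].iloc[0]
        raise ValueError(f"{path}: bad genotype code {bad!r}")
    return make_sites(
        df["chrom"].values, df["pos"].values, gt.astype(np.int8).values,
        depth=df["depth"].astype(float).values, mq=df["mq"].astype(float).values,
        biallelic=df["biallelic"].astype(bool).values,
    )


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64, "gt": str})
    gt = df["gt"].map(_TEXT_TO_GT)
    if gt.isna().any():
        bad = df.loc[gt.isna(), "gt"].iloc[0]
        raise ValueError(f"{path}: bad genotype code {bad!r}")
    return make_sites(df["chrom"].values, df["pos"].values, gt.astype(np.int8).values)
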