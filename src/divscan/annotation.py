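"""Gene density, multicopy gene-family classification and enrichment.

Genes are reduced to one interval each (the span of the longest isoform) and
classified into multicopy families — MHC, olfactory receptor (OR), other
G-protein-coupled receptor (GPCR), zinc finger (ZNF), other immune-related
(IMMUNE) — by case-insensitive keyword matching against their functional
annotation terms, with a fixed precedence (MHC > OR > GPCR > ZNF > IMMUNE;
ORs are GPCRs and MHC genes are immune genes, so the more specific class
wins). Unmatched genes are OTHER.

Family enrichment inside a region set (e.g. consensus hotspots) is a
one-sided Fisher exact test on the 2x2 table (in-region x family) against
all other annotated genes, with Benjamini-Hochberg correction applied
jointly across the tests of a run.

The shipped keyword lists are a synthetic stand-in for a curated
database-backed vocabulary and are user-replaceable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeIndex
from .intervals import IntervalSet

FAMILY_PRECEDENCE = ("MHC", "OR", "GPCR", "ZNF", "IMMUNE")
OTHER = "OTHER"

DEFAULT_FAMILY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "MHC": ("major histocompatibility", "histocompatibility antigen", "mhc class"),
    "OR": ("olfactory receptor", "odorant receptor"),
    "GPCR": ("g protein-coupled receptor", "g-protein coupled receptor",
             "g-protein-coupled receptor", "7 transmembrane receptor"),
    "ZNF": ("zinc finger", "zinc-finger"),
    "IMMUNE": ("immunoglobulin", "interleukin", "t-cell receptor", "interferon",
               "tumor necrosis factor", "toll-like receptor", "complement component"),
}

GENE_COLUMNS = ["id", "chrom", "start", "end", "terms", "family"]


# ------------------------------------------------------------------ GFF3 I/O
def _validate_gff3(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: expected 9 fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: bad coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: bad coordinate range")


def read_genes(
    path,
    terms: dict[str, list[str]] | None = None,
    term_attribute: str = "functional_terms",
    keywords: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Read GFF3 genes, keeping the longest isoform span per gene.

    Functional terms come from the given GFF3 attribute (semicolon-safe,
    comma-separated) or from an external ``terms`` mapping (gene id -> list
    of term strings), which takes precedence. Coordinates are converted to
    0-based half-open. Genes without mRNA/transcript children fall back to
    the gene-line span.
    """
    import gffutils

    _validate_gff3(path)
    try:
        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)
    except gffutils.exceptions.EmptyInputError:
        return pd.DataFrame(columns=GENE_COLUMNS)
    if keywords is None:
        keywords = DEFAULT_FAMILY_KEYWORDS
    records = []
    for gene in db.features_of_type("gene"):
        spans = [
            (child.start, child.end)
            for child in db.children(gene, featuretype=("mRNA", "transcript"))
        ]
        if spans:
            start, end = max(spans, key=lambda se: se[1] - se[0])
        else:
            start, end = gene.start, gene.end
        gid = gene.attributes.get("ID", [gene.id])[0]
        if terms is not None and gid in terms:
            gene_terms = tuple(terms[gid])
        else:
            raw = gene.attributes.get(term_attribute, [])
            gene_terms = tuple(t.strip() for chunk in raw for t in chunk.split(",") if t.strip())
        records.append(
            {
                "id": gid,
                "chrom": gene.seqid,
                "start": start - 1,
                "end": end,
                "terms": gene_terms,
                "family": classify_family(gene_terms, keywords),
            }
        )
    return pd.DataFrame(records, columns=GENE_COLUMNS)


def read_terms_tsv(path) -> dict[str, list[str]]:
    """Two-column TSV: gene id, term string (repeated ids accumulate)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            out.setdefault(fields[0], []).append(fields[1])
    return out


# -------------------------------------------------------------- family calls
def classify_family(terms, keywords: dict[str, tuple[str, ...]] | None = None) -> str:
    """First matching family in precedence order wins; no match -> OTHER."""
    if keywords is None:
        keywords = DEFAULT_FAMILY_KEYWORDS
    if not keywords:
        raise ValueError("empty family keyword configuration")
    blob = " | ".join(terms).lower()
    for family in FAMILY_PRECEDENCE:
        for kw in keywords.get(family, ()):
            if kw.lower() in blob:
                return family
    return OTHER


# -------------------------------------------------------------- gene density
def gene_density(genes: pd.DataFrame, index: GenomeIndex, window: int = 1_000_000):
    """Genes per Mb.

    Returns (window_counts, per_chromosome) where window_counts tiles each
    chromosome at ``window`` bp with the number of gene starts per window,
    and per_chromosome gives n_genes / (length/1e6).
    """
    from .window_stats import make_windows

    wins = make_windows(index, size=window)[["chrom", "start", "end", "window_len"]]
    counts = np.zeros(len(wins), dtype=np.int64)
    win_by_chrom = {c: g for c, g in wins.groupby("chrom", sort=False)}
    per_chrom_n = dict.fromkeys(index.names, 0)
    for chrom, grp in genes.groupby("chrom", sort=False):
        if chrom not in win_by_chrom:
            raise ValueError(f"gene on chromosome {chrom!r} not in index")
        w = win_by_chrom[chrom]
        idx = np.searchsorted(w["start"].values, grp["start"].values, side="right") - 1
        np.add.at(counts, w.index.values[idx], 1)
        per_chrom_n[chrom] = len(grp)
    wins = wins.copy()
    wins["n_genes"] = counts
    per_chrom = pd.Series(
        {name: per_chrom_n[name] / (index.length_of(name) / 1e6) for name in index.names},
        dtype=float,
    )
    return wins, per_chrom


# --------------------------------------------------------------- enrichment
def _genes_in_regions(genes: pd.DataFrame, regions: IntervalSet) -> np.ndarray:
    """Boolean: gene interval overlaps any region by >= 1 bp."""
    hit = np.zeros(len(genes), dtype=bool)
    for chrom, grp in genes.groupby("chrom", sort=False):
        arr = regions.restricted_to(chrom)
        if arr.size == 0:
            continue
        s = grp["start"].values
        e = grp["end"].values
        lo = np.searchsorted(arr[:, 1], s, side="right")
        hi = np.searchsorted(arr[:, 0], e, side="left")
        hit[grp.index.values[hi > lo]] = True
    return hit


def fisher_enrichment(
    genes: pd.DataFrame,
    regions: IntervalSet,
    families=FAMILY_PRECEDENCE,
    region_set: str = "hotspots",
    alternative: str = "greater",
) -> pd.DataFrame:
    """One Fisher exact test per family on the (in-region x family) table.

    a = in-region & family, b = in-region & other, c = out & family,
    d = out & other. The odds ratio is the sample odds ratio a*d / b*c
    (inf when b*c = 0 and a*d > 0). Degenerate tables (a margin of zero)
    report p = 1 with the ``degenerate`` flag.
    """
    if len(genes) == 0:
        raise ValueError("no genes")
    in_region = _genes_in_regions(genes, regions)
    fam = genes["family"].values
    rows = []
    for family in families:
        is_fam = fam == family
        a = int((in_region & is_fam).sum())
        b = int((in_region & ~is_fam).sum())
        c = int((~in_region & is_fam).sum())
        d = int((~in_region & ~is_fam).sum())
        degenerate = (a + c == 0) or (c + d == 0) or (a + b == 0)
        if degenerate:
            p = 1.0
        else:
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        if b * c > 0:
            odds = (a * d) / (b * c)
        else:
            odds = np.inf if a * d > 0 else 0.0
        rows.append(
            {
                "region_set": region_set, "family": family,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds, "p_value": float(p), "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(genes, regions, families=FAMILY_PRECEDENCE, region_set="hotspots",
                     alternative="greater") -> pd.DataFrame:
    """Fisher tests plus joint BH correction across all tests of the run."""
    tab = fisher_enrichment(genes, regions, families, region_set, alternative)
    tab["q_value"] = bh_correct(tab["p_value"].values)
    return tab
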