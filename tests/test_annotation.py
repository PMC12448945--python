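"""Gene reading, family classification, density, Fisher and BH behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

import divscan as d
from divscan.annotation import OTHER, bh_correct, fisher_enrichment, read_terms_tsv

GFF_HEADER = "##gff-version 3\n##sequence-region c1 1 100000\n"


def _write_gff(tmp_path, body):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF_HEADER + body)
    return p


def test_read_genes_keeps_longest_isoform(tmp_path):
    body = (
        "c1\tsrc\tgene\t1001\t9000\t.\t+\t.\tID=g1;functional_terms=olfactory receptor 5\n"
        "c1\tsrc\tmRNA\t1001\t4000\t.\t+\t.\tID=g1.t1;Parent=g1\n"
        "c1\tsrc\tmRNA\t2001\t7000\t.\t+\t.\tID=g1.t2;Parent=g1\n"
        "c1\tsrc\tgene\t20001\t22000\t.\t+\t.\tID=g2;functional_terms=hypothetical protein\n"
    )
    genes = d.read_genes(_write_gff(tmp_path, body))
    g1 = genes.set_index("id").loc["g1"]
    # longest isoform (5 kb span) wins over the 3-kb one; 0-based half-open
    assert (g1.start, g1.end) == (2000, 7000)
    assert g1.family == "OR"
    g2 = genes.set_index("id").loc["g2"]
    assert (g2.start, g2.end) == (20000, 22000)  # gene-line fallback
    assert g2.family == OTHER


def test_read_genes_empty_and_malformed(tmp_path):
    assert len(d.read_genes(_write_gff(tmp_path, ""))) == 0
    bad = tmp_path / "bad.gff3"
    bad.write_text(GFF_HEADER + "c1\tsrc\tgene\tx\t10\t.\t+\t.\tID=g1\n")
    with pytest.raises(ValueError, match="line 3"):
        d.read_genes(bad)


def test_external_terms_tsv_takes_precedence(tmp_path):
    body = "c1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;functional_terms=hypothetical protein\n"
    path = _write_gff(tmp_path, body)
    terms_path = tmp_path / "terms.tsv"
    terms_path.write_text("g1\tzinc finger protein 42\ng1\tDNA binding\n")
    genes = d.read_genes(path, terms=read_terms_tsv(terms_path))
    assert genes.family.iloc[0] == "ZNF"
    assert genes.terms.iloc[0] == ("zinc finger protein 42", "DNA binding")


@pytest.mark.parametrize(
    "terms,expected",
    [
        (("olfactory receptor 51E2",), "OR"),
        (("G protein-coupled receptor 12", "olfactory receptor 4"), "OR"),  # OR beats GPCR
        (("major histocompatibility complex class II", "immunoglobulin domain"), "MHC"),
        (("interleukin 6 receptor",), "IMMUNE"),
        (("Zinc-Finger protein",), "ZNF"),
        (("kinesin motor protein",), OTHER),
        ((), OTHER),
    ],
)
def test_classify_family_precedence(terms, expected):
    assert d.classify_family(terms) == expected


def test_classify_family_rejects_empty_config():
    with pytest.raises(ValueError):
        d.classify_family(("anything",), keywords={})


def test_gene_density_counts_and_per_chromosome():
    idx = d.GenomeIndex(("c1", "c2"), (2_000_000, 1_000_000))
    rng = np.random.default_rng(9)
    starts = np.sort(rng.integers(0, 2_000_000, size=150))
    genes = pd.DataFrame({
        "id": [f"g{i}" for i in range(150)],
        "chrom": ["c1"] * 150,
        "start": starts,
        "end": starts + 1_000,
        "terms": [()] * 150,
        "family": [OTHER] * 150,
    })
    wins, per_chrom = d.gene_density(genes, idx)
    assert per_chrom["c1"] == pytest.approx(75.0)  # 150 genes / 2 Mb
    assert per_chrom["c2"] == 0.0
    # window counts sum to the chromosome gene count (oracle recount)
    assert wins[wins.chrom == "c1"].n_genes.sum() == 150
    for row in wins[wins.chrom == "c1"].itertuples(index=False):
        assert row.n_genes == ((starts >= row.start) & (starts < row.end)).sum()


def _gene_table(families, in_region_flags, region_end=1_000):
    rows = []
    for i, (fam, inside) in enumerate(zip(families, in_region_flags)):
        start = 100 + i * 10 if inside else region_end + 100 + i * 10
        rows.append({"id": f"g{i}", "chrom": "c1", "start": start, "end": start + 5,
                     "terms": (), "family": fam})
    return pd.DataFrame(rows)


def test_fisher_example_and_enumeration_oracle():
    regions = d.IntervalSet.from_pairs([("c1", 0, 1_000)])
    genes = _gene_table(["OR"] * 4 + [OTHER] * 4,
                        [True, True, True, False, True, False, False, False])
    tab = fisher_enrichment(genes, regions, families=("OR",))
    row = tab.iloc[0]
    assert (row.a, row.b, row.c, row.d) == (3, 1, 1, 3)
    assert row.p_value == pytest.approx(17 / 70)
    assert row.odds_ratio == pytest.approx(9.0)

    # randomized tables vs hypergeometric tail enumeration, N <= 60
    rng = np.random.default_rng(10)
    for _ in range(30):
        N = int(rng.integers(4, 61))
        K = int(rng.integers(1, N))          # family size
        n = int(rng.integers(1, N))          # genes in region
        fams = ["OR"] * K + [OTHER] * (N - K)
        inside = rng.permutation([True] * n + [False] * (N - n))
        genes = _gene_table(fams, inside)
        a = int(sum(1 for f, i in zip(fams, inside) if f == "OR" and i))
        p_oracle = sum(
            math.comb(K, x) * math.comb(N - K, n - x)
            for x in range(a, min(K, n) + 1)
            if n - x <= N - K
        ) / math.comb(N, n)
        row = fisher_enrichment(genes, regions, families=("OR",)).iloc[0]
        assert row.p_value == pytest.approx(p_oracle, rel=1e-9)


def test_fisher_degenerate_tables():
    regions = d.IntervalSet.from_pairs([("c1", 0, 1_000)])
    # family absent everywhere: a = c = 0
    genes = _gene_table([OTHER] * 6, [True, True, False, False, False, False])
    row = fisher_enrichment(genes, regions, families=("OR",)).iloc[0]
    assert row.p_value == 1.0 and row.degenerate
    # all genes inside the region: c = d = 0
    genes2 = _gene_table(["OR", OTHER], [True, True])
    row2 = fisher_enrichment(genes2, regions, families=("OR",)).iloc[0]
    assert row2.p_value == 1.0 and row2.degenerate
    with pytest.raises(ValueError):
        fisher_enrichment(genes2.iloc[:0], regions)


def test_gene_in_region_needs_one_bp_overlap():
    regions = d.IntervalSet.from_pairs([("c1", 1_000, 2_000)])
    genes = pd.DataFrame({
        "id": ["touch", "abut"],
        "chrom": ["c1", "c1"],
        "start": [995, 2_000],
        "end": [1_001, 2_100],   # [995,1001) overlaps by 1 bp; [2000,2100) abuts
        "terms": [(), ()],
        "family": ["OR", "OR"],
    })
    tab = fisher_enrichment(genes, regions, families=("OR",))
    assert tab.iloc[0].a == 1  # the touching gene only


def test_bh_step_up_examples_and_monotonicity():
    assert bh_correct([0.03]) == pytest.approx([0.03])
    assert bh_correct([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    rng = np.random.default_rng(11)
    p = rng.uniform(size=25)
    q = bh_correct(p)
    assert (q <= 1).all() and (q >= p).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()  # non-decreasing in sorted-p order
    # hand step-up trace oracle
    m = len(p)
    ranked = np.sort(p)
    q_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    assert np.allclose(np.sort(q), np.minimum(q_sorted, 1))
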