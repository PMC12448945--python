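"""Window tiling, heterozygosity accounting and the macro/micro contrast."""

import itertools

import numpy as np
import pandas as pd
import pytest

import divscan as d
from divscan.window_stats import MACRO, MICRO


def test_make_windows_tiles_with_truncation():
    idx = d.GenomeIndex(("c1", "c2"), (120_000, 50_000))
    w = d.make_windows(idx, size=50_000)
    c1 = w[w.chrom == "c1"]
    assert list(zip(c1.start, c1.end)) == [(0, 50_000), (50_000, 100_000), (100_000, 120_000)]
    assert len(w[w.chrom == "c2"]) == 1
    # tiling invariant: lengths sum to chromosome length, no overlap
    for name, length in idx:
        grp = w[w.chrom == name]
        assert grp.window_len.sum() == length
        assert (grp.start.values[1:] == grp.end.values[:-1]).all()


def test_make_windows_rejects_bad_size():
    idx = d.GenomeIndex(("c1",), (100,))
    with pytest.raises(ValueError):
        d.make_windows(idx, size=0)
    with pytest.raises(ValueError):
        d.GenomeIndex(("c1",), (0,))


def test_window_het_matches_per_site_oracle():
    """Counts per window equal a brute-force per-position scan (dense table)."""
    rng = np.random.default_rng(3)
    length, size = 200_000, 50_000
    idx = d.GenomeIndex(("c1",), (length,))
    pos = np.arange(1, length + 1)
    gt = rng.choice([d.HOM_REF, d.HET, d.HOM_ALT, d.MISSING], size=length,
                    p=[0.8, 0.1, 0.05, 0.05])
    sites = d.make_sites(["c1"] * length, pos, gt)
    win = d.window_heterozygosity(sites, d.make_windows(idx, size))

    for row in win.itertuples(index=False):
        n_het = n_nonmiss = 0
        for p, g in zip(pos, gt):  # brute force
            if row.start < p <= row.end:
                n_het += g == d.HET
                n_nonmiss += g != d.MISSING
        assert row.n_het == n_het
        assert row.n_missing == row.window_len - n_nonmiss
    assert win.n_het.sum() == (gt == d.HET).sum()


def test_window_het_sparse_sidecar_and_edge_cases():
    idx = d.GenomeIndex(("c1",), (100_000,))
    grid = d.make_windows(idx, 50_000)
    # 25 HET sites in the first window, everything callable
    sites = d.make_sites(["c1"] * 25, np.arange(1, 26) * 100, [d.HET] * 25)
    win = d.window_heterozygosity(sites, grid, implicit_missing=np.array([0, 0]))
    assert win.het.iloc[0] == pytest.approx(5.0e-4)
    assert win.missing_prop.iloc[0] == 0
    # fully missing window via sidecar
    win2 = d.window_heterozygosity(sites.iloc[:0], grid, implicit_missing=np.array([50_000, 0]))
    assert win2.het.iloc[0] == 0 and win2.missing_prop.iloc[0] == 1.0


def test_window_het_rejects_out_of_frame_sites():
    idx = d.GenomeIndex(("c1",), (100_000,))
    grid = d.make_windows(idx, 50_000)
    with pytest.raises(ValueError):
        d.window_heterozygosity(d.make_sites(["cX"], [10], [d.HET]), grid)
    with pytest.raises(ValueError):
        d.window_heterozygosity(d.make_sites(["c1"], [100_001], [d.HET]), grid)


def _windows_from_counts(chrom_lengths, size, counts):
    idx = d.GenomeIndex(tuple(chrom_lengths.keys()), tuple(chrom_lengths.values()))
    w = d.make_windows(idx, size)
    w["n_het"] = counts
    w["n_missing"] = 0
    w["het"] = w.n_het / w.window_len
    w["missing_prop"] = 0.0
    return w


def test_chromosome_and_genome_means_are_length_weighted():
    w = _windows_from_counts({"c1": 150_000, "c2": 50_000}, 50_000, [10, 20, 30, 5])
    means = d.chromosome_mean_het(w)
    assert means["c1"] == pytest.approx(60 / 150_000)
    assert means["c2"] == pytest.approx(5 / 50_000)
    assert d.genome_mean_het(w) == pytest.approx(65 / 200_000)
    # truncated final window counted at true length equals the site-count oracle
    w2 = _windows_from_counts({"c1": 120_000}, 50_000, [10, 20, 6])
    assert d.chromosome_mean_het(w2)["c1"] == pytest.approx(36 / 120_000)
    # permutation invariance of the genome mean
    assert d.genome_mean_het(w.iloc[::-1]) == pytest.approx(d.genome_mean_het(w))


def test_normalize_round_trips_and_flags_degenerate():
    w = _windows_from_counts({"c1": 150_000, "c2": 100_000}, 50_000, [10, 20, 30, 0, 0])
    out = d.normalize_windows(w)
    means = d.chromosome_mean_het(w)
    recovered = out.norm_het * out.chrom.map(means)
    assert np.allclose(recovered, out.het, atol=1e-12)
    c2 = out[out.chrom == "c2"]
    assert (c2.norm_het == 0).all() and c2.degenerate.all()
    assert not out[out.chrom == "c1"].degenerate.any()
    mid = out[(out.chrom == "c1") & (out.start == 50_000)]
    assert mid.norm_het.iloc[0] == pytest.approx((20 / 50_000) / means["c1"])


def test_classify_chromosomes_strict_threshold():
    idx = d.GenomeIndex(("a", "b", "c"), (50_000_001, 50_000_000, 1_000))
    cls = d.classify_chromosomes(idx).set_index("chrom")["size_class"]
    assert cls["a"] == MACRO and cls["b"] == MICRO and cls["c"] == MICRO
    scaled = d.classify_chromosomes(d.GenomeIndex(("a",), (1_000_001,)), macro_threshold=1_000_000)
    assert scaled["size_class"].iloc[0] == MACRO


def _exact_two_sided_p(macro, micro):
    """Enumeration oracle: all assignments of the pooled values into groups."""
    from scipy.stats import rankdata

    pooled = np.array(macro + micro, dtype=float)
    n_micro = len(micro)
    ranks = rankdata(pooled)

    def u_stat(micro_idx):
        r = ranks[list(micro_idx)].sum()
        return r - n_micro * (n_micro + 1) / 2

    obs = u_stat(range(len(macro), len(pooled)))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n_micro)]
    us = np.array(us)
    p = 2 * min((us <= obs).mean(), (us >= obs).mean())
    return min(p, 1.0)


def test_compare_macro_micro_matches_enumeration():
    idx = d.GenomeIndex(("m1", "m2", "u1", "u2"), (200, 200, 50, 50))
    cls = d.classify_chromosomes(idx, macro_threshold=100)
    vals = pd.Series({"m1": 1.0, "m2": 2.0, "u1": 3.0, "u2": 4.0})
    res = d.compare_macro_micro(vals, cls)
    assert res.p_value == pytest.approx(2 / 6)
    assert res.direction > 0
    # randomized instances with n <= 10, no ties
    rng = np.random.default_rng(4)
    for _ in range(20):
        n_macro = int(rng.integers(2, 5))
        n_micro = int(rng.integers(2, 5))
        vals = rng.permutation(np.arange(1.0, n_macro + n_micro + 1))
        names = [f"M{i}" for i in range(n_macro)] + [f"U{i}" for i in range(n_micro)]
        idx = d.GenomeIndex(tuple(names), tuple([200] * n_macro + [50] * n_micro))
        cls = d.classify_chromosomes(idx, macro_threshold=100)
        series = pd.Series(dict(zip(names, vals)))
        res = d.compare_macro_micro(series, cls)
        oracle = _exact_two_sided_p(list(vals[:n_macro]), list(vals[n_macro:]))
        assert res.p_value == pytest.approx(oracle, rel=1e-9)


def test_compare_macro_micro_degenerate_and_empty():
    idx = d.GenomeIndex(("m1", "u1"), (200, 50))
    cls = d.classify_chromosomes(idx, macro_threshold=100)
    res = d.compare_macro_micro(pd.Series({"m1": 1.0, "u1": 1.0}), cls)
    assert res.p_value == 1.0 and res.direction == 0
    all_macro = d.classify_chromosomes(d.GenomeIndex(("m1", "m2"), (200, 200)), 100)
    with pytest.raises(ValueError):
        d.compare_macro_micro(pd.Series({"m1": 1.0, "m2": 2.0}), all_macro)
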