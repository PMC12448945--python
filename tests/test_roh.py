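"""ROH run-calling rules and the FROH length-class decomposition."""

import numpy as np
import pytest

import divscan as d
from divscan.roh import ROHParams


def _window_table(chrom_len, size, het_rates, missing_props=None):
    idx = d.GenomeIndex(("c1",), (chrom_len,))
    w = d.make_windows(idx, size)
    assert len(w) == len(het_rates)
    w["het"] = np.asarray(het_rates, dtype=float)
    w["n_het"] = (w.het * w.window_len).round().astype(int)
    w["missing_prop"] = 0.0 if missing_props is None else np.asarray(missing_props, dtype=float)
    w["n_missing"] = (w.missing_prop * w.window_len).round().astype(int)
    return w


SIZE = 50_000
LOW, HIGH = 1e-5, 2e-3
THRESHOLD = 3e-4  # one fifth of a 1.5e-3 genome mean


def test_roh_threshold_rule():
    assert d.roh_threshold(1.5e-3) == pytest.approx(3.0e-4)
    assert d.roh_threshold(0.0) == 0.0
    assert d.roh_threshold(1e-3, fraction=1.0) == pytest.approx(1e-3)


def test_ten_low_windows_make_one_roh_nine_do_not():
    ten = _window_table(12 * SIZE, SIZE, [LOW] * 10 + [HIGH] * 2)
    segs = d.call_roh(ten, THRESHOLD)
    assert len(segs) == 1
    assert (segs.start.iloc[0], segs.end.iloc[0], segs.n_windows.iloc[0]) == (0, 500_000, 10)

    nine = _window_table(12 * SIZE, SIZE, [LOW] * 9 + [HIGH] * 3)
    assert len(d.call_roh(nine, THRESHOLD)) == 0


def test_high_missingness_window_splits_run():
    rates = [LOW] * 22
    missing = [0.0] * 22
    missing[10] = 0.8  # window 11 of 22
    w = _window_table(22 * SIZE, SIZE, rates, missing)
    segs = d.call_roh(w, THRESHOLD)
    assert segs.n_windows.tolist() == [10, 11]
    # boundary: missing_prop exactly 0.7 is still eligible
    missing[10] = 0.7
    w2 = _window_table(22 * SIZE, SIZE, rates, missing)
    assert d.call_roh(w2, THRESHOLD).n_windows.tolist() == [22]


def test_het_exactly_at_threshold_is_not_low():
    w = _window_table(10 * SIZE, SIZE, [THRESHOLD] * 10)
    assert len(d.call_roh(w, THRESHOLD)) == 0


def test_bridge_mode_spans_high_missing_windows():
    rates = [LOW] * 21
    missing = [0.0] * 21
    missing[10] = 0.9
    w = _window_table(21 * SIZE, SIZE, rates, missing)
    params = ROHParams(bridge_high_missing=True)
    segs = d.call_roh(w, THRESHOLD, params)
    assert len(segs) == 1
    assert segs.n_windows.iloc[0] == 20  # bridged window not counted
    assert (segs.start.iloc[0], segs.end.iloc[0]) == (0, 21 * SIZE)


def test_call_roh_matches_maximal_run_oracle():
    """Exhaustive maximal-run scan oracle on random small chromosomes."""
    rng = np.random.default_rng(5)
    params = ROHParams(min_windows=3, min_length=150_000)
    for _ in range(30):
        n = int(rng.integers(5, 50))
        rates = rng.choice([LOW, HIGH], size=n)
        missing = rng.choice([0.0, 0.8], size=n, p=[0.9, 0.1])
        w = _window_table(n * SIZE, SIZE, rates, missing)
        segs = d.call_roh(w, THRESHOLD, params)

        low = (rates < THRESHOLD) & (missing <= params.max_missing_prop)
        expected = []
        i = 0
        while i < n:
            if low[i]:
                j = i
                while j + 1 < n and low[j + 1]:
                    j += 1
                count = j - i + 1
                if count >= params.min_windows and count * SIZE >= params.min_length:
                    expected.append((i * SIZE, (j + 1) * SIZE))
                i = j + 1
            else:
                i += 1
        assert list(zip(segs.start, segs.end)) == expected


def test_threshold_monotonicity_of_total_roh_bp():
    rng = np.random.default_rng(6)
    rates = rng.uniform(0, 1e-3, size=60)
    w = _window_table(60 * SIZE, SIZE, rates)
    totals = []
    for frac in (0.1, 0.3, 0.6, 1.0):
        segs = d.call_roh(w, 1e-3 * frac)
        totals.append(int((segs.end - segs.start).sum()) if len(segs) else 0)
    assert totals == sorted(totals)


def test_froh_arithmetic_and_class_sum():
    idx = d.GenomeIndex(("c1",), (10_000_000,))
    import pandas as pd

    segs = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 1_000_000],
                         "end": [600_000, 2_500_000], "n_windows": [12, 30],
                         "mean_het": [0.0, 0.0]})
    rep = d.froh(segs, idx)
    assert rep.froh_total == pytest.approx(0.21)
    assert rep.froh_by_class["0.5-1Mb"] == pytest.approx(0.06)
    assert rep.froh_by_class["1-2Mb"] == pytest.approx(0.15)
    assert rep.froh_by_class["2-5Mb"] == 0.0
    assert sum(rep.froh_by_class.values()) == rep.froh_total  # exact identity

    empty = d.froh(segs.iloc[:0], idx)
    assert empty.froh_total == 0.0 and empty.n_segments == 0

    overlapping = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 500_000],
                                "end": [600_000, 1_200_000], "n_windows": [12, 14],
                                "mean_het": [0.0, 0.0]})
    with pytest.raises(ValueError):
        d.froh(overlapping, idx)


def test_roh_params_validation():
    with pytest.raises(ValueError):
        ROHParams(min_windows=5, min_length=500_000, window_size=50_000)
    with pytest.raises(ValueError):
        ROHParams(het_threshold_fraction=0)


def test_call_roh_rejects_nontiling_windows():
    w = _window_table(10 * SIZE, SIZE, [LOW] * 10)
    broken = w.drop(index=3)
    with pytest.raises(ValueError):
        d.call_roh(broken, THRESHOLD)
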