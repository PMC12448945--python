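"""Exact interval arithmetic on 0-based half-open genomic coordinates.

Every stage of the pipeline (masking, ROH segments, hotspot regions,
gene/region overlap) funnels its interval work through :class:`IntervalSet`
so that boundary semantics are identical everywhere: intervals are
``[start, end)`` with ``start < end``, sorted and non-overlapping per
chromosome. BED3 input/output is strand-agnostic.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np

__all__ = ["IntervalSet"]


def _normalize(pairs: np.ndarray, gap: int = 0) -> np.ndarray:
    """Sort (n,2) interval pairs and merge any separated by <= gap."""
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    out = []
    cur_s, cur_e = pairs[0]
    for s, e in pairs[1:]:
        if s - cur_e <= gap:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.asarray(out, dtype=np.int64)


class IntervalSet:
    """A per-chromosome set of sorted, non-overlapping half-open intervals."""

    def __init__(self, data: Mapping[str, np.ndarray] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if data:
            for chrom, arr in data.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.size:
                    if np.any(arr[:, 0] >= arr[:, 1]):
                        raise ValueError(f"empty or inverted interval on {chrom}")
                    if np.any(arr[1:, 0] < arr[:-1, 1]):
                        raise ValueError(f"overlapping/unsorted intervals on {chrom}")
                    self._data[chrom] = arr

    # ---------------------------------------------------------------- builders
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        """Build from (chrom, start, end) triples; overlapping inputs are unioned."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in pairs:
            s, e = int(s), int(e)
            if s >= e:
                raise ValueError(f"empty or inverted interval {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((s, e))
        obj = cls()
        for chrom, lst in by_chrom.items():
            obj._data[chrom] = _normalize(np.asarray(lst, dtype=np.int64), gap=-1)
        return obj

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
                try:
                    s, e = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
                pairs.append((fields[0], s, e))
        if not pairs:
            return cls()
        return cls.from_pairs(pairs)

    def to_bed(self, path, chrom_order: Iterable[str] | None = None) -> None:
        order = list(chrom_order) if chrom_order is not None else sorted(self._data)
        with open(path, "w") as fh:
            for chrom in order:
                for s, e in self._data.get(chrom, ()):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    # ------------------------------------------------------------- operations
    def merge(self, gap: int = 0) -> "IntervalSet":
        """Join intervals separated by <= gap base pairs."""
        if gap < 0:
            raise ValueError("gap must be >= 0")
        out = IntervalSet()
        for chrom, arr in self._data.items():
            out._data[chrom] = _normalize(arr, gap=gap)
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for chrom in self._data.keys() & other._data.keys():
            a, b = self._data[chrom], other._data[chrom]
            res = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    res.append((s, e))
                if a[i, 1] <= b[j, 1]:
                    i += 1
                else:
                    j += 1
            if res:
                out._data[chrom] = np.asarray(res, dtype=np.int64)
        return out

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for chrom in self._data.keys() | other._data.keys():
            parts = [x for x in (self._data.get(chrom), other._data.get(chrom)) if x is not None]
            out._data[chrom] = _normalize(np.concatenate(parts), gap=-1)
        return out

    def complement(self, chrom_lengths: Mapping[str, int]) -> "IntervalSet":
        out = IntervalSet()
        for chrom, length in chrom_lengths.items():
            arr = self._data.get(chrom)
            if arr is None or arr.size == 0:
                out._data[chrom] = np.asarray([[0, length]], dtype=np.int64)
                continue
            bounds = np.concatenate([[0], arr.ravel(), [length]])
            pairs = bounds.reshape(-1, 2)
            keep = pairs[:, 0] < pairs[:, 1]
            if keep.any():
                out._data[chrom] = pairs[keep].astype(np.int64)
        return out

    def overlap_bp(self, other: "IntervalSet") -> int:
        return self.intersect(other).total_bp()

    def total_bp(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._data.values()))

    def contains(self, chrom: str, positions0) -> np.ndarray:
        """Vectorised membership test for 0-based positions on one chromosome."""
        positions0 = np.asarray(positions0, dtype=np.int64)
        arr = self._data.get(chrom)
        if arr is None or arr.size == 0:
            return np.zeros(positions0.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(positions0.shape, dtype=bool)
        inside[ok] = positions0[ok] < arr[idx[ok], 1]
        return inside

    def restricted_to(self, chrom: str) -> np.ndarray:
        """(n,2) int64 array of intervals on one chromosome (possibly empty)."""
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    # ---------------------------------------------------------------- dunders
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def items(self):
        return self._data.items()

    def __len__(self) -> int:
        return int(sum(len(a) for a in self._data.values()))

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self._data.keys() != other._data.keys():
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._data)} chromosomes)"
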