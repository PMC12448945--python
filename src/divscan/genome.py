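"""Genome index: the ordered chromosome frame shared by every stage.

The analysis is restricted to a fixed set of assembled chromosomes (for sea
turtles, the 28 autosome-scale molecules); small scaffolds are excluded
upstream. The index order defines output order everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered (name, length) chromosome table."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    _length_of: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l < 1 for l in self.lengths):
            raise ValueError("chromosome lengths must be >= 1")
        object.__setattr__(self, "_length_of", dict(zip(self.names, self.lengths)))

    def length_of(self, name: str) -> int:
        return self._length_of[name]

    def __contains__(self, name: str) -> bool:
        return name in self._length_of

    def __iter__(self):
        return iter(zip(self.names, self.lengths))

    def __len__(self) -> int:
        return len(self.names)

    @property
    def total_bp(self) -> int:
        return sum(self.lengths)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    # ----------------------------------------------------------------- I/O
    @classmethod
    def from_tsv(cls, path) -> "GenomeIndex":
        """Read a two-column (name, length) TSV; .fai files also parse (extra
        columns are ignored)."""
        names, lengths = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
                try:
                    length = int(fields[1])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: bad length {fields[1]!r}") from exc
                names.append(fields[0])
                lengths.append(length)
        return cls(tuple(names), tuple(lengths))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self:
                fh.write(f"{name}\t{length}\n")
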