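"""Genome model, interval arithmetic and randomized interval placement.

Coordinates are 0-based, half-open (BED dialect) throughout the package:
an interval covers bases ``start .. end-1``. Strand is carried but only
consulted by cleavage-profile aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Genome",
    "GenomicInterval",
    "overlaps",
    "merge",
    "random_placement",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names with lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(
            self, "_index", dict(zip(self.chrom_names, self.chrom_lengths))
        )

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "Genome":
        return cls(tuple(sizes.keys()), tuple(int(v) for v in sizes.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    def length(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None

    def check(self, iv: GenomicInterval) -> None:
        """Validate that ``iv`` fits on a known chromosome."""
        if iv.chrom not in self._index:
            raise KeyError(f"unknown chromosome: {iv.chrom!r}")
        if iv.end > self._index[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._index[iv.chrom]}"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval, genome: Genome | None = None) -> bool:
    """True iff the two half-open intervals share at least one base.

    When ``genome`` is given, both intervals are validated against it first.
    """
    if genome is not None:
        genome.check(a)
        genome.check(b)
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sorted, non-overlapping cover of the union of ``intervals``.

    Strand is discarded. Abutting intervals (end == next start) are joined,
    matching the per-base union semantics.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def interval_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays sorted by start.

    Internal helper shared by the overlap-counting routines.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        arr = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def random_placement(
    intervals: Sequence[GenomicInterval],
    genome: Genome,
    seed: int | np.random.Generator,
) -> list[GenomicInterval]:
    """Place length-matched intervals uniformly at random on ``genome``.

    Each input interval keeps its width; the chromosome is drawn with
    probability proportional to chromosome length (among chromosomes long
    enough to host the interval) and the start uniformly over the valid
    range. Placed intervals may overlap each other.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = genome.chrom_names
    lengths = np.asarray(genome.chrom_lengths, dtype=np.int64)
    max_len = int(lengths.max())
    widths = np.array([iv.width for iv in intervals], dtype=np.int64)
    if len(widths) and widths.max() > max_len:
        raise ValueError(
            f"interval width {int(widths.max())} exceeds every chromosome length"
        )
    out: list[GenomicInterval | None] = [None] * len(intervals)
    for w in np.unique(widths):
        sel = np.flatnonzero(widths == w)
        ok = lengths >= w
        cand = np.flatnonzero(ok)
        probs = lengths[cand] / lengths[cand].sum()
        ci = rng.choice(cand, size=len(sel), p=probs)
        starts = rng.integers(0, lengths[ci] - w + 1)
        for pos, c, s in zip(sel, ci, starts):
            out[pos] = GenomicInterval(
                names[c], int(s), int(s + w), intervals[pos].strand
            )
    return out  # type: ignore[return-value]
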