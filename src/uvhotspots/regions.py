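"""Genomic interval masks.

A :class:`GenomicMask` couples a fast per-chromosome boolean membership array
(0-based) with an annotated interval list, so that a position can be tested
for membership in O(1) while per-gene semantics (which gene's window a
position belongs to, template/non-template strand) remain available.
Intervals are 0-based half-open; membership queries take 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["Interval", "GenomicMask"]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gene_id: str | None = None
    gene_strand: str | None = None
    tier: int | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    @property
    def template_strand(self) -> str | None:
        """Chromosomal strand that is the transcription template of the gene."""
        if self.gene_strand is None:
            return None
        return "-" if self.gene_strand == "+" else "+"


@dataclass
class GenomicMask:
    lengths: dict[str, int]
    intervals: list[Interval] = field(default_factory=list)
    _arrays: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @classmethod
    def from_intervals(
        cls, lengths: Mapping[str, int], intervals: Iterable[Interval]
    ) -> "GenomicMask":
        mask = cls(lengths=dict(lengths), intervals=[])
        for iv in intervals:
            if iv.chrom not in mask.lengths:
                raise KeyError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.start < 0 or iv.end > mask.lengths[iv.chrom]:
                raise ValueError(
                    f"interval [{iv.start}, {iv.end}) outside chromosome "
                    f"{iv.chrom!r} of length {mask.lengths[iv.chrom]}"
                )
            mask.intervals.append(iv)
        return mask

    def array(self, chrom: str) -> np.ndarray:
        """Boolean membership array (0-based) for one chromosome."""
        if chrom not in self._arrays:
            arr = np.zeros(self.lengths[chrom], dtype=bool)
            for iv in self.intervals:
                if iv.chrom == chrom:
                    arr[iv.start : iv.end] = True
            self._arrays[chrom] = arr
        return self._arrays[chrom]

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        if chrom not in self.lengths:
            return False
        if not 1 <= pos <= self.lengths[chrom]:
            return False
        return bool(self.array(chrom)[pos - 1])

    def contains_array(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership for an array of 1-based positions."""
        if chrom not in self.lengths:
            return np.zeros(len(positions), dtype=bool)
        arr = self.array(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        ok = (positions >= 1) & (positions <= len(arr))
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = arr[positions[ok] - 1]
        return out

    def size(self) -> int:
        """Number of distinct genomic positions covered."""
        return int(sum(self.array(c).sum() for c in self.lengths))

    def covering_intervals(self, chrom: str, pos: int) -> list[Interval]:
        """All annotated intervals covering a 1-based position."""
        return [
            iv
            for iv in self.intervals
            if iv.chrom == chrom and iv.start <= pos - 1 < iv.end
        ]

    def to_bed(self, path) -> None:
        with open(path, "w") as handle:
            for iv in self.intervals:
                name = iv.gene_id or iv.label or "."
                strand = iv.gene_strand or "."
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")
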