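"""Reference sequence access, strand normalization, and motif scanning.

Conventions used throughout the package:

* Variant positions and motif start coordinates are 1-based inclusive
  (VCF convention).  Internal interval masks are 0-based half-open.
* Sequence contexts are reported on the *pyrimidine strand*: the strand on
  which the mutated (or potentially mutated) base is C or T.  This is the
  standard orientation for mutational-signature work.
* Windows that run off a contig edge are padded with ``N`` rather than
  rejected, so edge positions are retained but can never match a context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "reverse_complement",
    "ReferenceGenome",
    "ContextSpec",
    "extract_context",
    "scan_motif",
    "count_context_instances",
    "context_instance_positions",
    "PYRIMIDINE_TRINUCLEOTIDES",
    "trinucleotide_instance_counts",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")

# A=0, C=1, G=2, T=3, N=4 integer encoding used for vectorized operations.
_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the {A,C,G,T,N} alphabet."""
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-DNA character(s) in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """In-memory reference genome over the {A,C,G,T,N} alphabet.

    Sequences are stored uppercase.  Suitable for the megabase-scale genomes
    this package analyses and simulates; a 30 Mb genome occupies ~30 MB.
    """

    sequences: dict[str, str]
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("genome must contain at least one chromosome")
        normalized = {}
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-DNA characters: {sorted(bad)!r}"
                )
            normalized[name] = seq
        self.sequences = normalized

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def _require(self, chrom: str) -> str:
        try:
            return self.sequences[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def codes(self, chrom: str) -> np.ndarray:
        """Integer-encoded sequence (A=0,C=1,G=2,T=3,N=4), cached per contig."""
        if chrom not in self._codes:
            seq = self._require(chrom)
            self._codes[chrom] = _BASE_TO_CODE[
                np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            ]
        return self._codes[chrom]

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position; positions outside [1, length] are rejected."""
        seq = self._require(chrom)
        if not 1 <= pos <= len(seq):
            raise IndexError(
                f"position {pos} outside [1, {len(seq)}] on chromosome {chrom!r}"
            )
        return seq[pos - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice, N-padded where it extends past contig edges."""
        seq = self._require(chrom)
        if end < start:
            raise ValueError(f"end {end} < start {start}")
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - len(seq))
        core = seq[max(start - 1, 0) : min(end, len(seq))]
        return "N" * left_pad + core + "N" * right_pad

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        sequences = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate chromosome name {record.id!r} in FASTA")
            sequences[record.id] = str(record.seq).upper()
        if not sequences:
            raise ValueError(f"no sequences found in {path}")
        return cls(sequences)

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as handle:
            for name, seq in self.sequences.items():
                handle.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    handle.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class ContextSpec:
    """An extended sequence pattern plus the index of the mutated base.

    ``pattern`` is read on the pyrimidine strand of the mutated base:
    unless ``strand_literal`` is set, the base at ``mut_index`` must be C
    or T.  ``N`` in the pattern matches any of A/C/G/T (never a genomic N).
    """

    pattern: str
    mut_index: int
    label: str = ""
    strand_literal: bool = False

    def __post_init__(self) -> None:
        pattern = self.pattern.upper()
        object.__setattr__(self, "pattern", pattern)
        if len(pattern) < 1:
            raise ValueError("pattern must be non-empty")
        bad = set(pattern) - _VALID_BASES
        if bad:
            raise ValueError(f"pattern contains invalid characters: {sorted(bad)!r}")
        if not 0 <= self.mut_index < len(pattern):
            raise ValueError(
                f"mut_index {self.mut_index} outside pattern of length {len(pattern)}"
            )
        if not self.strand_literal and pattern[self.mut_index] not in "CTN":
            raise ValueError(
                "mutated base must be a pyrimidine (C/T) under the pyrimidine-strand "
                "convention; set strand_literal=True for literal patterns"
            )

    @property
    def mutated_base(self) -> str:
        return self.pattern[self.mut_index]

    def reverse_complemented(self) -> "ContextSpec":
        """The same context written on the opposite strand."""
        return ContextSpec(
            pattern=reverse_complement(self.pattern),
            mut_index=len(self.pattern) - 1 - self.mut_index,
            label=self.label,
            strand_literal=True,
        )


def extract_context(
    genome: ReferenceGenome,
    chrom: str,
    pos: int,
    flank: int,
    pyrimidine_normalize: bool = True,
) -> tuple[str, str]:
    """Sequence window of ``2*flank + 1`` bases centered on ``pos``.

    Returns ``(context, strand)``.  With ``pyrimidine_normalize`` the window
    is reverse-complemented when the central base is a purine, so the center
    is always C or T (strand ``-`` is then reported).  Contig edges pad
    with N.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    window = genome.fetch(chrom, pos - flank, pos + flank)
    center = window[flank]
    if pyrimidine_normalize and center in "AG":
        return reverse_complement(window), "-"
    return window, "+"


def _pattern_to_regex(pattern: str) -> re.Pattern:
    # N in a query pattern is a wildcard over real bases only; genomic N
    # never matches anything.
    return re.compile(pattern.upper().replace("N", "[ACGT]"))


def scan_motif(
    genome: ReferenceGenome, pattern: str, chroms: Iterable[str] | None = None
) -> list[tuple[str, int, str]]:
    """All occurrences of ``pattern`` on both strands.

    Matches are reported as ``(chrom, start, strand)`` where ``start`` is the
    1-based plus-strand coordinate of the leftmost base of the occurrence.
    Overlapping occurrences are all reported; a palindromic pattern yields
    one match per strand at the same coordinate.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    fwd = _pattern_to_regex(pattern)
    rev = _pattern_to_regex(reverse_complement(pattern))
    palindromic = pattern.upper() == reverse_complement(pattern)
    hits: list[tuple[str, int, str]] = []
    for chrom in chroms if chroms is not None else genome.chromosomes:
        seq = genome.sequences[chrom]
        # lookahead so overlapping matches are found
        for m in re.finditer(f"(?=({fwd.pattern}))", seq):
            hits.append((chrom, m.start() + 1, "+"))
        if palindromic:
            hits.extend((chrom, s, "-") for c, s, _ in list(hits) if c == chrom)
            continue
        for m in re.finditer(f"(?=({rev.pattern}))", seq):
            hits.append((chrom, m.start() + 1, "-"))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def context_instance_positions(
    genome: ReferenceGenome, spec: ContextSpec
) -> list[tuple[str, int, str]]:
    """Genomic positions of the mutated base for every instance of ``spec``.

    An occurrence of the pattern on either strand contributes one instance at
    the plus-strand coordinate of its ``mut_index`` base, tagged with the
    strand carrying the pattern.  Both strands are counted (pyrimidine-strand
    symmetry): each strand's pyrimidine is an independent mutational target.
    """
    length = len(spec.pattern)
    out = []
    for chrom, start, strand in scan_motif(genome, spec.pattern):
        if strand == "+":
            out.append((chrom, start + spec.mut_index, "+"))
        else:
            out.append((chrom, start + (length - 1 - spec.mut_index), "-"))
    return out


def count_context_instances(genome: ReferenceGenome, spec: ContextSpec, mask=None) -> int:
    """Number of genomic instances of ``spec`` (optionally mask-restricted).

    ``mask`` is any object with a ``contains(chrom, pos)`` method taking a
    1-based position (see :class:`uvhotspots.regions.GenomicMask`).
    """
    positions = context_instance_positions(genome, spec)
    if mask is None:
        return len(positions)
    return sum(1 for chrom, pos, _ in positions if mask.contains(chrom, pos))


# ---------------------------------------------------------------------------
# Fast trinucleotide machinery
# ---------------------------------------------------------------------------

#: The 32 pyrimidine-centered trinucleotides (16 NpCpN + 16 NpTpN), the row
#: space of conventional signature analyses.
PYRIMIDINE_TRINUCLEOTIDES: list[str] = [
    f"{left}{center}{right}"
    for center in "CT"
    for left in "ACGT"
    for right in "ACGT"
]

_TRINUC_INDEX = {t: i for i, t in enumerate(PYRIMIDINE_TRINUCLEOTIDES)}


def _build_trinuc_lut() -> np.ndarray:
    """Map 64 plus-strand trinucleotide codes -> pyrimidine-normalized index.

    Code = 16*left + 4*center + right with A=0,C=1,G=2,T=3.  Purine-centered
    trinucleotides map to the index of their reverse complement.
    """
    lut = np.full(64, -1, dtype=np.int8)
    bases = "ACGT"
    for left in range(4):
        for center in range(4):
            for right in range(4):
                tri = bases[left] + bases[center] + bases[right]
                if tri[1] in "AG":
                    tri = reverse_complement(tri)
                lut[16 * left + 4 * center + right] = _TRINUC_INDEX[tri]
    return lut


_TRINUC_LUT = _build_trinuc_lut()


def trinucleotide_codes(genome: ReferenceGenome, chrom: str) -> np.ndarray:
    """Pyrimidine-normalized trinucleotide index per position (-1 at edges/N).

    Index ``i`` (0-based position) refers to the 1-based genomic position
    ``i + 1``; the first and last positions of a contig and any window
    containing N are -1.
    """
    codes = genome.codes(chrom)
    n = len(codes)
    out = np.full(n, -1, dtype=np.int8)
    if n < 3:
        return out
    left = codes[:-2].astype(np.int16)
    center = codes[1:-1].astype(np.int16)
    right = codes[2:].astype(np.int16)
    valid = (left < 4) & (center < 4) & (right < 4)
    tri = 16 * left + 4 * center + right
    inner = np.full(n - 2, -1, dtype=np.int8)
    inner[valid] = _TRINUC_LUT[tri[valid]]
    out[1:-1] = inner
    return out


def trinucleotide_instance_counts(genome: ReferenceGenome, mask=None) -> np.ndarray:
    """Instance count per pyrimidine-centered trinucleotide (length-32 array).

    Every non-edge, N-free genomic position contributes exactly one instance
    (that of its pyrimidine-strand trinucleotide), mirroring the convention
    used for signature denominators.
    """
    counts = np.zeros(32, dtype=np.int64)
    for chrom in genome.chromosomes:
        tri = trinucleotide_codes(genome, chrom)
        if mask is not None:
            sel = mask.array(chrom)
            tri = np.where(sel, tri, -1)
        valid = tri[tri >= 0]
        counts += np.bincount(valid, minlength=32)
    return counts
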