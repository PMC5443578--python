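"""Sequence access, strand normalization, motif scanning and instance counts."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from uvhotspots.genome import (
    PYRIMIDINE_TRINUCLEOTIDES,
    ContextSpec,
    ReferenceGenome,
    context_instance_positions,
    count_context_instances,
    extract_context,
    reverse_complement,
    scan_motif,
    trinucleotide_instance_counts,
)
from uvhotspots.regions import GenomicMask, Interval

from conftest import make_random_genome

dna = st.text(alphabet="ACGTN", min_size=1, max_size=40)


# ---------------------------------------------------------------------- utils


def oracle_scan(seq: str, pattern: str):
    """Independent sliding-window scan on both strands (Bio.Seq complement)."""
    hits = []
    rc = str(Seq(pattern).reverse_complement())
    L = len(pattern)

    def matches(window: str, pat: str) -> bool:
        return len(window) == L and all(
            w in "ACGT" and (p == "N" or p == w) for p, w in zip(pat, window)
        )

    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if matches(window, pattern):
            hits.append((i + 1, "+"))
        if matches(window, rc):
            hits.append((i + 1, "-"))
    return sorted(hits)


# ------------------------------------------------------------------- revcomp


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("CTTCCG", "CGGAAG"), ("NCA", "TGN")],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_rejects_non_dna():
    with pytest.raises(ValueError, match="X"):
        reverse_complement("ACXGT")


@settings(derandomize=True, max_examples=100)
@given(dna)
def test_reverse_complement_involution_and_oracle(seq):
    assert reverse_complement(reverse_complement(seq)) == seq
    assert reverse_complement(seq) == str(Seq(seq).reverse_complement())


# ------------------------------------------------------------ extract_context


@pytest.mark.parametrize(
    "seq,pos,flank,normalize,expected",
    [
        ("AAGAA", 3, 1, True, ("TCT", "-")),  # central G flipped to C
        ("AACAA", 3, 1, True, ("ACA", "+")),  # central base already pyrimidine
        ("ACGTACGT", 1, 2, False, ("NNACG", "+")),  # left padding at contig edge
    ],
)
def test_extract_context_examples(seq, pos, flank, normalize, expected):
    genome = ReferenceGenome({"chr1": seq})
    assert extract_context(genome, "chr1", pos, flank, normalize) == expected


def test_extract_context_unknown_chromosome():
    genome = ReferenceGenome({"chr1": "ACGT"})
    with pytest.raises(KeyError):
        extract_context(genome, "chr9", 1, 1)


def test_extract_context_normalization_idempotent():
    """Re-normalizing an already-pyrimidine-centered window changes nothing."""
    genome = make_random_genome(3, 2000)
    for pos in range(5, 1990, 37):
        ctx, strand = extract_context(genome, "chr1", pos, 2)
        assert ctx[2] in "CT"
        if strand == "-":
            # the minus-strand window reverse-complements back to the plus one
            plus, _ = extract_context(genome, "chr1", pos, 2, pyrimidine_normalize=False)
            assert reverse_complement(ctx) == plus


# ----------------------------------------------------------------- scan_motif


def test_scan_motif_plus_strand():
    genome = ReferenceGenome({"chr1": "AACTTCCGTT"})
    assert scan_motif(genome, "CTTCCG") == [("chr1", 3, "+")]


def test_scan_motif_minus_strand():
    genome = ReferenceGenome({"chr1": "AACGGAAGTT"})
    assert scan_motif(genome, "CTTCCG") == [("chr1", 3, "-")]


def test_scan_motif_matches_brute_force_oracle():
    genome = make_random_genome(7, 10_000, gc=0.5)
    seq = genome.sequences["chr1"]
    for pattern in ("NCTTCCGN", "TCT", "CATG"):
        ours = sorted((s, st_) for _, s, st_ in scan_motif(genome, pattern))
        assert ours == oracle_scan(seq, pattern)


def test_scan_motif_palindrome_reported_once_per_strand():
    genome = ReferenceGenome({"chr1": "AACATGTT"})
    hits = scan_motif(genome, "CATG")
    assert hits == [("chr1", 3, "+"), ("chr1", 3, "-")]


# ------------------------------------------------------ count_context_instances


def test_count_instances_both_strands():
    genome = ReferenceGenome({"chr1": "TCTAGA"})  # AGA = revcomp of TCT
    assert count_context_instances(genome, ContextSpec("TCT", 1)) == 2


def test_count_instances_mask_restriction():
    genome = ReferenceGenome({"chr1": "TCTAGA"})
    mask = GenomicMask.from_intervals({"chr1": 6}, [Interval("chr1", 0, 3)])
    assert count_context_instances(genome, ContextSpec("TCT", 1), mask) == 1


def test_count_instances_matches_brute_force_oracle():
    genome = make_random_genome(11, 50_000, gc=0.4)
    seq = genome.sequences["chr1"]
    spec = ContextSpec("NCTTCCGN", 1)
    expected = 0
    for start1, strand in oracle_scan(seq, spec.pattern):
        expected += 1
    assert count_context_instances(genome, spec) == expected


def test_count_symmetric_under_pattern_reverse_complement():
    genome = make_random_genome(17, 20_000)
    spec = ContextSpec("TCC", 1)
    mirrored = spec.reverse_complemented()
    assert count_context_instances(genome, spec) == count_context_instances(
        genome, mirrored
    )


def test_context_spec_validation():
    with pytest.raises(ValueError):
        ContextSpec("ACG", 3)
    with pytest.raises(ValueError):
        ContextSpec("AGA", 1)  # purine center without strand_literal
    ContextSpec("AGA", 1, strand_literal=True)  # allowed when explicit


# -------------------------------------------------------------- trinucleotides


def test_trinucleotide_instance_counts_match_enumeration():
    genome = make_random_genome(23, 5_000)
    seq = genome.sequences["chr1"]
    expected = {t: 0 for t in PYRIMIDINE_TRINUCLEOTIDES}
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        if tri[1] in "AG":
            tri = str(Seq(tri).reverse_complement())
        expected[tri] += 1
    counts = trinucleotide_instance_counts(genome)
    for i, t in enumerate(PYRIMIDINE_TRINUCLEOTIDES):
        assert counts[i] == expected[t]
    # every interior position contributes exactly one instance
    assert counts.sum() == len(seq) - 2


def test_genome_rejects_bad_input():
    with pytest.raises(ValueError):
        ReferenceGenome({"chr1": "ACGU"})
    with pytest.raises(ValueError):
        ReferenceGenome({"chr1": ""})
    genome = ReferenceGenome({"chr1": "ACGT"})
    with pytest.raises(IndexError):
        genome.base("chr1", 5)
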