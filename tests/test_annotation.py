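"""TSS derivation, expression tiers and TSS-relative geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvhotspots.annotation import (
    GeneRecord,
    assign_expression_tiers,
    derive_tss,
    nearest_tier_masks,
    nearest_tss,
    region_mask_near_tss,
)


def gene(gene_id, tss, strand="+", chrom="chr1", starts=None):
    return GeneRecord(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        transcript_starts=tuple(starts) if starts else (tss,),
    )


# ------------------------------------------------------------------ derive_tss


@pytest.mark.parametrize(
    "strand,starts,expected",
    [("+", (100, 150), 100), ("-", (100, 150), 150), ("+", (42,), 42)],
)
def test_derive_tss_five_prime_most(strand, starts, expected):
    index = derive_tss([gene("g", starts[0], strand=strand, starts=starts)])
    assert index.entries[0].tss == expected


def test_gene_record_requires_transcript_starts():
    with pytest.raises(ValueError, match="g1"):
        GeneRecord(gene_id="g1", chrom="chr1", strand="+", transcript_starts=())


# ------------------------------------------------------------------- tiering


def test_tiers_exact_thirds():
    genes = [gene(f"g{i}", 100 * (i + 1)) for i in range(6)]
    index = derive_tss(genes)
    expr = {f"g{i}": float(i) for i in range(6)}
    tiered = assign_expression_tiers(index, expr)
    tiers = {e.gene_id: e.tier for e in tiered.entries}
    assert [tiers[f"g{i}"] for i in range(6)] == [1, 1, 2, 2, 3, 3]


def test_tiers_remainder_goes_to_lower_tiers():
    genes = [gene(f"g{i}", 100 * (i + 1)) for i in range(7)]
    tiered = assign_expression_tiers(
        derive_tss(genes), {f"g{i}": float(i) for i in range(7)}
    )
    sizes = {t: sum(1 for e in tiered.entries if e.tier == t) for t in (1, 2, 3)}
    assert sizes == {1: 3, 2: 2, 3: 2}


def test_tiers_tie_break_by_gene_id():
    genes = [gene(f"g{i}", 100 * (i + 1)) for i in range(6)]
    tiered = assign_expression_tiers(derive_tss(genes), {f"g{i}": 1.0 for i in range(6)})
    tiers = {e.gene_id: e.tier for e in tiered.entries}
    assert [tiers[f"g{i}"] for i in range(6)] == [1, 1, 2, 2, 3, 3]


def test_tiers_missing_expression_rejected():
    index = derive_tss([gene("g0", 100), gene("g1", 200), gene("g2", 300)])
    with pytest.raises(ValueError, match="g2"):
        assign_expression_tiers(index, {"g0": 1.0, "g1": 2.0})


@settings(derandomize=True, max_examples=30)
@given(st.permutations(list(range(8))))
def test_tiers_invariant_under_input_permutation(order):
    genes = [gene(f"g{i}", 100 * (i + 1)) for i in range(8)]
    expr = {f"g{i}": float(i % 3) for i in range(8)}  # with ties
    reference = assign_expression_tiers(derive_tss(genes), expr)
    permuted = assign_expression_tiers(derive_tss([genes[i] for i in order]), expr)
    ref_tiers = {e.gene_id: e.tier for e in reference.entries}
    perm_tiers = {e.gene_id: e.tier for e in permuted.entries}
    assert ref_tiers == perm_tiers
    sizes = sorted(
        sum(1 for t in ref_tiers.values() if t == k) for k in (1, 2, 3)
    )
    assert sizes[-1] - sizes[0] <= 1


# ---------------------------------------------------------------- nearest_tss


def test_nearest_distance_sign_convention():
    index = derive_tss([gene("g", 1000, "+")])
    gene_id, dist, strand, second = nearest_tss(index, "chr1", 990)
    assert (gene_id, dist, strand, second) == ("g", -10, "+", None)


def test_nearest_distance_minus_strand_flips_sign():
    index = derive_tss([gene("g", 1000, "-")])
    _, dist, _, _ = nearest_tss(index, "chr1", 990)
    assert dist == 10  # downstream of a minus-strand TSS


def test_nearest_tie_breaks_to_lower_coordinate_with_second_hit():
    index = derive_tss([gene("a", 900), gene("b", 1100)])
    gene_id, dist, _, second = nearest_tss(index, "chr1", 1000)
    assert gene_id == "a" and dist == 100
    assert second == ("b", -100, "+")


def test_nearest_absent_on_empty_chromosome():
    index = derive_tss([gene("a", 900)])
    assert nearest_tss(index, "chr2", 1000) is None


# --------------------------------------------------------------------- masks


def test_mask_symmetric_window():
    index = derive_tss([gene("g", 10_000, "+")])
    mask = region_mask_near_tss(index, {"chr1": 50_000}, window=500)
    assert mask.contains("chr1", 9_500) and mask.contains("chr1", 10_500)
    assert not mask.contains("chr1", 9_499) and not mask.contains("chr1", 10_501)
    assert mask.size() == 1001


def test_mask_upstream_only_minus_strand_is_rightward():
    index = derive_tss([gene("g", 10_000, "-")])
    mask = region_mask_near_tss(
        index, {"chr1": 50_000}, window=500, side="upstream_only"
    )
    assert mask.contains("chr1", 10_001) and mask.contains("chr1", 10_500)
    assert not mask.contains("chr1", 10_000) and not mask.contains("chr1", 10_501)


def test_mask_tier_filter():
    genes = [gene(f"g{i}", 5_000 * (i + 1)) for i in range(3)]
    tiered = assign_expression_tiers(
        derive_tss(genes), {"g0": 0.0, "g1": 1.0, "g2": 2.0}
    )
    mask = region_mask_near_tss(tiered, {"chr1": 50_000}, tier_filter={3})
    assert mask.contains("chr1", 15_000)
    assert not mask.contains("chr1", 5_000) and not mask.contains("chr1", 10_000)


def test_mask_positions_are_within_window_of_a_tss():
    rng = np.random.default_rng(0)
    genes = [gene(f"g{i}", int(p), rng.choice(["+", "-"])) for i, p in
             enumerate(sorted(rng.integers(1_000, 49_000, size=12)))]
    index = derive_tss(genes)
    mask = region_mask_near_tss(index, {"chr1": 50_000}, window=500)
    arr = mask.array("chr1")
    for pos0 in np.flatnonzero(arr)[::97]:
        _, dist, _, _ = nearest_tss(index, "chr1", int(pos0) + 1)
        assert abs(dist) <= 500


def test_nearest_tier_masks_partition_tss_territory():
    genes = [gene(f"g{i}", 2_000 + 700 * i) for i in range(9)]  # overlapping windows
    tiered = assign_expression_tiers(
        derive_tss(genes), {f"g{i}": float(i) for i in range(9)}
    )
    lengths = {"chr1": 20_000}
    masks = nearest_tier_masks(tiered, lengths, window=500)
    union = region_mask_near_tss(tiered, lengths, window=500)
    total = np.zeros(20_000, dtype=int)
    for m in masks.values():
        total += m.array("chr1").astype(int)
    assert total.max() <= 1  # disjoint
    assert (total.astype(bool) == union.array("chr1")).all()  # exhaustive
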