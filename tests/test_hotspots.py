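"""Recurrence tallies, hotspot calling and motif classification."""

import numpy as np
import pandas as pd
import pytest

from uvhotspots.annotation import assign_expression_tiers, derive_tss, GeneRecord
from uvhotspots.genome import ReferenceGenome
from uvhotspots.hotspots import (
    MotifIndex,
    call_hotspots,
    differential_expression_test,
    motif_positional_distribution,
    recurrence_vs_distance,
    tally_recurrence,
)
from uvhotspots.variants import SampleSet, Variant


def make_index(*genes):
    return derive_tss(
        [
            GeneRecord(gene_id=g, chrom=c, strand=s, transcript_starts=(t,))
            for g, c, s, t in genes
        ]
    )


# ------------------------------------------------------------------- tallies


def test_tally_direct_count():
    ss = SampleSet.from_variants(
        [Variant(f"s{i}", "chr1", 50, "C", "T") for i in range(3)]
    )
    tal = tally_recurrence(ss)
    assert tal.loc[("chr1", 50), "recurrence"] == 3


def test_tally_per_sample_cap_with_two_alts():
    ss = SampleSet.from_variants(
        [Variant("s1", "chr1", 50, "C", "T"), Variant("s1", "chr1", 50, "C", "A")]
    )
    tal = tally_recurrence(ss)
    assert tal.loc[("chr1", 50), "recurrence"] == 1
    assert tal.loc[("chr1", 50), "alt_T"] == 1 and tal.loc[("chr1", 50), "alt_A"] == 1


def test_tally_singletons():
    ss = SampleSet.from_variants(
        [Variant(f"s{i}", "chr1", 10 + i, "C", "T") for i in range(4)]
    )
    assert (tally_recurrence(ss)["recurrence"] == 1).all()


def test_tally_invariant_to_sample_relabeling_and_order():
    variants = [Variant(f"s{i % 3}", "chr1", 10 + (i % 5), "C", "T") for i in range(9)]
    a = tally_recurrence(SampleSet.from_variants(variants))
    relabeled = [
        Variant(f"x{v.sample_id}", v.chrom, v.pos, v.ref, v.alt) for v in variants[::-1]
    ]
    b = tally_recurrence(SampleSet.from_variants(relabeled))
    assert (a["recurrence"] == b["recurrence"]).all()


# ------------------------------------------------------------- hotspot calls


def test_hotspot_outside_tss_window_excluded():
    seq = "A" * 2000
    genome = ReferenceGenome({"chr1": seq[:900] + "C" + seq[901:]})
    index = make_index(("g", "chr1", "+", 1501))  # position 901 is 600 bp away
    ss = SampleSet.from_variants(
        [Variant(f"s{i}", "chr1", 901, "C", "T") for i in range(10)]
    )
    assert len(call_hotspots(ss, index, genome, min_recurrence=5)) == 0


def test_hotspot_on_planted_motif(hotspot_sim):
    cfg, bundle, ss, truth = hotspot_sim
    table = call_hotspots(ss, bundle.index, bundle.genome, min_recurrence=5)
    assert len(table) >= 1
    assert table["motif_overlap"].any()
    # every hotspot context is centered on its pyrimidine-normalized ref base
    for row in table.itertuples(index=False):
        ref = bundle.genome.base(row.chrom, row.pos)
        center = row.context11[5]
        assert center == (ref if ref in "CT" else {"A": "T", "G": "C"}[ref])
        assert abs(row.tss_distance) <= 500
        assert row.recurrence >= 5


def test_highly_recurrent_threshold_is_13_percent_of_38():
    assert 5 / 38 == pytest.approx(0.13, abs=0.005)


# ----------------------------------------------------- positional distribution


def test_positional_distribution_point_mass():
    genome = ReferenceGenome({"chr1": "AAACTTCCGAAA"})  # CTTCCG at 4..9
    mi = MotifIndex(genome)
    hist = motif_positional_distribution([("chr1", 4)], mi)  # the first C
    assert hist[1] == 1 and hist.sum() == 1


def test_positional_distribution_minus_strand_mirrors_plus():
    plus = ReferenceGenome({"chr1": "AAACTTCCGAAA"})
    minus = ReferenceGenome({"chr1": "TTTCGGAAGTTT"})  # reverse complement
    hist_plus = motif_positional_distribution(
        [("chr1", p) for p in range(3, 11)], MotifIndex(plus)
    )
    hist_minus = motif_positional_distribution(
        [("chr1", p) for p in range(3, 11)], MotifIndex(minus)
    )
    assert (hist_plus == hist_minus).all()
    assert hist_plus.sum() == 8  # offsets 0..7 each hit once


def test_positional_distribution_uniform_plant(hotspot_sim):
    """Mutations planted uniformly across offsets give a flat histogram."""
    cfg, bundle, _, _ = hotspot_sim
    mi = MotifIndex(bundle.genome)
    positions = []
    for chrom, start, strand in mi.occurrences[:50]:
        for off in range(8):
            pos = start - 1 + off if strand == "+" else start + 6 - off
            positions.append((chrom, pos))
    hist = motif_positional_distribution(positions, mi)
    assert (hist[list(range(8))] >= 45).all()  # near-flat (shared positions allowed)
    assert hist[-1] == 0


# ------------------------------------------------------ recurrence vs distance


def test_recurrence_vs_distance_empty_without_motif():
    genome = ReferenceGenome({"chr1": "A" * 200})
    index = make_index(("g", "chr1", "+", 100))
    ss = SampleSet.from_variants([])
    ss.samples = ["s1"]
    out = recurrence_vs_distance(ss, genome, index)
    assert len(out) == 0


def test_recurrence_vs_distance_adjacency_is_one_base(hotspot_sim):
    cfg, bundle, ss, _ = hotspot_sim
    mi = MotifIndex(bundle.genome)
    with_adj = recurrence_vs_distance(ss, bundle.genome, bundle.index, motif_index=mi)
    without = recurrence_vs_distance(
        ss, bundle.genome, bundle.index, adjacency=0, motif_index=mi
    )
    extra = set(map(tuple, with_adj[["chrom", "pos"]].to_numpy())) - set(
        map(tuple, without[["chrom", "pos"]].to_numpy())
    )
    # the extra positions are exactly the flanking N bases of occurrences
    for chrom, pos in extra:
        offs = [off for _, _, off in mi.hits(chrom, int(pos))]
        assert 0 in offs or 7 in offs


def test_recurrence_vs_distance_concentrates_in_active_tier(small_sim):
    """With vulnerability only near active TSSs, recurrent motif mutations
    sit within the TSS window of the top tier."""
    cfg, bundle, ss, _ = small_sim
    table = recurrence_vs_distance(ss, bundle.genome, bundle.index)
    recurrent = table[table["recurrence"] >= 4]
    tier3 = recurrent[recurrent["tier"] == 3]
    assert len(tier3) > 0
    assert (tier3["tss_distance"].abs() <= 500).mean() > 0.9


# -------------------------------------------------- differential expression


def test_differential_expression_exact_p():
    expr = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
        index=["g"],
        columns=[f"s{i}" for i in range(6)],
    )
    p = differential_expression_test(expr, "g", {"s0", "s1", "s2"})
    assert p == pytest.approx(0.1)


def test_differential_expression_degenerate_group_absent():
    expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s0", "s1"])
    assert differential_expression_test(expr, "g", set()) is None
    assert differential_expression_test(expr, "g", {"s0", "s1"}) is None
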