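"""Barcode-family grouping, consensus thresholds and error correction."""

import numpy as np
import pytest

from uvhotspots.consensus import (
    AmpliconDesign,
    BarcodeFamily,
    call_consensus,
    family_diagnostics,
    group_families,
    simulate_amplicon_library,
    tabulate_frequencies,
)

REF36 = "ACGATCCTTCCGAAGTACGGATCTAGCATCGATTGC"  # 36 bp, CTTCCG at 7-12


@pytest.fixture()
def design():
    return AmpliconDesign("DPH3_like", REF36, barcode_length=8)


def reads_for(design, barcode_seqs):
    """Synthesize raw reads as barcode + amplicon strings."""
    return [bc + seq for bc, seq in barcode_seqs]


# ------------------------------------------------------------------ grouping


def test_grouping_partitions_reads(design):
    rng = np.random.default_rng(0)
    barcodes = ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG", "TTTTTTTT"]
    raw = []
    sizes = {}
    for bc in barcodes:
        n = int(rng.integers(10, 40))
        sizes[bc] = n
        raw += reads_for(design, [(bc, REF36)] * n)
    families, stats = group_families(raw, design)
    assert stats["n_families"] == 4
    assert sum(f.size for f in families) == stats["retained_reads"] == len(raw)
    assert {f.barcode: f.size for f in families} == sizes


def test_short_reads_dropped_and_logged(design):
    raw = reads_for(design, [("AAAAAAAA", REF36)]) + ["AAAA" + REF36[:10]]
    families, stats = group_families(raw, design)
    assert stats["dropped_short"] == 1 and stats["retained_reads"] == 1


def test_singleton_family_later_rejected(design):
    families, _ = group_families(reads_for(design, [("AAAAAAAA", REF36)]), design)
    assert families[0].size == 1
    assert call_consensus(families[0]) is None


# ------------------------------------------------------------------ consensus


def variant_read():
    return REF36[:6] + "T" + REF36[7:]


@pytest.mark.parametrize(
    "n_identical,n_other,accepted",
    [
        (19, 0, False),  # below the 20-read family floor
        (18, 2, True),   # 20 reads, 90% identical: boundary passes
        (17, 3, False),  # 85% identical: below the identity bar
        (20, 0, True),
    ],
)
def test_consensus_thresholds(n_identical, n_other, accepted):
    family = BarcodeFamily(
        "AAAA", [REF36] * n_identical + [variant_read()] * n_other
    )
    consensus = call_consensus(family)
    assert (consensus is not None) == accepted
    if accepted:
        assert consensus == REF36


def test_consensus_modal_tie_rejected():
    family = BarcodeFamily("AAAA", [REF36] * 10 + [variant_read()] * 10)
    assert call_consensus(family, min_family_size=20, identity_threshold=0.5) is None


def test_positional_mode_agrees_on_clean_family():
    family = BarcodeFamily("AAAA", [REF36] * 19 + [variant_read()])
    exact = call_consensus(family)
    family2 = BarcodeFamily("AAAA", [REF36] * 19 + [variant_read()])
    positional = call_consensus(family2, mode="positional")
    assert exact == positional == REF36


# ---------------------------------------------------------------- frequencies


def test_all_reference_reads_give_zero_frequencies(design):
    families = [BarcodeFamily(f"BC{i:06d}", [REF36] * 25) for i in range(5)]
    table = tabulate_frequencies(families, design)
    assert (table["raw_freq"] == 0).all()
    assert (table["corrected_freq"] == 0).all()
    assert table.attrs["consensus_reads"] == 5


def test_noise_free_library_recovers_exact_fraction(design):
    reads, truth = simulate_amplicon_library(
        design, [(7, "T", 0.5)], n_molecules=300,
        pcr_error_rate=0.0, seq_error_rate=0.0, seed=2,
    )
    families, _ = group_families(reads, design)
    table = tabulate_frequencies(families, design)
    accepted = table.attrs["consensus_reads"]
    site = table[(table["position"] == 7) & (table["alt"] == "T")].iloc[0]
    # without noise, every family is accepted and the corrected frequency
    # equals the realized molecule fraction exactly
    realized = truth["realized_fractions"]["7C>T"]
    small_families = sum(1 for f in families if f.size < 20)
    assert accepted == 300 - small_families
    if small_families == 0:
        assert site["corrected_freq"] == realized


def test_small_families_never_reach_corrected_counts(design):
    reads, truth = simulate_amplicon_library(
        design, [(7, "T", 1.0)], n_molecules=60,
        family_size_log_mean=2.0, family_size_log_sigma=0.3,  # sizes ~7
        pcr_error_rate=0.0, seq_error_rate=0.0, seed=3,
    )
    families, stats = group_families(reads, design)
    table = tabulate_frequencies(families, design)
    eligible = [f for f in families if f.size >= 20]
    assert table.attrs["consensus_reads"] == len(eligible)
    site = table[(table["position"] == 7) & (table["alt"] == "T")].iloc[0]
    assert site["corrected_count"] == len(eligible)
    assert sum(f.size for f in families) == stats["retained_reads"]


def test_library_simulation_deterministic(design):
    kwargs = dict(n_molecules=50, seed=9)
    r1, _ = simulate_amplicon_library(design, [(7, "T", 0.1)], **kwargs)
    r2, _ = simulate_amplicon_library(design, [(7, "T", 0.1)], **kwargs)
    assert [str(a.seq) for a in r1] == [str(b.seq) for b in r2]


def test_fastq_round_trip(design, tmp_path):
    path = tmp_path / "lib.fastq"
    r1, _ = simulate_amplicon_library(
        design, [(7, "T", 0.2)], n_molecules=30, seed=4, out_path=path
    )
    families_mem, stats_mem = group_families(r1, design)
    families_file, stats_file = group_families(path, design)
    assert stats_mem == stats_file
    assert [f.reads for f in families_mem] == [f.reads for f in families_file]


def test_corrected_estimator_unbiased_across_seeds(design):
    """Mean corrected frequency over replicates tracks the realized
    molecule fraction within two standard errors."""
    diffs = []
    for seed in range(15):
        reads, truth = simulate_amplicon_library(
            design, [(7, "T", 0.05)], n_molecules=150,
            seq_error_rate=0.002, pcr_error_rate=1e-4, seed=seed,
        )
        families, _ = group_families(reads, design)
        table = tabulate_frequencies(families, design)
        site = table[(table["position"] == 7) & (table["alt"] == "T")].iloc[0]
        realized = truth["realized_fractions"]["7C>T"]
        if not np.isnan(site["corrected_freq"]):
            diffs.append(site["corrected_freq"] - realized)
    diffs = np.array(diffs)
    assert len(diffs) >= 10
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) <= 2 * max(se, 1e-4)


def test_family_diagnostics_table(design):
    families = [
        BarcodeFamily("A" * 8, [REF36] * 25),
        BarcodeFamily("C" * 8, [REF36] * 5),
    ]
    tabulate_frequencies(families, design)
    diag = family_diagnostics(families)
    assert list(diag["accepted"]) == [True, False]
    assert list(diag["size"]) == [25, 5]
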