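"""Barcode-family consensus calling for ultra-deep amplicon sequencing.

Reads carry a molecular barcode followed by the amplicon sequence; reads
sharing a barcode form a family descended from one original molecule.  A
family yields an accepted consensus read only when it has at least
``min_family_size`` members of which at least ``identity_threshold`` are
exactly identical (whole-read equality); the consensus is that modal read,
and a tie for the modal read rejects the family as ambiguous.  Raw variant
frequencies are computed over all retained reads, corrected frequencies over
accepted consensus reads only — the contrast quantifies how much PCR and
sequencing error the barcode collapse removes.

A matched library simulator generates reads from molecules carrying true
subclonal variants, with PCR errors propagating to a lineage-dependent
subset of each family and sequencing errors applied per read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmpliconDesign",
    "BarcodeFamily",
    "group_families",
    "call_consensus",
    "tabulate_frequencies",
    "simulate_amplicon_library",
    "family_diagnostics",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class AmpliconDesign:
    """Read layout of one amplicon assay: barcode then amplicon sequence."""

    name: str
    reference: str
    barcode_length: int = 12
    chrom: str | None = None
    genomic_start: int | None = None  # 1-based coordinate of amplicon base 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", self.reference.upper())
        if self.barcode_length <= 0:
            raise ValueError("barcode length must be positive")
        if not self.reference or set(self.reference) - set(_BASES):
            raise ValueError("amplicon reference must be non-empty A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.reference)


@dataclass
class BarcodeFamily:
    barcode: str
    reads: list[str]
    consensus: str | None = None
    accepted: bool = False

    @property
    def size(self) -> int:
        return len(self.reads)

    @property
    def modal_read(self) -> tuple[str | None, int, bool]:
        """(modal sequence or None on a tie, modal count, tied flag)."""
        counts = Counter(self.reads)
        best_two = counts.most_common(2)
        seq, n = best_two[0]
        tied = len(best_two) > 1 and best_two[1][1] == n
        return (None if tied else seq), n, tied

    @property
    def max_identical_fraction(self) -> float:
        _, n, _ = self.modal_read
        return n / self.size


def group_families(reads, design: AmpliconDesign) -> tuple[list[BarcodeFamily], dict]:
    """Group reads by exact barcode into families.

    ``reads`` may be a FASTQ path or an iterable of sequence strings /
    SeqRecords.  Reads shorter than barcode + amplicon are dropped (counted
    in the returned stats).  Member reads are the trimmed amplicon portions.
    """
    if isinstance(reads, (str, Path)):
        reads = SeqIO.parse(str(reads), "fastq")
    min_len = design.barcode_length + design.length
    families: dict[str, list[str]] = {}
    dropped_short = 0
    retained = 0
    for read in reads:
        seq = str(read.seq) if isinstance(read, SeqRecord) else str(read)
        seq = seq.upper()
        if len(seq) < min_len:
            dropped_short += 1
            continue
        barcode = seq[: design.barcode_length]
        amplicon = seq[design.barcode_length : min_len]
        families.setdefault(barcode, []).append(amplicon)
        retained += 1
    out = [BarcodeFamily(bc, members) for bc, members in sorted(families.items())]
    stats = {
        "retained_reads": retained,
        "dropped_short": dropped_short,
        "n_families": len(out),
    }
    return out, stats


def call_consensus(
    family: BarcodeFamily,
    min_family_size: int = 20,
    identity_threshold: float = 0.90,
    mode: str = "exact",
) -> str | None:
    """Accept or reject one family's consensus.

    Acceptance requires ``size >= min_family_size`` and a modal read shared
    by at least ``identity_threshold`` of the members; ties for the modal
    read reject the family as ambiguous.  ``mode="positional"`` builds the
    consensus by per-position majority instead of taking the modal read
    verbatim (the acceptance rule is unchanged); per-position ties also
    reject.
    """
    modal, n_modal, tied = family.modal_read
    accepted = (
        family.size >= min_family_size
        and not tied
        and n_modal / family.size >= identity_threshold
    )
    if not accepted:
        family.consensus, family.accepted = None, False
        return None
    if mode == "exact":
        consensus = modal
    elif mode == "positional":
        cols = []
        for i in range(len(family.reads[0])):
            counts = Counter(r[i] for r in family.reads)
            top = counts.most_common(2)
            if len(top) > 1 and top[1][1] == top[0][1]:
                family.consensus, family.accepted = None, False
                return None
            cols.append(top[0][0])
        consensus = "".join(cols)
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    family.consensus, family.accepted = consensus, True
    return consensus


def tabulate_frequencies(
    families: Sequence[BarcodeFamily],
    design: AmpliconDesign,
    min_family_size: int = 20,
    identity_threshold: float = 0.90,
    mode: str = "exact",
) -> pd.DataFrame:
    """Raw vs corrected per-position substitution frequencies.

    Raw frequencies are over all member reads of all families; corrected
    frequencies are over accepted consensus reads only.  The frame has one
    row per (position, alt base) with the reference base, counts and both
    frequencies; totals are stored in ``DataFrame.attrs`` (raw read count,
    accepted consensus count, and the reads-per-consensus oversampling
    ratio).  When no family is accepted the corrected columns are NaN.
    """
    L = design.length
    raw_counts = np.zeros((L, 4), dtype=np.int64)
    corr_counts = np.zeros((L, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    raw_total = 0
    corr_total = 0
    for fam in families:
        for read in fam.reads:
            raw_total += 1
            for i, b in enumerate(read[:L]):
                if b in base_idx:
                    raw_counts[i, base_idx[b]] += 1
        consensus = call_consensus(
            fam, min_family_size=min_family_size,
            identity_threshold=identity_threshold, mode=mode,
        )
        if consensus is not None:
            corr_total += 1
            for i, b in enumerate(consensus[:L]):
                if b in base_idx:
                    corr_counts[i, base_idx[b]] += 1
    rows = []
    for i in range(L):
        ref = design.reference[i]
        for b in _BASES:
            if b == ref:
                continue
            rows.append(
                {
                    "position": i + 1,
                    "ref": ref,
                    "alt": b,
                    "raw_count": int(raw_counts[i, base_idx[b]]),
                    "raw_freq": raw_counts[i, base_idx[b]] / raw_total if raw_total else np.nan,
                    "corrected_count": int(corr_counts[i, base_idx[b]]),
                    "corrected_freq": (
                        corr_counts[i, base_idx[b]] / corr_total if corr_total else np.nan
                    ),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["raw_reads"] = raw_total
    out.attrs["consensus_reads"] = corr_total
    out.attrs["oversampling"] = raw_total / corr_total if corr_total else np.nan
    return out


def family_diagnostics(families: Sequence[BarcodeFamily]) -> pd.DataFrame:
    """Per-family size, identity fraction and acceptance, for QC export."""
    return pd.DataFrame(
        [
            {
                "barcode": f.barcode,
                "size": f.size,
                "max_identical_fraction": f.max_identical_fraction,
                "accepted": f.accepted,
            }
            for f in families
        ]
    )


def simulate_amplicon_library(
    design: AmpliconDesign,
    true_variants: Sequence[tuple[int, str, float]],
    n_molecules: int = 2000,
    family_size_log_mean: float = 3.6,
    family_size_log_sigma: float = 0.5,
    pcr_error_rate: float = 1e-4,
    seq_error_rate: float = 0.005,
    seed: int = 0,
    out_path=None,
):
    """Simulate an amplicon library with barcoded molecule families.

    ``true_variants`` is a list of (1-based amplicon position, alt base,
    molecule fraction); each molecule carries each variant independently
    with its fraction.  Every molecule receives a unique random barcode and
    a log-normal family size.  PCR errors occur per molecule lineage and
    propagate to a random early-cycle fraction (1/2, 1/4 or 1/8) of the
    family's reads; sequencing errors are per read and base.  Returns
    ``(records, truth)`` where truth holds realized per-variant molecule
    fractions; with ``out_path`` the reads are also written as FASTQ
    (deterministic under the seed).
    """
    rng = np.random.default_rng(seed)
    for pos, alt, frac in true_variants:
        if not 1 <= pos <= design.length:
            raise ValueError(f"variant position {pos} outside amplicon")
        if alt == design.reference[pos - 1]:
            raise ValueError(f"variant alt at {pos} equals the reference base")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("variant fractions must be in [0, 1]")
    barcodes: set[str] = set()
    records: list[SeqRecord] = []
    realized = {(pos, alt): 0 for pos, alt, _ in true_variants}
    read_no = 0
    for mol in range(n_molecules):
        while True:
            barcode = "".join(rng.choice(list(_BASES), size=design.barcode_length))
            if barcode not in barcodes:
                barcodes.add(barcode)
                break
        template = list(design.reference)
        for pos, alt, frac in true_variants:
            if rng.random() < frac:
                template[pos - 1] = alt
                realized[(pos, alt)] += 1
        size = max(1, int(round(rng.lognormal(family_size_log_mean, family_size_log_sigma))))
        # PCR errors: per lineage, propagating to an early-cycle fraction
        pcr_variants = []
        n_pcr = rng.binomial(design.length, pcr_error_rate)
        for _ in range(n_pcr):
            pos0 = int(rng.integers(design.length))
            current = template[pos0]
            alt = str(rng.choice([b for b in _BASES if b != current]))
            fraction = float(rng.choice([0.5, 0.25, 0.125]))
            affected = set(
                rng.choice(size, size=rng.binomial(size, fraction), replace=False)
            )
            pcr_variants.append((pos0, alt, affected))
        for r in range(size):
            read = template.copy()
            for pos0, alt, affected in pcr_variants:
                if r in affected:
                    read[pos0] = alt
            n_err = rng.binomial(design.length, seq_error_rate)
            for _ in range(n_err):
                pos0 = int(rng.integers(design.length))
                read[pos0] = str(rng.choice([b for b in _BASES if b != read[pos0]]))
            read_no += 1
            seq = barcode + "".join(read)
            rec = SeqRecord(
                Seq(seq),
                id=f"{design.name}_m{mol}_r{r}",
                description="",
            )
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
    truth = {
        "n_molecules": n_molecules,
        "realized_fractions": {
            f"{pos}{design.reference[pos-1]}>{alt}": count / n_molecules
            for (pos, alt), count in realized.items()
        },
        "n_reads": read_no,
    }
    if out_path is not None:
        with open(out_path, "w") as fh:
            SeqIO.write(records, fh, "fastq")
    return records, truth
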