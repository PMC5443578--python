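"""Gene annotation: TSS derivation, expression tiers, TSS-relative geometry.

The transcription start site (TSS) of a gene is its 5'-most annotated
transcript start: the minimum start coordinate for plus-strand genes and the
maximum for minus-strand genes.  Genes are split into three expression tiers
of (near-)equal size by ascending mean expression; tier 3 is the most highly
expressed third.  Signed TSS distances are positive downstream of the TSS in
the gene's transcription direction and negative upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GenomicMask, Interval

__all__ = [
    "GeneRecord",
    "TssEntry",
    "TssIndex",
    "derive_tss",
    "assign_expression_tiers",
    "nearest_tss",
    "region_mask_near_tss",
    "nearest_tier_masks",
    "read_genes_tsv",
    "read_genes_gtf",
    "read_expression_tsv",
]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    transcript_starts: tuple[int, ...]
    mean_expression: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not self.transcript_starts:
            raise ValueError(f"gene {self.gene_id!r} has no transcript starts")
        if self.mean_expression is not None and self.mean_expression < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative mean expression")


@dataclass(frozen=True)
class TssEntry:
    gene_id: str
    chrom: str
    tss: int  # 1-based
    strand: str
    tier: int | None = None  # 1 (low) .. 3 (high) expression


class TssIndex:
    """One TSS per gene, with optional expression tiers and fast queries."""

    def __init__(self, entries: Sequence[TssEntry]):
        self.entries: list[TssEntry] = list(entries)
        seen = set()
        for e in self.entries:
            if e.gene_id in seen:
                raise ValueError(f"duplicate gene {e.gene_id!r} in TSS index")
            seen.add(e.gene_id)
        self._by_chrom: dict[str, tuple[np.ndarray, list[TssEntry]]] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def tiered(self) -> bool:
        return all(e.tier is not None for e in self.entries)

    def subset(self, tiers: Iterable[int]) -> "TssIndex":
        tiers = set(tiers)
        return TssIndex([e for e in self.entries if e.tier in tiers])

    def _chrom_index(self, chrom: str):
        if chrom not in self._by_chrom:
            on_chrom = sorted(
                (e for e in self.entries if e.chrom == chrom),
                key=lambda e: (e.tss, e.gene_id),
            )
            self._by_chrom[chrom] = (
                np.array([e.tss for e in on_chrom], dtype=np.int64),
                on_chrom,
            )
        return self._by_chrom[chrom]

    def nearest(self, chrom: str, pos: int, second_window: int = 500):
        """Nearest TSS on ``chrom`` (and second-nearest if within the window).

        Returns ``(entry, signed_distance, second_entry_or_None,
        second_distance_or_None)`` or ``None`` when the chromosome has no
        genes.  Exact distance ties break toward the lower genomic
        coordinate.
        """
        tss_arr, entries = self._chrom_index(chrom)
        if len(entries) == 0:
            return None
        idx, dist = self._nearest_vector(chrom, np.array([pos], dtype=np.int64))
        best = entries[int(idx[0])]
        best_dist = int(dist[0])
        # second nearest: smallest absolute distance among the rest
        second = None
        second_dist = None
        if len(entries) > 1:
            abs_d = np.abs(tss_arr - pos)
            order = np.lexsort((tss_arr, abs_d))
            for j in order:
                if entries[j] is best:
                    continue
                if abs(int(tss_arr[j]) - pos) <= second_window:
                    second = entries[j]
                    second_dist = _signed_distance(second, pos)
                break
        return best, best_dist, second, second_dist

    def _nearest_vector(self, chrom: str, positions: np.ndarray):
        """Vectorized nearest-TSS query: (entry index array, signed distances)."""
        tss_arr, entries = self._chrom_index(chrom)
        if len(entries) == 0:
            raise KeyError(f"no genes on chromosome {chrom!r}")
        positions = np.asarray(positions, dtype=np.int64)
        right = np.searchsorted(tss_arr, positions, side="left")
        left = np.clip(right - 1, 0, len(tss_arr) - 1)
        right = np.clip(right, 0, len(tss_arr) - 1)
        d_left = np.abs(positions - tss_arr[left])
        d_right = np.abs(tss_arr[right] - positions)
        # ties break toward the lower coordinate, i.e. the left candidate
        take_left = d_left <= d_right
        idx = np.where(take_left, left, right)
        strands = np.array([1 if e.strand == "+" else -1 for e in entries])
        signed = (positions - tss_arr[idx]) * strands[idx]
        return idx, signed

    def with_tiers(self, tiers: Mapping[str, int]) -> "TssIndex":
        return TssIndex(
            [replace(e, tier=tiers[e.gene_id]) for e in self.entries]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": e.gene_id,
                    "chrom": e.chrom,
                    "tss": e.tss,
                    "strand": e.strand,
                    "tier": e.tier,
                }
                for e in self.entries
            ]
        )


def _signed_distance(entry: TssEntry, pos: int) -> int:
    d = pos - entry.tss
    return d if entry.strand == "+" else -d


def derive_tss(genes: Iterable[GeneRecord]) -> TssIndex:
    """5'-most annotated transcript start per gene (tiers unset)."""
    entries = []
    for g in genes:
        tss = min(g.transcript_starts) if g.strand == "+" else max(g.transcript_starts)
        entries.append(TssEntry(g.gene_id, g.chrom, tss, g.strand))
    return TssIndex(entries)


def assign_expression_tiers(
    index: TssIndex, expressions: Mapping[str, float]
) -> TssIndex:
    """Three expression tiers of near-equal size (ascending expression).

    Genes are sorted by (mean expression, gene_id); the lowest third is tier
    1 and the highest tier 3.  When the gene count is not divisible by 3 the
    extra genes go to the lower tiers, so tier sizes differ by at most one.
    Ties in expression break by gene_id, making the assignment deterministic
    under input permutation.
    """
    missing = [e.gene_id for e in index.entries if e.gene_id not in expressions]
    if missing:
        raise ValueError(f"missing expression values for genes: {missing[:5]!r}")
    ordered = sorted(index.entries, key=lambda e: (expressions[e.gene_id], e.gene_id))
    n = len(ordered)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base]
    tiers: dict[str, int] = {}
    start = 0
    for tier, size in zip((1, 2, 3), sizes):
        for e in ordered[start : start + size]:
            tiers[e.gene_id] = tier
        start += size
    return index.with_tiers(tiers)


def nearest_tss(index: TssIndex, chrom: str, pos: int, second_window: int = 500):
    """Nearest (and second-nearest within ``second_window``) TSS for a position.

    Returns ``(gene_id, signed_distance, strand, second)`` where ``second``
    is ``(gene_id, signed_distance, strand)`` or ``None``; the whole result
    is ``None`` when the chromosome has no annotated genes.
    """
    hit = index.nearest(chrom, pos, second_window=second_window)
    if hit is None:
        return None
    best, dist, second, second_dist = hit
    second_out = (
        (second.gene_id, second_dist, second.strand) if second is not None else None
    )
    return best.gene_id, dist, best.strand, second_out


def region_mask_near_tss(
    index: TssIndex,
    lengths: Mapping[str, int],
    window: int = 500,
    tier_filter: Iterable[int] | None = None,
    side: str = "both",
    strand_mode: str | None = None,
) -> GenomicMask:
    """Per-gene TSS windows as an annotated mask.

    ``side="both"`` gives the symmetric window [TSS-window, TSS+window];
    ``side="upstream_only"`` gives only the transcriptionally upstream window
    (leftward of the TSS for plus-strand genes, rightward for minus-strand
    genes), excluding the TSS itself.  Each interval carries its gene and
    strand so callers can resolve template/non-template strands; a position
    near two TSSs belongs to each gene's interval.  ``strand_mode`` is a
    label recorded on the intervals ("template"/"non_template"/None) for
    bookkeeping by strand-split analyses.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if side not in ("both", "upstream_only"):
        raise ValueError(f"unknown side {side!r}")
    tiers = set(tier_filter) if tier_filter is not None else None
    intervals = []
    for e in index.entries:
        if tiers is not None and e.tier not in tiers:
            continue
        if e.chrom not in lengths:
            continue  # caller restricted to a subset of chromosomes
        length = lengths[e.chrom]
        if side == "both":
            lo1, hi1 = e.tss - window, e.tss + window  # 1-based inclusive
        elif e.strand == "+":
            lo1, hi1 = e.tss - window, e.tss - 1
        else:
            lo1, hi1 = e.tss + 1, e.tss + window
        start = max(lo1 - 1, 0)
        end = min(hi1, length)
        if end <= start:
            continue
        intervals.append(
            Interval(
                chrom=e.chrom,
                start=start,
                end=end,
                gene_id=e.gene_id,
                gene_strand=e.strand,
                tier=e.tier,
                label=strand_mode,
            )
        )
    return GenomicMask.from_intervals(lengths, intervals)


def nearest_tier_masks(
    index: TssIndex, lengths: Mapping[str, int], window: int = 500
) -> dict[int, GenomicMask]:
    """Tier masks that partition the TSS+/-window territory.

    Each position within ``window`` of at least one TSS is assigned to the
    tier of its *nearest* gene (distance ties toward the lower coordinate),
    so the three masks are disjoint and their union is the full TSS-proximal
    set.  Used for tier-stratified denominators so that tier strata
    partition cleanly.
    """
    if not index.tiered:
        raise ValueError("expression tiers must be assigned before tier masks")
    out_intervals: dict[int, list[Interval]] = {1: [], 2: [], 3: []}
    for chrom, length in lengths.items():
        union = region_mask_near_tss(index, {chrom: length}, window=window)
        arr = union.array(chrom)
        covered = np.flatnonzero(arr)  # 0-based
        if covered.size == 0:
            continue
        positions = covered + 1
        idx, _ = index._nearest_vector(chrom, positions)
        _, entries = index._chrom_index(chrom)
        tiers = np.array([entries[i].tier for i in idx], dtype=np.int64)
        for tier in (1, 2, 3):
            sel = covered[tiers == tier]
            if sel.size == 0:
                continue
            # compress runs of consecutive positions into intervals
            breaks = np.flatnonzero(np.diff(sel) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(sel) - 1]])
            for s, t in zip(starts, ends):
                out_intervals[tier].append(
                    Interval(
                        chrom=chrom,
                        start=int(sel[s]),
                        end=int(sel[t]) + 1,
                        tier=tier,
                        label=f"nearest_tier_{tier}",
                    )
                )
    return {
        tier: GenomicMask.from_intervals(lengths, ivs)
        for tier, ivs in out_intervals.items()
    }


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_genes_tsv(path) -> list[GeneRecord]:
    """Simplified annotation: gene_id, chrom, strand, tss (or comma-separated
    transcript_starts) and optional mean_expression columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    genes = []
    for _, row in df.iterrows():
        if "transcript_starts" in df.columns and not pd.isna(row.get("transcript_starts")):
            starts = tuple(int(s) for s in str(row["transcript_starts"]).split(","))
        elif "tss" in df.columns:
            starts = (int(row["tss"]),)
        else:
            raise ValueError("annotation TSV needs a 'tss' or 'transcript_starts' column")
        expr = row.get("mean_expression")
        genes.append(
            GeneRecord(
                gene_id=str(row["gene_id"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                transcript_starts=starts,
                mean_expression=None if expr is None or pd.isna(expr) else float(expr),
            )
        )
    return genes


def read_genes_gtf(path) -> list[GeneRecord]:
    """Minimal GTF reader: 'transcript' features (or 'exon' fallback) with a
    gene_id attribute; other attributes are ignored."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    feature_types = set(db.featuretypes())
    use_type = "transcript" if "transcript" in feature_types else "exon"
    by_gene: dict[str, dict] = {}
    for feat in db.features_of_type(use_type):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            continue
        gene_id = gene_ids[0]
        start5 = feat.start if feat.strand == "+" else feat.end
        rec = by_gene.setdefault(
            gene_id, {"chrom": feat.seqid, "strand": feat.strand, "starts": []}
        )
        rec["starts"].append(start5)
    return [
        GeneRecord(
            gene_id=g,
            chrom=rec["chrom"],
            strand=rec["strand"],
            transcript_starts=tuple(sorted(set(rec["starts"]))),
        )
        for g, rec in sorted(by_gene.items())
    ]


def read_expression_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "mean_expression"} <= set(df.columns):
        raise ValueError("expression TSV must have gene_id and mean_expression columns")
    return dict(zip(df["gene_id"].astype(str), df["mean_expression"].astype(float)))
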