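"""Recurrence tallies and promoter hotspot calling against the CTTCCG motif.

A hotspot is a single genomic position mutated in at least ``min_recurrence``
samples and lying within a fixed window of an annotated TSS.  Hotspots are
classified by overlap with the extended motif NCTTCCGN: offsets are 0-based
on the CTTCCG-bearing strand with offset 0 at the leading N, offsets 1..6
spanning CTTCCG, offset 7 at the trailing N, and offset -1 one base upstream
of the leading N (reported for context, not counted as overlap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import TssIndex, nearest_tss
from .genome import ReferenceGenome, extract_context, scan_motif
from .stats import wilcoxon_rank_sum

__all__ = [
    "MotifIndex",
    "tally_recurrence",
    "call_hotspots",
    "motif_positional_distribution",
    "recurrence_vs_distance",
    "differential_expression_test",
]

DEFAULT_MOTIF = "CTTCCG"


class MotifIndex:
    """Occurrences of a motif on both strands with NCTTCCGN-style offsets.

    For a plus-strand occurrence starting at ``s`` (1-based), the extended
    N<motif>N element spans ``s-1 .. s+len``; for a minus-strand occurrence
    the element is read rightward-to-leftward, so offset 0 (the leading N on
    the motif strand) sits at plus-coordinate ``s+len``.
    """

    def __init__(self, genome: ReferenceGenome, motif: str = DEFAULT_MOTIF):
        self.motif = motif.upper()
        self.length = len(self.motif)
        self.occurrences = scan_motif(genome, self.motif)
        # position -> list of (occurrence start, strand, offset in N<motif>N)
        self._offsets: dict[tuple[str, int], list[tuple[int, str, int]]] = {}
        L = self.length
        for chrom, start, strand in self.occurrences:
            for off in range(-1, L + 2):  # offsets -1..L+1 in N<motif>N space
                if strand == "+":
                    pos = start - 1 + off
                else:
                    pos = start + L - off
                self._offsets.setdefault((chrom, pos), []).append((start, strand, off))

    def hits(self, chrom: str, pos: int) -> list[tuple[int, str, int]]:
        return self._offsets.get((chrom, pos), [])

    def offset_of(self, chrom: str, pos: int) -> tuple[int, str] | None:
        """(offset, strand) of the occurrence covering ``pos``, or None.

        Overlap (offset within the N<motif>N element) is preferred over
        adjacency; among equals, the occurrence closest to having the
        position central is reported.
        """
        hits = self.hits(chrom, pos)
        if not hits:
            return None
        L = self.length

        def rank(hit):
            _, _, off = hit
            overlap = 0 <= off <= L + 1
            return (not overlap, abs(off - (L + 1) / 2.0))

        start, strand, off = min(hits, key=rank)
        return off, strand

    def overlaps(self, chrom: str, pos: int) -> bool:
        """Overlap with the extended element N<motif>N (offsets 0..len+1)."""
        return any(0 <= off <= self.length + 1 for _, _, off in self.hits(chrom, pos))

    def overlap_positions(self) -> set[tuple[str, int]]:
        """All (chrom, pos) covered by any N<motif>N element."""
        return {
            key
            for key, hits in self._offsets.items()
            if any(0 <= off <= self.length + 1 for _, _, off in hits)
        }


def tally_recurrence(ss) -> pd.DataFrame:
    """Per-position recurrence across samples.

    A sample contributes at most one count to a position regardless of how
    many alternative alleles it carries there.  Returns a frame indexed by
    (chrom, pos) with a ``recurrence`` column and one ``alt_<B>`` count per
    observed alternative base.
    """
    df = ss.df
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "recurrence"]).set_index(["chrom", "pos"])
    rec = df.groupby(["chrom", "pos"])["sample_id"].nunique().rename("recurrence")
    alts = (
        df.groupby(["chrom", "pos", "alt"])["sample_id"]
        .nunique()
        .unstack("alt", fill_value=0)
        .add_prefix("alt_")
    )
    out = pd.concat([rec, alts], axis=1)
    out = out.sort_index()
    return out


def call_hotspots(
    ss,
    index: TssIndex,
    genome: ReferenceGenome,
    min_recurrence: int = 5,
    tss_window: int = 500,
    motif: str = DEFAULT_MOTIF,
    expression_matrix: pd.DataFrame | None = None,
    tallies: pd.DataFrame | None = None,
    motif_index: MotifIndex | None = None,
) -> pd.DataFrame:
    """Promoter hotspots: recurrent positions within ``tss_window`` of a TSS.

    Output columns mirror the fields of a hotspot report: recurrence,
    position, reference base, alt alleles, the +/-5 bp pyrimidine-strand
    context, motif overlap/offset, nearest and second-nearest gene with
    signed distances and tiers, and (when an expression matrix is supplied)
    a two-sided rank-sum p-value comparing expression of the nearest gene
    between mutated and non-mutated samples.  Sorted by descending
    recurrence, then coordinate.
    """
    if min_recurrence < 1:
        raise ValueError("min_recurrence must be >= 1")
    if tallies is None:
        tallies = tally_recurrence(ss)
    if motif_index is None:
        motif_index = MotifIndex(genome, motif)
    tiers = {e.gene_id: e.tier for e in index.entries}
    records = []
    recurrent = tallies[tallies["recurrence"] >= min_recurrence]
    for (chrom, pos), row in recurrent.iterrows():
        pos = int(pos)
        hit = nearest_tss(index, chrom, pos, second_window=tss_window)
        if hit is None:
            continue
        gene_id, dist, strand, second = hit
        if abs(dist) > tss_window:
            continue
        context11, ctx_strand = extract_context(genome, chrom, pos, flank=5)
        off = motif_index.offset_of(chrom, pos)
        overlap = motif_index.overlaps(chrom, pos)
        alt_cols = {
            c.replace("alt_", ""): int(row[c])
            for c in recurrent.columns
            if c.startswith("alt_") and row[c] > 0
        }
        de_p = None
        if expression_matrix is not None and gene_id in expression_matrix.index:
            mutated = set(
                ss.df[(ss.df["chrom"] == chrom) & (ss.df["pos"] == pos)]["sample_id"]
            )
            de_p = differential_expression_test(expression_matrix, gene_id, mutated)
        records.append(
            {
                "chrom": chrom,
                "pos": pos,
                "recurrence": int(row["recurrence"]),
                "ref": genome.base(chrom, pos),
                "alts": ",".join(f"{a}:{n}" for a, n in sorted(alt_cols.items())),
                "context11": context11,
                "context_strand": ctx_strand,
                "motif_overlap": overlap,
                "motif_offset": off[0] if off is not None else pd.NA,
                "motif_strand": off[1] if off is not None else pd.NA,
                "gene": gene_id,
                "tss_distance": int(dist),
                "tier": tiers.get(gene_id),
                "second_gene": second[0] if second else pd.NA,
                "second_distance": second[1] if second else pd.NA,
                "second_tier": tiers.get(second[0]) if second else pd.NA,
                "de_p": de_p if de_p is not None else pd.NA,
            }
        )
    out = pd.DataFrame.from_records(records)
    if len(out):
        out = out.sort_values(
            ["recurrence", "chrom", "pos"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return out


def motif_positional_distribution(
    positions: Iterable[tuple[str, int]] | pd.DataFrame,
    motif_index: MotifIndex,
    weights: Mapping[tuple[str, int], int] | None = None,
) -> pd.Series:
    """Histogram of mutated positions over offsets -1..len+1 of N<motif>N.

    ``positions`` is an iterable of (chrom, pos) or a frame with chrom/pos
    columns (e.g. a hotspot table).  With ``weights`` (such as per-position
    recurrence) mutation events rather than positions are counted.  Offsets
    are resolved on the motif-bearing strand, so minus-strand occurrences
    mirror plus-strand ones.
    """
    if isinstance(positions, pd.DataFrame):
        positions = list(zip(positions["chrom"], positions["pos"].astype(int)))
    L = motif_index.length
    counts = pd.Series(0, index=range(-1, L + 2), name="count")
    for chrom, pos in positions:
        off = motif_index.offset_of(chrom, pos)
        if off is None:
            continue
        w = weights.get((chrom, pos), 1) if weights is not None else 1
        counts[off[0]] += w
    return counts


def recurrence_vs_distance(
    ss,
    genome: ReferenceGenome,
    index: TssIndex,
    motif: str = DEFAULT_MOTIF,
    adjacency: int = 1,
    per_site: bool = False,
    motif_index: MotifIndex | None = None,
) -> pd.DataFrame:
    """Recurrence vs TSS distance for motif-overlapping/adjacent mutations.

    Every mutated position overlapping a motif occurrence or within
    ``adjacency`` bp of its boundary is emitted once per expression tier,
    with the signed distance to the nearest TSS among that tier's genes.
    With ``per_site`` recurrence is aggregated per motif occurrence
    (summing distinct mutated samples over the site) instead of per
    position.
    """
    if motif_index is None:
        motif_index = MotifIndex(genome, motif)
    L = motif_index.length
    lo, hi = 1 - adjacency, L + adjacency  # offsets inside CTTCCG are 1..L
    tallies = tally_recurrence(ss)
    tier_indices = {t: index.subset([t]) for t in (1, 2, 3)} if index.tiered else {None: index}
    rows = []
    site_samples: dict[tuple, set] = {}
    for (chrom, pos), row in tallies.iterrows():
        pos = int(pos)
        hits = [h for h in motif_index.hits(chrom, pos) if lo <= h[2] <= hi]
        if not hits:
            continue
        if per_site:
            start, strand, _ = hits[0]
            samples = set(
                ss.df[(ss.df["chrom"] == chrom) & (ss.df["pos"] == pos)]["sample_id"]
            )
            site_samples.setdefault((chrom, start, strand), set()).update(samples)
            continue
        for tier, sub in tier_indices.items():
            hit = nearest_tss(sub, chrom, pos, second_window=0)
            if hit is None:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "recurrence": int(row["recurrence"]),
                    "tier": tier,
                    "tss_distance": hit[1],
                    "gene": hit[0],
                }
            )
    if per_site:
        for (chrom, start, strand), samples in sorted(site_samples.items()):
            for tier, sub in tier_indices.items():
                hit = nearest_tss(sub, chrom, start, second_window=0)
                if hit is None:
                    continue
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": start,
                        "recurrence": len(samples),
                        "tier": tier,
                        "tss_distance": hit[1],
                        "gene": hit[0],
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "recurrence", "tier", "tss_distance", "gene"]
    )


def differential_expression_test(
    expression_matrix: pd.DataFrame, gene: str, mutated_samples: set
) -> float | None:
    """Two-sided Wilcoxon rank-sum p for expression vs mutation status.

    ``expression_matrix`` is genes x samples.  Returns None (absent result)
    when either group is empty.
    """
    if gene not in expression_matrix.index:
        return None
    row = expression_matrix.loc[gene].dropna()
    mutated = row[row.index.isin(mutated_samples)]
    unmutated = row[~row.index.isin(mutated_samples)]
    if len(mutated) == 0 or len(unmutated) == 0:
        return None
    return wilcoxon_rank_sum(mutated.to_numpy(), unmutated.to_numpy()).p_value
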