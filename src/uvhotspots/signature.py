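"""Context-specific mutation probabilities for trinucleotide and extended
CTTCCG-related contexts, stratified by genomic region.

The central statistic is

    probability = mutations / (instances * n_samples)

where ``mutations`` is the number of observed substitutions whose
pyrimidine-strand context matches the pattern at the mutated index (within
the stratum), ``instances`` the number of genomic occurrences of the
pattern in the stratum, and ``n_samples`` the cohort size.  The three
factors are reported separately in every row so the probability can be
recomputed exactly.  Rows with zero instances carry an undefined (NaN)
probability, serialized as "NA", never a division result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import TssIndex, nearest_tier_masks, region_mask_near_tss
from .genome import (
    PYRIMIDINE_TRINUCLEOTIDES,
    ContextSpec,
    ReferenceGenome,
    context_instance_positions,
    reverse_complement,
    trinucleotide_codes,
    trinucleotide_instance_counts,
)
from .regions import GenomicMask
from .variants import SUBSTITUTION_CLASSES, SampleSet

logger = logging.getLogger(__name__)

__all__ = [
    "context_mutation_probability",
    "trinucleotide_panel",
    "motif_panel",
    "stratified_run",
    "vulnerability_ratio",
    "VulnerabilityRatio",
    "serialize_table",
]

_TABLE_COLUMNS = [
    "stratum",
    "context",
    "mut_index",
    "substitution",
    "mutations",
    "instances",
    "n_samples",
    "probability",
]


def _probability(mutations: int, instances: int, n_samples: int) -> float:
    if instances == 0:
        return float("nan")
    return mutations / (instances * n_samples)


def _normalized_class(ref: str, alt: str) -> str:
    if ref in "AG":
        return f"{reverse_complement(ref)}>{reverse_complement(alt)}"
    return f"{ref}>{alt}"


def _variant_matches_spec(
    genome: ReferenceGenome, chrom: str, pos: int, ref: str, spec: ContextSpec
) -> bool:
    """Does the pyrimidine-strand context of a variant match ``spec``?"""
    L = len(spec.pattern)
    mi = spec.mut_index
    if ref in "CT":
        window = genome.fetch(chrom, pos - mi, pos + (L - 1 - mi))
    else:
        window = reverse_complement(
            genome.fetch(chrom, pos - (L - 1 - mi), pos + mi)
        )
    return all(
        c in "ACGT" and (p == "N" or p == c) for p, c in zip(spec.pattern, window)
    )


def context_mutation_probability(
    ss: SampleSet,
    genome: ReferenceGenome,
    spec: ContextSpec,
    mask: GenomicMask | None = None,
    stratum: str = "genome_wide",
    exclude_positions: set[tuple[str, int]] | None = None,
    instances: int | None = None,
) -> pd.DataFrame:
    """Probability rows (per substitution class + total) for one context.

    Mutations are counted at positions whose pyrimidine-normalized context
    matches ``spec`` at the mutated index, restricted to ``mask`` when
    given.  ``exclude_positions`` removes specific sites from both the
    mutation and instance counts (used for motif-free baselines).
    ``instances`` short-circuits the instance scan when the caller has
    already counted.
    """
    if ss.n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if instances is None:
        positions = context_instance_positions(genome, spec)
        inst = 0
        for chrom, pos, _strand in positions:
            if mask is not None and not mask.contains(chrom, pos):
                continue
            if exclude_positions and (chrom, pos) in exclude_positions:
                continue
            inst += 1
    else:
        inst = instances
    class_counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    for row in ss.df.itertuples(index=False):
        pos = int(row.pos)
        if mask is not None and not mask.contains(row.chrom, pos):
            continue
        if exclude_positions and (row.chrom, pos) in exclude_positions:
            continue
        if not _variant_matches_spec(genome, row.chrom, pos, row.ref, spec):
            continue
        class_counts[_normalized_class(row.ref, row.alt)] += 1
    rows = []
    for cls in SUBSTITUTION_CLASSES:
        rows.append(
            {
                "stratum": stratum,
                "context": spec.label or spec.pattern,
                "mut_index": spec.mut_index,
                "substitution": cls,
                "mutations": class_counts[cls],
                "instances": inst,
                "n_samples": ss.n_samples,
                "probability": _probability(class_counts[cls], inst, ss.n_samples),
            }
        )
    total = sum(class_counts.values())
    rows.append(
        {
            "stratum": stratum,
            "context": spec.label or spec.pattern,
            "mut_index": spec.mut_index,
            "substitution": "total",
            "mutations": total,
            "instances": inst,
            "n_samples": ss.n_samples,
            "probability": _probability(total, inst, ss.n_samples),
        }
    )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def _variant_trinuc_classes(ss: SampleSet, genome: ReferenceGenome):
    """(trinuc index, class index, chrom, pos) arrays for all variants."""
    tri_idx = []
    cls_idx = []
    chroms = []
    poss = []
    cls_lookup = {c: i for i, c in enumerate(SUBSTITUTION_CLASSES)}
    tri_cache = {}
    for row in ss.df.itertuples(index=False):
        chrom = row.chrom
        if chrom not in tri_cache:
            tri_cache[chrom] = trinucleotide_codes(genome, chrom)
        t = int(tri_cache[chrom][int(row.pos) - 1])
        tri_idx.append(t)
        cls_idx.append(cls_lookup[_normalized_class(row.ref, row.alt)])
        chroms.append(chrom)
        poss.append(int(row.pos))
    return (
        np.array(tri_idx, dtype=np.int64),
        np.array(cls_idx, dtype=np.int64),
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
    )


def trinucleotide_panel(
    ss: SampleSet,
    genome: ReferenceGenome,
    mask: GenomicMask | None = None,
    stratum: str = "genome_wide",
    variant_filter: np.ndarray | None = None,
) -> pd.DataFrame:
    """Probability table over the 32 pyrimidine-centered trinucleotides.

    Each SNV falls in exactly one trinucleotide row (its pyrimidine-strand
    context), so row mutation totals partition the SNV count in the mask.
    ``variant_filter`` is an optional boolean array over ``ss.df`` rows that
    further restricts which mutations are counted (used by tier strata,
    where mutation membership is by nearest gene, not by mask geometry).
    """
    instances = trinucleotide_instance_counts(genome, mask)
    tri_idx, cls_idx, chroms, poss = _variant_trinuc_classes(ss, genome)
    keep = tri_idx >= 0
    if mask is not None:
        in_mask = np.array(
            [mask.contains(c, p) for c, p in zip(chroms, poss)], dtype=bool
        )
        keep &= in_mask
    if variant_filter is not None:
        keep &= np.asarray(variant_filter, dtype=bool)
    counts = np.zeros((32, len(SUBSTITUTION_CLASSES)), dtype=np.int64)
    np.add.at(counts, (tri_idx[keep], cls_idx[keep]), 1)
    rows = []
    for i, tri in enumerate(PYRIMIDINE_TRINUCLEOTIDES):
        inst = int(instances[i])
        for j, cls in enumerate(SUBSTITUTION_CLASSES):
            # purely cosmetic: skip classes whose center base cannot occur here
            if cls[0] != tri[1]:
                continue
            rows.append(
                {
                    "stratum": stratum,
                    "context": tri,
                    "mut_index": 1,
                    "substitution": cls,
                    "mutations": int(counts[i, j]),
                    "instances": inst,
                    "n_samples": ss.n_samples,
                    "probability": _probability(int(counts[i, j]), inst, ss.n_samples),
                }
            )
        total = int(counts[i].sum())
        rows.append(
            {
                "stratum": stratum,
                "context": tri,
                "mut_index": 1,
                "substitution": "total",
                "mutations": total,
                "instances": inst,
                "n_samples": ss.n_samples,
                "probability": _probability(total, inst, ss.n_samples),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


#: Mutable cytosines of the extended element N-CTTCCG-N, written as context
#: specs on the motif-bearing (pyrimidine) strand, with the marginal matched
#: trinucleotide for each (the trinucleotide centered on the same base).
MOTIF_CONTEXTS: list[tuple[ContextSpec, ContextSpec]] = [
    (
        ContextSpec("CCTTCCG", 0, label="[C]CTTCCG"),
        ContextSpec("NCC", 1, label="N[C]C"),
    ),
    (
        ContextSpec("NCTTCCGN", 1, label="N[C]TTCCGN"),
        ContextSpec("NCT", 1, label="N[C]T"),
    ),
    (
        ContextSpec("NCTTCCGN", 4, label="NCTT[C]CGN"),
        ContextSpec("TCC", 1, label="T[C]C"),
    ),
    (
        ContextSpec("NCTTCCGN", 5, label="NCTTC[C]GN"),
        ContextSpec("CCG", 1, label="C[C]G"),
    ),
]


def motif_panel(
    ss: SampleSet,
    genome: ReferenceGenome,
    mask: GenomicMask | None = None,
    stratum: str = "genome_wide",
) -> pd.DataFrame:
    """Extended-motif probability rows with their matched trinucleotides.

    Emits one block per mutable cytosine of N-CTTCCG-N (the 5' flanking C,
    the first C of CTTCCG, and the two central Cs) alongside the marginal
    trinucleotide centered on the same base, enabling side-by-side
    comparison of extended-context vs trinucleotide probabilities.  Specific
    trinucleotide rows (e.g. TCT vs NCT) come from
    :func:`trinucleotide_panel`.
    """
    frames = []
    for motif_spec, matched_spec in MOTIF_CONTEXTS:
        frames.append(
            context_mutation_probability(ss, genome, motif_spec, mask, stratum=stratum)
        )
        frames.append(
            context_mutation_probability(ss, genome, matched_spec, mask, stratum=stratum)
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class VulnerabilityRatio:
    """Pooled motif 5'-cytosine probability over a motif-free matched
    trinucleotide baseline, in one stratum."""

    ratio: float
    motif_probability: float
    baseline_probability: float
    motif_mutations: int
    motif_instances: int
    baseline_mutations: int
    baseline_instances: int
    n_samples: int


def vulnerability_ratio(
    ss: SampleSet,
    genome: ReferenceGenome,
    mask: GenomicMask | None = None,
    motif: str = "CTTCCG",
    motif_index=None,
) -> VulnerabilityRatio:
    """Elevation of motif 5'-cytosine mutation probability over baseline.

    The numerator pools the two 5'-end cytosines of the extended element
    (the leading flank base when it is a C, and the first C of the motif).
    The baseline pools the marginal matched trinucleotides (NCC and NCT)
    over positions *not* overlapping any N<motif>N element: in compact
    synthetic genomes the motif positions themselves are a non-negligible
    share of the matched trinucleotide rows, which would otherwise drag the
    ratio toward 1.
    """
    from .hotspots import MotifIndex

    if motif_index is None:
        motif_index = MotifIndex(genome, motif)
    excluded = motif_index.overlap_positions()

    # numerator sites: offset 1 always (first C of the motif); offset 0 when
    # the leading flank base is a C on the motif strand
    L = motif_index.length
    numer_sites: set[tuple[str, int]] = set()
    for chrom, start, strand in motif_index.occurrences:
        if strand == "+":
            first_c = start
            lead = start - 1
            lead_base, want = (
                genome.fetch(chrom, lead, lead) if lead >= 1 else "N",
                "C",
            )
        else:
            first_c = start + L - 1
            lead = start + L
            lead_base, want = (
                genome.fetch(chrom, lead, lead)
                if lead <= genome.lengths[chrom]
                else "N",
                "G",  # C on the minus strand
            )
        numer_sites.add((chrom, first_c))
        if lead_base == want:
            numer_sites.add((chrom, lead))
    if mask is not None:
        numer_sites = {
            (c, p) for c, p in numer_sites if mask.contains(c, p)
        }
    motif_inst = len(numer_sites)
    motif_mut = 0
    for row in ss.df.itertuples(index=False):
        if (row.chrom, int(row.pos)) in numer_sites:
            motif_mut += 1

    base_mut = 0
    base_inst = 0
    for spec in (ContextSpec("NCC", 1), ContextSpec("NCT", 1)):
        tbl = context_mutation_probability(
            ss, genome, spec, mask=mask, exclude_positions=excluded
        )
        total = tbl[tbl["substitution"] == "total"].iloc[0]
        base_mut += int(total["mutations"])
        base_inst += int(total["instances"])

    p_motif = _probability(motif_mut, motif_inst, ss.n_samples)
    p_base = _probability(base_mut, base_inst, ss.n_samples)
    ratio = p_motif / p_base if p_base and not np.isnan(p_base) and p_base > 0 else float("nan")
    return VulnerabilityRatio(
        ratio=ratio,
        motif_probability=p_motif,
        baseline_probability=p_base,
        motif_mutations=motif_mut,
        motif_instances=motif_inst,
        baseline_mutations=base_mut,
        baseline_instances=base_inst,
        n_samples=ss.n_samples,
    )


def stratified_run(
    ss: SampleSet,
    genome: ReferenceGenome,
    index: TssIndex,
    strata: tuple[str, ...] = (
        "genome_wide",
        "tss500_tier1",
        "tss500_tier2",
        "tss500_tier3",
    ),
    window: int = 500,
    include_motif_panel: bool = True,
) -> dict[str, pd.DataFrame]:
    """Probability tables per stratum.

    Supported strata: ``genome_wide``; ``tss500_tier{1,2,3}`` (positions
    whose nearest TSS is within ``window``, assigned to the nearest gene's
    tier, so the three tier strata partition the TSS-proximal set); and
    ``upstream500_tier3_template`` / ``upstream500_tier3_non_template``
    (transcriptionally upstream windows of top-tier genes, mutations and
    instances split by whether the pyrimidine/motif-bearing chromosomal
    strand is the template or non-template strand of the downstream gene).
    """
    out: dict[str, pd.DataFrame] = {}
    lengths = genome.lengths
    tier_masks = None
    for stratum in strata:
        if stratum == "genome_wide":
            frames = [trinucleotide_panel(ss, genome, None, stratum=stratum)]
            if include_motif_panel:
                frames.append(motif_panel(ss, genome, None, stratum=stratum))
            out[stratum] = pd.concat(frames, ignore_index=True)
        elif stratum.startswith("tss") and "_tier" in stratum:
            tier = int(stratum.rsplit("tier", 1)[1])
            if tier_masks is None:
                tier_masks = nearest_tier_masks(index, lengths, window=window)
            mask = tier_masks[tier]
            frames = [trinucleotide_panel(ss, genome, mask, stratum=stratum)]
            if include_motif_panel:
                frames.append(motif_panel(ss, genome, mask, stratum=stratum))
            out[stratum] = pd.concat(frames, ignore_index=True)
        elif stratum.startswith("upstream"):
            strand_kind = "template" if stratum.endswith("_template") and not stratum.endswith(
                "non_template"
            ) else "non_template"
            out[stratum] = _strand_split_tables(
                ss, genome, index, strand_kind, window=window,
                stratum=stratum, include_motif_panel=include_motif_panel,
            )
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
    return out


def _strand_split_tables(
    ss, genome, index, strand_kind, window, stratum, include_motif_panel=True
):
    """Upstream-window, top-tier, strand-resolved probability tables.

    A mutation is assigned by which chromosomal strand carries its
    pyrimidine (plus when the reference base is C/T); a context instance by
    the chromosomal strand carrying its pattern.  A position inside the
    upstream windows of two opposite-strand genes is counted once per gene
    (logged).
    """
    mask = region_mask_near_tss(
        index, genome.lengths, window=window, tier_filter=[3], side="upstream_only"
    )
    double_counted = 0
    # per-interval membership with strand requirement
    selected_intervals = []
    for iv in mask.intervals:
        wanted_strand = iv.template_strand if strand_kind == "template" else iv.gene_strand
        selected_intervals.append((iv, wanted_strand))

    def variant_in_stratum(chrom, pos, ref):
        pyr_strand = "+" if ref in "CT" else "-"
        n = 0
        for iv, wanted in selected_intervals:
            if iv.chrom == chrom and iv.start <= pos - 1 < iv.end and pyr_strand == wanted:
                n += 1
        return n

    # mutation filter (may count a variant in two genes' windows)
    variant_mult = np.array(
        [
            variant_in_stratum(row.chrom, int(row.pos), row.ref)
            for row in ss.df.itertuples(index=False)
        ],
        dtype=np.int64,
    )
    double_counted = int((variant_mult > 1).sum())
    if double_counted:
        logger.info(
            "%s: %d mutations fall in upstream windows of two genes and are "
            "counted once per gene", stratum, double_counted,
        )

    frames = []
    # trinucleotide rows, strand-resolved: instance = position whose
    # pyrimidine strand matches the interval's required strand
    tri_rows = []
    tri_instances = np.zeros(32, dtype=np.int64)
    for iv, wanted in selected_intervals:
        tri = trinucleotide_codes(genome, iv.chrom)[iv.start : iv.end]
        codes = genome.codes(iv.chrom)[iv.start : iv.end]
        pyr_plus = (codes == 1) | (codes == 3)  # C or T on plus strand
        strand_ok = pyr_plus if wanted == "+" else ~pyr_plus
        valid = (tri >= 0) & strand_ok
        tri_instances += np.bincount(tri[valid], minlength=32)
    tri_idx, cls_idx, chroms, poss = _variant_trinuc_classes(ss, genome)
    counts = np.zeros((32, len(SUBSTITUTION_CLASSES)), dtype=np.int64)
    refs = ss.df["ref"].to_numpy()
    for k in range(len(ss.df)):
        if tri_idx[k] < 0 or variant_mult[k] == 0:
            continue
        counts[tri_idx[k], cls_idx[k]] += variant_mult[k]
    for i, tri in enumerate(PYRIMIDINE_TRINUCLEOTIDES):
        inst = int(tri_instances[i])
        total = int(counts[i].sum())
        for j, cls in enumerate(SUBSTITUTION_CLASSES):
            if cls[0] != tri[1]:
                continue
            tri_rows.append(
                {
                    "stratum": stratum, "context": tri, "mut_index": 1,
                    "substitution": cls, "mutations": int(counts[i, j]),
                    "instances": inst, "n_samples": ss.n_samples,
                    "probability": _probability(int(counts[i, j]), inst, ss.n_samples),
                }
            )
        tri_rows.append(
            {
                "stratum": stratum, "context": tri, "mut_index": 1,
                "substitution": "total", "mutations": total,
                "instances": inst, "n_samples": ss.n_samples,
                "probability": _probability(total, inst, ss.n_samples),
            }
        )
    frames.append(pd.DataFrame(tri_rows, columns=_TABLE_COLUMNS))

    if include_motif_panel:
        motif_rows = []
        for motif_spec, matched_spec in MOTIF_CONTEXTS:
            for spec in (motif_spec, matched_spec):
                inst = 0
                for chrom, pos, strand in context_instance_positions(genome, spec):
                    for iv, wanted in selected_intervals:
                        if iv.chrom == chrom and iv.start <= pos - 1 < iv.end and strand == wanted:
                            inst += 1
                mut = {c: 0 for c in SUBSTITUTION_CLASSES}
                for k, row in enumerate(ss.df.itertuples(index=False)):
                    if variant_mult[k] == 0:
                        continue
                    if _variant_matches_spec(genome, row.chrom, int(row.pos), row.ref, spec):
                        mut[_normalized_class(row.ref, row.alt)] += int(variant_mult[k])
                total = sum(mut.values())
                motif_rows.append(
                    {
                        "stratum": stratum, "context": spec.label or spec.pattern,
                        "mut_index": spec.mut_index, "substitution": "total",
                        "mutations": total, "instances": inst,
                        "n_samples": ss.n_samples,
                        "probability": _probability(total, inst, ss.n_samples),
                    }
                )
        frames.append(pd.DataFrame(motif_rows, columns=_TABLE_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def serialize_table(table: pd.DataFrame, path) -> None:
    """Write a probability table as TSV, undefined probabilities as 'NA'."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")
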