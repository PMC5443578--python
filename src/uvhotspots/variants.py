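"""Somatic variant ingestion, blacklist filtering, pyrimidine normalization.

Only single-nucleotide substitutions are retained: indels and multi-allelic
records are dropped (with counts recorded in ``SampleSet.meta``).  CC>TT
dinucleotide events enter as two adjacent same-sample C>T substitutions;
:func:`flag_dinucleotide_events` reports them without collapsing, since all
recurrence and probability statistics in this package are per-position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, extract_context, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "SampleSet",
    "read_variants",
    "write_variants_tsv",
    "write_variants_vcf",
    "read_blacklist_tsv",
    "apply_blacklist",
    "filter_by_vaf",
    "pyrimidine_normalize",
    "normalize_table",
    "flag_dinucleotide_events",
]

_BASES = frozenset("ACGT")
_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vaf"]

#: The six pyrimidine-centered substitution classes.
SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]


@dataclass(frozen=True)
class Variant:
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")


@dataclass
class SampleSet:
    """An ordered cohort of samples and their SNVs.

    ``samples`` lists every declared sample, including ones with zero
    variants; ``n_samples`` (the probability denominator) is its length.
    """

    samples: list[str]
    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df is None or len(self.df) == 0:
            self.df = pd.DataFrame(columns=_COLUMNS)
        self.df = self.df.reindex(columns=_COLUMNS)
        unknown = set(self.df["sample_id"]) - set(self.samples)
        if unknown:
            raise ValueError(f"variants reference undeclared samples: {sorted(unknown)[:5]}")
        self.sort()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self.df)

    def sort(self) -> None:
        self.df = self.df.sort_values(
            ["chrom", "pos", "sample_id", "alt"], kind="mergesort"
        ).reset_index(drop=True)

    def variants(self) -> Iterator[Variant]:
        for row in self.df.itertuples(index=False):
            yield Variant(
                sample_id=row.sample_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                vaf=None if pd.isna(row.vaf) else float(row.vaf),
            )

    @classmethod
    def from_variants(
        cls, variants: Iterable[Variant], samples: Iterable[str] | None = None
    ) -> "SampleSet":
        records = [
            (v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.vaf) for v in variants
        ]
        df = pd.DataFrame(records, columns=_COLUMNS)
        if samples is None:
            samples = sorted(df["sample_id"].unique())
        return cls(samples=list(samples), df=df)

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Reject the set if any ref base disagrees with the genome."""
        mismatches = []
        for row in self.df.itertuples(index=False):
            actual = genome.base(row.chrom, int(row.pos))
            if actual != row.ref:
                mismatches.append(f"{row.chrom}:{row.pos} ref={row.ref} genome={actual}")
                if len(mismatches) >= 10:
                    break
        if mismatches:
            raise ValueError(
                "reference mismatches between variants and genome: "
                + "; ".join(mismatches)
            )


def read_variants(
    path,
    fmt: str | None = None,
    samples: Iterable[str] | None = None,
    sample_id: str | None = None,
    genome: ReferenceGenome | None = None,
) -> SampleSet:
    """Read SNVs from a VCF (single- or multi-sample) or a sample-column TSV.

    Indels and multi-allelic records are dropped with counts recorded in
    ``meta['dropped_indels']`` / ``meta['dropped_multiallelic']``.  When a
    genome is supplied, every retained ref base is validated against it.
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        ss = _read_vcf(path, samples=samples, sample_id=sample_id)
    elif fmt == "tsv":
        ss = _read_tsv(path, samples=samples)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")
    if genome is not None:
        ss.validate_against(genome)
    return ss


def _read_vcf(path, samples=None, sample_id=None) -> SampleSet:
    import pysam

    dropped_indels = 0
    dropped_multi = 0
    records = []
    with pysam.VariantFile(path) as vcf:
        header_samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                dropped_multi += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                dropped_indels += 1
                continue
            if header_samples:
                for name in header_samples:
                    gt = rec.samples[name].get("GT")
                    if gt and any(a == 1 for a in gt if a is not None):
                        records.append((name, rec.chrom, rec.pos, ref, alt, None))
            else:
                if sample_id is None:
                    raise ValueError(
                        "VCF has no sample columns; pass sample_id= for single-sample input"
                    )
                records.append((sample_id, rec.chrom, rec.pos, ref, alt, None))
    declared = list(samples) if samples is not None else (
        header_samples or ([sample_id] if sample_id else [])
    )
    df = pd.DataFrame(records, columns=_COLUMNS)
    if not declared:
        declared = sorted(df["sample_id"].unique())
    if dropped_indels or dropped_multi:
        logger.info(
            "dropped %d indel and %d multi-allelic records from %s",
            dropped_indels, dropped_multi, path,
        )
    ss = SampleSet(samples=declared, df=df)
    ss.meta.update(dropped_indels=dropped_indels, dropped_multiallelic=dropped_multi)
    return ss


def _read_tsv(path, samples=None) -> SampleSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if len(df) == 0 and samples is None:
        return SampleSet(samples=[], df=None)
    # tolerate 'sample' as an alias
    if "sample" in df.columns and "sample_id" not in df.columns:
        df = df.rename(columns={"sample": "sample_id"})
    required = {"sample_id", "chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"variant TSV must have columns {sorted(required)}")
    dropped = 0
    keep = df["ref"].isin(_BASES) & df["alt"].isin(_BASES) & (df["ref"] != df["alt"])
    dropped = int((~keep).sum())
    bad_rows = df.index[~keep]
    for i in bad_rows[:5]:
        logger.info("dropping non-SNV record at line %d of %s", i + 2, path)
    df = df[keep].copy()
    df["pos"] = df["pos"].astype(int)
    if "vaf" not in df.columns:
        df["vaf"] = np.nan
    declared = list(samples) if samples is not None else sorted(df["sample_id"].unique())
    ss = SampleSet(samples=declared, df=df[["sample_id", "chrom", "pos", "ref", "alt", "vaf"]])
    ss.meta.update(dropped_indels=dropped, dropped_multiallelic=0)
    return ss


def write_variants_tsv(ss: SampleSet, path) -> None:
    out = ss.df.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="")


def write_variants_vcf(ss: SampleSet, path, genome: ReferenceGenome | None = None) -> None:
    """Minimal multi-sample VCF 4.2 writer (GT genotypes only)."""
    grouped = ss.df.groupby(["chrom", "pos", "ref", "alt"], sort=True)["sample_id"].agg(set)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if genome is not None:
            for chrom, length in genome.lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in sorted(ss.df["chrom"].unique()):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ss.samples)
            + "\n"
        )
        for (chrom, pos, ref, alt), carriers in grouped.items():
            gts = "\t".join("0/1" if s in carriers else "0/0" for s in ss.samples)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_blacklist_tsv(path) -> set[tuple]:
    """Position blacklist: columns chrom, pos and optional alt.

    Rows without an alt exclude the position for every alternative allele;
    rows with an alt exclude only that substitution.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError("blacklist TSV must have chrom and pos columns")
    entries: set[tuple] = set()
    has_alt = "alt" in df.columns
    for row in df.itertuples(index=False):
        if has_alt and isinstance(row.alt, str) and row.alt in _BASES:
            entries.add((row.chrom, int(row.pos), row.alt))
        else:
            entries.add((row.chrom, int(row.pos)))
    return entries


def apply_blacklist(ss: SampleSet, blacklist: set[tuple]) -> SampleSet:
    """Remove variants at blacklisted positions (or position+alt entries)."""
    if not blacklist:
        out = SampleSet(samples=list(ss.samples), df=ss.df.copy(), meta=dict(ss.meta))
        out.meta["blacklist_removed"] = 0
        return out
    pos_level = {(c, p) for entry in blacklist if len(entry) == 2 for c, p in [entry]}
    allele_level = {entry for entry in blacklist if len(entry) == 3}
    keys_pos = list(zip(ss.df["chrom"], ss.df["pos"].astype(int)))
    keys_allele = list(zip(ss.df["chrom"], ss.df["pos"].astype(int), ss.df["alt"]))
    drop = np.array(
        [kp in pos_level or ka in allele_level for kp, ka in zip(keys_pos, keys_allele)],
        dtype=bool,
    )
    out = SampleSet(
        samples=list(ss.samples),
        df=ss.df[~drop].copy(),
        meta=dict(ss.meta),
    )
    out.meta["blacklist_removed"] = int(drop.sum())
    return out


def filter_by_vaf(ss: SampleSet, min_vaf: float) -> SampleSet:
    """Keep variants with VAF >= min_vaf (variants lacking a VAF are kept)."""
    keep = ss.df["vaf"].isna() | (ss.df["vaf"] >= min_vaf)
    out = SampleSet(samples=list(ss.samples), df=ss.df[keep].copy(), meta=dict(ss.meta))
    out.meta["vaf_removed"] = int((~keep).sum())
    return out


def pyrimidine_normalize(
    variant: Variant, genome: ReferenceGenome, flank: int = 1
) -> tuple[str, str]:
    """Pyrimidine-strand substitution class and context for one variant.

    If the reference base is a purine, ref/alt are complemented and the
    context window reverse-complemented, so the class is one of the six
    pyrimidine-centered classes (C>A, C>G, C>T, T>A, T>C, T>G).
    """
    context, strand = extract_context(
        genome, variant.chrom, variant.pos, flank, pyrimidine_normalize=True
    )
    if strand == "-":
        ref = reverse_complement(variant.ref)
        alt = reverse_complement(variant.alt)
    else:
        ref, alt = variant.ref, variant.alt
    return f"{ref}>{alt}", context


def normalize_table(ss: SampleSet, genome: ReferenceGenome, flank: int = 1) -> pd.DataFrame:
    """Vectorized pyrimidine normalization of a whole SampleSet.

    Returns the variant table with added ``pyr_strand``, ``subst_class`` and
    ``context`` columns.
    """
    df = ss.df.copy()
    strands = []
    classes = []
    contexts = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for row in df.itertuples(index=False):
        context, strand = extract_context(genome, row.chrom, int(row.pos), flank)
        if strand == "-":
            classes.append(f"{comp[row.ref]}>{comp[row.alt]}")
        else:
            classes.append(f"{row.ref}>{row.alt}")
        strands.append(strand)
        contexts.append(context)
    df["pyr_strand"] = strands
    df["subst_class"] = classes
    df["context"] = contexts
    return df


def flag_dinucleotide_events(ss: SampleSet) -> pd.DataFrame:
    """Same-sample adjacent C>T pairs (CC>TT candidates on either strand).

    Reported for annotation only; positions remain independent elsewhere.
    A pair is flagged when one sample carries C>T (or G>A, the minus-strand
    reading) at two adjacent positions on the same chromosome.
    """
    df = ss.df
    ct = df[((df["ref"] == "C") & (df["alt"] == "T")) | ((df["ref"] == "G") & (df["alt"] == "A"))]
    pairs = []
    for (sample, chrom), grp in ct.groupby(["sample_id", "chrom"]):
        positions = np.sort(grp["pos"].astype(int).to_numpy())
        adjacent = positions[:-1][np.diff(positions) == 1]
        for p in adjacent:
            pairs.append({"sample_id": sample, "chrom": chrom, "pos1": int(p), "pos2": int(p) + 1})
    return pd.DataFrame(pairs, columns=["sample_id", "chrom", "pos1", "pos2"])
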