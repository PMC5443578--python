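"""Synthetic genomes, cohorts and ground truth for the full analysis chain.

The generator emulates the statistical structure the analysis assumes: a
random genome with CTTCCG elements planted near transcription start sites of
genes in each expression tier, a UV-like trinucleotide substitution
signature (C>T at dipyrimidines dominant, occasional CC>TT extension), per-
tumor mutation loads spanning orders of magnitude, and a multiplicative
position-specific vulnerability factor ``f`` applied at the 5'-end cytosines
of motif elements near active-tier TSSs (with a separate smaller factor at
the central CC).  Ground truth (per-position weights, the vulnerable-site
table and realized loads) is returned alongside the cohort so parameter
recovery can be checked.

Mutations are sampled without within-tumor position replacement (a site
mutates at most once per tumor) by weighted reservoir keys, and the number
of emitted substitutions per tumor equals the drawn load exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    GeneRecord,
    TssIndex,
    assign_expression_tiers,
    derive_tss,
)
from .genome import PYRIMIDINE_TRINUCLEOTIDES, ReferenceGenome, scan_motif, trinucleotide_codes
from .variants import SUBSTITUTION_CLASSES, SampleSet

__all__ = [
    "SimulationConfig",
    "ReferenceBundle",
    "SimulationTruth",
    "default_uv_signature",
    "uniform_signature",
    "generate_reference",
    "simulate_tumors",
    "write_bundle",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def default_uv_signature() -> dict[tuple[str, str], float]:
    """UV-like relative weights per (pyrimidine trinucleotide, class).

    C>T at dipyrimidine cytosines (5' neighbor T or C) dominates, matching
    the photoproduct-driven spectrum; transversions at C and mutations at T
    carry small weights so the spectrum is not degenerate.
    """
    weights: dict[tuple[str, str], float] = {}
    for tri in PYRIMIDINE_TRINUCLEOTIDES:
        five, center, _ = tri
        if center == "C":
            weights[(tri, "C>T")] = 1.0 if five in "CT" else 0.05
            weights[(tri, "C>A")] = 0.02
            weights[(tri, "C>G")] = 0.02
        else:
            weights[(tri, "T>C")] = 0.05 if five in "CT" else 0.01
            weights[(tri, "T>A")] = 0.01
            weights[(tri, "T>G")] = 0.01
    return weights


def uniform_signature() -> dict[tuple[str, str], float]:
    """Flat signature: every (trinucleotide, class) pair equally likely."""
    weights = {}
    for tri in PYRIMIDINE_TRINUCLEOTIDES:
        for cls in SUBSTITUTION_CLASSES:
            if cls[0] == tri[1]:
                weights[(tri, cls)] = 1.0
    return weights


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a 10 Mb two-chromosome genome with 300 genes (100 per
    expression tier), 60 planted CTTCCG elements in the TSS windows of each
    tier, 38 tumors with log-uniform loads of 1e2-1e4 substitutions (two
    orders of magnitude, scaled to the genome size), and a 50-fold
    vulnerability at motif 5' cytosines near top-tier TSSs.  The load range
    keeps per-site per-tumor mutation probabilities well below one so a
    multiplicative vulnerability remains identifiable from probability
    ratios; pass a heavier range (e.g. 1e3-1e5) to reach the saturated
    regime where individual positions recur in >=5 of 38 tumors.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_genes: int = 300
    expression_log_mean: float = 1.0
    expression_log_sigma: float = 2.0
    motif: str = "CTTCCG"
    motifs_per_tier: int = 60
    motifs_background: int = 0
    motif_max_tss_distance: int = 450
    n_tumors: int = 38
    load_range: tuple[int, int] = (100, 10_000)
    signature: dict[tuple[str, str], float] = field(default_factory=default_uv_signature)
    cc_tt_rate: float = 0.1
    vulnerability_factor: float = 50.0
    central_factor: float = 5.0
    active_tier: int = 3
    vulnerability_window: int = 500

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if self.vulnerability_factor < 1 or self.central_factor < 1:
            raise ValueError("vulnerability factors must be >= 1")
        if not 0.0 <= self.cc_tt_rate <= 1.0:
            raise ValueError("cc_tt_rate must be in [0, 1]")
        if self.load_range[0] < 1 or self.load_range[1] < self.load_range[0]:
            raise ValueError("invalid load range")

    def signature_matrix(self) -> np.ndarray:
        """(32, 6) weight matrix indexed by trinucleotide and class."""
        mat = np.zeros((32, len(SUBSTITUTION_CLASSES)))
        tri_index = {t: i for i, t in enumerate(PYRIMIDINE_TRINUCLEOTIDES)}
        cls_index = {c: j for j, c in enumerate(SUBSTITUTION_CLASSES)}
        for (tri, cls), w in self.signature.items():
            if w < 0:
                raise ValueError("signature weights must be non-negative")
            if cls[0] != tri[1]:
                raise ValueError(f"class {cls} invalid for trinucleotide {tri}")
            mat[tri_index[tri], cls_index[cls]] = w
        return mat


@dataclass
class ReferenceBundle:
    genome: ReferenceGenome
    genes: list[GeneRecord]
    expression: dict[str, float]
    index: TssIndex  # tiered
    motif_manifest: pd.DataFrame
    config: SimulationConfig


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated cohort."""

    loads: np.ndarray  # realized load per tumor
    total_weight: float
    weights: dict[str, np.ndarray]  # per-chromosome per-position weight
    vulnerable_sites: pd.DataFrame  # chrom, pos, role, factor
    n_extensions: int
    signature_matrix: np.ndarray

    def expected_site_probability(self, site_weight: float) -> float:
        """Model probability that a site of given weight mutates in a tumor,
        averaged over the realized loads (weighted sampling without
        replacement gives ~1 - exp(-load * w / W))."""
        lam = self.loads * (site_weight / self.total_weight)
        return float(np.mean(1.0 - np.exp(-lam)))


def _random_chromosome(rng, length: int, composition) -> bytearray:
    codes = rng.choice(4, size=length, p=np.asarray(composition))
    return bytearray(bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]))


def _scan_local(seq_bytes: bytearray, motif: str, rc_motif: str, lo: int, hi: int) -> int:
    """Occurrences of motif (either orientation) in seq[lo:hi] (0-based)."""
    window = seq_bytes[max(lo, 0) : hi].decode()
    count = 0
    for pat in (motif, rc_motif):
        start = 0
        while True:
            i = window.find(pat, start)
            if i < 0:
                break
            count += 1
            start = i + 1
    return count


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Random genome + annotation + expression + planted-motif manifest.

    Motif placements are re-drawn when an insertion would create an
    unintended extra occurrence adjacent to the planted one, so the manifest
    is an exact subset of a genome-wide motif scan.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    motif = config.motif.upper()
    rc_motif = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs: dict[str, bytearray] = {
        c: _random_chromosome(rng, config.chromosome_length, config.base_composition)
        for c in chroms
    }

    # genes: jittered even spacing, random strand, 1-3 transcript starts
    margin = 2000
    genes: list[GeneRecord] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gene_no = 0
    for chrom, n_chrom_genes in zip(chroms, per_chrom):
        if n_chrom_genes == 0:
            continue
        anchors = np.linspace(margin, config.chromosome_length - margin, n_chrom_genes)
        spacing = anchors[1] - anchors[0] if n_chrom_genes > 1 else config.chromosome_length / 2
        jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, size=n_chrom_genes)
        tss_positions = np.clip(
            (anchors + jitter).astype(int), margin, config.chromosome_length - margin
        )
        strands = rng.choice(["+", "-"], size=n_chrom_genes)
        for tss, strand in zip(tss_positions, strands):
            gene_no += 1
            n_starts = int(rng.integers(1, 4))
            extra = rng.integers(100, 5000, size=n_starts - 1)
            if strand == "+":
                starts = (int(tss),) + tuple(int(tss + e) for e in extra)
            else:
                starts = (int(tss),) + tuple(max(int(tss - e), 1) for e in extra)
            genes.append(
                GeneRecord(
                    gene_id=f"G{gene_no:04d}",
                    chrom=chrom,
                    strand=strand,
                    transcript_starts=starts,
                )
            )
    expression = {
        g.gene_id: float(
            rng.lognormal(config.expression_log_mean, config.expression_log_sigma)
        )
        for g in genes
    }
    index = assign_expression_tiers(derive_tss(genes), expression)
    tss_by_gene = {e.gene_id: e for e in index.entries}

    # plant motifs near TSSs per tier, then in background
    occupied: dict[str, set[int]] = {c: set() for c in chroms}
    manifest_rows = []

    def plant(chrom: str, start1: int, gene_id, tier, distance) -> bool:
        """Try to write the motif at a 1-based start; False on collision."""
        L = len(motif)
        if start1 < 8 or start1 + L + 6 > config.chromosome_length:
            return False
        span = range(start1 - 8, start1 + L + 8)
        if any(p in occupied[chrom] for p in span):
            return False
        strand = str(rng.choice(["+", "-"]))
        seq = motif if strand == "+" else rc_motif
        lo0 = start1 - 1
        original = seqs[chrom][lo0 : lo0 + L]
        seqs[chrom][lo0 : lo0 + L] = seq.encode()
        # re-scan the neighborhood: exactly one occurrence may be present
        if _scan_local(seqs[chrom], motif, rc_motif, lo0 - 7, lo0 + L + 7) != 1:
            seqs[chrom][lo0 : lo0 + L] = original  # collision: restore, re-draw
            return False
        occupied[chrom].update(span)
        manifest_rows.append(
            {
                "chrom": chrom,
                "start": start1,
                "strand": strand,
                "gene_id": gene_id,
                "tier": tier,
                "tss_distance": distance,
            }
        )
        return True

    for tier in (1, 2, 3):
        tier_entries = [e for e in index.entries if e.tier == tier]
        if config.motifs_per_tier > len(tier_entries):
            raise ValueError(
                f"cannot plant {config.motifs_per_tier} motifs in tier {tier}: "
                f"only {len(tier_entries)} genes"
            )
        chosen = rng.choice(len(tier_entries), size=config.motifs_per_tier, replace=False)
        for gi in chosen:
            entry = tier_entries[int(gi)]
            placed = False
            for _attempt in range(200):
                offset = int(
                    rng.integers(
                        -config.motif_max_tss_distance,
                        config.motif_max_tss_distance - len(motif) + 2,
                    )
                )
                start1 = entry.tss + offset
                if plant(entry.chrom, start1, entry.gene_id, tier, offset):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"infeasible motif placement near TSS of {entry.gene_id} "
                    f"(window too crowded after 200 attempts)"
                )

    for _ in range(config.motifs_background):
        placed = False
        for _attempt in range(200):
            chrom = str(rng.choice(chroms))
            start1 = int(rng.integers(10, config.chromosome_length - 10))
            hit = index.nearest(chrom, start1, second_window=0)
            if hit is not None and abs(hit[1]) <= 2 * config.vulnerability_window:
                continue  # keep background motifs away from promoters
            if plant(chrom, start1, None, None, None):
                placed = True
                break
        if not placed:
            raise ValueError("infeasible background motif placement")

    genome = ReferenceGenome({c: seqs[c].decode() for c in chroms})
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["chrom", "start", "strand", "gene_id", "tier", "tss_distance"],
    )
    return ReferenceBundle(
        genome=genome,
        genes=genes,
        expression=expression,
        index=index,
        motif_manifest=manifest,
        config=config,
    )


def _vulnerable_sites(config: SimulationConfig, bundle: ReferenceBundle) -> pd.DataFrame:
    """Vulnerability map: every motif 5'/central cytosine near an active-tier
    TSS, with its factor and CC-pair partner (for CC>TT extension)."""
    genome = bundle.genome
    motif = config.motif.upper()
    L = len(motif)
    active = bundle.index.subset([config.active_tier])
    rows = []
    for chrom, start, strand in scan_motif(genome, motif):
        if strand == "+":
            first_c, lead = start, start - 1
            lead_is_c = genome.fetch(chrom, lead, lead) == "C" if lead >= 1 else False
            central = (start + 3, start + 4)
        else:
            first_c, lead = start + L - 1, start + L
            lead_is_c = (
                genome.fetch(chrom, lead, lead) == "G"
                if lead <= genome.lengths[chrom]
                else False
            )
            central = (start + 2, start + 1)
        hit = active.nearest(chrom, first_c, second_window=0) if len(active) else None
        if hit is None or abs(first_c - hit[0].tss) > config.vulnerability_window:
            continue
        rows.append(
            {
                "chrom": chrom, "pos": first_c, "role": "five_prime",
                "factor": config.vulnerability_factor,
                "partner": lead if lead_is_c else 0,
            }
        )
        if lead_is_c:
            rows.append(
                {
                    "chrom": chrom, "pos": lead, "role": "five_prime",
                    "factor": config.vulnerability_factor, "partner": first_c,
                }
            )
        rows.append(
            {
                "chrom": chrom, "pos": central[0], "role": "central",
                "factor": config.central_factor, "partner": central[1],
            }
        )
        rows.append(
            {
                "chrom": chrom, "pos": central[1], "role": "central",
                "factor": config.central_factor, "partner": central[0],
            }
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "role", "factor", "partner"])
    if len(df):
        # a position shared by two elements keeps its largest factor
        df = (
            df.sort_values("factor")
            .drop_duplicates(["chrom", "pos"], keep="last")
            .reset_index(drop=True)
        )
    return df


def simulate_tumors(
    config: SimulationConfig, bundle: ReferenceBundle
) -> tuple[SampleSet, SimulationTruth]:
    """Simulate a tumor cohort over a reference bundle.

    Per tumor, a target load is drawn log-uniformly, then that many distinct
    positions are sampled with probability proportional to trinucleotide
    signature weight times the vulnerability factor at motif sites near
    active TSSs; drawn C>T mutations at motif CC pairs extend to the
    adjacent cytosine with probability ``cc_tt_rate`` (an unprotected drawn
    mutation is dropped per extension, keeping the emitted count equal to
    the drawn load).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    genome = bundle.genome
    sig = config.signature_matrix()
    tri_weight = sig.sum(axis=1)  # total weight per trinucleotide
    with np.errstate(invalid="ignore", divide="ignore"):
        cls_prob = sig / np.where(tri_weight[:, None] > 0, tri_weight[:, None], 1.0)
    cls_cum = np.cumsum(cls_prob, axis=1)

    chroms = genome.chromosomes
    offsets = {}
    weights_by_chrom: dict[str, np.ndarray] = {}
    tri_by_chrom: dict[str, np.ndarray] = {}
    total = 0
    parts = []
    tri_parts = []
    for chrom in chroms:
        tri = trinucleotide_codes(genome, chrom)
        w = np.where(tri >= 0, tri_weight[np.clip(tri, 0, 31)], 0.0)
        offsets[chrom] = total
        total += len(w)
        weights_by_chrom[chrom] = w
        tri_by_chrom[chrom] = tri
        parts.append(w)
        tri_parts.append(tri)

    vulnerable = _vulnerable_sites(config, bundle)
    for row in vulnerable.itertuples(index=False):
        weights_by_chrom[row.chrom][row.pos - 1] *= row.factor
    w_all = np.concatenate(parts)
    tri_all = np.concatenate(tri_parts)
    W = float(w_all.sum())
    nz = np.flatnonzero(w_all > 0)
    w_nz = w_all[nz]

    chrom_bounds = np.array([offsets[c] for c in chroms] + [total])

    def global_to_coord(gidx: np.ndarray):
        ci = np.searchsorted(chrom_bounds, gidx, side="right") - 1
        return ci, gidx - chrom_bounds[ci] + 1  # 1-based position

    partner_map = {
        (row.chrom, int(row.pos)): int(row.partner)
        for row in vulnerable.itertuples(index=False)
        if row.partner
    }

    lo, hi = config.load_range
    loads = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=config.n_tumors)
    ).round().astype(int)
    loads = np.clip(loads, 1, len(nz))

    samples = [f"TUMOR_{i + 1:03d}" for i in range(config.n_tumors)]
    records = []
    n_ext_total = 0
    for t, (sample, load) in enumerate(zip(samples, loads)):
        keys = rng.standard_exponential(len(nz)) / w_nz
        take = np.argpartition(keys, load - 1)[:load] if load < len(nz) else np.arange(len(nz))
        gidx = nz[take]
        ci, pos1 = global_to_coord(gidx)
        tri_sel = tri_all[gidx]
        u = rng.random(load)
        cum = cls_cum[tri_sel]
        local = (u[:, None] > cum + 1e-15).sum(axis=1)
        local = np.clip(local, 0, len(SUBSTITUTION_CLASSES) - 1)

        chosen = {}
        order = rng.permutation(load)
        for k in order:
            chrom = chroms[int(ci[k])]
            pos = int(pos1[k])
            cls = SUBSTITUTION_CLASSES[int(local[k])]
            pyr_ref, pyr_alt = cls[0], cls[2]
            plus_ref = genome.base(chrom, pos)
            plus_alt = pyr_alt if plus_ref in "CT" else _COMP[pyr_alt]
            chosen[(chrom, pos)] = (plus_ref, plus_alt, False)

        # CC>TT extension at motif cytosine pairs
        extensions = []
        for (chrom, pos), (plus_ref, plus_alt, _) in list(chosen.items()):
            cls_is_ct = (plus_ref == "C" and plus_alt == "T") or (
                plus_ref == "G" and plus_alt == "A"
            )
            partner = partner_map.get((chrom, pos))
            if not cls_is_ct or partner is None:
                continue
            if (chrom, partner) in chosen:
                continue
            if rng.random() < config.cc_tt_rate:
                p_ref = genome.base(chrom, partner)
                p_alt = "T" if p_ref == "C" else "A"
                extensions.append(((chrom, partner), (p_ref, p_alt, True)))
        protected = set(chosen) & set(partner_map)  # motif-pair members stay
        removable = [k for k in chosen if k not in protected]
        rng.shuffle(removable)
        kept_extensions = 0
        for ext_key, ext_val in extensions:
            if not removable:
                break  # cannot trim further; drop remaining extensions
            chosen.pop(removable.pop())
            chosen[ext_key] = ext_val
            kept_extensions += 1
        n_ext_total += kept_extensions
        assert len(chosen) == load

        for (chrom, pos), (plus_ref, plus_alt, _is_ext) in chosen.items():
            records.append((sample, chrom, pos, plus_ref, plus_alt, np.nan))

    df = pd.DataFrame(
        records, columns=["sample_id", "chrom", "pos", "ref", "alt", "vaf"]
    )
    ss = SampleSet(samples=samples, df=df)
    ss.meta.update(n_extensions=n_ext_total, seed=config.seed)
    truth = SimulationTruth(
        loads=loads,
        total_weight=W,
        weights=weights_by_chrom,
        vulnerable_sites=vulnerable,
        n_extensions=n_ext_total,
        signature_matrix=sig,
    )
    return ss, truth


def write_bundle(bundle: ReferenceBundle, outdir) -> dict[str, str]:
    """Write FASTA, annotation TSV, expression TSV and motif manifest.

    Returns a manifest of written paths; the config (including the seed) is
    recorded as JSON so a run is fully reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(outdir / "genome.fa"),
        "genes": str(outdir / "genes.tsv"),
        "expression": str(outdir / "expression.tsv"),
        "motifs": str(outdir / "planted_motifs.tsv"),
        "config": str(outdir / "sim_config.json"),
    }
    bundle.genome.to_fasta(paths["genome"])
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "transcript_starts": ",".join(map(str, g.transcript_starts)),
                "mean_expression": bundle.expression[g.gene_id],
            }
            for g in bundle.genes
        ]
    ).to_csv(paths["genes"], sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": list(bundle.expression),
            "mean_expression": list(bundle.expression.values()),
        }
    ).to_csv(paths["expression"], sep="\t", index=False)
    bundle.motif_manifest.to_csv(paths["motifs"], sep="\t", index=False)
    cfg = dataclasses.asdict(bundle.config)
    cfg["signature"] = {f"{tri}|{cls}": w for (tri, cls), w in bundle.config.signature.items()}
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2)
    return paths
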