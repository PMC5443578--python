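"""End-to-end orchestration: ingest -> hotspots -> signature -> correlation.

Produces the report tables as TSVs plus a JSON run manifest recording
inputs, parameters, the seed and the record counts at every filter step, so
a run is auditable and reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    assign_expression_tiers,
    derive_tss,
    read_expression_tsv,
    read_genes_gtf,
    read_genes_tsv,
)
from .burden import burden_correlation, hotspot_positions, per_sample_summary
from .genome import ReferenceGenome
from .hotspots import (
    MotifIndex,
    call_hotspots,
    motif_positional_distribution,
    recurrence_vs_distance,
    tally_recurrence,
)
from .signature import serialize_table, stratified_run, vulnerability_ratio
from .variants import apply_blacklist, filter_by_vaf, read_blacklist_tsv, read_variants

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    genome: str
    annotation: str
    variants: str
    outdir: str
    expression: str | None = None
    blacklist: str | None = None
    min_recurrence: int = 5
    burden_min_recurrence: int = 3
    tss_window: int = 500
    vaf_min: float | None = None
    motif: str = "CTTCCG"
    strata: tuple[str, ...] = (
        "genome_wide",
        "tss500_tier1",
        "tss500_tier2",
        "tss500_tier3",
    )
    seed: int = 0

    def validate(self) -> None:
        for label in ("genome", "annotation", "variants"):
            path = getattr(self, label)
            if not Path(path).exists():
                raise PipelineError("validate", f"{label} file not found: {path}")
        for label in ("expression", "blacklist"):
            path = getattr(self, label)
            if path is not None and not Path(path).exists():
                raise PipelineError("validate", f"{label} file not found: {path}")
        if self.min_recurrence < 1 or self.tss_window < 1:
            raise PipelineError("validate", "thresholds must be positive")
        needs_tiers = any("tier" in s for s in self.strata)
        if needs_tiers and self.expression is None:
            raise PipelineError(
                "validate", "tier strata requested but no expression table given"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "inputs": {
            "genome": config.genome,
            "annotation": config.annotation,
            "variants": config.variants,
            "expression": config.expression,
            "blacklist": config.blacklist,
        },
        "parameters": {
            "min_recurrence": config.min_recurrence,
            "burden_min_recurrence": config.burden_min_recurrence,
            "tss_window": config.tss_window,
            "vaf_min": config.vaf_min,
            "motif": config.motif,
            "strata": list(config.strata),
        },
        "counts": {},
        "outputs": {},
    }
    counts = manifest["counts"]

    try:
        genome = ReferenceGenome.from_fasta(config.genome)
        if config.annotation.endswith((".gtf", ".gff", ".gff3")):
            genes = read_genes_gtf(config.annotation)
        else:
            genes = read_genes_tsv(config.annotation)
        index = derive_tss(genes)
        if config.expression is not None:
            expressions = read_expression_tsv(config.expression)
            index = assign_expression_tiers(index, expressions)
        counts["genes"] = len(genes)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ingest-reference", str(exc)) from exc

    try:
        ss = read_variants(config.variants, genome=genome)
        counts["variants_loaded"] = len(ss)
        counts["dropped_indels"] = ss.meta.get("dropped_indels", 0)
        counts["dropped_multiallelic"] = ss.meta.get("dropped_multiallelic", 0)
        if config.blacklist is not None:
            ss = apply_blacklist(ss, read_blacklist_tsv(config.blacklist))
            counts["blacklist_removed"] = ss.meta["blacklist_removed"]
        if config.vaf_min is not None:
            ss = filter_by_vaf(ss, config.vaf_min)
            counts["vaf_removed"] = ss.meta["vaf_removed"]
        counts["variants_analyzed"] = len(ss)
        counts["samples"] = ss.n_samples
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ingest-variants", str(exc)) from exc

    try:
        motif_index = MotifIndex(genome, config.motif)
        tallies = tally_recurrence(ss)
        hotspot_table = call_hotspots(
            ss, index, genome,
            min_recurrence=config.min_recurrence,
            tss_window=config.tss_window,
            motif=config.motif,
            tallies=tallies,
            motif_index=motif_index,
        )
        hotspot_table.to_csv(outdir / "hotspots.tsv", sep="\t", index=False, na_rep="NA")
        manifest["outputs"]["hotspots"] = str(outdir / "hotspots.tsv")
        counts["hotspots"] = len(hotspot_table)
        hist = motif_positional_distribution(hotspot_table, motif_index)
        hist.rename_axis("offset").reset_index().to_csv(
            outdir / "motif_offset_histogram.tsv", sep="\t", index=False
        )
        manifest["outputs"]["motif_offset_histogram"] = str(
            outdir / "motif_offset_histogram.tsv"
        )
        if index.tiered:
            rvd = recurrence_vs_distance(
                ss, genome, index, motif=config.motif, motif_index=motif_index
            )
            rvd.to_csv(outdir / "recurrence_vs_distance.tsv", sep="\t", index=False)
            manifest["outputs"]["recurrence_vs_distance"] = str(
                outdir / "recurrence_vs_distance.tsv"
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("hotspots", str(exc)) from exc

    try:
        strata = config.strata if index.tiered else ("genome_wide",)
        tables = stratified_run(ss, genome, index, strata=strata, window=config.tss_window)
        combined = pd.concat(tables.values(), ignore_index=True)
        serialize_table(combined, outdir / "probability_tables.tsv")
        manifest["outputs"]["probability_tables"] = str(outdir / "probability_tables.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("signature", str(exc)) from exc

    try:
        # established motif-related promoter positions (a laxer recurrence bar
        # than the highly-recurrent report threshold)
        burden_table = call_hotspots(
            ss, index, genome,
            min_recurrence=config.burden_min_recurrence,
            tss_window=config.tss_window,
            motif=config.motif,
            tallies=tallies,
            motif_index=motif_index,
        )
        if len(burden_table):
            burden_table = burden_table[burden_table["motif_overlap"]]
        hotspots = {
            (row.chrom, int(row.pos)) for row in burden_table.itertuples(index=False)
        }
        counts["burden_hotspot_positions"] = len(hotspots)
        if hotspots:
            summary = per_sample_summary(ss, hotspots)
            summary.to_csv(outdir / "burden_summary.tsv", sep="\t", index=False)
            manifest["outputs"]["burden_summary"] = str(outdir / "burden_summary.tsv")
            result = burden_correlation(summary)
            pd.DataFrame(
                [{"rho": result.rho, "p_value": result.p_value, "method": result.method}]
            ).to_csv(outdir / "burden_correlation.tsv", sep="\t", index=False)
            manifest["outputs"]["burden_correlation"] = str(
                outdir / "burden_correlation.tsv"
            )
            manifest["burden_rho"] = result.rho
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("correlation", str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
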