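"""Per-sample hotspot burden vs genome-wide mutation load.

Across tumors, the number of established hotspot positions that are mutated
tracks the total mutation load when hotspots arise from elevated mutation
probability rather than selection; the rank correlation between the two is
the summary statistic.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .stats import SpearmanResult, spearman

__all__ = [
    "per_sample_summary",
    "spearman_correlation",
    "hotspot_positions",
    "burden_correlation",
]


def hotspot_positions(tallies: pd.DataFrame, min_recurrence: int = 3) -> set[tuple[str, int]]:
    """Established hotspot set: positions recurrent in >= min_recurrence samples.

    The default of 3 matches the convention for the burden analysis (a
    laxer bar than the >=5 used for the "highly recurrent" report).
    """
    sel = tallies[tallies["recurrence"] >= min_recurrence]
    return {(chrom, int(pos)) for chrom, pos in sel.index}


def per_sample_summary(
    ss,
    hotspots: set[tuple[str, int]],
    flags: Mapping[str, Mapping[str, object]] | None = None,
    count_events: bool = False,
) -> pd.DataFrame:
    """Per-tumor total SNV load and hotspot-position count.

    Every declared sample appears, including zero-variant samples.  By
    default ``hotspot_count`` is the number of *distinct* hotspot positions
    mutated in the sample; with ``count_events`` it is the number of hotspot
    mutation events.  ``flags`` is an optional user-supplied annotation map
    (e.g. driver-gene status) passed through to the output.
    """
    if not hotspots:
        raise ValueError("hotspot set must be non-empty")
    df = ss.df
    rows = []
    keys = list(zip(df["chrom"], df["pos"].astype(int)))
    is_hot = pd.Series([k in hotspots for k in keys], index=df.index, dtype=bool)
    for sample in ss.samples:
        sub = df[df["sample_id"] == sample]
        hot = is_hot[sub.index]
        if count_events:
            hotspot_count = int(hot.sum())
        else:
            hotspot_count = int(
                sub[hot][["chrom", "pos"]].drop_duplicates().shape[0]
            )
        row = {
            "sample_id": sample,
            "total_load": int(len(sub)),
            "hotspot_count": hotspot_count,
        }
        if flags and sample in flags:
            row.update(flags[sample])
        rows.append(row)
    return pd.DataFrame(rows)


def spearman_correlation(x: Iterable[float], y: Iterable[float]) -> SpearmanResult:
    """Spearman rank correlation (see :func:`uvhotspots.stats.spearman`)."""
    return spearman(x, y)


def burden_correlation(summary: pd.DataFrame) -> SpearmanResult:
    """Rank correlation of hotspot count vs total load from a summary table."""
    return spearman(summary["hotspot_count"], summary["total_load"])
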