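"""Percentile binning of scored windows and merging into regions.

Windows carrying a score are ranked and divided into eight percentile
bins (0-10, 10-25, 25-50, 50-75, 75-90, 90-95, 95-99, 99-100 by
default).  Overlapping or book-ended windows in the same bin are then
merged into maximal "nucleosome" regions, the analysis unit for all
overlap statistics.  Ties in score are broken by genomic coordinate so
the binning is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig

REGION_COLUMNS = ["chrom", "start", "end", "score_kind", "bin", "n_windows", "mean_score"]


def bin_labels(edges: tuple[float, ...]) -> list[str]:
    """Human-readable labels, e.g. ``['0-10', '10-25', ..., '99-100']``."""
    return [f"{lo:g}-{hi:g}" for lo, hi in zip(edges, edges[1:])]


def assign_bins(
    scored: pd.DataFrame, score_kind: str, config: PipelineConfig
) -> pd.Series:
    """Percentile-bin label per window for one score kind ("IS" or "RS").

    A window with percent rank p (p = 100 * rank / N, ranks ascending
    by score, ties broken by (chrom, start)) falls in bin (lo, hi] —
    the bottom bin is closed at 0.  Windows without the score get NaN.
    """
    edges = np.asarray(config.percentile_edges)
    labels = bin_labels(config.percentile_edges)
    valid = scored[score_kind].notna()
    if not valid.any():
        raise ValueError(f"no windows carry a {score_kind} score")
    sub = scored.loc[valid, ["chrom", "start", score_kind]]
    order = sub.sort_values([score_kind, "chrom", "start"], kind="stable").index
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    pct = 100.0 * ranks / len(ranks)
    which = np.searchsorted(edges, pct.to_numpy(), side="left") - 1
    which = np.clip(which, 0, len(labels) - 1)
    out = pd.Series(pd.NA, index=scored.index, dtype="object")
    out.loc[pct.index] = [labels[i] for i in which]
    return out


def merge_regions(
    scored: pd.DataFrame,
    bins: pd.Series,
    score_kind: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Merge same-bin windows into maximal regions.

    Two windows of the same bin merge when their intervals overlap, or
    touch end-to-start when ``merge_bookended`` is set (the default);
    merging is iterated to a fixed point, so regions are maximal and
    disjoint within a (score_kind, bin).  Each region records its
    window count and mean score.
    """
    valid = bins.notna()
    df = scored.loc[valid, ["chrom", "start", "end", score_kind]].copy()
    df["bin"] = bins[valid]
    rows = []
    for (chrom, label), group in df.groupby(["chrom", "bin"], sort=False):
        group = group.sort_values("start", kind="stable")
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        values = group[score_kind].to_numpy()
        cur_start, cur_end = starts[0], ends[0]
        members = [values[0]]
        for s, e, v in zip(starts[1:], ends[1:], values[1:]):
            joined = s <= cur_end if config.merge_bookended else s < cur_end
            if joined:
                cur_end = max(cur_end, e)
                members.append(v)
            else:
                rows.append((chrom, cur_start, cur_end, score_kind, label, len(members), float(np.mean(members))))
                cur_start, cur_end, members = s, e, [v]
        rows.append((chrom, cur_start, cur_end, score_kind, label, len(members), float(np.mean(members))))
    regions = pd.DataFrame(rows, columns=REGION_COLUMNS)
    return regions.sort_values(["chrom", "start", "bin"], kind="stable").reset_index(drop=True)


def bin_and_merge(
    scored: pd.DataFrame, score_kind: str, config: PipelineConfig
) -> tuple[pd.Series, pd.DataFrame]:
    """Convenience: assign bins and merge regions for one score kind."""
    bins = assign_bins(scored, score_kind, config)
    return bins, merge_regions(scored, bins, score_kind, config)
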