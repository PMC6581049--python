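"""Relating scores and regions to genomic features.

Covers the downstream, TSS-centric analyses: the operational
nucleosome-free region (NFR, 250-50 bp upstream of the TSS), overlap
fractions of percentile bins with feature sets, a per-25-bp genome
track of window scores, strand-aware TSS metaprofiles (optionally
mean-centered), H2AZ+/- stratification of genomic bins, Wilcoxon
rank-sum comparisons, and per-gene target enrichment across bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneModel, GenomeAssembly, PipelineConfig

logger = logging.getLogger(__name__)

_ALTERNATIVES = {
    "two-sided": "two-sided",
    "one-sided-greater": "greater",
    "one-sided-less": "less",
}


@dataclass
class MetaProfile:
    """Average of a genomic signal around TSSs, in transcription direction.

    ``offsets`` are the starts of the offset bins (bp relative to the
    TSS); ``mean_value`` is the across-gene mean of the signal in each
    bin and ``n`` the number of genes contributing.  When ``centered``,
    the genome-wide mean of the signal was subtracted first.
    """

    score_kind: str
    offsets: np.ndarray
    mean_value: np.ndarray
    n: np.ndarray
    centered: bool


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of a Wilcoxon rank-sum (Mann-Whitney U) comparison."""

    test_name: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    alternative: str


def nfr_interval(gene: GeneModel, config: PipelineConfig, chrom_length: int | None = None) -> tuple[int, int]:
    """Operational NFR of a gene: 250-50 bp upstream of the TSS.

    Upstream is in transcription direction, so a minus-strand gene's
    NFR lies at higher coordinates.  Clipped to the chromosome.
    """
    far, near = config.nfr_upstream_far, config.nfr_upstream_near
    if gene.strand == "+":
        start, end = gene.tss - far, gene.tss - near
    else:
        start, end = gene.tss + near, gene.tss + far
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, max(start, end)


def promoter_interval(gene: GeneModel, config: PipelineConfig, chrom_length: int | None = None) -> tuple[int, int]:
    """Promoter of a gene: ``promoter_upstream`` bp upstream of the TSS."""
    up = config.promoter_upstream
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss
    else:
        start, end = gene.tss, gene.tss + up
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, max(start, end)


def _merge_intervals(features: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, group in features.groupby("chrom", sort=False):
        group = group.sort_values("start", kind="stable")
        starts, ends = [], []
        for s, e in zip(group["start"], group["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def overlaps_any(elements: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Boolean per element: does it overlap >= 1 bp of any feature?"""
    merged = _merge_intervals(features)
    out = np.zeros(len(elements), dtype=bool)
    for chrom, idx in elements.groupby("chrom", sort=False).groups.items():
        if chrom not in merged:
            continue
        f_starts, f_ends = merged[chrom]
        e_starts = elements.loc[idx, "start"].to_numpy()
        e_ends = elements.loc[idx, "end"].to_numpy()
        # first feature whose end is past the element start
        i = np.searchsorted(f_ends, e_starts, side="right")
        hit = (i < len(f_starts)) & (np.where(i < len(f_starts), f_starts[np.minimum(i, len(f_starts) - 1)], 0) < e_ends)
        out[elements.index.get_indexer(idx)] = hit
    return out


def overlap_fraction_by_bin(
    elements: pd.DataFrame, bins: pd.Series, features: pd.DataFrame
) -> pd.Series:
    """Per percentile bin: fraction of elements overlapping any feature."""
    hit = overlaps_any(elements, features)
    df = pd.DataFrame({"bin": bins.to_numpy(), "hit": hit}).dropna(subset=["bin"])
    return df.groupby("bin", sort=False)["hit"].mean()


def score_per_bp(
    scored: pd.DataFrame, score_kind: str, config: PipelineConfig
) -> pd.DataFrame:
    """Project window scores onto the step-size genome grid.

    Each grid bin (width = ``window_step``) receives the mean score of
    all kept windows whose span contains the bin start.  Bins covered
    by no kept window are absent from the output Track.
    """
    step = config.window_step
    valid = scored[score_kind].notna()
    frames = []
    for chrom, group in scored.loc[valid].groupby("chrom", sort=False):
        n_bins = int(group["end"].max()) // step + 1
        total = np.zeros(n_bins + 1)
        count = np.zeros(n_bins + 1)
        j_min = -(-group["start"].to_numpy() // step)
        j_max = -(-group["end"].to_numpy() // step) - 1  # last bin start < end
        vals = group[score_kind].to_numpy()
        np.add.at(total, j_min, vals)
        np.add.at(total, j_max + 1, -vals)
        np.add.at(count, j_min, 1)
        np.add.at(count, j_max + 1, -1)
        total = np.cumsum(total[:-1])
        count = np.cumsum(count[:-1])
        covered = count > 0
        starts = np.nonzero(covered)[0] * step
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + step,
                    "value": total[covered] / count[covered],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return pd.concat(frames, ignore_index=True)


def rasterize_track(
    track: pd.DataFrame, genome: GenomeAssembly, bin_size: int
) -> dict[str, np.ndarray]:
    """Track -> per-chromosome arrays of bin means (NaN where uncovered).

    Interval values are averaged into each grid bin weighted by the
    number of overlapping base pairs.
    """
    grids: dict[str, np.ndarray] = {}
    for chrom, length in genome.chrom_lengths.items():
        n = -(-length // bin_size)
        total = np.zeros(n)
        cover = np.zeros(n)
        grids[chrom] = (total, cover)
    for row in track.itertuples(index=False):
        if row.chrom not in grids:
            continue
        total, cover = grids[row.chrom]
        j0, j1 = row.start // bin_size, -(-row.end // bin_size)
        for j in range(j0, min(j1, len(total))):
            lo = max(row.start, j * bin_size)
            hi = min(row.end, (j + 1) * bin_size)
            total[j] += row.value * (hi - lo)
            cover[j] += hi - lo
    out: dict[str, np.ndarray] = {}
    for chrom, (total, cover) in grids.items():
        vals = np.full(len(total), np.nan)
        covered = cover > 0
        vals[covered] = total[covered] / cover[covered]
        out[chrom] = vals
    return out


def tss_metaprofile(
    track: pd.DataFrame,
    genes: list[GeneModel],
    genome: GenomeAssembly,
    config: PipelineConfig,
    center: bool = False,
    score_kind: str = "score",
    center_value: float | None = None,
) -> MetaProfile:
    """Average a genomic value track around gene TSSs.

    Offsets run from -halfwidth to +halfwidth in ``metaprofile_bin``
    steps and are measured in transcription direction (minus-strand
    genes are flipped).  Each gene contributes the track value of the
    genome bin containing the center of each offset bin; the profile
    reports the across-gene mean and the number of genes contributing
    per offset.  ``center`` subtracts the genome-wide mean of the track
    first, as used for score metaprofiles; when comparing profiles of
    *subsets* of a track (e.g. H2AZ+ vs H2AZ- bins) pass the full
    track's mean as ``center_value`` so both subsets share the same
    zero.
    """
    if not genes:
        raise ValueError("no genes supplied for metaprofile")
    B = config.metaprofile_bin
    H = config.metaprofile_halfwidth
    grids = rasterize_track(track, genome, B)
    if center:
        if center_value is None:
            all_vals = np.concatenate([g for g in grids.values()])
            center_value = float(np.nanmean(all_vals))
        grids = {c: g - center_value for c, g in grids.items()}
    offsets = np.arange(-H, H, B)
    total = np.zeros(len(offsets))
    n = np.zeros(len(offsets), dtype=np.int64)
    for gene in genes:
        grid = grids.get(gene.chrom)
        if grid is None:
            continue
        if gene.strand == "+":
            centers = gene.tss + offsets + B / 2
        else:
            centers = gene.tss - offsets - B / 2
        j = np.floor(centers / B).astype(np.int64)
        ok = (j >= 0) & (j < len(grid))
        vals = np.full(len(offsets), np.nan)
        vals[ok] = grid[j[ok]]
        have = ~np.isnan(vals)
        total[have] += vals[have]
        n[have] += 1
    mean_value = np.full(len(offsets), np.nan)
    mean_value[n > 0] = total[n > 0] / n[n > 0]
    return MetaProfile(score_kind, offsets, mean_value, n, center)


def tss_element_profile(
    elements: pd.DataFrame,
    genes: list[GeneModel],
    config: PipelineConfig,
) -> MetaProfile:
    """Density of element midpoints around TSSs (per gene, per offset bin).

    Used for positional profiles of top-percentile regions: each
    element contributes its midpoint; the profile value is the mean
    number of midpoints per gene in each offset bin.
    """
    if not genes:
        raise ValueError("no genes supplied for metaprofile")
    B = config.metaprofile_bin
    H = config.metaprofile_halfwidth
    offsets = np.arange(-H, H, B)
    counts = np.zeros(len(offsets))
    mids_by_chrom = {
        chrom: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
        for chrom, g in elements.groupby("chrom", sort=False)
    }
    for gene in genes:
        mids = mids_by_chrom.get(gene.chrom)
        if mids is None:
            continue
        rel = mids - gene.tss if gene.strand == "+" else gene.tss - mids
        inside = rel[(rel >= -H) & (rel < H)]
        j = (inside + H) // B
        np.add.at(counts, j.astype(np.int64), 1)
    n = np.full(len(offsets), len(genes), dtype=np.int64)
    return MetaProfile("density", offsets, counts / len(genes), n, False)


def element_track_means(elements: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Coverage-weighted mean track value over each element (NaN if none)."""
    out = np.full(len(elements), np.nan)
    track_by_chrom = {
        chrom: g.sort_values("start", kind="stable")
        for chrom, g in track.groupby("chrom", sort=False)
    }
    for chrom, idx in elements.groupby("chrom", sort=False).groups.items():
        g = track_by_chrom.get(chrom)
        if g is None:
            continue
        t_starts = g["start"].to_numpy()
        t_ends = g["end"].to_numpy()
        t_vals = g["value"].to_numpy()
        pos = elements.index.get_indexer(idx)
        e_starts = elements.loc[idx, "start"].to_numpy()
        e_ends = elements.loc[idx, "end"].to_numpy()
        lo = np.searchsorted(t_ends, e_starts, side="right")
        hi = np.searchsorted(t_starts, e_ends, side="left")
        for k, (s, e, i0, i1) in enumerate(zip(e_starts, e_ends, lo, hi)):
            if i0 >= i1:
                continue
            ov = np.minimum(t_ends[i0:i1], e) - np.maximum(t_starts[i0:i1], s)
            ov = np.clip(ov, 0, None)
            w = ov.sum()
            if w > 0:
                out[pos[k]] = (t_vals[i0:i1] * ov).sum() / w
    return out


def classify_h2az(
    track: pd.DataFrame, elements: pd.DataFrame, config: PipelineConfig
) -> pd.Series:
    """Label elements H2AZ+ / H2AZ- / neither by mean track value.

    H2AZ+ means the element's mean H2AZ density is strictly above the
    (100 - h2az_top_percentile)-th percentile of all element values;
    H2AZ- strictly below the h2az_bottom_percentile-th.  Strict
    inequalities mean a constant track classifies nothing.  Elements
    not covered by the track are labeled neither and counted in the
    log.
    """
    values = element_track_means(elements, track)
    missing = np.isnan(values)
    if missing.any():
        logger.info("classify_h2az: %d element(s) not covered by track", int(missing.sum()))
    covered = values[~missing]
    labels = np.full(len(elements), "neither", dtype=object)
    if len(covered):
        hi = np.percentile(covered, 100 - config.h2az_top_percentile)
        lo = np.percentile(covered, config.h2az_bottom_percentile)
        labels[~missing & (values > hi)] = "H2AZ+"
        labels[~missing & (values < lo)] = "H2AZ-"
    return pd.Series(labels, index=elements.index)


def h2az_stratified_profiles(
    scored: pd.DataFrame,
    score_kind: str,
    h2az_track: pd.DataFrame,
    genes: list[GeneModel],
    genome: GenomeAssembly,
    config: PipelineConfig,
) -> tuple[MetaProfile, MetaProfile]:
    """Centered TSS metaprofiles of a score for H2AZ+ vs H2AZ- bins.

    The score is projected onto the step-size grid, grid bins are
    stratified by mean H2AZ density (top vs bottom percentile of the
    config), and both strata are profiled around the TSSs with a
    common zero: the mean of the *full* score track, so the two
    profiles are directly comparable.
    """
    track = score_per_bp(scored, score_kind, config)
    labels = classify_h2az(h2az_track, track, config)
    center_value = float(track["value"].mean())
    prof_plus = tss_metaprofile(
        track[labels == "H2AZ+"], genes, genome, config,
        center=True, score_kind=score_kind, center_value=center_value,
    )
    prof_minus = tss_metaprofile(
        track[labels == "H2AZ-"], genes, genome, config,
        center=True, score_kind=score_kind, center_value=center_value,
    )
    return prof_plus, prof_minus


def rank_sum_test(
    values_a,
    values_b,
    alternative: str = "two-sided",
    test_name: str = "rank-sum",
) -> EnrichmentResult:
    """Wilcoxon rank-sum (Mann-Whitney U) comparison of two groups.

    Exact p by enumeration for small tie-free samples (n_a + n_b <= 12),
    otherwise the normal approximation with midranks, tie correction
    and continuity correction.  ``alternative`` is one of two-sided /
    one-sided-greater / one-sided-less, stated for group a vs group b.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative: {alternative}")
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=_ALTERNATIVES[alternative], method=method)
    return EnrichmentResult(
        test_name, len(a), len(b), float(res.statistic), float(min(res.pvalue, 1.0)), alternative
    )


def gene_promoter_score(
    scored: pd.DataFrame,
    score_kind: str,
    genes: list[GeneModel],
    config: PipelineConfig,
) -> pd.Series:
    """Per-gene score summary: max over windows whose midpoint lies
    within ``gene_score_halfwidth`` bp of the TSS.

    The maximum captures the most strongly scored promoter/TSS window
    of each gene.  Genes with no scored window in range get NaN.
    """
    half = config.gene_score_halfwidth
    valid = scored[score_kind].notna()
    by_chrom = {}
    for chrom, g in scored.loc[valid].groupby("chrom", sort=False):
        mids = ((g["start"] + g["end"]) // 2).to_numpy()
        order = np.argsort(mids, kind="stable")
        by_chrom[chrom] = (mids[order], g[score_kind].to_numpy()[order])
    out = {}
    for gene in genes:
        val = np.nan
        if gene.chrom in by_chrom:
            mids, vals = by_chrom[gene.chrom]
            i0 = np.searchsorted(mids, gene.tss - half, side="left")
            i1 = np.searchsorted(mids, gene.tss + half, side="left")
            if i1 > i0:
                val = float(vals[i0:i1].max())
        out[gene.gene_id] = val
    return pd.Series(out, name=score_kind)


def target_fraction_by_bin(
    per_gene_scores: pd.Series,
    target_genes: set[str],
    config: PipelineConfig,
) -> tuple[pd.Series, EnrichmentResult]:
    """Fraction of target genes per score-percentile bin, plus the
    one-sided rank-sum test of target scores exceeding nontarget scores.
    """
    scores = per_gene_scores.dropna()
    if not set(scores.index) & target_genes:
        raise ValueError("no target gene carries a score")
    from .regions import assign_bins

    frame = pd.DataFrame(
        {"chrom": "", "start": np.arange(len(scores)), "S": scores.to_numpy()},
        index=scores.index,
    )
    bins = assign_bins(frame, "S", config)
    is_target = scores.index.isin(sorted(target_genes))
    frac = (
        pd.DataFrame({"bin": bins.to_numpy(), "target": is_target})
        .groupby("bin", sort=False)["target"]
        .mean()
    )
    test = rank_sum_test(
        scores[is_target],
        scores[~is_target],
        alternative="one-sided-greater",
        test_name="target-vs-nontarget",
    )
    return frac, test
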