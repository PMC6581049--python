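"""Count normalization and the Instability / Remodeling Scores.

The Instability Score of a window is the normalized log-ratio of naked
DNA to nucleosomal reads from the reaction without remodeler,

    IS = log2(DNA / NUC),

averaged over replicates; a high IS marks an intrinsically unstable
nucleosome.  The Remodeling Score subtracts the IS from the same
log-ratio of the reaction with remodeler,

    RS = log2(DNAR / NUCR) - IS,

so a high RS marks a nucleosome disassembled by the remodeler beyond
its intrinsic instability.  Because the IS enters RS with a negative
sign, the two scores are anticorrelated by construction on null data.

Order of operations: the coverage filter is applied to *raw* counts
(it is stated on reads); counts are then corrected for GC content
within each sample, scaled by median-of-ratios size factors across
samples, and finally turned into pseudocounted log-ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import BANDS, REPLICATES, PipelineConfig, count_columns

logger = logging.getLogger(__name__)


def filter_windows(raw_counts: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Coverage filter: drop windows with fewer than ``min_reads`` reads
    in DNA + NUC (for the IS) or DNAR + NUCR (for the RS) in *both*
    replicates.  A window failing in only one replicate is kept.

    Returns a DataFrame with boolean columns ``keep_is`` and ``keep_rs``.
    """
    t = config.min_reads
    fail_is = pd.Series(True, index=raw_counts.index)
    fail_rs = pd.Series(True, index=raw_counts.index)
    for rep in REPLICATES:
        fail_is &= (raw_counts[f"DNA_{rep}"] + raw_counts[f"NUC_{rep}"]) < t
        fail_rs &= (raw_counts[f"DNAR_{rep}"] + raw_counts[f"NUCR_{rep}"]) < t
    return pd.DataFrame({"keep_is": ~fail_is, "keep_rs": ~fail_rs})


def _gc_bin_assignment(gc: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-occupancy GC bins: sort by GC, split into n_bins runs."""
    order = np.argsort(gc, kind="stable")
    bins = np.empty(len(gc), dtype=np.int64)
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        bins[idx] = b
    return bins


def gc_normalize(
    counts: pd.DataFrame,
    gc: np.ndarray,
    n_bins: int = 20,
    method: str = "median",
) -> pd.DataFrame:
    """Remove the dependence of counts on window GC content, per sample.

    ``median`` (default): windows are grouped into ``n_bins``
    equal-occupancy GC bins; the counts of bin b are rescaled by
    (median of per-bin medians) / (median of bin b), medians taken over
    windows with a positive count.  Deterministic and dependency-light.

    ``loess``: a lowess fit of log counts on GC is subtracted instead
    (positive counts only); provided as a cross-check on the default.
    """
    corrected = counts.astype(float).copy()
    gc = np.asarray(gc, dtype=float)
    if method == "loess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        for col in counts.columns:
            c = corrected[col].to_numpy()
            if not (c > 0).any():
                raise ValueError(f"sample {col} has no positive counts")
            pos = c > 0
            logc = np.log(c[pos])
            fit = lowess(logc, gc[pos], frac=0.4, return_sorted=False)
            c[pos] = np.exp(logc - fit + logc.mean())
            corrected[col] = c
        return corrected
    if method != "median":
        raise ValueError(f"unknown GC normalization method: {method}")

    bins = _gc_bin_assignment(gc, n_bins)
    for col in counts.columns:
        c = corrected[col].to_numpy()
        if not (c > 0).any():
            raise ValueError(f"sample {col} has no positive counts")
        bin_medians = np.full(n_bins, np.nan)
        for b in range(n_bins):
            vals = c[(bins == b) & (c > 0)]
            if len(vals):
                bin_medians[b] = np.median(vals)
        overall = np.nanmedian(bin_medians)
        factors = np.where(np.isnan(bin_medians), 1.0, overall / bin_medians)
        corrected[col] = c * factors[bins]
    return corrected


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    For windows positive in every sample, factor_j is the median of
    count_wj / geometric-mean_w; factors are rescaled to geometric mean
    one so that they carry no overall scale.
    """
    mat = count_matrix.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no window has positive counts in all samples")
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1)
    log_factors = np.median(logs - log_geomean[:, None], axis=0)
    log_factors -= log_factors.mean()
    return pd.Series(np.exp(log_factors), index=count_matrix.columns)


def _mean_log2_ratio(
    norm: pd.DataFrame, num_band: str, den_band: str, pseudocount: float
) -> pd.Series:
    parts = []
    for rep in REPLICATES:
        num = norm[f"{num_band}_{rep}"] + pseudocount
        den = norm[f"{den_band}_{rep}"] + pseudocount
        parts.append(np.log2(num / den))
    return sum(parts) / len(parts)


def instability_score(norm_counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.Series:
    """IS = mean over replicates of log2((DNA + c) / (NUC + c))."""
    return _mean_log2_ratio(norm_counts, "DNA", "NUC", pseudocount)


def remodeling_score(
    norm_counts: pd.DataFrame, IS: pd.Series, pseudocount: float = 0.5
) -> pd.Series:
    """RS = mean over replicates of log2((DNAR + c) / (NUCR + c)) - IS."""
    return _mean_log2_ratio(norm_counts, "DNAR", "NUCR", pseudocount) - IS


def score_windows(window_table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Run filter -> GC correction -> size factors -> IS/RS on a counted
    window table (as built by :mod:`nucscore.windows`).

    Returns the table extended with normalized count columns
    (``norm_<sample>``), ``keep_is``/``keep_rs`` flags, and ``IS``/``RS``
    columns that are NaN where the respective score is undefined.  The
    RS additionally requires the IS (it subtracts it), so RS is defined
    only on windows kept by both filters.
    """
    cols = count_columns()
    raw = window_table[cols]
    keep = filter_windows(raw, config)

    corrected = gc_normalize(
        raw, window_table["gc"].to_numpy(), n_bins=config.n_gc_bins, method=config.gc_method
    )
    factors = size_factors(corrected)
    norm = corrected / factors

    scored = window_table.copy()
    for col in cols:
        scored[f"norm_{col}"] = norm[col]
    scored["keep_is"] = keep["keep_is"].to_numpy()
    scored["keep_rs"] = keep["keep_rs"].to_numpy()

    IS = instability_score(norm, config.pseudocount)
    RS = remodeling_score(norm, IS, config.pseudocount)
    scored["IS"] = IS.where(scored["keep_is"])
    scored["RS"] = RS.where(scored["keep_is"] & scored["keep_rs"])

    n = len(scored)
    logger.info(
        "scored %d windows: %d with IS (%.1f%%), %d with RS (%.1f%%)",
        n,
        scored["IS"].notna().sum(),
        100 * scored["IS"].notna().mean() if n else 0.0,
        scored["RS"].notna().sum(),
        100 * scored["RS"].notna().mean() if n else 0.0,
    )
    return scored
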