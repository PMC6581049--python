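"""Genome tiling, window sequence content, and fragment counting.

The genome is tiled into fixed-width windows (default 167 bp, the
length of a chromatosome-sized MNase fragment) advanced by a fixed step
(default 25 bp).  Each window records its G+C fraction, the number of
base pairs covered by poly(dA:dT) tracts, and one raw fragment count
per (band, replicate) sample.

A fragment is assigned to every window that contains its midpoint
``floor((start + end) / 2)``.  With the default geometry an interior
midpoint lies in exactly ``ceil(167 / 25) = 7`` windows, so counting
preserves one "position" per fragment while populating all windows that
cover it.  Fragments whose midpoint lies in no full window (chromosome
ends) are dropped and reported through the module logger.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .config import BANDS, REPLICATES, GenomeAssembly, PipelineConfig, count_columns

logger = logging.getLogger(__name__)

WINDOW_KEY = ["chrom", "start", "end"]


def tile_windows(genome: GenomeAssembly, config: PipelineConfig) -> pd.DataFrame:
    """Tile every chromosome with fixed-width windows on the step grid.

    Windows start at 0, step, 2*step, ... and must fit entirely on the
    chromosome; trailing bases not covered by a full window are dropped
    so that per-window content and counts stay comparable.
    """
    width, step = config.window_width, config.window_step
    frames = []
    for chrom, length in genome.chrom_lengths.items():
        if length < width:
            continue
        starts = np.arange(0, length - width + 1, step, dtype=np.int64)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width})
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_KEY)
    return pd.concat(frames, ignore_index=True)


def _gc_indicator(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)


def window_gc(genome: GenomeAssembly, windows: pd.DataFrame) -> np.ndarray:
    """G+C fraction of each window; N bases count as neither."""
    gc = np.empty(len(windows), dtype=float)
    for chrom, idx in windows.groupby("chrom", sort=False).groups.items():
        cum = np.concatenate([[0], np.cumsum(_gc_indicator(genome[chrom]))])
        starts = windows.loc[idx, "start"].to_numpy()
        ends = windows.loc[idx, "end"].to_numpy()
        gc[windows.index.get_indexer(idx)] = (cum[ends] - cum[starts]) / (ends - starts)
    return gc


def poly_dadt_tracts(
    sequence: str, min_len: int, mixed_at: bool = False
) -> list[tuple[int, int]]:
    """Locate poly(dA:dT) tracts in an uppercase sequence.

    By default a tract is a maximal homopolymer run of A, or of T, at
    least ``min_len`` long — the conventional reading of poly(dA:dT).
    With ``mixed_at`` any run over the alphabet {A, T} qualifies.
    """
    if mixed_at:
        pattern = re.compile(r"[AT]{%d,}" % min_len)
    else:
        pattern = re.compile(r"A{%d,}|T{%d,}" % (min_len, min_len))
    return [(m.start(), m.end()) for m in pattern.finditer(sequence)]


def window_tract_bp(
    genome: GenomeAssembly, windows: pd.DataFrame, config: PipelineConfig
) -> np.ndarray:
    """Base pairs of each window covered by poly(dA:dT) tracts."""
    out = np.zeros(len(windows), dtype=np.int64)
    for chrom, idx in windows.groupby("chrom", sort=False).groups.items():
        seq = genome[chrom]
        coverage = np.zeros(len(seq), dtype=np.int64)
        for s, e in poly_dadt_tracts(seq, config.tract_min_len, config.tract_mixed_at):
            coverage[s:e] = 1
        cum = np.concatenate([[0], np.cumsum(coverage)])
        starts = windows.loc[idx, "start"].to_numpy()
        ends = windows.loc[idx, "end"].to_numpy()
        out[windows.index.get_indexer(idx)] = cum[ends] - cum[starts]
    return out


def _window_layout(windows: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per chromosome: (row offset of first window, number of windows)."""
    layout: dict[str, tuple[int, int]] = {}
    for chrom, idx in windows.groupby("chrom", sort=False).groups.items():
        positions = windows.index.get_indexer(idx)
        if not (np.diff(positions) == 1).all():
            raise ValueError("window table must be contiguous per chromosome")
        layout[chrom] = (int(positions[0]), len(positions))
    return layout


def count_fragments(
    fragments: pd.DataFrame, windows: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Fill the per-(band, replicate) fragment counts of a window table.

    Each fragment increments every window containing its midpoint.
    Returns a copy of ``windows`` with one integer column per sample
    (``NUC_1`` ... ``DNAR_2``).
    """
    width, step = config.window_width, config.window_step
    layout = _window_layout(windows)
    table = windows.copy()
    for col in count_columns():
        table[col] = 0

    unknown = set(fragments["chrom"]) - set(layout) if len(fragments) else set()
    if unknown:
        raise ValueError(f"fragments on chromosome(s) without windows: {sorted(unknown)}")

    dropped = 0
    for (band, rep), group in fragments.groupby(["band", "replicate"], sort=False):
        if band not in BANDS or rep not in REPLICATES:
            raise ValueError(f"unknown band/replicate label: {band}/{rep}")
        col = f"{band}_{rep}"
        counts = np.zeros(len(windows) + 1, dtype=np.int64)
        for chrom, sub in group.groupby("chrom", sort=False):
            offset, n_windows = layout[chrom]
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            k_min = np.maximum(-(-(mids - width + 1) // step), 0)
            k_max = np.minimum(mids // step, n_windows - 1)
            valid = k_min <= k_max
            dropped += int((~valid).sum())
            np.add.at(counts, offset + k_min[valid], 1)
            np.add.at(counts, offset + k_max[valid] + 1, -1)
        table[col] = np.cumsum(counts[:-1])
    if dropped:
        logger.info("count_fragments: dropped %d fragment(s) outside full windows", dropped)
    return table


def annotate_windows(
    genome: GenomeAssembly, windows: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Attach gc and tract_bp columns to a tiled window table."""
    table = windows.copy()
    table["gc"] = window_gc(genome, windows)
    table["tract_bp"] = window_tract_bp(genome, windows, config)
    return table


def build_window_table(
    genome: GenomeAssembly,
    fragments: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Tile, annotate sequence content, and count fragments in one call."""
    windows = annotate_windows(genome, tile_windows(genome, config), config)
    return count_fragments(fragments, windows, config)
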