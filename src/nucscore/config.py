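"""Pipeline configuration and shared domain types.

Every numeric constant used by the window-based nucleosome scoring
pipeline lives in :class:`PipelineConfig`, so that the defaults document
the analysis in one place: 167-bp windows stepped by 25 bp, the
five-read coverage filter, the eight percentile bins, the operational
NFR (250-50 bp upstream of the TSS), the H2AZ top/bottom 30% split, the
5-bp poly(dA:dT) tract minimum, and the 1-kb/25-bp metaprofile grid.

All genomic intervals are 0-based, half-open ``[start, end)`` — the BED
convention — throughout the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "BANDS",
    "REPLICATES",
    "PipelineConfig",
    "GenomeAssembly",
    "GeneModel",
    "ConfigError",
    "load_config",
    "save_config",
    "count_columns",
]

#: The four native-gel bands of the disassembly assay: nucleosomal and
#: naked DNA, each without (NUC/DNA) or with (NUCR/DNAR) the remodeler.
BANDS = ("NUC", "DNA", "NUCR", "DNAR")
REPLICATES = (1, 2)

DEFAULT_PERCENTILE_EDGES = (0, 10, 25, 50, 75, 90, 95, 99, 100)


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or inconsistent."""


def count_columns() -> list[str]:
    """Column names of the per-window count matrix, e.g. ``NUC_1``."""
    return [f"{band}_{rep}" for band in BANDS for rep in REPLICATES]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the scoring pipeline.

    Defaults reproduce the published analysis settings; see the methods
    note for the reasoning behind the ones the analysis left open.
    """

    window_width: int = 167
    window_step: int = 25
    min_reads: int = 5
    percentile_edges: tuple[float, ...] = DEFAULT_PERCENTILE_EDGES
    nfr_upstream_far: int = 250
    nfr_upstream_near: int = 50
    h2az_top_percentile: float = 30.0
    h2az_bottom_percentile: float = 30.0
    tract_min_len: int = 5
    metaprofile_halfwidth: int = 1000
    metaprofile_bin: int = 25
    pseudocount: float = 0.5
    rng_seed: int = 42
    # open-analysis switches, documented in docs/methods.md
    n_gc_bins: int = 20
    gc_method: str = "median"  # "median" (binned) or "loess"
    merge_bookended: bool = True
    tract_mixed_at: bool = False
    promoter_upstream: int = 250
    gene_score_halfwidth: int = 250

    def __post_init__(self) -> None:
        object.__setattr__(self, "percentile_edges", tuple(float(e) for e in self.percentile_edges))
        edges = self.percentile_edges
        if len(edges) < 2 or edges[0] != 0 or edges[-1] != 100:
            raise ConfigError("percentile_edges must start at 0 and end at 100")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError("percentile_edges must be strictly increasing")
        for name in (
            "window_width",
            "window_step",
            "min_reads",
            "nfr_upstream_far",
            "nfr_upstream_near",
            "tract_min_len",
            "metaprofile_halfwidth",
            "metaprofile_bin",
            "n_gc_bins",
            "promoter_upstream",
            "gene_score_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.window_step > self.window_width:
            raise ConfigError("window_step must not exceed window_width")
        if self.nfr_upstream_near >= self.nfr_upstream_far:
            raise ConfigError("nfr_upstream_near must be < nfr_upstream_far")
        if not 0 < self.h2az_top_percentile < 100:
            raise ConfigError("h2az_top_percentile must be in (0, 100)")
        if not 0 < self.h2az_bottom_percentile < 100:
            raise ConfigError("h2az_bottom_percentile must be in (0, 100)")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if self.gc_method not in ("median", "loess"):
            raise ConfigError("gc_method must be 'median' or 'loess'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["percentile_edges"] = list(self.percentile_edges)
        return d


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config file, or return the defaults when ``path`` is None.

    The file is a flat mapping whose keys match the
    :class:`PipelineConfig` field names exactly; unknown keys are
    rejected so typos fail loudly.
    """
    if path is None:
        return PipelineConfig()
    raw = Path(path).read_text()
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    if "percentile_edges" in data:
        data["percentile_edges"] = tuple(data["percentile_edges"])
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a config to YAML such that :func:`load_config` round-trips."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class GenomeAssembly:
    """An in-memory genome: ordered chromosome names and sequences.

    Sequences are uppercase strings over {A, C, G, T, N}.  N bases count
    as neither G/C nor A/T in all content computations.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        names = list(self.sequences)
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what the TSS-centric analyses need.

    ``tss`` is the 0-based position of the transcription start; for a
    minus-strand gene drawn from a BED interval this is ``end - 1``.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_class: str = "mRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.gene_class not in ("mRNA", "tRNA"):
            raise ValueError(f"gene {self.gene_id}: gene_class must be 'mRNA' or 'tRNA'")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")


def validate_genes(genes: Iterable[GeneModel], genome: GenomeAssembly) -> None:
    """Check every gene's TSS lies on a known chromosome within bounds."""
    lengths = genome.chrom_lengths
    for g in genes:
        if g.chrom not in lengths:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        if g.tss >= lengths[g.chrom]:
            raise ValueError(f"gene {g.gene_id}: tss beyond end of {g.chrom}")
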