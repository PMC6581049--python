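"""End-to-end orchestration: simulate/load -> count -> score -> regions
-> annotate, with a manifest that fully determines a rerun."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as nio
from .annotate import (
    nfr_interval,
    overlap_fraction_by_bin,
    rank_sum_test,
    score_per_bp,
    tss_metaprofile,
)
from .config import BANDS, REPLICATES, GenomeAssembly, GeneModel, PipelineConfig
from .regions import bin_and_merge
from .scoring import score_windows
from .synthetic import SimulatedExperiment, SimulationDesign, simulate_experiment, write_truth_and_inputs
from .windows import build_window_table

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run, written as manifest.json."""

    version: str
    seed: int
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(
    indir: str | Path,
) -> tuple[GenomeAssembly, list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Read the standard input layout written by the simulator:
    genome.fa, genes.bed, h2az.bedgraph and <BAND>_<rep>.bed files."""
    indir = Path(indir)
    genome = nio.read_fasta(indir / "genome.fa")
    genes = nio.read_genes(indir / "genes.bed")
    h2az = nio.read_track_bedgraph(indir / "h2az.bedgraph")
    parts = []
    for band in BANDS:
        for rep in REPLICATES:
            parts.append(nio.read_fragments_bed(indir / f"{band}_{rep}.bed", band, rep, genome))
    fragments = pd.concat(parts, ignore_index=True)
    return genome, genes, h2az, fragments


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    design: SimulationDesign | None = None,
    inputs: str | Path | None = None,
    seed: int | None = None,
    depth: float = 50.0,
    gc_beta: float = 0.5,
    n_chrom: int = 2,
    chrom_length: int = 100_000,
) -> RunManifest:
    """Run the whole pipeline into ``outdir``.

    Either ``inputs`` names a directory of real inputs (the layout of
    :func:`nucscore.synthetic.write_truth_and_inputs`) or a simulation
    ``design`` is used to generate them first.  Deterministic given
    (config, seed, inputs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    manifest = RunManifest(__version__, seed, config.to_dict())

    if inputs is not None:
        genome, genes, h2az, fragments = load_inputs(inputs)
        gene_spans = nio.read_gene_intervals(Path(inputs) / "genes.bed")
        for f in sorted(Path(inputs).iterdir()):
            if f.is_file():
                manifest.input_checksums[f.name] = _sha256(f)
    else:
        experiment = simulate_experiment(
            config,
            design=design,
            n_chrom=n_chrom,
            chrom_length=chrom_length,
            depth=depth,
            gc_beta=gc_beta,
            seed=seed,
        )
        paths = write_truth_and_inputs(experiment, outdir / "inputs")
        for name, path in sorted(paths.items()):
            manifest.input_checksums[path.name] = _sha256(path)
        genome, genes = experiment.genome, experiment.genes
        h2az, fragments = experiment.h2az_track, experiment.fragments
        gene_spans = pd.DataFrame(
            [
                (g.chrom, *experiment.gene_intervals[g.gene_id], g.gene_id, g.strand, g.gene_class)
                for g in genes
            ],
            columns=["chrom", "start", "end", "gene_id", "strand", "gene_class"],
        )
    manifest.row_counts["fragments"] = len(fragments)

    # count
    table = build_window_table(genome, fragments, config)
    manifest.row_counts["windows"] = len(table)
    nio.write_table_tsv(table, outdir / "windows.tsv")

    # score
    scored = score_windows(table, config)
    manifest.row_counts["windows_is"] = int(scored["IS"].notna().sum())
    manifest.row_counts["windows_rs"] = int(scored["RS"].notna().sum())
    nio.write_table_tsv(scored, outdir / "scores.tsv")
    nio.write_scores_bedgraph(scored, "IS", outdir / "IS.bedgraph")
    nio.write_scores_bedgraph(scored, "RS", outdir / "RS.bedgraph")

    # regions
    for kind in ("IS", "RS"):
        bins, regions = bin_and_merge(scored, kind, config)
        scored[f"bin_{kind}"] = bins
        manifest.row_counts[f"regions_{kind.lower()}"] = len(regions)
        nio.write_regions_bed(regions, outdir / f"regions_{kind}.bed")

    # annotate
    lengths = genome.chrom_lengths
    nfr = pd.DataFrame(
        [(g.chrom, *nfr_interval(g, config, lengths[g.chrom])) for g in genes],
        columns=["chrom", "start", "end"],
    )
    frac = overlap_fraction_by_bin(scored, scored["bin_RS"], nfr)
    nio.write_table_tsv(
        frac.rename("nfr_overlap_fraction").reset_index(), outdir / "nfr_overlap_by_RS_bin.tsv"
    )

    rs_track = score_per_bp(scored, "RS", config)
    profile = tss_metaprofile(rs_track, genes, genome, config, center=True, score_kind="RS")
    nio.write_table_tsv(
        pd.DataFrame(
            {"offset": profile.offsets, "mean_RS": profile.mean_value, "n_genes": profile.n}
        ),
        outdir / "tss_metaprofile_RS.tsv",
    )

    bodies = gene_spans.loc[gene_spans["gene_class"] == "tRNA", ["chrom", "start", "end"]]
    if len(bodies):
        in_trna = overlap_fraction_by_bin(scored, scored["bin_IS"], bodies)
        nio.write_table_tsv(
            in_trna.rename("trna_overlap_fraction").reset_index(),
            outdir / "trna_overlap_by_IS_bin.tsv",
        )

    manifest.write(outdir / "manifest.json")
    logger.info("run complete: %s", manifest.row_counts)
    return manifest
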