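"""Generative simulator of the four-band mononucleosome disassembly assay.

The simulator builds a toy genome with spatially varying GC content,
plants genes (mRNA and tRNA) with non-overlapping nucleosomes at
physiological spacing, assigns each nucleosome an occupancy, an
intrinsic disassembly probability ``p_unstable`` and a remodeler
disassembly probability ``r_remodel``, and samples ~167-bp fragment
libraries for the four gel bands x two replicates.

The band model follows the assay's material balance.  For a nucleosome
with occupancy w, instability p and remodeling propensity r, the
expected fragment weights are::

    NUC  = w (1 - p)            # input nucleosomes that stayed intact
    DNA  = w p                  # DNA released without remodeler
    NUCR = w (1 - p)(1 - r)     # intact despite the remodeler
    DNAR = w (p + (1 - p) r)    # released intrinsically or by remodeler

so NUC + DNA = NUCR + DNAR = w: material is conserved within each band
pair.  Counts are drawn Poisson around ``depth`` x weight per replicate
(optionally Gamma-Poisson for overdispersion), fragment lengths are
truncated-normal around the window width, and a multiplicative
acceptance weight exp(gc_beta * (gc_fragment - 0.5)) imposes the
GC sampling bias that the scoring pipeline must correct.

Base p_unstable ~ U(0.08, 0.40) and r_remodel ~ U(0.02, 0.80) span the
scores' dynamic range; class effects (tRNA-body and promoter
instability, H2AZ-dependent remodeling at the TSS) are planted
additively on top and recorded in the ground-truth table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BANDS, REPLICATES, GenomeAssembly, GeneModel, PipelineConfig
from . import io as nio

TRUTH_COLUMNS = [
    "chrom",
    "dyad",
    "occupancy",
    "p_unstable",
    "r_remodel",
    "h2az",
    "position_class",
]

NUCLEOSOME_HALF = 73  # footprint [dyad - 73, dyad + 74), ~147 bp core


@dataclass(frozen=True)
class SimulationDesign:
    """Layout and effect sizes of a simulated experiment.

    Effects are additive on the underlying probabilities (clipped to
    [0.005, 0.95]): tRNA-body and promoter nucleosomes gain
    ``delta_p``, H2AZ-flagged TSS-proximal nucleosomes gain
    ``delta_r_h2az`` (~1.5 log2 units of DNAR/NUCR shift at the design
    means).  Set the deltas to zero for a null experiment.
    """

    n_mrna: int = 60
    n_trna: int = 20
    mrna_length: int = 1200
    trna_length: int = 75
    intergenic_gap: int = 600
    spacing_min: int = 165
    spacing_max: int = 200
    p_base_low: float = 0.08
    p_base_high: float = 0.40
    r_base_low: float = 0.02
    r_base_high: float = 0.80
    delta_p_trna: float = 0.35
    delta_p_promoter: float = 0.20
    delta_r_h2az: float = 0.30
    h2az_fraction: float = 0.6
    tss_proximal_halfwidth: int = 150
    occupancy_shape: float = 20.0
    overdispersion: float = 0.0

    def null(self) -> "SimulationDesign":
        """The same layout with every planted effect removed."""
        return dataclasses.replace(
            self, delta_p_trna=0.0, delta_p_promoter=0.0, delta_r_h2az=0.0
        )


def generate_genome(
    n_chrom: int,
    lengths: list[int] | int,
    gc_target: float = 0.5,
    gc_amplitude: float = 0.15,
    gc_period: int = 10_000,
    seed: int = 0,
) -> GenomeAssembly:
    """Random genome with a sinusoidal GC wave.

    The per-base probability of G or C follows
    ``gc_target + gc_amplitude * sin(2 pi x / gc_period)``, so per-kb
    GC spans roughly [target - amplitude, target + amplitude] and the
    GC normalization step has real structure to remove.  Deterministic
    per seed.
    """
    if isinstance(lengths, int):
        lengths = [lengths] * n_chrom
    if len(lengths) != n_chrom:
        raise ValueError("lengths must match n_chrom")
    if any(L <= 0 for L in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    bases_at = np.array(list("AT"))
    bases_gc = np.array(list("GC"))
    sequences = {}
    for c, length in enumerate(lengths):
        x = np.arange(length)
        p_gc = np.clip(gc_target + gc_amplitude * np.sin(2 * np.pi * x / gc_period), 0.02, 0.98)
        is_gc = rng.random(length) < p_gc
        letters = np.where(
            is_gc,
            bases_gc[rng.integers(0, 2, length)],
            bases_at[rng.integers(0, 2, length)],
        )
        sequences[f"chr{c + 1}"] = "".join(letters)
    return GenomeAssembly(sequences)


def _place_genes(
    genome: GenomeAssembly, design: SimulationDesign, rng: np.random.Generator
) -> tuple[list[GeneModel], dict[str, tuple[int, int]]]:
    """Lay out non-overlapping genes across chromosomes, promoter gaps
    between them, random strands, tRNAs interleaved among mRNAs."""
    classes = ["mRNA"] * design.n_mrna + ["tRNA"] * design.n_trna
    order = rng.permutation(len(classes))
    queue = [classes[i] for i in order]
    genes: list[GeneModel] = []
    intervals: dict[str, tuple[int, int]] = {}
    counters = {"mRNA": 0, "tRNA": 0}
    chrom_iter = list(genome.chrom_lengths.items())
    margin = 400
    for chrom, length in chrom_iter:
        cursor = margin
        while queue:
            gene_class = queue[0]
            glen = design.mrna_length if gene_class == "mRNA" else design.trna_length
            start = cursor + design.intergenic_gap
            end = start + glen
            if end + margin > length:
                break
            queue.pop(0)
            counters[gene_class] += 1
            gene_id = f"{'G' if gene_class == 'mRNA' else 'T'}{counters[gene_class]:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            genes.append(GeneModel(gene_id, chrom, tss, strand, gene_class))
            intervals[gene_id] = (start, end)
            cursor = end
    if queue:
        raise ValueError(
            f"genome too small for design: {len(queue)} gene(s) could not be placed"
        )
    return genes, intervals


def place_genes_and_truth(
    genome: GenomeAssembly,
    design: SimulationDesign,
    config: PipelineConfig,
    seed: int = 0,
) -> tuple[list[GeneModel], dict[str, tuple[int, int]], pd.DataFrame, pd.DataFrame]:
    """Plant genes, nucleosomes, per-nucleosome truth, and the H2AZ track.

    Returns (genes, gene intervals, truth table, H2AZ bedGraph-style
    track).  Nucleosome classes: ``tRNA`` (footprint overlaps a tRNA
    body), ``NFR-proximal`` (dyad in the promoter of an mRNA gene),
    ``genic`` (dyad inside an mRNA body), else ``intergenic``.  The
    H2AZ track is a per-nucleosome density: high for flagged
    nucleosomes, low elsewhere, with a faint baseline between
    footprints.
    """
    rng = np.random.default_rng(seed)
    genes, intervals = _place_genes(genome, design, rng)

    from .annotate import promoter_interval

    margin = max(config.window_width // 2, NUCLEOSOME_HALF + 1)
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        dyad = margin + int(rng.integers(0, design.spacing_min))
        while dyad < length - margin:
            rows.append((chrom, dyad))
            dyad += int(rng.integers(design.spacing_min, design.spacing_max + 1))
    truth = pd.DataFrame(rows, columns=["chrom", "dyad"])
    n = len(truth)

    truth["occupancy"] = rng.gamma(design.occupancy_shape, 1.0 / design.occupancy_shape, n)
    truth["p_unstable"] = rng.uniform(design.p_base_low, design.p_base_high, n)
    truth["r_remodel"] = rng.uniform(design.r_base_low, design.r_base_high, n)

    # classify nucleosomes against the planted annotation
    trna_iv: dict[str, list[tuple[int, int]]] = {}
    mrna_iv: dict[str, list[tuple[int, int]]] = {}
    prom_iv: dict[str, list[tuple[int, int]]] = {}
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        s, e = intervals[g.gene_id]
        if g.gene_class == "tRNA":
            trna_iv.setdefault(g.chrom, []).append((s, e))
        else:
            mrna_iv.setdefault(g.chrom, []).append((s, e))
            prom_iv.setdefault(g.chrom, []).append(promoter_interval(g, config))
            tss_by_chrom.setdefault(g.chrom, []).append(g.tss)

    def _in_any(chrom: str, lo: int, hi: int, table: dict) -> bool:
        return any(s < hi and lo < e for s, e in table.get(chrom, ()))

    classes = []
    tss_proximal = np.zeros(n, dtype=bool)
    for i, (chrom, dyad) in enumerate(zip(truth["chrom"], truth["dyad"])):
        foot_lo, foot_hi = dyad - NUCLEOSOME_HALF, dyad + NUCLEOSOME_HALF + 1
        if _in_any(chrom, foot_lo, foot_hi, trna_iv):
            classes.append("tRNA")
        elif _in_any(chrom, dyad, dyad + 1, prom_iv):
            classes.append("NFR-proximal")
        elif _in_any(chrom, dyad, dyad + 1, mrna_iv):
            classes.append("genic")
        else:
            classes.append("intergenic")
        tss_proximal[i] = any(
            abs(dyad - t) <= design.tss_proximal_halfwidth
            for t in tss_by_chrom.get(chrom, ())
        )
    truth["position_class"] = classes

    truth["h2az"] = tss_proximal & (rng.random(n) < design.h2az_fraction)

    cls = truth["position_class"].to_numpy()
    p = truth["p_unstable"].to_numpy()
    r = truth["r_remodel"].to_numpy()
    p = p + design.delta_p_trna * (cls == "tRNA")
    p = p + design.delta_p_promoter * (cls == "NFR-proximal")
    r = r + design.delta_r_h2az * truth["h2az"].to_numpy()
    truth["p_unstable"] = np.clip(p, 0.005, 0.95)
    truth["r_remodel"] = np.clip(r, 0.005, 0.95)

    h2az_track = _h2az_track(genome, truth, rng)
    return genes, intervals, truth, h2az_track


def _h2az_track(
    genome: GenomeAssembly, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-nucleosome H2AZ density: footprints of flagged nucleosomes get
    high values, other footprints low ones, gaps a faint baseline."""
    weights = np.where(
        truth["h2az"].to_numpy(),
        rng.uniform(5.0, 10.0, len(truth)),
        rng.uniform(0.1, 2.0, len(truth)),
    )
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        sel = truth["chrom"] == chrom
        dyads = truth.loc[sel, "dyad"].to_numpy()
        w = weights[sel.to_numpy()]
        cursor = 0
        for dyad, value in zip(dyads, w):
            lo, hi = dyad - NUCLEOSOME_HALF, dyad + NUCLEOSOME_HALF + 1
            if lo > cursor:
                rows.append((chrom, cursor, lo, 0.05))
            rows.append((chrom, max(lo, cursor), hi, float(value)))
            cursor = hi
        if cursor < length:
            rows.append((chrom, cursor, length, 0.05))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _band_weights(p: np.ndarray, r: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "NUC": 1.0 - p,
        "DNA": p,
        "NUCR": (1.0 - p) * (1.0 - r),
        "DNAR": p + (1.0 - p) * r,
    }


def _gc_cumsums(genome: GenomeAssembly) -> dict[str, np.ndarray]:
    out = {}
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        ind = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
        out[chrom] = np.concatenate([[0], np.cumsum(ind)])
    return out


def simulate_library(
    genome: GenomeAssembly,
    truth: pd.DataFrame,
    depth: float = 50.0,
    frag_len_mean: float = 167.0,
    frag_len_sd: float = 15.0,
    gc_beta: float = 0.0,
    overdispersion: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample the four-band x two-replicate fragment libraries.

    ``depth`` is the expected number of fragments per nucleosome per
    band pair (so NUC + DNA counts sum to ~depth x occupancy).  Counts
    are Poisson (Gamma-Poisson when ``overdispersion`` > 0, with
    variance depth*(1 + overdispersion*depth)); each fragment draws a
    truncated-normal length in [100, 250] and a start jittered +-10 bp
    around dyad centering; fragments are then thinned with acceptance
    weight exp(gc_beta * (gc - 0.5)) to impose GC bias.  Deterministic
    per seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    gc_cum = _gc_cumsums(genome)
    lengths = genome.chrom_lengths
    weights = _band_weights(truth["p_unstable"].to_numpy(), truth["r_remodel"].to_numpy())
    occ = truth["occupancy"].to_numpy()
    chroms = truth["chrom"].to_numpy()
    dyads = truth["dyad"].to_numpy()

    frames = []
    for band in BANDS:
        lam_base = depth * occ * weights[band]
        for rep in REPLICATES:
            if overdispersion > 0:
                lam = rng.gamma(1.0 / overdispersion, overdispersion * lam_base)
            else:
                lam = lam_base
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total == 0:
                continue
            nuc_idx = np.repeat(np.arange(len(truth)), counts)
            flen = rng.normal(frag_len_mean, frag_len_sd, total)
            # redraw the rare out-of-range lengths (truncated normal)
            bad = (flen < 100) | (flen > 250)
            while bad.any():
                flen[bad] = rng.normal(frag_len_mean, frag_len_sd, int(bad.sum()))
                bad = (flen < 100) | (flen > 250)
            flen = np.round(flen).astype(np.int64)
            jitter = rng.integers(-10, 11, total)
            starts = dyads[nuc_idx] - flen // 2 + jitter
            frag_chroms = chroms[nuc_idx]
            chrom_len = np.array([lengths[c] for c in frag_chroms])
            starts = np.clip(starts, 0, chrom_len - flen)
            ends = starts + flen
            if gc_beta != 0.0:
                gc = np.empty(total)
                for chrom in np.unique(frag_chroms):
                    m = frag_chroms == chrom
                    cum = gc_cum[chrom]
                    gc[m] = (cum[ends[m]] - cum[starts[m]]) / flen[m]
                accept_w = np.exp(gc_beta * (gc - 0.5))
                keep = rng.random(total) < accept_w / np.exp(abs(gc_beta) * 0.5)
            else:
                rng.random(total)  # keep the stream aligned across gc_beta settings
                keep = np.ones(total, dtype=bool)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": frag_chroms[keep],
                        "start": starts[keep],
                        "end": ends[keep],
                        "band": band,
                        "replicate": rep,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=nio.FRAGMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimulatedExperiment:
    """Everything one simulated assay produced, in memory."""

    genome: GenomeAssembly
    genes: list[GeneModel]
    gene_intervals: dict[str, tuple[int, int]]
    truth: pd.DataFrame
    h2az_track: pd.DataFrame
    fragments: pd.DataFrame
    design: SimulationDesign
    seed: int


def simulate_experiment(
    config: PipelineConfig,
    design: SimulationDesign | None = None,
    n_chrom: int = 2,
    chrom_length: int = 100_000,
    depth: float = 50.0,
    gc_beta: float = 0.5,
    seed: int | None = None,
) -> SimulatedExperiment:
    """Run the full generator with named substreams per stage."""
    design = design or SimulationDesign()
    seed = config.rng_seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_genome, s_truth, s_library = (int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(3))
    genome = generate_genome(n_chrom, chrom_length, seed=s_genome)
    genes, intervals, truth, h2az = place_genes_and_truth(genome, design, config, seed=s_truth)
    fragments = simulate_library(
        genome,
        truth,
        depth=depth,
        gc_beta=gc_beta,
        overdispersion=design.overdispersion,
        seed=s_library,
    )
    return SimulatedExperiment(genome, genes, intervals, truth, h2az, fragments, design, seed)


def write_truth_and_inputs(experiment: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input in its standard on-disk format.

    Emits the genome FASTA (60-column), genes BED6 (class in the name
    suffix), one fragment BED per band x replicate, the H2AZ bedGraph,
    and the ground-truth TSV.  Returns the mapping of artifact name to
    path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    nio.write_fasta(experiment.genome, paths["genome"])
    paths["genes"] = outdir / "genes.bed"
    nio.write_genes_bed(experiment.genes, experiment.gene_intervals, paths["genes"])
    paths["h2az"] = outdir / "h2az.bedgraph"
    nio.write_track_bedgraph(experiment.h2az_track, paths["h2az"])
    paths["truth"] = outdir / "truth.tsv"
    nio.write_table_tsv(experiment.truth[TRUTH_COLUMNS], paths["truth"])
    for band in BANDS:
        for rep in REPLICATES:
            sel = (experiment.fragments["band"] == band) & (
                experiment.fragments["replicate"] == rep
            )
            path = outdir / f"{band}_{rep}.bed"
            nio.write_fragments_bed(experiment.fragments[sel], path)
            paths[f"{band}_{rep}"] = path
    return paths


def match_windows_to_truth(
    windows: pd.DataFrame, truth: pd.DataFrame, max_dist: int = 60
) -> pd.Series:
    """Index of the nucleosome whose dyad is nearest each window midpoint.

    Windows whose midpoint lies farther than ``max_dist`` bp from any
    dyad get -1; used to evaluate parameter recovery against the
    planted truth.
    """
    out = np.full(len(windows), -1, dtype=np.int64)
    for chrom, idx in windows.groupby("chrom", sort=False).groups.items():
        sel = truth.index[truth["chrom"] == chrom]
        if len(sel) == 0:
            continue
        dyads = truth.loc[sel, "dyad"].to_numpy()
        order = np.argsort(dyads)
        dyads_sorted = dyads[order]
        mids = ((windows.loc[idx, "start"] + windows.loc[idx, "end"]) // 2).to_numpy()
        j = np.searchsorted(dyads_sorted, mids)
        j_lo = np.clip(j - 1, 0, len(dyads_sorted) - 1)
        j_hi = np.clip(j, 0, len(dyads_sorted) - 1)
        pick = np.where(
            np.abs(dyads_sorted[j_hi] - mids) < np.abs(dyads_sorted[j_lo] - mids), j_hi, j_lo
        )
        dist = np.abs(dyads_sorted[pick] - mids)
        matched = np.where(dist <= max_dist, sel.to_numpy()[order[pick]], -1)
        out[windows.index.get_indexer(idx)] = matched
    return pd.Series(out, index=windows.index)
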