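"""Readers and writers for the standard formats the pipeline touches.

FASTA (genome), BED3/BED6 (fragments, genes, regions), bedGraph (value
tracks such as H2AZ density) and TSV tables.  All paths ending in
``.gz`` are read and written gzip-compressed transparently.  Writers
sort by (chrom, start) and format floats at six decimals, so identical
inputs always produce byte-identical files.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .config import GeneModel, GenomeAssembly

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "band", "replicate"]
TRACK_COLUMNS = ["chrom", "start", "end", "value"]

_GFF_CLASS_MAP = {
    "gene": "mRNA",
    "mRNA": "mRNA",
    "protein_coding_gene": "mRNA",
    "tRNA_gene": "tRNA",
    "tRNA": "tRNA",
}


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t") if mode == "rt" else mode)


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`.

    Record names are taken up to the first whitespace; sequences are
    uppercased.  Duplicate names and empty records are errors.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else ""
            if not name:
                raise ValueError(f"{path}: FASTA record with empty name")
            if name in sequences:
                raise ValueError(f"{path}: duplicate FASTA record '{name}'")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"{path}: empty sequence for record '{name}'")
            sequences[name] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return GenomeAssembly(sequences)


def write_fasta(genome: GenomeAssembly, path: str | Path, width: int = 60) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in genome.sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def _bed_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_fragments_bed(
    path: str | Path,
    band: str,
    replicate: int,
    genome: GenomeAssembly | None = None,
) -> pd.DataFrame:
    """Read aligned fragments from a BED3+ file for one band/replicate.

    Returns a DataFrame with columns chrom, start, end, band, replicate.
    Coordinates are taken as-is (BED is already 0-based half-open).
    """
    rows = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path} line {lineno}: expected >= 3 BED fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: non-integer coordinates") from exc
        if start >= end or start < 0:
            raise ValueError(f"{path} line {lineno}: invalid interval [{start}, {end})")
        if genome is not None:
            if chrom not in genome:
                raise ValueError(f"{path} line {lineno}: unknown chromosome {chrom}")
            if end > len(genome[chrom]):
                raise ValueError(f"{path} line {lineno}: interval beyond end of {chrom}")
        rows.append((chrom, start, end))
    if not rows:
        logger.warning("%s: no fragments found", path)
        return pd.DataFrame(columns=FRAGMENT_COLUMNS).astype(
            {"start": int, "end": int, "replicate": int}
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["band"] = band
    df["replicate"] = replicate
    return df


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    """Write fragment intervals (one band/replicate) as BED3, sorted."""
    df = fragments.sort_values(["chrom", "start", "end"], kind="stable")
    with _open_text(path, "wt") as out:
        for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
            out.write(f"{chrom}\t{start}\t{end}\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read genes from BED6(+).

    The TSS is the BED start for + strand genes and end-1 for - strand.
    The gene class (mRNA vs tRNA) may be carried as a ``|class`` suffix
    on the name (``YAL001C|tRNA``) or in a seventh column ``class=tRNA``;
    it defaults to mRNA.  Strand is required.
    """
    genes: list[GeneModel] = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 6:
            raise ValueError(f"{path} line {lineno}: gene BED needs 6 columns (strand required)")
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: non-integer coordinates") from exc
        if start_i >= end_i:
            raise ValueError(f"{path} line {lineno}: invalid interval")
        if strand not in ("+", "-"):
            raise ValueError(f"{path} line {lineno}: strand must be '+' or '-'")
        gene_class = "mRNA"
        if "|" in name:
            name, gene_class = name.rsplit("|", 1)
        for extra in fields[6:]:
            if extra.startswith("class="):
                gene_class = extra[len("class=") :]
        tss = start_i if strand == "+" else end_i - 1
        genes.append(GeneModel(name, chrom, tss, strand, gene_class))
    if not genes:
        raise ValueError(f"{path}: no genes found")
    return genes


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Read genes from GFF3, mapping feature types to mRNA/tRNA classes.

    Only feature types in the known map (gene, mRNA, tRNA_gene, tRNA)
    are kept.  GFF coordinates are 1-based inclusive, so the TSS is
    ``start - 1`` (+ strand) or ``end - 1`` (- strand).
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path} line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
            if ftype not in _GFF_CLASS_MAP:
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path} line {lineno}: strand must be '+' or '-'")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("Name")
            if gene_id is None:
                raise ValueError(f"{path} line {lineno}: feature lacks ID/Name attribute")
            if gene_id in seen:
                continue
            seen.add(gene_id)
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            genes.append(GeneModel(gene_id, chrom, tss, strand, _GFF_CLASS_MAP[ftype]))
    if not genes:
        raise ValueError(f"{path}: no gene features found")
    return genes


def write_genes_bed(genes: list[GeneModel], intervals: dict[str, tuple[int, int]], path: str | Path) -> None:
    """Write genes as BED6 with the class carried in the name suffix.

    ``intervals`` maps gene_id to its (start, end) span.
    """
    rows = []
    for g in genes:
        start, end = intervals[g.gene_id]
        rows.append((g.chrom, start, end, f"{g.gene_id}|{g.gene_class}", 0, g.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with _open_text(path, "wt") as out:
        for row in rows:
            out.write("\t".join(str(x) for x in row) + "\n")


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Read gene spans from BED6 as a DataFrame
    (chrom, start, end, gene_id, strand, gene_class)."""
    rows = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 6:
            raise ValueError(f"{path} line {lineno}: gene BED needs 6 columns")
        chrom, start, end, name, _score, strand = fields[:6]
        gene_class = "mRNA"
        if "|" in name:
            name, gene_class = name.rsplit("|", 1)
        for extra in fields[6:]:
            if extra.startswith("class="):
                gene_class = extra[len("class=") :]
        rows.append((chrom, int(start), int(end), name, strand, gene_class))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "strand", "gene_class"]
    )


def read_track_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a Track DataFrame (chrom, start, end, value).

    Intervals must be non-overlapping within a chromosome; overlapping
    tracks are rejected rather than silently averaged.
    """
    rows = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path} line {lineno}: bedGraph needs 4 columns")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: malformed bedGraph fields") from exc
        if start >= end:
            raise ValueError(f"{path} line {lineno}: invalid interval")
        rows.append((fields[0], start, end, value))
    if not rows:
        raise ValueError(f"{path}: empty bedGraph")
    track = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    track = track.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    same_chrom = track["chrom"].shift(-1) == track["chrom"]
    overlapping = same_chrom & (track["end"] > track["start"].shift(-1))
    if overlapping.any():
        bad = track.loc[overlapping.idxmax()]
        raise ValueError(
            f"{path}: overlapping bedGraph intervals on {bad['chrom']} near {bad['start']}"
        )
    return track


def write_track_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    df = track.sort_values(["chrom", "start"], kind="stable")
    with _open_text(path, "wt") as out:
        for chrom, start, end, value in zip(df["chrom"], df["start"], df["end"], df["value"]):
            out.write(f"{chrom}\t{start}\t{end}\t{value:.6f}\n")


def write_scores_bedgraph(scored: pd.DataFrame, column: str, path: str | Path) -> None:
    """Write one score column of a scored window table as bedGraph.

    Windows where the score is undefined (NaN) are omitted.
    """
    df = scored.loc[scored[column].notna(), ["chrom", "start", "end", column]]
    df = df.rename(columns={column: "value"})
    write_track_bedgraph(df, path)


def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write merged regions as BED6 (name = percentile bin, score = mean)."""
    df = regions.sort_values(["chrom", "start"], kind="stable")
    with _open_text(path, "wt") as out:
        for row in df.itertuples(index=False):
            out.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.bin}\t{row.mean_score:.6f}\t.\n"
            )


def write_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with deterministic 6-decimal floats."""
    with _open_text(path, "wt") as out:
        df.to_csv(out, sep="\t", index=False, float_format="%.6f")


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as handle:
        return pd.read_csv(handle, sep="\t")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-gene-per-line list (e.g. remodeler target genes)."""
    with _open_text(path) as handle:
        return {line.strip() for line in handle if line.strip()}
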