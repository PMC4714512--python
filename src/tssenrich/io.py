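"""Plain-text I/O: BED, BED12, minimal GTF, bedGraph, chrom.sizes, TSV.

All writers accept ``.gz`` paths transparently.  Coordinates are 0-based
half-open internally; GTF (1-based, end-inclusive) is converted on read
and write.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

from .synthetic_data import GeneModel, GenomeModel

__all__ = [
    "read_chrom_sizes", "write_chrom_sizes",
    "read_reads_bed", "write_reads_bed",
    "read_peaks_bed", "write_peaks_bed",
    "read_genes_bed12", "write_genes_bed12",
    "read_genes_gtf", "write_genes_gtf",
    "read_expression_tsv", "write_expression_tsv",
    "write_bedgraph", "write_track_tsv",
]


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


# -- genome ---------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeModel:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return GenomeModel(tuple((str(c), int(l))
                             for c, l in zip(df["chrom"], df["length"])))


def write_chrom_sizes(genome: GenomeModel, path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


# -- reads / peaks --------------------------------------------------------

def read_reads_bed(path: str | Path) -> pd.DataFrame:
    """6-column BED; name and score columns are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 5], dtype={0: str})
    df.columns = ["chrom", "start", "end", "strand"]
    return df


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for chrom, start, end, strand in zip(reads["chrom"], reads["start"],
                                             reads["end"], reads["strand"]):
            fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{strand}\n")


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ (narrowPeak included); extra columns are dropped."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for chrom, start, end in zip(peaks["chrom"], peaks["start"],
                                     peaks["end"]):
            fh.write(f"{chrom}\t{start}\t{end}\n")


# -- gene models ----------------------------------------------------------

def write_genes_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offs = ",".join(str(s - g.tx_start) for s, _ in g.exons) + ","
            fh.write("\t".join(map(str, (
                g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                g.tx_start, g.tx_end, 0, len(g.exons), sizes, offs))) + "\n")


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with _open_text(path, "r") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def write_genes_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Minimal GTF dialect: transcript and exon features, gene_id attribute."""
    with _open_text(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\ttssenrich\ttranscript\t{g.tx_start + 1}\t"
                     f"{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\ttssenrich\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")


def _gtf_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    raise ValueError(f"GTF attribute {key!r} not found in {attrs!r}")


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Parse the minimal transcript/exon GTF dialect written by this package."""
    tx: dict[str, dict] = {}
    order: list[str] = []
    with _open_text(path, "r") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            gid = _gtf_attr(attrs, "gene_id")
            start0, end0 = int(start) - 1, int(end)
            if feature == "transcript":
                tx[gid] = {"chrom": chrom, "strand": strand,
                           "tx_start": start0, "tx_end": end0, "exons": []}
                order.append(gid)
            elif feature == "exon":
                tx[gid]["exons"].append((start0, end0))
    return [GeneModel(gid, tx[gid]["chrom"], tx[gid]["strand"],
                      tx[gid]["tx_start"], tx[gid]["tx_end"],
                      tuple(sorted(tx[gid]["exons"])))
            for gid in order]


# -- expression -----------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if list(df.columns[:2]) != ["gene_id", "fpkm"]:
        raise ValueError("expression table must have header 'gene_id\\tfpkm'")
    return df[["gene_id", "fpkm"]]


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr[["gene_id", "fpkm"]].to_csv(path, sep="\t", index=False)


# -- tracks ---------------------------------------------------------------

def write_bedgraph(values: dict, bin_size: int, path: str | Path,
                   genome: GenomeModel | None = None) -> None:
    """Write a binned track as bedGraph lines (one per bin).

    The final bin of a chromosome is truncated at the chromosome end when
    the genome is supplied.
    """
    lengths = genome.lengths if genome is not None else {}
    with _open_text(path, "w") as fh:
        for chrom, vec in values.items():
            L = lengths.get(chrom)
            for i, v in enumerate(vec):
                start = i * bin_size
                end = start + bin_size
                if L is not None:
                    end = min(end, L)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def write_track_tsv(values: dict, bin_size: int, path: str | Path) -> None:
    rows = []
    for chrom, vec in values.items():
        for i, v in enumerate(vec):
            rows.append((chrom, i * bin_size, v))
    pd.DataFrame(rows, columns=["chrom", "bin_start", "value"]).to_csv(
        path, sep="\t", index=False)
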