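"""Readers and writers for the plain-text formats the pipeline consumes.

BED and GTF coordinates follow their native conventions: BED is 0-based
half-open on disk and in memory; GTF is written/read 1-based inclusive on
disk and converted to 0-based half-open records.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, Interval, Peak

# ---------------------------------------------------------------------------
# genome sizes


def write_genome_sizes(sizes: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_genome_sizes(path) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
    return out


# ---------------------------------------------------------------------------
# BED


def write_bed(records: Iterable, path) -> None:
    """Write peaks/intervals as BED6 (name=id, score=-log10 p when present)."""
    with open(path, "w") as fh:
        for rec in records:
            name = getattr(rec, "peak_id", "") or getattr(rec, "name", ".")
            p = getattr(rec, "p_value", None)
            score = 0.0 if p is None else min(1000.0, -np.log10(max(p, 1e-300)))
            strand = getattr(rec, "strand", ".")
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{name}\t{score:.4g}\t{strand}\n"
            )


def read_peaks_bed(path, cell_type: str = "", condition: str = "") -> List[Peak]:
    peaks: List[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            peaks.append(
                Peak(chrom, start, end, name, cell_type=cell_type, condition=condition)
            )
    return peaks


def read_intervals_bed(path) -> List[Interval]:
    out: List[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(Interval(f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
    return out


# ---------------------------------------------------------------------------
# minimal GTF (gene features only)


def write_gtf(genes: Sequence[GeneModel], path, source: str = "rretools") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "protein_coding";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gtf_genes(path) -> List[GeneModel]:
    """Parse gene features from a GTF; gene_id is extracted by attribute key."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            gene_id = _gtf_attr(f[8], "gene_id")
            if gene_id is None:
                raise ValueError(f"GTF gene line without gene_id attribute: {line!r}")
            genes.append(GeneModel(gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return genes


def _gtf_attr(attr_field: str, key: str):
    for chunk in attr_field.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: Dict[str, str], path) -> None:
    """Write id->sequence mapping as FASTA, 60-column wrap."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# JASPAR-style PFM text

BASES = "ACGT"


def read_jaspar_pfms(path) -> Dict[str, np.ndarray]:
    """Parse JASPAR-format PFMs into column-stochastic 4 x W arrays (rows A,C,G,T)."""
    out: Dict[str, np.ndarray] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            colsum = counts.sum(axis=0)
            if np.any(colsum <= 0):
                raise ValueError(f"PFM {m.matrix_id}: zero column")
            name = m.name or m.matrix_id
            out[name] = counts / colsum
    return out


def write_jaspar_pfms(pfms: Dict[str, np.ndarray], path, scale: int = 100) -> None:
    with open(path, "w") as fh:
        for name, pwm in pfms.items():
            fh.write(f">{name} {name}\n")
            counts = np.round(np.asarray(pwm) * scale).astype(int)
            for i, b in enumerate(BASES):
                row = " ".join(f"{c:4d}" for c in counts[i])
                fh.write(f"{b} [ {row} ]\n")


def write_meme_motifs(pwms: Dict[str, np.ndarray], path) -> None:
    """Minimal MEME text format writer."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for name, pwm in pwms.items():
            pwm = np.asarray(pwm)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.shape[1]} nsites= 20 E= 0\n"
            )
            for col in pwm.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# count triplets and tables


def write_counts_triplets(
    cell_ids: Sequence[str], peak_ids: Sequence[str], counts: np.ndarray, path
) -> None:
    """Write a cells x peaks matrix as (cell_id, peak_id, count) triplets, zeros omitted."""
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write("cell_id\tpeak_id\tcount\n")
        rows, cols = np.nonzero(counts)
        for r, c in zip(rows, cols):
            fh.write(f"{cell_ids[r]}\t{peak_ids[c]}\t{int(counts[r, c])}\n")


def read_counts_triplets(
    path, cell_ids: Sequence[str] = None, peak_ids: Sequence[str] = None
) -> Tuple[List[str], List[str], np.ndarray]:
    """Read triplets back into a dense cells x peaks integer matrix."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "peak_id": str})
    cells = list(cell_ids) if cell_ids is not None else sorted(df["cell_id"].unique())
    peaks = list(peak_ids) if peak_ids is not None else sorted(df["peak_id"].unique())
    ci = {c: i for i, c in enumerate(cells)}
    pi = {p: i for i, p in enumerate(peaks)}
    mat = np.zeros((len(cells), len(peaks)), dtype=np.int64)
    for cell, peak, count in df.itertuples(index=False):
        mat[ci[cell], pi[peak]] = count
    return cells, peaks, mat


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
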