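"""Readers and writers for the plain-text formats the pipeline exchanges.

Sequences travel as FASTA, counts as MatrixMarket triplets plus row/column
name files, annotations and pairwise matrices as TSV, motifs as JASPAR-style
four-row count records, trees as Newick, and ion images as dense TSV grids.
Everything round-trips losslessly through these functions.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import Phylo, SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix, PairMatrix, Pfm

ANNOTATION_COLUMNS = [
    "gene_id", "scaffold", "start", "end", "strand", "tss", "class", "family", "group",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotation table (1-based inclusive coordinates)

def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "scaffold": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts: MatrixMarket + name files

def read_counts_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    sample_kind: str = "cell",
) -> CountMatrix:
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    return CountMatrix(np.asarray(mat, dtype=np.int64), genes, samples, sample_kind)


def write_counts_mtx(
    counts: CountMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(counts.values))
    Path(genes_path).write_text("\n".join(counts.gene_ids) + "\n")
    Path(samples_path).write_text("\n".join(counts.sample_ids) + "\n")


# ---------------------------------------------------------------------------
# Motifs (JASPAR-style ">id name" + four count rows)

def read_pfms(path: str | Path) -> list[Pfm]:
    text = Path(path).read_text()
    try:
        records = motifs.parse(_io.StringIO(text), "jaspar")
    except Exception as exc:  # malformed record: surface a parse error
        raise ValueError(f"could not parse motif file {path}: {exc}") from exc
    n_headers = sum(1 for line in text.splitlines() if line.startswith(">"))
    if len(records) != n_headers:
        raise ValueError(
            f"motif file {path}: {n_headers} headers but {len(records)} complete "
            "records (each record needs four base rows A/C/G/T)"
        )
    out = []
    for m in records:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        out.append(Pfm(id=m.matrix_id or m.name, name=m.name, counts=counts))
    return out


def write_pfms(pfms: list[Pfm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.id} {p.name}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{v:g}" for v in p.counts[bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Pairwise matrices and generic tables

def read_pair_matrix(path: str | Path, measure: str = "", kind: str = "similarity") -> PairMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return PairMatrix.from_frame(df, measure=measure, kind=kind)


def write_pair_matrix(pm: PairMatrix, path: str | Path) -> None:
    pm.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trees (Newick)

def read_newick(path: str | Path):
    return Phylo.read(str(path), "newick")


def write_newick(tree, path: str | Path) -> None:
    Phylo.write(tree, str(path), "newick", format_branch_length="%.10g")


def tree_from_newick_string(s: str):
    return Phylo.read(_io.StringIO(s), "newick")


# ---------------------------------------------------------------------------
# Ion-image grids

def read_grid(path: str | Path) -> np.ndarray:
    return np.loadtxt(str(path), delimiter="\t", ndmin=2)


def write_grid(grid: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(grid), delimiter="\t", fmt="%.10g")
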