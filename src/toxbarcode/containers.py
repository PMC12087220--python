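"""Shared in-memory containers used across the analysis modules.

The package deliberately keeps these light: a count matrix is a dense
non-negative integer array with row/column identifiers, and every pairwise
measure (Jaccard, patristic, genomic, spatial, co-expression) travels as a
:class:`PairMatrix` so the integrative correlation engine can treat them
uniformly. NaN encodes "not measured" (e.g., cross-scaffold genomic
distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "PairMatrix", "Pfm"]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer counts.

    ``sample_kind`` distinguishes single cells from bulk libraries; several
    operations require one or the other.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    sample_kind: str = "cell"  # "cell" | "bulk"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample identifiers must be unique")
        if self.sample_kind not in ("cell", "bulk"):
            raise ValueError("sample_kind must be 'cell' or 'bulk'")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.values[:, idx], self.gene_ids, list(sample_ids), self.sample_kind)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountMatrix(self.values[idx, :], list(gene_ids), self.sample_ids, self.sample_kind)


@dataclass
class PairMatrix:
    """Symmetric pairwise measure over a labelled set of genes/toxins.

    ``values[i, j]`` is the measure between ``labels[i]`` and ``labels[j]``;
    NaN marks missing pairs. ``kind`` is "similarity" (unit diagonal) or
    "distance" (zero diagonal).
    """

    labels: list[str]
    values: np.ndarray
    measure: str = ""
    kind: str = "similarity"

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if n:
            diff = np.abs(self.values - self.values.T)
            finite = np.isfinite(diff)
            asym = diff[finite].max() if finite.any() else 0.0
            if asym > 1e-8:
                raise ValueError(f"matrix not symmetric (max asymmetry {asym:.3g})")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """Return the upper-triangle pairs and their values (NaN included)."""
        iu, ju = np.triu_indices(self.n, k=1)
        pairs = [(self.labels[i], self.labels[j]) for i, j in zip(iu, ju)]
        return pairs, self.values[iu, ju]

    def reindex(self, labels: list[str]) -> "PairMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels not present: {missing}")
        idx = np.array([pos[l] for l in labels])
        return PairMatrix(list(labels), self.values[np.ix_(idx, idx)], self.measure, self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, measure: str = "", kind: str = "similarity") -> "PairMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("frame must have identical row and column labels")
        return cls(list(df.index), df.to_numpy(dtype=float), measure, kind)


@dataclass
class Pfm:
    """Position frequency matrix: base counts (rows A, C, G, T) per position."""

    id: str
    name: str
    counts: np.ndarray = field(repr=False)

    BASES = "ACGT"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.id}: counts must be 4 x L")
        if self.counts.shape[1] < 4:
            raise ValueError(f"{self.id}: motif length must be >= 4")
        if (self.counts < 0).any():
            raise ValueError(f"{self.id}: counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.id}: every column needs a positive total")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(self.BASES[i] for i in self.counts.argmax(axis=0))


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
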