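"""Integrative comparisons: barcode Jaccard similarity, physical genomic
distance, the pairwise-matrix correlation engine (with an optional Mantel
permutation p-value), GRN assembly and centrality analysis.

Every pairwise measure travels as a PairMatrix, so correlating, say, the
Jaccard similarity of TF barcodes against the spatial co-occurrence of the
same toxins is a single call with pairwise deletion of missing entries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from ._rng import substream
from .containers import PairMatrix
from .regnet import RegulatoryAssignment

__all__ = [
    "CorrelationResult",
    "jaccard_matrix",
    "genomic_distance",
    "matrix_correlation",
    "build_grn",
    "centralities",
]


def jaccard_matrix(assignment: RegulatoryAssignment) -> PairMatrix:
    """J(g, h) = |B_g ∩ B_h| / |B_g ∪ B_h| over barcode TF sets; a pair of
    empty barcodes is missing; non-empty diagonal is 1."""
    genes = sorted(assignment.barcode)
    n = len(genes)
    vals = np.ones((n, n))
    empty_warned = False
    for i, j in itertools.combinations(range(n), 2):
        a, b = assignment.barcode[genes[i]], assignment.barcode[genes[j]]
        union = a | b
        if not union:
            vals[i, j] = vals[j, i] = np.nan
            if not empty_warned:
                warnings.warn("pairs of empty barcodes are missing")
                empty_warned = True
        else:
            vals[i, j] = vals[j, i] = len(a & b) / len(union)
    for i, g in enumerate(genes):
        if not assignment.barcode[g]:
            vals[i, i] = np.nan
    return PairMatrix(genes, vals, measure="jaccard", kind="similarity")


def genomic_distance(annotation: pd.DataFrame, gene_ids: list[str]) -> PairMatrix:
    """|midpoint difference| between genes on the same scaffold (midpoint =
    (start + end) / 2); cross-scaffold pairs are not measured (missing)."""
    ann = annotation.set_index("gene_id")
    missing = [g for g in gene_ids if g not in ann.index]
    if missing:
        raise KeyError(f"genes not in annotation: {missing}")
    mids, scafs = {}, {}
    for g in gene_ids:
        row = ann.loc[g]
        start, end = int(row["start"]), int(row["end"])
        if start > end:
            raise ValueError(f"gene {g}: start > end")
        mids[g] = (start + end) / 2.0
        scafs[g] = row["scaffold"]
    n = len(gene_ids)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        gi, gj = gene_ids[i], gene_ids[j]
        if scafs[gi] != scafs[gj]:
            vals[i, j] = vals[j, i] = np.nan
        else:
            vals[i, j] = vals[j, i] = abs(mids[gi] - mids[gj])
    return PairMatrix(list(gene_ids), vals, measure="genomic_distance", kind="distance")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n_pairs: int
    mantel_p: float | None = None
    n_permutations: int = 0


def matrix_correlation(
    a: PairMatrix, b: PairMatrix, n_permutations: int = 0, seed: int = 0
) -> CorrelationResult:
    """Pearson correlation of the upper triangles of two pairwise matrices
    over the shared labels, with pairwise deletion of missing entries.

    The parametric p treats pairs as independent (as the source analyses
    do); with ``n_permutations`` > 0 a Mantel-style permutation p is added:
    rows/columns of ``b`` are jointly permuted and p = (1 + #{|R_perm| >=
    |R_obs|}) / (1 + n_permutations)."""
    shared = [l for l in a.labels if l in set(b.labels)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared labels")
    A = a.reindex(shared).values
    B = b.reindex(shared).values
    iu, ju = np.triu_indices(len(shared), k=1)
    av, bv = A[iu, ju], B[iu, ju]
    ok = np.isfinite(av) & np.isfinite(bv)
    n_pairs = int(ok.sum())
    if n_pairs < 3:
        raise ValueError("fewer than 3 complete pairs")
    r, p = scipy.stats.pearsonr(av[ok], bv[ok])

    mantel_p = None
    if n_permutations > 0:
        rng = substream(seed, "mantel")
        n = len(shared)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            Bp = B[np.ix_(perm, perm)]
            bpv = Bp[iu, ju]
            okp = np.isfinite(av) & np.isfinite(bpv)
            if okp.sum() < 3:
                continue
            rp = _pearson(av[okp], bpv[okp])
            if abs(rp) >= abs(r) - 1e-15:
                count += 1
        mantel_p = (1 + count) / (1 + n_permutations)
    return CorrelationResult(float(r), float(p), n_pairs, mantel_p, n_permutations)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc @ yc) / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# GRN assembly and centralities


def build_grn(
    assignment: RegulatoryAssignment, ppi_edges: list[tuple[str, str]] | None = None
) -> nx.MultiDiGraph:
    """Typed graph: one directed TF->toxin edge per candidate pair (with
    tfbs_count and importance weight), plus undirected TF-TF protein links
    (stored once with kind='ppi') kept only when both endpoints are
    candidate TFs. Isolated toxins are retained."""
    g = nx.MultiDiGraph()
    candidate_tfs: set[str] = set()
    for toxin in sorted(assignment.barcode):
        g.add_node(toxin, kind="toxin")
        for tf in sorted(assignment.barcode[toxin]):
            candidate_tfs.add(tf)
    for tf in sorted(candidate_tfs):
        g.add_node(tf, kind="tf")
    for toxin in sorted(assignment.barcode):
        for tf in sorted(assignment.barcode[toxin]):
            w = None
            if assignment.weights is not None and tf in assignment.weights.index \
                    and toxin in assignment.weights.columns:
                w = float(assignment.weights.loc[tf, toxin])
            g.add_edge(tf, toxin, kind="regulation",
                       tfbs_count=assignment.hit_counts[(toxin, tf)], weight=w)
    for edge in ppi_edges or []:
        if len(edge) != 2:
            raise ValueError(f"malformed protein link: {edge!r}")
        u, v = edge
        if u == v:
            continue
        if u in candidate_tfs and v in candidate_tfs:
            g.add_edge(*sorted((u, v)), kind="ppi")
    return g


def read_ppi_edges(path) -> list[tuple[str, str]]:
    """Two-column TSV of protein-protein links."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"malformed protein link at line {ln}")
            edges.append((parts[0], parts[1]))
    return edges


def centralities(graph: nx.MultiDiGraph) -> pd.DataFrame:
    """Degree, in-degree, out-degree (protein links count toward degree
    only) and unnormalized betweenness, with directed regulation edges kept
    directed and protein links walkable both ways."""
    nodes = sorted(graph.nodes)
    in_deg = {n: 0 for n in nodes}
    out_deg = {n: 0 for n in nodes}
    undirected = {n: 0 for n in nodes}
    walk = nx.DiGraph()
    walk.add_nodes_from(nodes)
    for u, v, data in graph.edges(data=True):
        if data.get("kind") == "ppi":
            undirected[u] += 1
            undirected[v] += 1
            walk.add_edge(u, v)
            walk.add_edge(v, u)
        else:
            out_deg[u] += 1
            in_deg[v] += 1
            walk.add_edge(u, v)
    btw = nx.betweenness_centrality(walk, normalized=False)
    return pd.DataFrame(
        {
            "degree": [in_deg[n] + out_deg[n] + undirected[n] for n in nodes],
            "in_degree": [in_deg[n] for n in nodes],
            "out_degree": [out_deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
        },
        index=nodes,
    )
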