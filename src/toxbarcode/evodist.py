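"""Sequence distances, neighbor-joining trees and patristic distances.

Distances use pairwise deletion (a site counts for a pair only when neither
sequence has a gap there). The JC69 correction d = -3/4 ln(1 - 4p/3) is
undefined at p >= 3/4; such pairs become missing with a warning. The NJ
implementation breaks Q-criterion ties by the lexicographically smallest
label pair (internal nodes carry the smallest leaf label beneath them), so
equidistant inputs yield a deterministic tree, and it recovers additive
matrices exactly. Patristic distances can also be taken from an externally
supplied Newick tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Phylo.BaseTree import Clade, Tree

__all__ = [
    "DistanceMatrix",
    "pairwise_distance",
    "neighbor_joining",
    "patristic",
]

_GAPS = set("-.")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, NaN = missing

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if n and not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu, ju = np.triu_indices(len(self.labels), k=1)
        return self.values[iu, ju]


def _read_aligned(source) -> dict[str, str]:
    if isinstance(source, dict):
        return source
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}


def pairwise_distance(aligned, model: str = "p") -> DistanceMatrix:
    """p-distance or JC69 distance over an aligned FASTA (path) or
    {name: sequence} dict; pairwise gap deletion."""
    seqs = _read_aligned(aligned)
    if model not in ("p", "jc69"):
        raise ValueError("model must be 'p' or 'jc69'")
    names = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("aligned sequences must all have the same length")
    arrs = {n: np.frombuffer(seqs[n].upper().encode(), dtype="S1") for n in names}
    gap = {n: np.isin(arrs[n], [b"-", b"."]) for n in names}
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[names[i]] | gap[names[j]])
            sites = int(ok.sum())
            if sites == 0:
                d[i, j] = d[j, i] = np.nan
                warnings.warn(f"no comparable sites for {names[i]} vs {names[j]}")
                continue
            p = float((arrs[names[i]][ok] != arrs[names[j]][ok]).mean())
            if model == "p":
                d[i, j] = d[j, i] = p
            else:
                if p >= 0.75:
                    warnings.warn(f"JC69 undefined at p={p:.3f} for {names[i]} vs {names[j]}")
                    d[i, j] = d[j, i] = np.nan
                else:
                    d[i, j] = d[j, i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic lexicographic
    tie-breaking; negative branch lengths are clamped to 0 with a warning.
    Returns an unrooted tree represented with a trifurcating root."""
    if np.isnan(dm.values).any():
        raise ValueError("neighbor joining requires a complete distance matrix")
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("need at least 3 taxa")

    # active nodes: sort key = smallest leaf label beneath the node
    nodes: list[Clade] = [Clade(name=l) for l in dm.labels]
    keys: list[str] = list(dm.labels)
    D = dm.values.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative branch length {x:.3g} clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in zip(*np.nonzero(np.isclose(Q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, i, j = min(cands)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = clamp(li)
        child_j.branch_length = clamp(lj)
        new = Clade(clades=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        # shrink matrix: drop i and j, append new node
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # join the final three nodes at a trifurcating root
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.branch_length = clamp(0.5 * (dab + dac - dbc))
    b.branch_length = clamp(0.5 * (dab + dbc - dac))
    c.branch_length = clamp(0.5 * (dac + dbc - dab))
    order = np.argsort(keys, kind="stable")
    root = Clade(clades=[nodes[k] for k in order])
    return Tree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# Patristic distances


def patristic(tree: Tree) -> DistanceMatrix:
    """Sum of branch lengths along the unique path between each leaf pair."""
    leaves = tree.get_terminals()
    names = [l.name for l in leaves]
    if len(set(names)) != len(names):
        raise ValueError("leaf labels must be unique")
    # root-to-node depth and parent maps via one traversal
    depth: dict[int, float] = {id(tree.root): 0.0}
    parent: dict[int, Clade] = {}
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for ch in node.clades:
            bl = ch.branch_length or 0.0
            depth[id(ch)] = depth[id(node)] + bl
            parent[id(ch)] = node
            stack.append(ch)

    def path_to_root(node: Clade) -> list[Clade]:
        path = [node]
        while id(node) in parent:
            node = parent[id(node)]
            path.append(node)
        return path

    paths = {l.name: path_to_root(l) for l in leaves}
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        anc_i = {id(x) for x in paths[names[i]]}
        for j in range(i + 1, n):
            lca = next(x for x in paths[names[j]] if id(x) in anc_i)
            dij = depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * depth[id(lca)]
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(names, d)
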