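"""Weighted co-expression module detection on toxin cells.

The procedure follows the standard weighted-network recipe: raise the
(absolute or signed-shifted) gene-gene correlation to a soft power chosen
for approximate scale-free topology, convert adjacency to topological
overlap, cluster genes by average linkage on 1 - TOM, cut at a fixed
height, drop clusters below the minimum module size, summarize each module
by its eigengene (first principal component), and merge modules whose
eigengene dissimilarity falls below the merge threshold (default 0.2, i.e.
eigengene correlation above 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

__all__ = [
    "CoexprParams",
    "SoftThresholdReport",
    "ModulePartition",
    "pick_soft_threshold",
    "adjacency",
    "tom",
    "detect_modules",
    "eigengenes_and_membership",
    "merge_modules",
    "module_trait_correlation",
]

UNASSIGNED = "unassigned"


@dataclass
class CoexprParams:
    powers_tested: tuple[int, ...] = tuple(range(1, 21))
    target_scale_free_r2: float = 0.8
    signed: bool = False
    min_module_size: int = 30
    merge_dissimilarity: float = 0.2
    cut_height: float = 0.99
    n_bins: int = 10

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.powers_tested):
            raise ValueError("powers must be >= 1")
        if not (0 < self.target_scale_free_r2 <= 1):
            raise ValueError("target R^2 must be in (0, 1]")
        if not (0 < self.merge_dissimilarity <= 1):
            raise ValueError("merge threshold must be in (0, 1]")


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame  # power, r2, mean_connectivity
    chosen_power: int


@dataclass
class ModulePartition:
    assignment: pd.Series  # gene -> module label (UNASSIGNED allowed)
    eigengenes: pd.DataFrame | None = None  # modules x samples
    kme: pd.DataFrame | None = None  # genes x modules

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.assignment) - {UNASSIGNED},
                      key=lambda m: (-int((self.assignment == m).sum()), m))

    def sizes(self) -> pd.Series:
        return self.assignment[self.assignment != UNASSIGNED].value_counts()


def _corr(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation over samples; constant genes get 0
    correlation with everything (with a warning)."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    const = sd <= 1e-10 * (np.abs(x).mean(axis=1) + 1.0)
    if const.any():
        warnings.warn(f"{const.sum()} constant gene(s): correlations treated as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 1.0)
    c[const, :] = 0.0
    c[:, const] = 0.0
    return np.clip(c, -1.0, 1.0)


def adjacency(expr: pd.DataFrame, beta: float, signed: bool = False) -> pd.DataFrame:
    """Unsigned: |cor|^beta; signed: ((1+cor)/2)^beta. Zero diagonal (the
    convention used for connectivity sums)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    c = _corr(expr)
    a = ((1 + c) / 2) ** beta if signed else np.abs(c) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def _scale_free_r2(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Fit log10 p(k) ~ log10 k over equal-occupancy bins of connectivity;
    returns (R^2, slope). R^2 is reported as 0 when the slope is positive."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    counts, edges = np.histogram(k, bins=n_bins)  # equal-width bins of k
    mids = np.array(
        [
            k[(k >= edges[i]) & (k < edges[i + 1] if i < n_bins - 1 else k <= edges[i + 1])].mean()
            if counts[i]
            else np.nan
            for i in range(n_bins)
        ]
    )
    ok = counts > 0
    x = np.log10(mids[ok])
    y = np.log10(counts[ok] / k.size)
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0, 0.0
    slope, _, r, _, _ = scipy.stats.linregress(x, y)
    r2 = 0.0 if slope > 0 else float(r**2)
    return r2, float(slope)


def pick_soft_threshold(expr: pd.DataFrame, params: CoexprParams = CoexprParams()) -> SoftThresholdReport:
    """For each candidate power compute the scale-free fit R^2 and mean
    connectivity; choose the smallest power reaching the target R^2, else
    the argmax R^2 with a warning."""
    if (expr.to_numpy().std(axis=1) == 0).all():
        raise ValueError("expression matrix is constant")
    c = _corr(expr)
    np.fill_diagonal(c, 0.0)
    rows = []
    for p in params.powers_tested:
        a = ((1 + c) / 2) ** p if params.signed else np.abs(c) ** p
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = _scale_free_r2(k, params.n_bins)
        rows.append((p, r2, slope, k.mean()))
    table = pd.DataFrame(rows, columns=["power", "r2", "slope", "mean_connectivity"])
    reaching = table[table.r2 >= params.target_scale_free_r2]
    if len(reaching):
        chosen = int(reaching.power.iloc[0])
    else:
        chosen = int(table.power.iloc[table.r2.idxmax()])
        warnings.warn(
            f"no power reached scale-free R^2 {params.target_scale_free_r2}; "
            f"using argmax power {chosen}"
        )
    return SoftThresholdReport(table, chosen)


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij); TOM_ii = 1."""
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + a) / (kmin + 1.0 - a)
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def detect_modules(tom_matrix: pd.DataFrame, params: CoexprParams = CoexprParams()) -> ModulePartition:
    """Average-linkage clustering on 1 - TOM, fixed-height cut, size filter.
    Labels "M1", "M2", ... ordered by decreasing size."""
    genes = list(tom_matrix.index)
    n = len(genes)
    if n < params.min_module_size:
        warnings.warn("fewer genes than the minimum module size; all unassigned")
        return ModulePartition(pd.Series(UNASSIGNED, index=genes, name="module"))
    d = 1.0 - tom_matrix.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    link = scipy.cluster.hierarchy.linkage(scipy.spatial.distance.squareform(d, checks=False),
                                           method="average")
    raw = scipy.cluster.hierarchy.fcluster(link, t=params.cut_height, criterion="distance")
    assignment = pd.Series(UNASSIGNED, index=genes, name="module", dtype=object)
    sizes = pd.Series(raw).value_counts()
    big = [cl for cl in sizes.index if sizes[cl] >= params.min_module_size]
    big.sort(key=lambda cl: (-sizes[cl], cl))
    for rank, cl in enumerate(big, start=1):
        assignment.iloc[np.where(raw == cl)[0]] = f"M{rank}"
    return ModulePartition(assignment)


def eigengenes_and_membership(expr: pd.DataFrame, partition: ModulePartition) -> ModulePartition:
    """Eigengene = first principal component of the module's standardized
    expression, sign-oriented to correlate positively with the module mean;
    kME_gm = Pearson correlation of gene g with eigengene m. Eigengene
    sample vectors are scaled to unit variance."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples for eigengenes")
    modules = partition.modules
    eigs = {}
    for m in modules:
        genes = partition.assignment.index[partition.assignment == m]
        sub = expr.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        e = e / e.std() if e.std() > 0 else e
        eigs[m] = e
    eigengenes = pd.DataFrame(eigs, index=expr.columns).T
    x = expr.to_numpy(dtype=float)
    kme = np.zeros((expr.shape[0], len(modules)))
    for j, m in enumerate(modules):
        e = eigengenes.loc[m].to_numpy()
        ec = e - e.mean()
        xc = x - x.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (ec**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            kme[:, j] = (xc @ ec) / denom
    kme_df = pd.DataFrame(kme, index=expr.index, columns=modules)
    return ModulePartition(partition.assignment.copy(), eigengenes, kme_df)


def merge_modules(
    expr: pd.DataFrame, partition: ModulePartition, merge_dissimilarity: float = 0.2
) -> ModulePartition:
    """Iteratively merge the closest module pair with eigengene
    dissimilarity (1 - cor) below the threshold, recomputing eigengenes
    after each merge, until no pair qualifies."""
    part = eigengenes_and_membership(expr, partition)
    while True:
        mods = part.modules
        if len(mods) < 2:
            return part
        E = part.eigengenes.loc[mods].to_numpy()
        c = np.corrcoef(E)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if 1.0 - c[i, j] >= merge_dissimilarity:
            return part
        keep, drop = sorted([mods[i], mods[j]], key=lambda m: int(m[1:]))
        assignment = part.assignment.copy()
        assignment[assignment == drop] = keep
        part = eigengenes_and_membership(expr, ModulePartition(assignment))


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Pearson R of each eigengene with a per-sample trait, with the
    Student-t p-value (df = n - 2)."""
    trait = trait.reindex(eigengenes.columns)
    t = trait.to_numpy(dtype=float)
    if np.std(t) == 0:
        raise ValueError("trait has zero variance")
    rows = []
    for m in eigengenes.index:
        r, p = scipy.stats.pearsonr(eigengenes.loc[m].to_numpy(), t)
        rows.append((m, float(r), float(p)))
    return pd.DataFrame(rows, columns=["module", "r", "p"]).set_index("module")
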