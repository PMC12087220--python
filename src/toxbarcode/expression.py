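"""Single-cell QC, pseudo-bulk construction, TMM normalization, the
clr/orthogonal-residual expression-divergence test, clustering, toxin-cell
classification, and Spearman co-expression.

The divergence test compares the composition of a pseudo-bulk (per-gene sum
over cells) against a matched bulk library: both are centered-log-ratio
transformed, a total-least-squares line is fitted through the non-toxin
genes, and a toxin is flagged as divergent when its signed orthogonal
residual falls outside the central interval (default 99%) of the non-toxin
residual distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._rng import child_seed
from .containers import CountMatrix, PairMatrix

__all__ = [
    "QcParams",
    "DivergenceReport",
    "CellAnnotation",
    "filter_cells",
    "pseudobulk",
    "tmm_factors",
    "pseudobulk_and_normalize",
    "clr",
    "clr_divergence",
    "cluster_cells",
    "classify_toxin_cells",
    "spearman_coexpression",
]


@dataclass
class QcParams:
    min_counts: int = 1000
    min_genes: int = 100

    def __post_init__(self) -> None:
        if self.min_counts < 0 or self.min_genes < 0:
            raise ValueError("QC thresholds must be >= 0")


def filter_cells(counts: CountMatrix, qc: QcParams = QcParams()) -> CountMatrix:
    """Keep cells with total counts >= min_counts AND distinct expressed
    genes >= min_genes ("at least" is inclusive). Idempotent."""
    if counts.sample_kind != "cell":
        raise ValueError("filter_cells expects a cell matrix")
    totals = counts.values.sum(axis=0)
    n_genes = (counts.values > 0).sum(axis=0)
    keep = (totals >= qc.min_counts) & (n_genes >= qc.min_genes)
    kept = [s for s, k in zip(counts.sample_ids, keep) if k]
    if not kept:
        warnings.warn("QC removed every cell")
    out = CountMatrix(counts.values[:, keep], counts.gene_ids, kept, "cell")
    return out


# ---------------------------------------------------------------------------
# Pseudo-bulk and TMM


def pseudobulk(cell_counts: CountMatrix, name: str = "pseudo_bulk") -> CountMatrix:
    """Per-gene sum over all cells, as a one-sample bulk matrix."""
    vals = cell_counts.values.sum(axis=1, keepdims=True)
    return CountMatrix(vals, cell_counts.gene_ids, [name], "bulk")


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Two-library TMM factor (edgeR's calcFactorTMM): 30% two-sided trim on
    M values, 5% on A values, precision-weighted mean of the retained M."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logR = np.log2((obs / lib_obs) / (ref / lib_ref))
        absE = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2
        v = (lib_obs - obs) / lib_obs / obs + (lib_ref - ref) / lib_ref / ref
    fin = np.isfinite(logR) & np.isfinite(absE) & (absE > -1e10)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    loL = np.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rR = scipy.stats.rankdata(logR)
    rS = scipy.stats.rankdata(absE)
    keep = (rR >= loL) & (rR <= hiL) & (rS >= loS) & (rS <= hiS)
    if not keep.any():
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors for a genes x samples
    count table; rescaled so their geometric mean is 1."""
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    for j, l in enumerate(lib):
        if l == 0:
            raise ValueError(f"library {counts.columns[j]!r} has zero total counts")
    # reference: sample whose 75th-percentile count fraction is closest to the mean
    with np.errstate(divide="ignore"):
        f75 = np.array([np.quantile(x[:, j], 0.75) / lib[j] for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [_tmm_pair_factor(x[:, j], x[:, ref], lib[j], lib[ref]) for j in range(x.shape[1])]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def pseudobulk_and_normalize(
    cell_counts: CountMatrix, bulk_counts: CountMatrix
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum cells into a pseudo-bulk, pool it with the bulk libraries, compute
    TMM factors across the pooled table and return effective-library CPM."""
    if cell_counts.gene_ids != bulk_counts.gene_ids:
        raise ValueError("cell and bulk matrices must share the gene index")
    pb = pseudobulk(cell_counts)
    table = pd.concat([pb.to_frame(), bulk_counts.to_frame()], axis=1)
    factors = tmm_factors(table)
    lib = table.sum(axis=0)
    cpm = table / (lib * factors) * 1e6
    return cpm, factors


# ---------------------------------------------------------------------------
# clr divergence


def clr(x: np.ndarray, pseudo: float | None = None) -> np.ndarray:
    """Centered log-ratio: ln(x_g) - mean_g ln(x). Zeros are lifted by a
    pseudo-value (default: half the smallest nonzero entry)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("clr requires non-negative input")
    if pseudo is None:
        nz = x[x > 0]
        if nz.size == 0:
            raise ValueError("clr of an all-zero vector is undefined")
        pseudo = nz.min() / 2.0
    y = np.log(np.where(x > 0, x, pseudo) if pseudo else x)
    return y - y.mean()


@dataclass
class DivergenceReport:
    gene_ids: list[str]
    clr_pseudobulk: np.ndarray
    clr_bulk: np.ndarray
    fit_slope: float
    fit_intercept: float
    residuals: np.ndarray
    interval: tuple[float, float]
    flags: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "clr_bulk": self.clr_bulk,
                "clr_pseudobulk": self.clr_pseudobulk,
                "residual": self.residuals,
            }
        )
        df["flagged"] = [self.flags.get(g, False) for g in self.gene_ids]
        return df


def _tls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Total-least-squares line through (x, y): first principal axis of the
    centered cloud. Returns slope, intercept and the unit direction."""
    mx, my = x.mean(), y.mean()
    cov = np.cov(np.vstack([x - mx, y - my]))
    w, v = np.linalg.eigh(cov)
    d = v[:, np.argmax(w)]
    if d[0] < 0:
        d = -d
    if abs(d[0]) < 1e-12:
        raise ValueError("total-least-squares line is vertical")
    slope = d[1] / d[0]
    intercept = my - slope * mx
    return slope, intercept, np.array([mx, my]), d


def clr_divergence(
    pseudo: pd.Series,
    bulk: pd.Series,
    toxin_ids: list[str],
    percentile: float = 99.0,
    pseudo_value: float | None = None,
) -> DivergenceReport:
    """Flag toxins whose clr expression diverges between pseudo-bulk and
    bulk beyond the central ``percentile`` interval of non-toxin orthogonal
    residuals."""
    if not pseudo.index.equals(bulk.index):
        raise ValueError("pseudo and bulk must share the gene index")
    genes = list(pseudo.index)
    toxin_set = set(toxin_ids)
    unknown = toxin_set - set(genes)
    if unknown:
        raise KeyError(f"toxin ids not in gene index: {sorted(unknown)}")
    non_toxin = np.array([g not in toxin_set for g in genes])
    if non_toxin.sum() < 10:
        raise ValueError("need at least 10 non-toxin genes to build the null")

    cp = clr(pseudo.to_numpy(), pseudo_value)
    cb = clr(bulk.to_numpy(), pseudo_value)
    slope, intercept, center, d = _tls_line(cb[non_toxin], cp[non_toxin])
    # signed orthogonal distance: positive above the line
    normal = np.array([-d[1], d[0]])
    if normal[1] < 0:
        normal = -normal
    pts = np.vstack([cb, cp]).T - center
    residuals = pts @ normal

    tail = (100.0 - percentile) / 2.0
    lo, hi = np.percentile(residuals[non_toxin], [tail, 100.0 - tail])
    flags = {
        g: bool(residuals[i] < lo or residuals[i] > hi)
        for i, g in enumerate(genes)
        if g in toxin_set
    }
    return DivergenceReport(genes, cp, cb, slope, intercept, residuals, (float(lo), float(hi)), flags)


# ---------------------------------------------------------------------------
# Clustering and toxin-cell classification


def log1p_cpm(counts: CountMatrix) -> pd.DataFrame:
    """log(1 + counts-per-million) per sample; all-zero samples stay zero."""
    lib = counts.values.sum(axis=0).astype(float)
    lib[lib == 0] = 1.0
    cpm = counts.values / lib * 1e6
    return pd.DataFrame(np.log1p(cpm), index=counts.gene_ids, columns=counts.sample_ids)


def cluster_cells(
    counts: CountMatrix,
    n_pcs: int = 30,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """log1p-CPM -> PCA -> kNN graph -> modularity community detection
    (Leiden); labels 0..K-1 ordered by decreasing community size."""
    if counts.n_samples < 2:
        raise ValueError("need at least 2 cells to cluster")
    if k_neighbors >= counts.n_samples:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    expr = log1p_cpm(counts).to_numpy().T  # cells x genes
    expr = expr - expr.mean(axis=0)
    if np.allclose(expr, 0.0):  # all cells identical: one community
        return pd.Series(0, index=counts.sample_ids, name="cluster")
    n_comp = int(min(n_pcs, expr.shape[0] - 1, expr.shape[1]))
    if n_comp >= 1 and expr.std() > 0:
        pcs = PCA(n_components=n_comp, svd_solver="full", random_state=0).fit_transform(expr)
    else:
        pcs = expr
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=counts.n_samples, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=child_seed(seed, "leiden"),
        n_iterations=-1,
    )
    labels = np.array(part.membership)
    order = np.argsort(-np.bincount(labels), kind="stable")
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    return pd.Series(labels, index=counts.sample_ids, name="cluster")


@dataclass
class CellAnnotation:
    cluster: pd.Series
    is_toxin_cell: pd.Series
    toxin_fraction: pd.Series
    marker_score: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.cluster,
                "is_toxin_cell": self.is_toxin_cell,
                "toxin_fraction": self.toxin_fraction,
                "marker_score": self.marker_score,
            }
        )


def classify_toxin_cells(
    counts: CountMatrix,
    clusters: pd.Series,
    marker_ids: list[str],
    toxin_ids: list[str],
    min_cluster_toxin_fraction: float = 0.2,
    min_marker_detect_fraction: float = 0.5,
) -> CellAnnotation:
    """A cluster is toxin-producing iff its mean per-cell toxin count
    fraction and its epithelial-marker detection rate both clear their
    thresholds; cells inherit the cluster call."""
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    missing = [g for g in list(marker_ids) + list(toxin_ids) if g not in gene_pos]
    if missing:
        raise KeyError(f"ids not in gene index: {missing}")
    tox_idx = [gene_pos[g] for g in toxin_ids]
    mk_idx = [gene_pos[g] for g in marker_ids]
    totals = counts.values.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    toxin_fraction = pd.Series(
        counts.values[tox_idx].sum(axis=0) / totals, index=counts.sample_ids
    )
    marker_detected = (counts.values[mk_idx] > 0).any(axis=0)
    expr = log1p_cpm(counts)
    marker_score = pd.Series(expr.iloc[mk_idx].mean(axis=0), index=counts.sample_ids)

    clusters = clusters.reindex(counts.sample_ids)
    is_toxin = pd.Series(False, index=counts.sample_ids)
    for cl, members in clusters.groupby(clusters).groups.items():
        mask = clusters.index.isin(members)
        mean_frac = toxin_fraction[mask].mean()
        detect = marker_detected[mask].mean()
        if mean_frac >= min_cluster_toxin_fraction and detect >= min_marker_detect_fraction:
            is_toxin[mask] = True
    return CellAnnotation(clusters, is_toxin, toxin_fraction, marker_score)


# ---------------------------------------------------------------------------
# Spearman co-expression


def spearman_coexpression(counts: CountMatrix, gene_ids: list[str]) -> PairMatrix:
    """Pairwise Spearman rank correlation (average ranks for ties) of
    log1p-CPM across cells; constant genes yield missing rows/columns."""
    if counts.n_samples < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    expr = log1p_cpm(counts)
    sub = expr.loc[list(gene_ids)].to_numpy()
    const = sub.std(axis=1) <= 1e-10 * (np.abs(sub).mean(axis=1) + 1.0)
    if const.any():
        bad = [g for g, c in zip(gene_ids, const) if c]
        warnings.warn(f"constant genes have undefined correlation: {bad}")
    ranks = scipy.stats.rankdata(sub, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    return PairMatrix(list(gene_ids), rho, measure="spearman_coexpression", kind="similarity")
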