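"""Promoter extraction, PWM motif scanning, candidate-TF calling (the
regulatory "barcode"), and tree-ensemble TF->gene importance weights.

The scanner mirrors the standard log-odds PWM with a background-distributed
pseudocount; a window is reported when its score reaches a configurable
fraction of the motif's maximum attainable score (a "deficit" threshold,
default 0.15, i.e. score_fraction 0.85). The importance network is a
GENIE3-style randomized-forest regression of each target on the TF
expression profiles, with per-target importances normalized to sum 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from sklearn.ensemble import RandomForestRegressor

from ._rng import child_seed
from .containers import Pfm

__all__ = [
    "PromoterSet",
    "ScanParams",
    "TfbsHit",
    "RegulatoryAssignment",
    "extract_promoters",
    "pwm_scan",
    "log_odds_matrix",
    "call_candidate_tfs",
    "importance_network",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class PromoterRecord:
    sequence: str
    scaffold: str
    start: int  # 1-based inclusive genomic span of the promoter
    end: int
    strand: str


@dataclass
class PromoterSet:
    promoters: dict[str, PromoterRecord]

    def __getitem__(self, gene: str) -> PromoterRecord:
        return self.promoters[gene]

    def __iter__(self):
        return iter(self.promoters)

    def __len__(self) -> int:
        return len(self.promoters)

    def sequences(self) -> dict[str, str]:
        return {g: r.sequence for g, r in self.promoters.items()}


def extract_promoters(
    genome: dict[str, str], annotation: pd.DataFrame, promoter_len: int = 500,
    classes: tuple[str, ...] = ("toxin",),
) -> PromoterSet:
    """The ``promoter_len`` bases upstream of the TSS (1-based inclusive):
    plus strand [tss-L, tss-1]; minus strand the reverse complement of
    [tss+1, tss+L]. Clamped at scaffold edges with a warning."""
    out: dict[str, PromoterRecord] = {}
    for _, row in annotation.iterrows():
        if str(row["class"]) not in classes:
            continue
        gene, scaf, tss, strand = row["gene_id"], row["scaffold"], int(row["tss"]), row["strand"]
        if scaf not in genome:
            raise KeyError(f"gene {gene}: scaffold {scaf!r} not in genome")
        seq = genome[scaf]
        if not 1 <= tss <= len(seq):
            raise ValueError(f"gene {gene}: TSS {tss} outside scaffold {scaf} (len {len(seq)})")
        if strand == "+":
            start, end = tss - promoter_len, tss - 1
        elif strand == "-":
            start, end = tss + 1, tss + promoter_len
        else:
            raise ValueError(f"gene {gene}: strand must be '+' or '-', got {strand!r}")
        cstart, cend = max(start, 1), min(end, len(seq))
        if (cstart, cend) != (start, end):
            warnings.warn(f"gene {gene}: promoter clamped to scaffold bounds")
        sub = seq[cstart - 1 : cend].upper()
        if strand == "-":
            sub = str(Seq(sub).reverse_complement())
        out[gene] = PromoterRecord(sub, scaf, cstart, cend, strand)
    return PromoterSet(out)


# ---------------------------------------------------------------------------
# Scanning


@dataclass
class ScanParams:
    pseudocount: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    score_fraction: float = 0.85
    both_strands: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-8:
            raise ValueError("background must sum to 1")
        if not 0 < self.score_fraction <= 1:
            raise ValueError("score_fraction must be in (0, 1]")


@dataclass
class TfbsHit:
    tf_id: str
    gene_id: str
    offset: int  # 0-based within the promoter
    strand: str
    score: float  # log2-odds bits


def log_odds_matrix(pfm: Pfm, params: ScanParams = ScanParams()) -> np.ndarray:
    """PWM_b,i = log2( (count + pseudocount*bg_b) / (column total +
    pseudocount) / bg_b ), with a fifth zero row so N scores 0."""
    bg = np.asarray(params.background)[:, None]
    col_tot = pfm.counts.sum(axis=0, keepdims=True)
    pwm = np.log2((pfm.counts + params.pseudocount * bg) / (col_tot + params.pseudocount) / bg)
    return np.vstack([pwm, np.zeros((1, pfm.length))])


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.intp)


def pwm_scan(
    promoters: PromoterSet | dict[str, str],
    pfms: list[Pfm],
    params: ScanParams = ScanParams(),
) -> list[TfbsHit]:
    """Score every window on the forward (and optionally reverse) strand;
    report those reaching score_fraction x the maximum attainable score.
    Reverse-strand offsets index the forward sequence position of the
    window start."""
    seqs = promoters.sequences() if isinstance(promoters, PromoterSet) else promoters
    hits: list[TfbsHit] = []
    for pfm in pfms:
        pwm = log_odds_matrix(pfm, params)
        max_score = pwm[:4].max(axis=0).sum()
        threshold = params.score_fraction * max_score
        L = pfm.length
        for gene, seq in seqs.items():
            if L > len(seq):
                warnings.warn(f"motif {pfm.name} longer than promoter of {gene}; skipped")
                continue
            enc = _encode(seq)
            windows = np.lib.stride_tricks.sliding_window_view(enc, L)
            cols = np.arange(L)
            fwd = pwm[windows, cols].sum(axis=1)
            for off in np.nonzero(fwd >= threshold - 1e-12)[0]:
                hits.append(TfbsHit(pfm.name, gene, int(off), "+", float(fwd[off])))
            if params.both_strands:
                # complement (3 - code; N stays N) and reverse the motif
                comp = np.where(windows == 4, 4, 3 - windows)
                rev = pwm[comp[:, ::-1], cols].sum(axis=1)
                for off in np.nonzero(rev >= threshold - 1e-12)[0]:
                    hits.append(TfbsHit(pfm.name, gene, int(off), "-", float(rev[off])))
    return hits


# ---------------------------------------------------------------------------
# Candidate calling and importances


@dataclass
class RegulatoryAssignment:
    """Per toxin gene: its candidate-TF set (the "barcode"), per-pair
    binding-site counts, and TF->gene importance weights."""

    barcode: dict[str, set[str]]
    hit_counts: dict[tuple[str, str], int]  # (gene, tf) -> n sites
    weights: pd.DataFrame | None = None  # TFs x genes importances

    def validate(self) -> None:
        for gene, tfs in self.barcode.items():
            for tf in tfs:
                if self.hit_counts.get((gene, tf), 0) < 1:
                    raise ValueError(f"barcode pair ({gene}, {tf}) has no binding site")
        if self.weights is not None and (self.weights.to_numpy() < 0).any():
            raise ValueError("importance weights must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, tf, self.hit_counts[(g, tf)]) for g in sorted(self.barcode)
            for tf in sorted(self.barcode[g])
        ]
        return pd.DataFrame(rows, columns=["gene_id", "tf", "n_sites"])


def call_candidate_tfs(
    module_tf_ids: list[str], hits: list[TfbsHit], toxin_ids: list[str]
) -> RegulatoryAssignment:
    """Candidate (TF, toxin) pairs: TF is in the toxin-module TF set AND has
    at least one binding site in that toxin's promoter."""
    module_set = set(module_tf_ids)
    if not module_set:
        warnings.warn("empty module TF set: empty assignment")
    toxin_set = set(toxin_ids)
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        if h.tf_id in module_set and h.gene_id in toxin_set:
            counts[(h.gene_id, h.tf_id)] = counts.get((h.gene_id, h.tf_id), 0) + 1
    barcode: dict[str, set[str]] = {g: set() for g in toxin_ids}
    for (g, tf) in counts:
        barcode[g].add(tf)
    asg = RegulatoryAssignment(barcode, counts)
    asg.validate()
    return asg


def importance_network(
    expr: pd.DataFrame,
    tf_ids: list[str],
    target_ids: list[str],
    n_trees: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GENIE3-style TF->target importances: per target, a random-forest
    regression on the TF profiles (sqrt feature subsampling); importances
    are the forest's variance-reduction shares, which sum to 1 whenever any
    split occurs. Returns a TFs x targets frame."""
    if expr.shape[1] < 10:
        raise ValueError("need at least 10 samples for the importance network")
    missing = [g for g in list(tf_ids) + list(target_ids) if g not in expr.index]
    if missing:
        raise KeyError(f"ids not in expression index: {missing}")
    weights = pd.DataFrame(0.0, index=list(tf_ids), columns=list(target_ids))
    for target in target_ids:
        predictors = [t for t in tf_ids if t != target]
        X = expr.loc[predictors].to_numpy(dtype=float).T
        y = expr.loc[target].to_numpy(dtype=float)
        if np.std(y) == 0:
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=child_seed(seed, f"rf:{target}"),
            n_jobs=1,
        )
        rf.fit(X, y)
        weights.loc[predictors, target] = rf.feature_importances_
    return weights
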