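"""Synthetic venom-gland world generator.

Builds self-contained fixtures with the statistical structure the analysis
assumes, so every downstream stage can be verified without the real genome,
single-cell or imaging data:

* a tandem toxin gene family evolved on one pure-birth tree for both
  promoter and coding sequence (two functional groups, neurotoxin-like "A"
  and cytotoxin-like "B");
* planted transcription-factor motif "barcodes" (shared + group-specific
  TFs) whose consensus sequences are stamped into the promoters;
* cell populations whose toxin counts are negative-binomial and driven by
  latent TF activities;
* gland sections with an anterior-posterior group gradient.

All randomness flows from one seed through named substreams, so adding a
component never perturbs the draws of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq

from . import io as tio
from ._rng import substream
from .containers import CountMatrix, Pfm

__all__ = [
    "FamilySimParams",
    "TruthRegulome",
    "CellSimParams",
    "Population",
    "SectionSimParams",
    "FamilySim",
    "simulate_family",
    "simulate_cells",
    "simulate_bulk",
    "simulate_sections",
    "write_fixture",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS]


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class FamilySimParams:
    """Stated world for the toxin gene family.

    Two functional groups by default, mirroring a neurotoxin-like clade with
    a rich specific TF repertoire and a cytotoxin-like clade with a smaller
    one, on top of a set of TFs shared by all family members.
    """

    n_genes: int = 24
    n_groups: int = 2
    birth_rate: float = 1.0
    stem_length: float = 1.0
    promoter_len: int = 500
    cds_len: int = 420
    subst_rate_promoter: float = 0.1
    subst_rate_cds: float = 0.1
    shared_tfs: tuple[str, ...] = ("TF-S1", "TF-S2", "TF-S3", "TF-S4")
    group_tfs: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "A": ("TF-A1", "TF-A2", "TF-A3", "TF-A4", "TF-A5", "TF-A6"),
            "B": ("TF-B1", "TF-B2", "TF-B3"),
        }
    )
    motif_gain_prob: float = 0.9
    motif_loss_prob: float = 0.05
    n_scaffolds: int = 2
    intergenic_gap: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not (1 <= self.n_groups <= self.n_genes):
            raise ValueError("n_groups must be in [1, n_genes]")
        for p in (self.motif_gain_prob, self.motif_loss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("motif probabilities must be in [0, 1]")
        for r in (self.birth_rate, self.subst_rate_promoter, self.subst_rate_cds):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.cds_len % 3:
            raise ValueError("cds_len must be a multiple of 3")
        groups = self.group_labels()
        for g in self.group_tfs:
            if g not in groups:
                raise ValueError(f"group_tfs references unknown group {g!r}")

    def group_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_groups)]

    def all_tfs(self) -> list[str]:
        out = list(self.shared_tfs)
        for g in self.group_labels():
            out.extend(self.group_tfs.get(g, ()))
        return out


@dataclass
class TruthRegulome:
    """Planted regulatory truth: which TF binds which promoter, and where."""

    planted_sets: dict[str, set[str]]
    motif_positions: dict[tuple[str, str], list[tuple[int, str]]]
    group_of: dict[str, str]
    tf_group: dict[str, str] = field(default_factory=dict)  # tf -> group label or "shared"

    def validate(self, promoter_len: int | None = None) -> None:
        for gene, tfs in self.planted_sets.items():
            if gene not in self.group_of:
                raise ValueError(f"gene {gene} has no group")
            for tf in tfs:
                if (gene, tf) not in self.motif_positions or not self.motif_positions[(gene, tf)]:
                    raise ValueError(f"planted pair ({gene}, {tf}) has no motif position")
        for (gene, tf), pos in self.motif_positions.items():
            if tf not in self.planted_sets.get(gene, set()):
                raise ValueError(f"position recorded for unplanted pair ({gene}, {tf})")
            if promoter_len is not None:
                for off, _ in pos:
                    if not 0 <= off < promoter_len:
                        raise ValueError(f"motif offset {off} outside promoter for {gene}/{tf}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.group_of)

    @property
    def tfs(self) -> list[str]:
        if self.tf_group:
            return sorted(self.tf_group)
        out: set[str] = set()
        for s in self.planted_sets.values():
            out |= s
        return sorted(out)


@dataclass
class Population:
    name: str
    fraction: float
    group_weights: dict[str, float]
    markers: tuple[str, ...] = ()


@dataclass
class CellSimParams:
    """Stated world for the single-cell experiment.

    Defaults emulate a gland in which roughly half the cells are secretory
    (split between the two toxin groups, both marked by the epithelial
    markers LAMA3/EPCAM) and the rest are non-secretory support cells.
    """

    n_cells: int = 600
    populations: tuple[Population, ...] | None = None
    depth_mean: float = 5000.0
    depth_log_sd: float = 0.3
    nb_dispersion: float = 0.3
    tf_activity_noise: float = 0.5
    leak_rate: float = 0.02
    n_background_genes: int = 200
    tf_expr_scale: float = 0.5
    marker_level: float = 2.0
    background_level: float = 0.05
    group_tf_weight: float = 3.0  # group-specific TFs dominate the toxin drive
    seed: int = 0

    def resolved_populations(self, groups: list[str]) -> tuple[Population, ...]:
        if self.populations is not None:
            return self.populations
        markers = ("LAMA3", "EPCAM")
        pops = []
        fracs = [0.3, 0.2] if len(groups) >= 2 else [0.5]
        for g, f in zip(groups, fracs):
            pops.append(Population(f"secretory_{g}", f, {h: (1.0 if h == g else 0.0) for h in groups}, markers))
        rest = 1.0 - sum(p.fraction for p in pops)
        pops.append(Population("non_secretory", rest, {g: 0.0 for g in groups}, ()))
        return tuple(pops)

    def validate(self, groups: list[str]) -> None:
        pops = self.resolved_populations(groups)
        if not pops:
            raise ValueError("populations must be non-empty")
        if abs(sum(p.fraction for p in pops) - 1.0) > 1e-8:
            raise ValueError("population fractions must sum to 1")
        if self.depth_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("depth_mean and nb_dispersion must be positive")
        for p in pops:
            for g in p.group_weights:
                if g not in groups:
                    raise ValueError(f"population {p.name} references unknown group {g!r}")


@dataclass
class SectionSimParams:
    """Stated world for the gland sections: a Gaussian anterior-posterior
    profile per toxin group over a gland-shaped mask."""

    grid_shape: tuple[int, int] = (40, 60)
    mask: np.ndarray | None = None  # default: inscribed ellipse
    axis: int = 1  # grid dimension running anterior (index 0) -> posterior
    group_gradient: dict[str, float] = field(default_factory=lambda: {"A": 0.2, "B": 0.8})
    gradient_sd: float = 0.15
    noise_sd: float = 0.05
    seed: int = 0

    def resolved_mask(self) -> np.ndarray:
        if self.mask is not None:
            return np.asarray(self.mask, dtype=bool)
        r, c = self.grid_shape
        y, x = np.mgrid[0:r, 0:c]
        return (((y - (r - 1) / 2) / (r / 2)) ** 2 + ((x - (c - 1) / 2) / (c / 2)) ** 2) <= 1.0

    def validate(self) -> None:
        mask = self.resolved_mask()
        if mask.shape != tuple(self.grid_shape):
            raise ValueError("mask shape must match grid_shape")
        if not mask.any():
            raise ValueError("mask must be non-empty")
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 or 1")
        for g, m in self.group_gradient.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"gradient mean for group {g} must be in [0, 1]")


# ---------------------------------------------------------------------------
# Tree machinery


class _Node:
    __slots__ = ("children", "parent", "time", "name", "group", "length")

    def __init__(self) -> None:
        self.children: list[_Node] = []
        self.parent: _Node | None = None
        self.time = 0.0
        self.name: str | None = None
        self.group: str | None = None
        self.length = 0.0

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _yule_subtree(n: int, rate: float, rng: np.random.Generator) -> _Node:
    """Ultrametric pure-birth subtree with ``n`` leaves; node.time is depth."""
    root = _Node()
    if n == 1:
        return root
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (rate * len(active)))
        parent = active.pop(int(rng.integers(len(active))))
        parent.time = t
        for _ in range(2):
            child = _Node()
            child.parent = parent
            parent.children.append(child)
            active.append(child)
    t += rng.exponential(1.0 / (rate * n))
    for leaf in active:
        leaf.time = t
    return root


def _build_family_tree(params: FamilySimParams, rng: np.random.Generator) -> _Node:
    """Groups are clean clades: one pure-birth subtree per group, joined at
    the root by stems sized to keep the whole tree ultrametric."""
    groups = params.group_labels()
    sizes = np.full(params.n_groups, params.n_genes // params.n_groups)
    sizes[: params.n_genes % params.n_groups] += 1
    subtrees = [_yule_subtree(int(s), params.birth_rate, rng) for s in sizes]
    heights = [max(l.time for l in st.leaves()) for st in subtrees]
    h_max = max(heights)
    if params.n_groups == 1:
        root = subtrees[0]
        _mark_group(root, groups[0])
    else:
        root = _Node()
        for st, h, g in zip(subtrees, heights, groups):
            _shift_times(st, params.stem_length + (h_max - h))
            st.parent = root
            root.children.append(st)
            _mark_group(st, g)
    # branch lengths from times
    def set_lengths(node: _Node, parent_time: float) -> None:
        node.length = node.time - parent_time
        for c in node.children:
            set_lengths(c, node.time)

    set_lengths(root, root.time)
    # name leaves in depth-first order so adjacency mirrors phylogeny
    for i, leaf in enumerate(root.leaves()):
        leaf.name = f"TOX-{i + 1:02d}"
    return root


def _shift_times(node: _Node, dt: float) -> None:
    node.time += dt
    for c in node.children:
        _shift_times(c, dt)


def _mark_group(node: _Node, group: str) -> None:
    node.group = group
    for c in node.children:
        _mark_group(c, group)


def _to_phylo(root: _Node) -> Tree:
    def conv(node: _Node) -> Clade:
        cl = Clade(branch_length=float(node.length), name=node.name)
        cl.clades = [conv(c) for c in node.children]
        return cl

    return Tree(root=conv(root), rooted=True)


# ---------------------------------------------------------------------------
# Sequence + motif evolution


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length).astype(np.int8)


def _encode(s: str) -> np.ndarray:
    lut = {ord(b): i for i, b in enumerate(_BASES)}
    return np.array([lut[ord(c)] for c in s], dtype=np.int8)


def _decode(a: np.ndarray) -> str:
    return "".join(_BASES[i] for i in a)


def _evolve(seq: np.ndarray, rate: float, t: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor-style: Poisson number of events, each a uniform site and
    a uniform different base."""
    out = seq.copy()
    n_sub = rng.poisson(rate * t * len(seq))
    for _ in range(int(n_sub)):
        site = int(rng.integers(len(seq)))
        out[site] = (out[site] + 1 + rng.integers(3)) % 4
    return out


def _make_pfms(tf_ids: list[str], rng: np.random.Generator) -> list[Pfm]:
    """Strongly informative motifs (consensus count 91 of 100 per column),
    unique consensus per TF, lengths 8-12."""
    pfms: list[Pfm] = []
    seen: set[str] = set()
    for i, tf in enumerate(tf_ids):
        while True:
            L = int(rng.integers(8, 13))
            cons = _random_seq(L, rng)
            key = _decode(cons)
            if key not in seen:
                seen.add(key)
                break
        counts = np.full((4, L), 3.0)
        counts[cons, np.arange(L)] = 91.0
        pfms.append(Pfm(id=f"M{i + 1:03d}", name=tf, counts=counts))
    return pfms


def _allocate_offsets(pfms: list[Pfm], promoter_len: int, rng: np.random.Generator) -> dict[str, int]:
    """One non-overlapping slot per TF, uniform among the free positions."""
    occupied: list[tuple[int, int]] = []
    offsets: dict[str, int] = {}
    for p in pfms:
        for _ in range(10_000):
            off = int(rng.integers(0, promoter_len - p.length + 1))
            if all(off + p.length <= s or off >= e for s, e in occupied):
                occupied.append((off, off + p.length))
                offsets[p.name] = off
                break
        else:
            raise ValueError("could not place all motifs without overlap; promoter too short")
    return offsets


# ---------------------------------------------------------------------------
# simulate_family


@dataclass
class FamilySim:
    """Bundle returned by :func:`simulate_family`."""

    tree: Tree
    promoters: dict[str, str]
    cds: dict[str, str]
    peptides: dict[str, str]
    annotation: pd.DataFrame
    regulome: TruthRegulome
    pfms: list[Pfm]
    genome: dict[str, str]
    params: FamilySimParams


def simulate_family(params: FamilySimParams) -> FamilySim:
    """Evolve the toxin family: one shared topology underlies promoter and
    CDS evolution; motifs are gained/lost along branches, group-specific TFs
    only within their group's clade; the final consensus is stamped into the
    leaf promoters so the planted truth is scanner-detectable."""
    params.validate()
    rng_tree = substream(params.seed, "family.tree")
    rng_seq = substream(params.seed, "family.seq")
    rng_motif = substream(params.seed, "family.motif")

    root = _build_family_tree(params, rng_tree)
    leaves = root.leaves()
    tf_ids = params.all_tfs()
    pfms = _make_pfms(tf_ids, rng_motif)
    pfm_by_tf = {p.name: p for p in pfms}
    offsets = _allocate_offsets(pfms, params.promoter_len, rng_motif)

    tf_group = {tf: "shared" for tf in params.shared_tfs}
    for g, tfs in params.group_tfs.items():
        for tf in tfs:
            tf_group[tf] = g

    # root states
    root_prom = _random_seq(params.promoter_len, rng_seq)
    root_cds = _encode("".join(_CODONS[i] for i in rng_seq.choice(len(_CODONS), size=params.cds_len // 3)))
    root_state = {tf: (tf_group[tf] == "shared") for tf in tf_ids}

    promoters: dict[str, str] = {}
    cds: dict[str, str] = {}
    planted: dict[str, set[str]] = {}
    positions: dict[tuple[str, str], list[tuple[int, str]]] = {}

    def walk(node: _Node, prom: np.ndarray, cseq: np.ndarray, state: dict[str, bool]) -> None:
        if node.parent is not None:
            prom = _evolve(prom, params.subst_rate_promoter, node.length, rng_seq)
            cseq = _evolve(cseq, params.subst_rate_cds, node.length, rng_seq)
            state = dict(state)
            for tf in tf_ids:
                grp = tf_group[tf]
                if state[tf]:
                    if rng_motif.random() < params.motif_loss_prob:
                        state[tf] = False
                elif grp == "shared" or grp == node.group:
                    if rng_motif.random() < params.motif_gain_prob:
                        state[tf] = True
        if node.children:
            for c in node.children:
                walk(c, prom, cseq, state)
            return
        gene = node.name
        final = prom.copy()
        present = {tf for tf in tf_ids if state[tf]}
        for tf in present:
            p = pfm_by_tf[tf]
            off = offsets[tf]
            final[off : off + p.length] = _encode(p.consensus)
        promoters[gene] = _decode(final)
        cds[gene] = _decode(cseq)
        planted[gene] = present
        for tf in present:
            positions[(gene, tf)] = [(offsets[tf], "+")]

    walk(root, root_prom, root_cds, root_state)

    group_of = {leaf.name: leaf.group for leaf in leaves}
    regulome = TruthRegulome(planted, positions, group_of, tf_group)
    regulome.validate(params.promoter_len)

    peptides = {g: str(Seq(s).translate()) for g, s in cds.items()}
    annotation, genome = _layout_genome(params, [l.name for l in leaves], group_of,
                                        promoters, cds, tf_ids, substream(params.seed, "family.layout"))
    return FamilySim(_to_phylo(root), promoters, cds, peptides, annotation, regulome, pfms, genome, params)


def _layout_genome(
    params: FamilySimParams,
    gene_order: list[str],
    group_of: dict[str, str],
    promoters: dict[str, str],
    cds: dict[str, str],
    tf_ids: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tandem layout in tree depth-first order over <= n_scaffolds scaffolds,
    so physical distance tracks phylogenetic distance. All genes on +."""
    n = len(gene_order)
    n_scaff = min(params.n_scaffolds, n)
    if n_scaff == 1:
        bounds = np.array([0, n])
    else:
        # random cut points so scaffold breaks need not align with clades
        cuts = np.sort(rng.choice(np.arange(1, n), size=n_scaff - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [n]])
    rows = []
    genome: dict[str, str] = {}
    for s in range(n_scaff):
        name = f"scaffold_{s + 1}"
        parts: list[str] = []
        cursor = 1  # 1-based
        for gene in gene_order[bounds[s] : bounds[s + 1]]:
            gap = _decode(_random_seq(params.intergenic_gap, rng))
            parts.append(gap)
            cursor += len(gap)
            prom, cd = promoters[gene], cds[gene]
            parts.append(prom)
            tss = cursor + len(prom)
            parts.append(cd)
            start, end = tss, tss + len(cd) - 1
            cursor = end + 1
            rows.append((gene, name, start, end, "+", tss, "toxin", "TOX", group_of[gene]))
        parts.append(_decode(_random_seq(params.intergenic_gap, rng)))
        genome[name] = "".join(parts)
    # TF genes live on their own filler scaffold (class 'tf'); only their
    # identities matter downstream, not their sequence.
    cursor = 1
    parts = []
    for tf in tf_ids:
        gap = _decode(_random_seq(200, rng))
        parts.append(gap)
        cursor += len(gap)
        body = _decode(_random_seq(300, rng))
        parts.append(body)
        start, end = cursor, cursor + len(body) - 1
        rows.append((tf, "scaffold_tf", start, end, "+", start, "tf", "TF", "-"))
        cursor = end + 1
    genome["scaffold_tf"] = "".join(parts)
    ann = pd.DataFrame(rows, columns=tio.ANNOTATION_COLUMNS)
    return ann, genome


# ---------------------------------------------------------------------------
# simulate_cells


def simulate_cells(
    regulome: TruthRegulome, params: CellSimParams
) -> tuple[CountMatrix, pd.Series, pd.DataFrame]:
    """Draw negative-binomial counts for toxins, TFs, markers and background
    genes across structured cell populations.

    A toxin's mean in a cell is proportional to the average latent activity
    of its planted TFs plus a leak term; TF transcripts co-vary with their
    activities; marker genes are high in the populations that carry them.
    """
    groups = sorted(set(regulome.group_of.values()))
    params.validate(groups)
    pops = params.resolved_populations(groups)
    rng = substream(params.seed, "cells")

    toxins = regulome.genes
    tfs = regulome.tfs
    markers = sorted({m for p in pops for m in p.markers})
    background = [f"BG-{i + 1:03d}" for i in range(params.n_background_genes)]
    genes = toxins + tfs + markers + background

    if params.n_cells == 0:
        empty = CountMatrix(np.zeros((len(genes), 0), dtype=np.int64), genes, [], "cell")
        return empty, pd.Series([], dtype=object), pd.DataFrame(index=tfs)

    fracs = np.array([p.fraction for p in pops])
    pop_idx = rng.choice(len(pops), size=params.n_cells, p=fracs / fracs.sum())
    cell_ids = [f"cell-{i + 1:04d}" for i in range(params.n_cells)]
    labels = pd.Series([pops[i].name for i in pop_idx], index=cell_ids, name="population")

    # base (noise-free) TF activity per population
    def base_activity(pop: Population, tf: str) -> float:
        grp = regulome.tf_group.get(tf, "shared")
        if grp == "shared":
            return max(pop.group_weights.values(), default=0.0)
        return pop.group_weights.get(grp, 0.0)

    base = np.array([[base_activity(p, tf) for p in pops] for tf in tfs])  # tfs x pops
    noise = rng.lognormal(mean=-params.tf_activity_noise**2 / 2, sigma=params.tf_activity_noise,
                          size=(len(tfs), params.n_cells))
    activity = base[:, pop_idx] * noise  # tfs x cells
    tf_index = {tf: i for i, tf in enumerate(tfs)}

    def tf_weight(tf: str) -> float:
        return 1.0 if regulome.tf_group.get(tf, "shared") == "shared" else params.group_tf_weight

    # relative expression levels, genes x cells
    rel = np.zeros((len(genes), params.n_cells))
    gi = {g: i for i, g in enumerate(genes)}
    for g in toxins:
        planted = sorted(regulome.planted_sets.get(g, set()))
        if planted:
            w = np.array([tf_weight(t) for t in planted])
            act = (w @ activity[[tf_index[t] for t in planted], :]) / w.sum()
        else:
            act = np.zeros(params.n_cells)
        rel[gi[g]] = act + params.leak_rate
    for t in tfs:
        rel[gi[t]] = params.tf_expr_scale * (activity[tf_index[t]] + params.leak_rate)
    for m in markers:
        on = np.array([m in pops[i].markers for i in pop_idx])
        rel[gi[m]] = np.where(on, params.marker_level, 0.02)
    for b in background:
        rel[gi[b]] = params.background_level

    # expected totals per population (noise-free), used to scale to depth
    exp_rel = np.zeros((len(genes), len(pops)))
    for g in toxins:
        planted = sorted(regulome.planted_sets.get(g, set()))
        if planted:
            w = np.array([tf_weight(t) for t in planted])
            act = (w @ base[[tf_index[t] for t in planted], :]) / w.sum()
        else:
            act = np.zeros(len(pops))
        exp_rel[gi[g]] = act + params.leak_rate
    for t in tfs:
        exp_rel[gi[t]] = params.tf_expr_scale * (base[tf_index[t]] + params.leak_rate)
    for m in markers:
        exp_rel[gi[m]] = [params.marker_level if m in p.markers else 0.02 for p in pops]
    for b in background:
        exp_rel[gi[b]] = params.background_level
    pop_totals = exp_rel.sum(axis=0)

    depth = params.depth_mean * np.exp(
        rng.normal(0.0, params.depth_log_sd, size=params.n_cells) - params.depth_log_sd**2 / 2
    )
    mu = rel * (depth / pop_totals[pop_idx])[None, :]

    alpha = params.nb_dispersion
    with np.errstate(divide="ignore"):
        p_nb = 1.0 / (1.0 + alpha * mu)
    counts = np.where(mu > 0, rng.negative_binomial(1.0 / alpha, p_nb), 0).astype(np.int64)

    cm = CountMatrix(counts, genes, cell_ids, "cell")
    act_df = pd.DataFrame(activity, index=tfs, columns=cell_ids)
    return cm, labels, act_df


def expected_mean_count(
    regulome: TruthRegulome, params: CellSimParams, pop: Population, gene: str
) -> float:
    """Noise-free expected NB mean of ``gene`` in population ``pop`` at the
    mean depth — the closed form the simulator targets (used as an oracle)."""
    groups = sorted(set(regulome.group_of.values()))
    pops = params.resolved_populations(groups)
    tfs = regulome.tfs
    tf_index = {tf: i for i, tf in enumerate(tfs)}

    def base_activity(p: Population, tf: str) -> float:
        grp = regulome.tf_group.get(tf, "shared")
        return max(p.group_weights.values(), default=0.0) if grp == "shared" else p.group_weights.get(grp, 0.0)

    base = np.array([[base_activity(p, tf) for p in pops] for tf in tfs])
    markers = sorted({m for p in pops for m in p.markers})
    background_total = params.n_background_genes * params.background_level

    def tf_weight(tf: str) -> float:
        return 1.0 if regulome.tf_group.get(tf, "shared") == "shared" else params.group_tf_weight

    def rel_for(p_i: int, g: str) -> float:
        planted = sorted(regulome.planted_sets.get(g, set()))
        if planted:
            w = np.array([tf_weight(t) for t in planted])
            act = float(w @ base[[tf_index[t] for t in planted], p_i] / w.sum())
        else:
            act = 0.0
        return act + params.leak_rate

    pi = [p.name for p in pops].index(pop.name)
    total = sum(rel_for(pi, g) for g in regulome.genes)
    total += sum(params.tf_expr_scale * (base[tf_index[t], pi] + params.leak_rate) for t in tfs)
    total += sum(params.marker_level if m in pops[pi].markers else 0.02 for m in markers)
    total += background_total
    return params.depth_mean * rel_for(pi, gene) / total


def simulate_bulk(
    cell_counts: CountMatrix, depth: float = 2e6, dispersion: float = 0.05, seed: int = 0
) -> CountMatrix:
    """A bulk library consistent with the cell profile: NB draws around the
    pooled cell composition scaled to ``depth``."""
    rng = substream(seed, "bulk")
    total = cell_counts.values.sum(axis=1).astype(float)
    if total.sum() == 0:
        raise ValueError("cannot derive bulk from an all-zero cell matrix")
    mu = depth * total / total.sum()
    p_nb = 1.0 / (1.0 + dispersion * mu)
    vals = np.where(mu > 0, rng.negative_binomial(1.0 / dispersion, p_nb), 0).astype(np.int64)
    return CountMatrix(vals[:, None], cell_counts.gene_ids, ["bulk_venom_gland"], "bulk")


# ---------------------------------------------------------------------------
# simulate_sections


def simulate_sections(regulome: TruthRegulome, params: SectionSimParams):
    """Per-toxin intensity grids: a masked Gaussian profile centred at the
    toxin's group position along the anterior-posterior axis, plus pixel
    noise; zero outside the mask."""
    from .spatial import IonImageStack  # local import to avoid a cycle

    params.validate()
    mask = params.resolved_mask()
    rng = substream(params.seed, "sections")
    n_axis = params.grid_shape[params.axis]
    u = np.arange(n_axis) / max(n_axis - 1, 1)
    images: dict[str, np.ndarray] = {}
    for gene in regulome.genes:
        grp = regulome.group_of[gene]
        if grp not in params.group_gradient:
            raise ValueError(f"no gradient mean configured for group {grp!r}")
        mu = params.group_gradient[grp]
        profile = np.exp(-((u - mu) ** 2) / (2 * params.gradient_sd**2))
        img = np.broadcast_to(
            profile[None, :] if params.axis == 1 else profile[:, None], params.grid_shape
        ).copy()
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=params.grid_shape)
        img = np.clip(img, 0.0, None)
        img[~mask] = 0.0
        images[gene] = img
    return IonImageStack(images=images, mask=mask, axis=params.axis)


# ---------------------------------------------------------------------------
# write_fixture


def write_fixture(
    directory: str | Path,
    family: FamilySim | None = None,
    cells: tuple[CountMatrix, pd.Series, pd.DataFrame] | None = None,
    bulk: CountMatrix | None = None,
    sections=None,
) -> dict[str, Path]:
    """Write whichever simulated components are given as plain-text files
    that round-trip losslessly through this package's readers."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def put(key: str, path: Path) -> Path:
        manifest[key] = path
        return path

    if family is not None:
        tio.write_fasta(family.genome, put("genome", d / "genome.fa"))
        tio.write_fasta(family.promoters, put("promoters", d / "promoters.fa"))
        tio.write_fasta(family.cds, put("cds", d / "cds.fa"))
        tio.write_fasta(family.peptides, put("peptides", d / "peptides.fa"))
        tio.write_annotation(family.annotation, put("annotation", d / "annotation.tsv"))
        tio.write_pfms(family.pfms, put("motifs", d / "motifs.jaspar"))
        tio.write_newick(family.tree, put("tree", d / "tree.nwk"))
        truth_rows = [
            (g, tf, off, strand)
            for (g, tf), pos in sorted(family.regulome.motif_positions.items())
            for off, strand in pos
        ]
        pd.DataFrame(truth_rows, columns=["gene_id", "tf", "offset", "strand"]).to_csv(
            put("truth_regulome", d / "truth_regulome.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            sorted(family.regulome.group_of.items()), columns=["gene_id", "group"]
        ).to_csv(put("truth_groups", d / "truth_groups.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(family.regulome.tf_group.items()), columns=["tf", "group"]
        ).to_csv(put("tf_groups", d / "tf_groups.tsv"), sep="\t", index=False)

    if cells is not None:
        cm, labels, activity = cells
        tio.write_counts_mtx(cm, put("counts", d / "counts.mtx"),
                             put("genes", d / "genes.txt"), put("cells", d / "cells.txt"))
        labels.rename_axis("cell_id").to_frame().to_csv(
            put("cell_labels", d / "cell_labels.tsv"), sep="\t"
        )
        activity.rename_axis("tf").to_csv(put("tf_activity", d / "tf_activity.tsv"), sep="\t")

    if bulk is not None:
        bulk.to_frame().rename_axis("gene_id").to_csv(put("bulk", d / "bulk_counts.tsv"), sep="\t")

    if sections is not None:
        img_dir = d / "images"
        img_dir.mkdir(exist_ok=True)
        for gene, img in sections.images.items():
            tio.write_grid(img, put(f"image:{gene}", img_dir / f"{gene}.tsv"))
        tio.write_grid(sections.mask.astype(int), put("mask", d / "mask.tsv"))
        (d / "sections.json").write_text(json.dumps({"axis": sections.axis}))
        manifest["sections_meta"] = d / "sections.json"

    return manifest


def read_fixture_counts(directory: str | Path) -> CountMatrix:
    d = Path(directory)
    return tio.read_counts_mtx(d / "counts.mtx", d / "genes.txt", d / "cells.txt")
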