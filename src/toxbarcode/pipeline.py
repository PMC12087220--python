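"""End-to-end orchestration: run the full analysis from a configuration
mapping (or YAML file) over a fixture directory, write every intermediate
table as TSV, and return a machine-readable report.

Steps run in analysis order — expression -> coexpr -> regnet -> evodist ->
spatial -> integrate — and any step can be skipped. All randomness derives
from the single configured seed, so re-running an identical config
reproduces every numeric output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, evodist, expression, integrate, regnet, spatial
from . import io as tio
from .containers import CountMatrix

logger = logging.getLogger("toxbarcode")

ALL_STEPS = ("expression", "coexpr", "regnet", "evodist", "spatial", "integrate")


@dataclass
class PipelineConfig:
    fixture_dir: str
    out_dir: str
    seed: int = 0
    steps: tuple[str, ...] = ALL_STEPS
    marker_ids: tuple[str, ...] = ("LAMA3", "EPCAM")
    qc_min_counts: int = 1000
    qc_min_genes: int = 100
    n_pcs: int = 30
    k_neighbors: int = 20
    resolution: float = 1.0
    divergence_percentile: float = 99.0
    min_module_size: int = 30
    merge_dissimilarity: float = 0.2
    signed_network: bool = False
    promoter_len: int = 500
    scan_deficit: float = 0.15
    n_trees: int = 1000
    distance_model: str = "p"
    mantel_permutations: int = 0
    shuffle_barcodes: bool = False  # negative control
    toxin_cells_only: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        for step in cfg.steps:
            if step not in ALL_STEPS:
                raise ValueError(f"unknown step {step!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


@dataclass
class ReportBundle:
    manifest: dict[str, str]
    summary: dict
    log: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"manifest": self.manifest, "summary": self.summary, "log": self.log},
                       indent=2)
        )


def run_pipeline(config: PipelineConfig | dict) -> ReportBundle:
    if isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    fx = Path(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    required = ["counts.mtx", "genes.txt", "cells.txt", "annotation.tsv"]
    missing = [f for f in required if not (fx / f).exists()]
    if missing:
        raise FileNotFoundError(f"fixture is missing inputs: {missing}")

    manifest: dict[str, str] = {}
    summary: dict = {"seed": config.seed, "config": {f.name: getattr(config, f.name)
                                                     for f in fields(PipelineConfig)}}
    log: list[str] = []

    def emit(name: str, path: Path) -> None:
        manifest[name] = str(path)

    def stamp(step: str, t0: float) -> None:
        msg = f"{step}: done in {time.perf_counter() - t0:.2f}s"
        logger.info(msg)
        log.append(msg)

    annotation = tio.read_annotation(fx / "annotation.tsv")
    toxin_ids = list(annotation.loc[annotation["class"] == "toxin", "gene_id"])
    tf_ids = list(annotation.loc[annotation["class"] == "tf", "gene_id"])
    counts = tio.read_counts_mtx(fx / "counts.mtx", fx / "genes.txt", fx / "cells.txt")

    filtered = counts
    annotation_cells = None
    toxin_cell_counts = None
    coexpr_matrix = None
    assignment = None
    prom_patristic = pep_patristic = None
    spatial_corr = None

    if "expression" in config.steps:
        t0 = time.perf_counter()
        filtered = expression.filter_cells(
            counts, expression.QcParams(config.qc_min_counts, config.qc_min_genes)
        )
        pd.DataFrame(
            {
                "n_cells_in": [counts.n_samples],
                "n_cells_kept": [filtered.n_samples],
            }
        ).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        emit("qc_report", out / "qc_report.tsv")

        clusters = expression.cluster_cells(
            filtered, config.n_pcs, min(config.k_neighbors, filtered.n_samples - 1),
            config.resolution, config.seed,
        )
        markers = [m for m in config.marker_ids if m in filtered.gene_ids]
        ann_cells = expression.classify_toxin_cells(filtered, clusters, markers, toxin_ids)
        ann_cells.to_frame().rename_axis("cell_id").to_csv(out / "cell_annotation.tsv", sep="\t")
        emit("cell_annotation", out / "cell_annotation.tsv")
        annotation_cells = ann_cells
        summary["n_cells"] = filtered.n_samples
        summary["n_toxin_cells"] = int(ann_cells.is_toxin_cell.sum())

        bulk_path = fx / "bulk_counts.tsv"
        if bulk_path.exists():
            bulk_df = pd.read_csv(bulk_path, sep="\t", index_col=0)
            bulk = CountMatrix(
                bulk_df.to_numpy(dtype=np.int64), list(bulk_df.index), list(bulk_df.columns), "bulk"
            )
            cpm, factors = expression.pseudobulk_and_normalize(filtered, bulk)
            report = expression.clr_divergence(
                cpm.iloc[:, 0], cpm.iloc[:, 1], toxin_ids, config.divergence_percentile
            )
            report.to_frame().to_csv(out / "divergence.tsv", sep="\t", index=False)
            emit("divergence", out / "divergence.tsv")
            summary["n_divergent_toxins"] = int(sum(report.flags.values()))

        if config.toxin_cells_only:
            keep_cells = list(ann_cells.is_toxin_cell.index[ann_cells.is_toxin_cell])
        else:
            keep_cells = list(ann_cells.is_toxin_cell.index)
        toxin_cell_counts = filtered.subset_samples(keep_cells)
        if toxin_cell_counts.n_samples >= 3:
            present = [g for g in toxin_ids if g in filtered.gene_ids]
            coexpr_matrix = expression.spearman_coexpression(toxin_cell_counts, present)
            tio.write_pair_matrix(coexpr_matrix, out / "coexpression.tsv")
            emit("coexpression", out / "coexpression.tsv")
        stamp("expression", t0)

    if "coexpr" in config.steps and toxin_cell_counts is not None:
        t0 = time.perf_counter()
        expr = expression.log1p_cpm(toxin_cell_counts)
        expr = expr.loc[expr.std(axis=1) > 0]
        params = coexpr.CoexprParams(
            min_module_size=config.min_module_size,
            merge_dissimilarity=config.merge_dissimilarity,
            signed=config.signed_network,
        )
        sft = coexpr.pick_soft_threshold(expr, params)
        sft.table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
        emit("soft_threshold", out / "soft_threshold.tsv")
        adj = coexpr.adjacency(expr, sft.chosen_power, params.signed)
        part = coexpr.detect_modules(coexpr.tom(adj), params)
        if part.modules:
            part = coexpr.merge_modules(expr, part, params.merge_dissimilarity)
            part.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
            emit("eigengenes", out / "eigengenes.tsv")
        mod_df = part.assignment.rename_axis("gene_id").to_frame()
        if part.kme is not None:
            mod_df = mod_df.join(part.kme)
        mod_df.to_csv(out / "modules.tsv", sep="\t")
        emit("modules", out / "modules.tsv")
        summary["n_modules"] = len(part.modules)
        summary["chosen_power"] = sft.chosen_power
        stamp("coexpr", t0)

    if "regnet" in config.steps:
        t0 = time.perf_counter()
        genome = tio.read_fasta(fx / "genome.fa")
        promoters = regnet.extract_promoters(genome, annotation, config.promoter_len)
        pfms = tio.read_pfms(fx / "motifs.jaspar")
        scan = regnet.ScanParams(score_fraction=1.0 - config.scan_deficit)
        hits = regnet.pwm_scan(promoters, pfms, scan)
        pd.DataFrame(
            [(h.tf_id, h.gene_id, h.offset, h.strand, h.score) for h in hits],
            columns=["tf", "gene", "offset", "strand", "score"],
        ).to_csv(out / "hits.tsv", sep="\t", index=False)
        emit("hits", out / "hits.tsv")
        assignment = regnet.call_candidate_tfs(tf_ids, hits, toxin_ids)
        assignment.to_frame().to_csv(out / "barcode.tsv", sep="\t", index=False)
        emit("barcode", out / "barcode.tsv")
        # importances are fitted on all QC-passing cells: the non-secretory
        # cells anchor the shared-TF signal, which toxin-cell-only data lacks
        if filtered.n_samples >= 10:
            expr = expression.log1p_cpm(filtered)
            targets = [g for g in toxin_ids if g in expr.index]
            preds = [t for t in tf_ids if t in expr.index]
            assignment.weights = regnet.importance_network(
                expr, preds, targets, config.n_trees, config.seed
            )
            assignment.weights.rename_axis("tf").to_csv(out / "weights.tsv", sep="\t")
            emit("weights", out / "weights.tsv")
        summary["n_candidate_pairs"] = int(sum(len(v) for v in assignment.barcode.values()))
        stamp("regnet", t0)

    if "evodist" in config.steps:
        t0 = time.perf_counter()
        prom = tio.read_fasta(fx / "promoters.fa")
        pep = tio.read_fasta(fx / "peptides.fa")
        dm_prom = evodist.pairwise_distance(prom, config.distance_model)
        dm_pep = evodist.pairwise_distance(pep, "p")
        prom_patristic = evodist.patristic(evodist.neighbor_joining(dm_prom))
        pep_patristic = evodist.patristic(evodist.neighbor_joining(dm_pep))
        dm_prom.to_frame().to_csv(out / "promoter_patristic.tsv", sep="\t")
        dm_pep.to_frame().to_csv(out / "peptide_patristic.tsv", sep="\t")
        emit("promoter_patristic", out / "promoter_patristic.tsv")
        emit("peptide_patristic", out / "peptide_patristic.tsv")
        stamp("evodist", t0)

    if "spatial" in config.steps and (fx / "mask.tsv").exists():
        t0 = time.perf_counter()
        mask = tio.read_grid(fx / "mask.tsv").astype(bool)
        meta = json.loads((fx / "sections.json").read_text()) if (fx / "sections.json").exists() else {"axis": 1}
        images = {}
        for g in toxin_ids:
            p = fx / "images" / f"{g}.tsv"
            if p.exists():
                images[g] = tio.read_grid(p)
        stack = spatial.IonImageStack(images, mask, int(meta["axis"]))
        spatial_corr = spatial.spatial_correlation(stack)
        tio.write_pair_matrix(spatial_corr, out / "spatial_correlation.tsv")
        emit("spatial_correlation", out / "spatial_correlation.tsv")
        centroids = spatial.axis_localization(stack)
        centroids.rename_axis("gene_id").to_frame().to_csv(out / "centroids.tsv", sep="\t")
        emit("centroids", out / "centroids.tsv")
        groups = annotation.set_index("gene_id")["group"].reindex(centroids.index)
        loc = spatial.group_location_test(centroids, groups)
        pd.DataFrame({"f": [loc.f_statistic], "p": [loc.p_value]}).to_csv(
            out / "location_test.tsv", sep="\t", index=False
        )
        emit("location_test", out / "location_test.tsv")
        summary["location_anova_p"] = loc.p_value
        stamp("spatial", t0)

    if "integrate" in config.steps and assignment is not None:
        t0 = time.perf_counter()
        if config.shuffle_barcodes:
            rng = np.random.default_rng(config.seed)
            genes = sorted(assignment.barcode)
            perm = rng.permutation(len(genes))
            shuffled = {genes[i]: assignment.barcode[genes[perm[i]]] for i in range(len(genes))}
            counts_map = {}
            for i, g in enumerate(genes):
                src = genes[perm[i]]
                for tf in shuffled[g]:
                    counts_map[(g, tf)] = assignment.hit_counts[(src, tf)]
            assignment = regnet.RegulatoryAssignment(shuffled, counts_map, assignment.weights)
        jac = integrate.jaccard_matrix(assignment)
        tio.write_pair_matrix(jac, out / "jaccard.tsv")
        emit("jaccard", out / "jaccard.tsv")
        gdist = integrate.genomic_distance(annotation, toxin_ids)
        tio.write_pair_matrix(gdist, out / "genomic_distance.tsv")
        emit("genomic_distance", out / "genomic_distance.tsv")

        matrices = {"jaccard": jac, "genomic_distance": gdist}
        if spatial_corr is not None:
            matrices["spatial"] = spatial_corr
        if coexpr_matrix is not None:
            matrices["coexpression"] = coexpr_matrix
        if prom_patristic is not None:
            matrices["promoter_patristic"] = _as_pair(prom_patristic, "promoter_patristic")
            matrices["peptide_patristic"] = _as_pair(pep_patristic, "peptide_patristic")
        rows = []
        names = sorted(matrices)
        for a_name, b_name in [(x, y) for i, x in enumerate(names) for y in names[i + 1 :]]:
            try:
                res = integrate.matrix_correlation(
                    matrices[a_name], matrices[b_name], config.mantel_permutations, config.seed
                )
            except ValueError:
                continue
            rows.append((a_name, b_name, res.r, res.p, res.n_pairs, res.mantel_p))
        corr_df = pd.DataFrame(rows, columns=["a", "b", "r", "p", "n_pairs", "mantel_p"])
        corr_df.to_csv(out / "correlations.tsv", sep="\t", index=False)
        emit("correlations", out / "correlations.tsv")
        summary["correlations"] = corr_df.drop(columns=["mantel_p"]).to_dict("records")

        ppi_path = fx / "ppi.tsv"
        ppi = integrate.read_ppi_edges(ppi_path) if ppi_path.exists() else []
        grn = integrate.build_grn(assignment, ppi)
        cent = integrate.centralities(grn)
        cent.rename_axis("node").to_csv(out / "centrality.tsv", sep="\t")
        emit("centrality", out / "centrality.tsv")
        edge_rows = [
            (u, v, d.get("kind"), d.get("tfbs_count"), d.get("weight"))
            for u, v, d in grn.edges(data=True)
        ]
        pd.DataFrame(edge_rows, columns=["source", "target", "kind", "tfbs_count", "weight"]).to_csv(
            out / "grn_edges.tsv", sep="\t", index=False
        )
        emit("grn_edges", out / "grn_edges.tsv")
        stamp("integrate", t0)

    bundle = ReportBundle(manifest, summary, log)
    bundle.write(out / "report.json")
    return bundle


def _as_pair(dm, measure: str):
    from .containers import PairMatrix

    return PairMatrix(dm.labels, dm.values, measure=measure, kind="distance")
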