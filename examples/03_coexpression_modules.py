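"""Co-expression modules within toxin cells.

Toxin-producing cells are identified by cluster-level toxin fraction and
epithelial markers (LAMA3/EPCAM); on those cells a weighted co-expression
network (soft power for scale-free topology, topological overlap, average
linkage, minimum module size 30, merge at eigengene dissimilarity 0.2)
groups genes into modules. Here the network is signed because the two
planted toxin groups are anti-correlated across secretory cell types.
"""

import warnings

warnings.simplefilter("ignore")

import pandas as pd

from toxbarcode import coexpr, expression, syndata

family = syndata.simulate_family(syndata.FamilySimParams(n_genes=80, seed=23))
counts, labels, _ = syndata.simulate_cells(
    family.regulome, syndata.CellSimParams(seed=23, n_background_genes=205)
)
filtered = expression.filter_cells(counts)
clusters = expression.cluster_cells(filtered, seed=1)
ann = expression.classify_toxin_cells(filtered, clusters, ["LAMA3", "EPCAM"], family.regulome.genes)
tox_cells = filtered.subset_samples(list(ann.is_toxin_cell.index[ann.is_toxin_cell]))
print(f"{tox_cells.n_samples} toxin cells across {clusters.nunique()} clusters")

expr = expression.log1p_cpm(tox_cells)
expr = expr.loc[expr.std(axis=1) > 0]
params = coexpr.CoexprParams(signed=True)
soft = coexpr.pick_soft_threshold(expr, params)
print(f"soft threshold beta = {soft.chosen_power} "
      f"(scale-free R^2 = {soft.table.set_index('power').loc[soft.chosen_power, 'r2']:.2f})")

partition = coexpr.detect_modules(coexpr.tom(coexpr.adjacency(expr, soft.chosen_power, True)), params)
partition = coexpr.merge_modules(expr, partition, params.merge_dissimilarity)
print("module sizes:", partition.sizes().to_dict())

groups = pd.Series(family.regulome.group_of)
for module in partition.modules:
    members = partition.assignment.index[partition.assignment == module]
    comp = groups.reindex(members).value_counts(dropna=True).to_dict()
    print(f"  {module}: planted-group composition {comp}")
# Each detected module should collect one planted toxin group (plus its TFs).
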