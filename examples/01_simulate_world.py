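"""Generate the synthetic venom-gland world and write it as a fixture.

A tandem toxin gene family evolves on one pure-birth tree (two functional
groups: neurotoxin-like A, cytotoxin-like B); TF motif barcodes are planted
in the promoters; cell populations draw negative-binomial counts driven by
TF activity; gland sections carry an anterior-posterior group gradient.
"""

from pathlib import Path

from toxbarcode import syndata

out = Path("scratch/example_fixture")

family = syndata.simulate_family(syndata.FamilySimParams(seed=1))
cells = syndata.simulate_cells(family.regulome, syndata.CellSimParams(seed=1))
bulk = syndata.simulate_bulk(cells[0], seed=1)
sections = syndata.simulate_sections(family.regulome, syndata.SectionSimParams(seed=1))
manifest = syndata.write_fixture(out, family=family, cells=cells, bulk=bulk, sections=sections)

reg = family.regulome
n_planted = sum(len(v) for v in reg.planted_sets.values())
print(f"simulated {len(reg.genes)} toxin genes in groups "
      f"{sorted(set(reg.group_of.values()))}, {len(reg.tfs)} TFs, "
      f"{n_planted} planted TF-binding relationships")
print(f"cells: {cells[0].n_samples} across populations "
      f"{cells[1].value_counts().to_dict()}")
print(f"wrote {len(manifest)} files to {out}")
# The planted truth (truth_regulome.tsv, truth_groups.tsv) is what the
# analysis modules are later scored against.
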