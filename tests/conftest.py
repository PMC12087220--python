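import warnings

import pytest

from toxbarcode import syndata


@pytest.fixture(scope="session")
def family():
    """Default synthetic toxin family (24 genes, two groups)."""
    return syndata.simulate_family(syndata.FamilySimParams(seed=11))


@pytest.fixture(scope="session")
def cells_sim(family):
    """Default cell simulation on the family's regulome."""
    return syndata.simulate_cells(family.regulome, syndata.CellSimParams(seed=11))


@pytest.fixture(scope="session")
def sections(family):
    return syndata.simulate_sections(family.regulome, syndata.SectionSimParams(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, family, cells_sim, sections):
    """A full on-disk fixture used by round-trip and pipeline tests."""
    d = tmp_path_factory.mktemp("fixture")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bulk = syndata.simulate_bulk(cells_sim[0], seed=11)
        syndata.write_fixture(d, family=family, cells=cells_sim, bulk=bulk, sections=sections)
    return d
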