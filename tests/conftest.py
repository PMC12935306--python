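import pytest

from quorumcomp.biofilm import SimGrid, SimulationConfig, StrainParams
from quorumcomp.genomes import make_reference_operon
from quorumcomp.references import default_references


@pytest.fixture(scope="session")
def refs():
    return default_references()


@pytest.fixture(scope="session")
def reference_genome():
    """An unmodified 3610-like operon genome."""
    return make_reference_operon("3610", seed=101)


@pytest.fixture()
def small_grid():
    return SimGrid.disc(radius=8.0, nx=48)


@pytest.fixture()
def equal_strains():
    return (StrainParams("B1", 1.0, 1.0), StrainParams("B2", 1.0, 1.0))


def small_config(grid, strains, layout, **kw):
    defaults = dict(t_end=8.0)
    defaults.update(kw)
    return SimulationConfig(grid, strains, layout, **defaults)
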