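import pytest

from mitocompare import make_table1_fixture, simulate_genome
from mitocompare.rearrangement import cluster_types, load_planorbid_orders
from mitocompare.synthetic_data import SimulationSpec


@pytest.fixture(scope="session")
def table1():
    """The packaged reference annotation (37 features, no sequence)."""
    return make_table1_fixture()


@pytest.fixture(scope="session")
def sim_genome():
    """One deterministic synthetic mitogenome with sequence."""
    genome, report = simulate_genome(SimulationSpec(seed=11))
    return genome, report


@pytest.fixture(scope="session")
def planorbid_orders():
    return load_planorbid_orders()


@pytest.fixture(scope="session")
def arrangement_table(planorbid_orders):
    return cluster_types(planorbid_orders)
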