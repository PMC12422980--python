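import numpy as np
import pandas as pd
import pytest

from stereoatlas import core, neuron_mapper, phantom


@pytest.fixture(scope="session")
def world():
    """Default phantom world (seed 7), shared read-only across the suite."""
    return phantom.make_phantom_atlas()


@pytest.fixture(scope="session")
def lookup(world):
    """Identity-step (10 μm) region lookup over the phantom annotation."""
    return core.build_lookup(world.annotation)


@pytest.fixture(scope="session")
def acronym_ids(world):
    return {node.acronym: node.id for node in world.ontology}


@pytest.fixture(scope="session")
def neurons_and_truth(world):
    return phantom.make_phantom_neurons(world)


@pytest.fixture(scope="session")
def relation_tables(world, lookup, neurons_and_truth):
    neurons, _truth = neurons_and_truth
    return pd.concat(
        [neuron_mapper.assign_regions(lookup, world.ontology, n) for n in neurons],
        ignore_index=True,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
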