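import pytest

from modulecover import (
    ActivityProfile,
    DatasetCollection,
    ExtractionConfig,
    InteractionNetwork,
    LSpec,
    SyntheticSpec,
    generate_synthetic_instance,
)


@pytest.fixture
def path_abc() -> InteractionNetwork:
    """A - B - C path."""
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star_hub() -> InteractionNetwork:
    """Star K1,4: hub 'h' with leaves l1..l4."""
    return InteractionNetwork.from_edges([("h", f"l{i}") for i in range(1, 5)])


def uniform_activity(network, active, n_cases=1, l=0):
    """Activity with the given nodes active (0 exceptions) and the rest
    fully inactive."""
    exceptions = {
        v: (0 if v in active else n_cases) for v in network.node_ids
    }
    return ActivityProfile(exceptions, n_cases, l)


@pytest.fixture
def planted_instance():
    """The reference planted-module benchmark: 100-node scale-free
    background, 10-node module, 40 cases, activity 0.95 vs 0.05."""
    spec = SyntheticSpec(seed=7)
    network, matrix, gold = generate_synthetic_instance(spec)
    collection = DatasetCollection([matrix])
    config = ExtractionConfig(
        strategy="INES", k=2, l_spec=LSpec("percent", 20), max_solutions=10
    )
    return network, collection, config, gold
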