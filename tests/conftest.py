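import numpy as np
import pytest

from memconn.connectome import AtlasDefinition
from memconn.synthetic import SimulationConfig, generate_atlas, simulate_cohort


@pytest.fixture(scope="session")
def atlas10() -> AtlasDefinition:
    """Small two-module atlas with hand-placed centroids."""
    rng = np.random.default_rng(11)
    centroids = rng.uniform([-90, -110, -70], [90, 110, 70], size=(10, 3))
    return AtlasDefinition(
        labels=[f"region_{i}" for i in range(10)],
        modules=["default mode"] * 5 + ["limbic"] * 5,
        centroids=centroids,
    )


@pytest.fixture(scope="session")
def atlas90() -> AtlasDefinition:
    return generate_atlas(90, 8, seed=12345)


def planted_edges(atlas, n_wanted, modules=("default mode", "limbic"), seed=0):
    """Random distinct edges among nodes of the given modules."""
    rng = np.random.default_rng(seed)
    nodes = [i for i, m in enumerate(atlas.modules) if m in modules]
    edges = set()
    while len(edges) < n_wanted:
        i, j = rng.choice(nodes, 2, replace=False)
        edges.add((min(i, j), max(i, j)))
    return tuple(sorted(edges))


@pytest.fixture(scope="session")
def planted_cohort(atlas90):
    """A 90-node cohort with 40 planted default-mode/limbic signal edges."""
    edges = planted_edges(atlas90, 40, seed=0)
    cfg = SimulationConfig(n_subjects=60, signal_edges=edges, random_seed=202)
    return simulate_cohort(cfg, atlas=atlas90), edges


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 20-node cohort for pipeline-level tests."""
    atlas = generate_atlas(20, 4, seed=5)
    edges = planted_edges(atlas, 8, modules=tuple(atlas.module_names[:2]), seed=5)
    cfg = SimulationConfig(
        n_subjects=24, n_nodes=20, signal_edges=edges, random_seed=31
    )
    return simulate_cohort(cfg)
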