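import numpy as np
import pytest
from shapely.geometry import Polygon

from pialnet.netcore import EdgeRecord, NodeRecord, PialNetwork, RegionMap
from pialnet.synthgen import GeneratorParams, generate_animal_network, generate_geometry


def make_network(nodes, edges, slab_id="s"):
    """nodes: (id, x, y, kind); edges: (id, a, b[, kind])."""
    return PialNetwork(
        nodes=[NodeRecord(i, float(x), float(y), k) for i, x, y, k in nodes],
        edges=[EdgeRecord(e[0], e[1], e[2],
                          e[3] if len(e) > 3 else "vessel") for e in edges],
        slab_id=slab_id)


@pytest.fixture
def square_cycle_with_offshoots():
    """A 4-node anastomosis loop with two single-PA offshoots."""
    # note: b and d are degree-2 loop nodes; the decomposition does not
    # require validation-clean kinds, matching hand-drawn sketches
    nodes = [("a", 0, 0, "bifurcation"), ("b", 1, 0, "bifurcation"),
             ("c", 1, 1, "bifurcation"), ("d", 0, 1, "bifurcation"),
             ("p1", -0.5, 0, "pa"), ("p2", 1.5, 1, "pa")]
    edges = [("e1", "a", "b"), ("e2", "b", "c"), ("e3", "c", "d"),
             ("e4", "d", "a", "lma"), ("o1", "a", "p1"), ("o2", "c", "p2")]
    return make_network(nodes, edges)


@pytest.fixture
def unit_square_regions():
    slab = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
    barrels = Polygon([(0.1, 0.1), (0.6, 0.1), (0.6, 0.6), (0.1, 0.6)])
    return RegionMap(slab=slab, regions={"barrels": barrels})


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams(seed=101)


@pytest.fixture(scope="session")
def one_animal(default_params):
    """One default-calibration synthetic animal (sham)."""
    rng = np.random.default_rng(2301)
    rm = generate_geometry(default_params, rng)
    return generate_animal_network(rm, default_params, "sham", rng)
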