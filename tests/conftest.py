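import numpy as np
import pytest

from lagat.kg_io import build_kg


@pytest.fixture
def triangle_kg():
    """3 entities, 1 relation, triangle of triples."""
    return build_kg([("A", "r1", "B"), ("B", "r1", "C"), ("A", "r1", "C")])


@pytest.fixture
def toy_kg():
    """12-node heterogeneous KG: 4 drugs, 2 hubs, 6 leaves."""
    triples = []
    drugs = [f"d{i}" for i in range(4)]
    hubs = ["h0", "h1"]
    leaves = [f"x{i}" for i in range(6)]
    # every drug touches one or two hubs, plus private leaves
    wiring = {
        "d0": ["h0", "x0", "x1"],
        "d1": ["h0", "h1", "x2"],
        "d2": ["h1", "x3", "x4"],
        "d3": ["h0", "x5"],
    }
    for d, targets in wiring.items():
        for t in targets:
            triples.append((d, "binds", t))
    return build_kg(triples)


@pytest.fixture
def star_kg():
    """Star graph: center c with 5 leaves."""
    return build_kg([("c", "r", f"l{i}") for i in range(5)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
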