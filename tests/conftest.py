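import numpy as np
import pytest

from arealscan import RegionMap, SimConfig, generate


def make_map(ids, coords, edges):
    return RegionMap(
        region_ids=tuple(ids),
        coords=np.asarray(coords, dtype=float),
        edges=frozenset(frozenset(e) for e in edges),
    )


@pytest.fixture
def path3():
    """Collinear path A - B - C at unit spacing."""
    return make_map(["A", "B", "C"], [[0, 0], [1, 0], [2, 0]], [("A", "B"), ("B", "C")])


@pytest.fixture
def star5():
    """Centre S with four leaves (leaves mutually non-adjacent)."""
    ids = ["S", "L1", "L2", "L3", "L4"]
    coords = [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]]
    edges = [("S", l) for l in ids[1:]]
    return make_map(ids, coords, edges)


@pytest.fixture
def line9():
    """Nine collinear, equally spaced regions (interval clusters)."""
    ids = [f"P{i}" for i in range(9)]
    coords = [[i * 10.0, 0.0] for i in range(9)]
    edges = [(ids[i], ids[i + 1]) for i in range(8)]
    return make_map(ids, coords, edges)


@pytest.fixture(scope="session")
def study():
    """One fixed synthetic study at the default (prefecture-like) scale."""
    return generate(SimConfig(seed=20260919))


@pytest.fixture(scope="session")
def small_study():
    """A small, fast study for pipeline/sensitivity integration tests."""
    return generate(
        SimConfig(
            n_regions=12,
            total_examinees=30_000,
            expected_total_cases=40.0,
            seed=11,
        )
    )
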