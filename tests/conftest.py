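import numpy as np
import pytest

import connharm as ch


@pytest.fixture(scope="session")
def ring8_graph():
    return ch.build_graph(ch.make_ring_mesh(8))


@pytest.fixture(scope="session")
def ico1_mesh():
    return ch.make_icosphere(1)  # 42 vertices


@pytest.fixture(scope="session")
def ico1_graph(ico1_mesh):
    return ch.build_graph(ico1_mesh, ch.plant_long_range(ico1_mesh, 12, seed=5))


@pytest.fixture(scope="session")
def ico1_basis(ico1_graph):
    lap = ch.connectome_laplacian(ico1_graph, "symmetric_normalized")
    return ch.compute_harmonics(lap, 42)


@pytest.fixture(scope="session")
def ico2_mesh():
    return ch.make_icosphere(2)  # 162 vertices


@pytest.fixture(scope="session")
def ico2_graph(ico2_mesh):
    return ch.build_graph(ico2_mesh, ch.plant_long_range(ico2_mesh, 40, seed=1))


@pytest.fixture(scope="session")
def ring32_laplacian():
    return ch.connectome_laplacian(ch.build_graph(ch.make_ring_mesh(32)), "combinatorial")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
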