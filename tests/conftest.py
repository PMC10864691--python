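import warnings

import numpy as np
import pytest
from shapely.geometry import Polygon

from coxhawk import Domain, Mesh, build_mesh

# planar-coordinate and zero-buffer notices are expected throughout the suite
warnings.filterwarnings("ignore", message="domain bounds fit inside lon/lat")
warnings.filterwarnings("ignore", message="building mesh without an outer buffer")


@pytest.fixture(scope="session")
def unit_square() -> Domain:
    return Domain(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]))


@pytest.fixture(scope="session")
def big_square() -> Domain:
    return Domain(Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]))


@pytest.fixture(scope="session")
def unit_mesh(unit_square) -> Mesh:
    return build_mesh(unit_square, max_edge=0.25)


@pytest.fixture(scope="session")
def coarse_big_mesh(big_square) -> Mesh:
    return build_mesh(big_square, max_edge=1.5)


@pytest.fixture(scope="session")
def tiny_mesh() -> Mesh:
    """Five nodes: unit-square corners plus the centre; four triangles."""
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.5, 0.5]])
    tris = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    return Mesh(nodes, tris)
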