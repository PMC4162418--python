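import numpy as np
import pytest

from atlasdai import (
    AxisSpec,
    Registry,
    SRSDescription,
    make_phantom_atlas,
    make_table1_registry,
)


def minimal_srs(code: str, name: str, family: str = "Test",
                version: str = "1.0", lo: float = 0.0,
                hi: float = 10.0) -> SRSDescription:
    """A minimal valid SRS record for graph/registry tests."""
    axes = (AxisSpec("X", "left-to-right", "mm", lo, hi),
            AxisSpec("Y", "posterior-to-anterior", "mm", lo, hi),
            AxisSpec("Z", "ventral-to-dorsal", "mm", lo, hi))
    return SRSDescription(code=code, name=name, srs_family=family,
                          version=version, species="Mouse", axes=axes)


def make_node_registry(n: int) -> Registry:
    """Registry with n minimal SRSs, codes LOCAL:0001..LOCAL:nnnn."""
    reg = Registry()
    for i in range(1, n + 1):
        reg.register_srs(minimal_srs(f"LOCAL:{i:04d}", f"Node_{i}"))
    return reg


@pytest.fixture(scope="session")
def table1():
    """The seven-SRS mouse registry fixture with its star graph."""
    return make_table1_registry()


@pytest.fixture(scope="session")
def phantom():
    return make_phantom_atlas(seed=11, shape=(24, 24, 16), n_structures=2,
                              min_radius=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
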