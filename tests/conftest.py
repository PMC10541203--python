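"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from leprmap.synthetic import (
    AtlasSpec,
    TrapSpec,
    make_atlas,
    make_trap_experiment,
)


@pytest.fixture(scope="session")
def small_atlas():
    """Compact 4-population atlas for unit-level checks."""
    spec = AtlasSpec(
        n_populations=4,
        cells_per_population=100,
        n_genes=600,
        markers_per_population=20,
        marker_log2fc=3.0,
        seed=101,
    )
    return make_atlas(spec)


@pytest.fixture(scope="session")
def standard_atlas():
    """The standard study-scale atlas: 6 populations x 300 cells, 2,000 genes."""
    return make_atlas(AtlasSpec(seed=7))


@pytest.fixture(scope="session")
def trap_data():
    """Default 4-pair TRAP experiment with planted enrichment and leptin effects."""
    return make_trap_experiment(TrapSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
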