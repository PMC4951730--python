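import numpy as np
import pytest

from gcim import (
    SimulationConfig,
    fill_expected,
    insert_pseudo_markers,
    simulate,
)


@pytest.fixture(scope="session")
def single_qtl_run():
    """One simulated single-QTL population (r2 = 0.2) on the 1 cM scan grid."""
    cfg = SimulationConfig(n=400, qtl=((1000.0, 0.2),), seed=11)
    data = simulate(cfg)
    grid = insert_pseudo_markers(data.gmap, 1.0)
    filled = fill_expected(data.geno, grid)
    return data, grid, filled


@pytest.fixture(scope="session")
def null_run():
    """One pure-noise population on the true-marker grid."""
    cfg = SimulationConfig(n=400, qtl=(), seed=7)
    data = simulate(cfg)
    filled = fill_expected(data.geno, data.gmap)
    return data, filled
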