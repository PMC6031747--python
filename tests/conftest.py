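import numpy as np
import pytest

from topochip.synthetic_screen import SynthConfig, simulate_screen
from topochip.topo_design import build_chip_layout, generate_catalog


@pytest.fixture(scope="session")
def small_catalog():
    """48 designs at 1 um resolution; fits a 10x10 grid with 4 flat wells."""
    designs, features = generate_catalog(n_unique=48, seed=42, resolution_um=1.0)
    return designs, features


@pytest.fixture(scope="session")
def small_layout(small_catalog):
    designs, _ = small_catalog
    unit_ids = [d.unit_id for d in designs if not d.is_flat]
    return build_chip_layout(48, seed=42, grid_shape=(10, 10), unit_ids=unit_ids)


@pytest.fixture(scope="session")
def small_screen(small_layout):
    """A 4-chip null screen on the small layout (~3600 cells)."""
    cfg = SynthConfig(n_chips=4, master_seed=7, effect_high=0.0, effect_low=0.0)
    return simulate_screen(cfg, small_layout)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
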