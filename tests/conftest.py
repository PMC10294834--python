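import numpy as np
import pytest

from habrisk.geodata import Grid, GridSpec
from habrisk.synthgen import SynthConfig, generate_study_system


@pytest.fixture
def small_spec() -> GridSpec:
    """10x10 grid, 10 m cells, top-left origin at (0, 100)."""
    return GridSpec(n_rows=10, n_cols=10, origin_x=0.0, origin_y=100.0, cell_size=10.0)


@pytest.fixture
def flat_dem(small_spec) -> Grid:
    return Grid(small_spec, np.full(small_spec.shape, 100.0))


def small_config(seed: int = 7, **overrides) -> SynthConfig:
    """A reduced study system: 96x96 grid, fewer points, same structure."""
    defaults = dict(
        n_rows=96,
        n_cols=96,
        seed=seed,
        presence_counts={"G_brevicaudus": 250, "G_ussuriensis": 400, "G_saxatilis": 60},
        n_pseudo_absences=1200,
        n_regions=16,
        n_trails=4,
        trail_steps=150,
        n_parks=3,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_system():
    """One shared small study system for tests that only read from it."""
    return generate_study_system(small_config())
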