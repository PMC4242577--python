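import numpy as np
import pytest

from cphylo.raster import RasterGrid


@pytest.fixture
def small_grid():
    """2x2 half-degree grid with simple values."""
    return RasterGrid(
        n_rows=2, n_cols=2, x_origin=-120.0, y_origin=45.0, cell_size=0.5,
        values=np.array([[1.0, 2.0], [3.0, 4.0]]),
    )


@pytest.fixture
def climate_stack():
    """Deterministic 40x50 synthetic climate stack with 3 variables."""
    from cphylo.simulate import make_climate_stack

    return make_climate_stack(seed=11, n_rows=40, n_cols=50, n_vars=3)


@pytest.fixture(scope="session")
def morph_tables():
    """Replicated categorical morphology table (130 rows) with labels."""
    from cphylo.datasets import morph_spec
    from cphylo.simulate import sample_morphology

    cont, cat, labels = sample_morphology(morph_spec(), seed=7)
    return cont, cat, labels
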