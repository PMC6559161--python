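import numpy as np
import pytest

from bgscale import (CommunitySpec, ElevationRaster, PlotCommunity, SurfaceSpec,
                     generate_elevation_surface, generate_plot_network)


@pytest.fixture
def flat_raster():
    """5x5 projected raster, 1 km cells, constant 100 m elevation."""
    return ElevationRaster(origin=(0.0, 5000.0), cell_size=1000.0,
                           values=np.full((5, 5), 100.0))


@pytest.fixture
def ramp_raster():
    """3x3 raster with 1 m cells and values 1..9 row-major (hand-checkable)."""
    return ElevationRaster(origin=(0.0, 3.0), cell_size=1.0,
                           values=np.arange(1.0, 10.0).reshape(3, 3))


@pytest.fixture
def three_plot_fixture(flat_raster):
    """Worked 3-plot neighbourhood: compositions {A:1}, {B:1}, {A:1} within 5 km.

    Pooled shares (2/3, 1/3) give gamma = exp(-(2/3)ln(2/3) - (1/3)ln(1/3))
    = 1.8899; pairwise Bray-Curtis values (1, 0, 1) give beta = 2/3.
    """
    plots = [
        PlotCommunity("p1", 1000.0, 1000.0, {"A": 1.0}),
        PlotCommunity("p2", 2000.0, 1000.0, {"B": 1.0}),
        PlotCommunity("p3", 1000.0, 2000.0, {"A": 1.0}),
    ]
    return plots, flat_raster


@pytest.fixture
def small_surface():
    """Seeded 96x96 fractal surface at 500 m cells (48 km on a side)."""
    return generate_elevation_surface(
        SurfaceSpec(nx=96, ny=96, cell_size=500.0, spectral_exponent=2.2,
                    sd_target=500.0, seed=11))


@pytest.fixture
def random_neighborhood_plots(small_surface):
    """A seeded niche-filtered plot network for property tests."""
    spec = CommunitySpec(n_plots=120, region=(2000, 2000, 46000, 46000),
                        pool_size=40, niche_breadth=200.0, seed=21)
    return generate_plot_network(spec, small_surface)
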