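"""Canonical desk-scale experiment configurations.

Two study designs used by the test suite, the acceptance script and the
worked examples. Both place plots on a 1,000 x 1,000 km region (a
western-US-sized study area) with a 100 km edge buffer and 100 km
minimum separation, giving spatially thinned subsamples of roughly
40-50 plots.

* The *null* design switches the diversity-heterogeneity mechanism off:
  ``heterogeneity_effect = 0`` and a niche breadth ten times the terrain
  SD, so suitability is essentially flat in elevation and neither the
  breadth-inflation mechanism nor elevation sorting couples diversity to
  terrain. Standardized-slope intervals should cover zero.
* The *signal* design uses a narrow niche breadth (100 m) with a strong
  breadth inflation (2 m of breadth per metre of local elevation SD), a
  large pool and modest abundance noise, so plots in rugged terrain
  support several-fold more species. Median standardized slopes for
  gamma (and beta at the larger radii) should be positive.
"""

from __future__ import annotations

from .pipeline import RunConfig
from .synthetic import CommunitySpec, SurfaceSpec

REGION_KM = 1000.0
_SURFACE = dict(nx=1000, ny=1000, cell_size=1000.0, spectral_exponent=2.2,
                sd_target=500.0, mean_elev=1000.0)
_REGION = (0.0, 0.0, REGION_KM * 1000.0, REGION_KM * 1000.0)


def null_calibration_config(master_seed: int, n_plots: int = 200,
                            n_replicates: int = 200,
                            radii_km=(5.0, 10.0, 20.0),
                            forms=("gamma",)) -> RunConfig:
    """Mechanism off: elevation-indifferent communities (broad niches)."""
    return RunConfig(
        mode="synthetic",
        surface=SurfaceSpec(**_SURFACE),
        community=CommunitySpec(
            n_plots=n_plots, region=_REGION, pool_size=120,
            niche_breadth=10.0 * _SURFACE["sd_target"],
            abundance_lognorm_sigma=0.5, heterogeneity_effect=0.0),
        radii_km=radii_km, edge_buffer_km=100.0, min_separation_km=100.0,
        n_replicates=n_replicates, master_seed=master_seed, forms=forms,
    )


def signal_detection_config(master_seed: int, n_plots: int = 5500,
                            n_replicates: int = 200,
                            radii_km=(5.0, 10.0, 20.0),
                            forms=("alpha", "beta", "gamma")) -> RunConfig:
    """Mechanism on: narrow niches, strong heterogeneity-driven breadth inflation."""
    return RunConfig(
        mode="synthetic",
        surface=SurfaceSpec(**_SURFACE),
        community=CommunitySpec(
            n_plots=n_plots, region=_REGION, pool_size=120,
            niche_breadth=100.0, abundance_lognorm_sigma=0.5,
            heterogeneity_effect=2.0),
        radii_km=radii_km, edge_buffer_km=100.0, min_separation_km=100.0,
        n_replicates=n_replicates, master_seed=master_seed, forms=forms,
    )
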