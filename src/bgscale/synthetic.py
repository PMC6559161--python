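"""Synthetic terrain, plot networks and regression responses.

Real forest-inventory coordinates are access-restricted and a continental
DEM is far too large to ship, so every downstream stage is exercised on
synthetic data with known structure:

* ``generate_elevation_surface`` — a Gaussian random field built by
  spectral synthesis: iid Gaussian Fourier coefficients damped by
  ``frequency ** (-spectral_exponent / 2)``, inverse-transformed, then
  affinely rescaled so the marginal mean and SD are hit exactly. Larger
  spectral exponents give smoother, longer-range terrain.
* ``generate_plot_network`` — uniform plot locations whose communities
  arise by Gaussian niche filtering on elevation: each species in the
  pool has an elevation optimum, suitability decays with squared
  elevation distance over a niche breadth, presence is a Bernoulli thin
  of suitability and realised basal area is suitability times a
  lognormal draw. A positive ``heterogeneity_effect`` widens the local
  niche breadth in proportion to the SD of elevation within a fixed
  1 km window, so plots in rugged terrain sample more of the pool — a
  known, tunable diversity-heterogeneity link for parameter recovery.
* ``generate_response_table`` — draws straight from the two fitted
  model families (gamma with log link; beta with logit link), so the
  regression machinery can be tested independently of any community
  mechanism.

All three are bit-reproducible from their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodiversity import CircularWindow, sd_elevation, window_values
from .io import ElevationRaster, PlotCommunity

LOCAL_SD_WINDOW_KM = 1.0  # window for the heterogeneity-driven breadth inflation


@dataclass
class SurfaceSpec:
    nx: int = 256
    ny: int = 256
    cell_size: float = 1000.0          # metres per cell
    spectral_exponent: float = 2.5     # power-spectrum slope; higher = smoother
    sd_target: float = 500.0           # marginal SD of elevation, metres
    mean_elev: float = 1000.0          # metres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("nx and ny must be >= 2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.sd_target < 0:
            raise ValueError("sd_target must be >= 0")


@dataclass
class CommunitySpec:
    n_plots: int = 2000
    region: tuple[float, float, float, float] = (0.0, 0.0, 256000.0, 256000.0)
    pool_size: int = 50                # tree species in the regional pool
    niche_breadth: float = 250.0       # Gaussian niche SD on elevation, metres
    abundance_lognorm_sigma: float = 1.0
    heterogeneity_effect: float = 0.0  # breadth inflation per metre of local SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be > 0")


@dataclass
class ResponseSpec:
    family: str = "gamma-log"          # or "beta-logit"
    beta0: float = 0.5
    beta1: float = 0.005
    shape_or_precision: float = 10.0   # gamma shape nu, or beta precision phi
    n: int = 500
    x_range: tuple[float, float] = (0.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("gamma-log", "beta-logit"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.shape_or_precision <= 0:
            raise ValueError("shape_or_precision must be > 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def generate_elevation_surface(spec: SurfaceSpec) -> ElevationRaster:
    """Fractal elevation surface via Fourier spectral synthesis."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    white = rng.standard_normal((spec.ny, spec.nx))
    fy = np.fft.fftfreq(spec.ny)[:, None]
    fx = np.fft.fftfreq(spec.nx)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-spec.spectral_exponent / 2.0)
    field = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    sd = field.std()
    if spec.sd_target == 0 or sd == 0:
        values = np.full((spec.ny, spec.nx), float(spec.mean_elev))
    else:
        values = (field - field.mean()) / sd * spec.sd_target + spec.mean_elev
    origin = (0.0, spec.ny * spec.cell_size)
    return ElevationRaster(origin=origin, cell_size=spec.cell_size, values=values)


def generate_plot_network(spec: CommunitySpec, raster: ElevationRaster) -> list[PlotCommunity]:
    """Seeded plot network with niche-filtered communities on the surface.

    Plots that land on nodata cells or end up with an empty community are
    dropped (every retained plot has at least one species).
    """
    x0, y0, x1, y1 = spec.region
    bx0, by0, bx1, by1 = raster.bounds()
    if not (bx0 <= x0 and bx1 >= x1 and by0 <= y0 and by1 >= y1):
        raise ValueError(
            f"region {spec.region} extends outside raster footprint {raster.bounds()}")

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    xs = rng.uniform(x0, x1, spec.n_plots)
    ys = rng.uniform(y0, y1, spec.n_plots)

    finite = raster.values[~np.isnan(raster.values)]
    emin, emax = float(finite.min()), float(finite.max())
    optima = rng.uniform(emin, emax, spec.pool_size)
    species = [f"S{k:03d}" for k in range(spec.pool_size)]

    plots: list[PlotCommunity] = []
    for i in range(spec.n_plots):
        # draw per-plot random numbers unconditionally: RNG stream does not
        # depend on data-driven branches, so outputs are seed-stable
        u = rng.random(spec.pool_size)
        lognorm = rng.lognormal(0.0, spec.abundance_lognorm_sigma, spec.pool_size)
        elev = raster.value_at(xs[i], ys[i])
        if np.isnan(elev):
            continue
        breadth = spec.niche_breadth
        if spec.heterogeneity_effect > 0:
            vals, _ = window_values(
                raster, CircularWindow((xs[i], ys[i]), LOCAL_SD_WINDOW_KM))
            local_sd = sd_elevation(vals)
            if np.isfinite(local_sd):
                breadth = breadth + spec.heterogeneity_effect * local_sd
        suitability = np.exp(-((elev - optima) ** 2) / (2.0 * breadth**2))
        present = u < suitability
        if not present.any():
            continue
        basal = suitability[present] * lognorm[present]
        abund = {species[k]: float(basal[j])
                 for j, k in enumerate(np.flatnonzero(present))}
        plots.append(PlotCommunity(plot_id=f"P{i:05d}", x=float(xs[i]), y=float(ys[i]),
                                   abundances=abund))
    return plots


def generate_response_table(spec: ResponseSpec) -> pd.DataFrame:
    """(x, y) samples from a gamma-log or beta-logit regression model.

    gamma-log: y ~ Gamma(shape=nu, mean=exp(b0 + b1 x));
    beta-logit: y ~ Beta(mu*phi, (1-mu)*phi), mu = expit(b0 + b1 x).
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    x = rng.uniform(spec.x_range[0], spec.x_range[1], spec.n)
    eta = spec.beta0 + spec.beta1 * x
    if spec.family == "gamma-log":
        mu = np.exp(eta)
        nu = spec.shape_or_precision
        y = rng.gamma(shape=nu, scale=mu / nu)
    else:
        from scipy.special import expit

        mu = expit(eta)
        phi = spec.shape_or_precision
        y = rng.beta(mu * phi, (1.0 - mu) * phi)
        # support is the open interval; exact 0/1 can only arise from
        # floating-point rounding, so nudge such draws back inside
        y = np.clip(y, np.finfo(float).tiny, np.nextafter(1.0, 0.0))
    return pd.DataFrame({"x": x, "y": y})
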