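"""End-to-end orchestration: generate/ingest -> aggregate -> subsample -> fit -> summarize.

A run is described by a :class:`RunConfig`. In synthetic mode the terrain
and plot network are generated in-process with seeds split from
``master_seed``; in files mode they are read from disk. Every replicate,
fit and summary is a pure function of the config plus ``master_seed``, so
repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as bio
from .aggregate import PipelineError, build_scale_table, filter_edge_plots, region_polygon
from .models import (BetaRegression, GammaLogGLM, ScalingSummary,
                     squeeze_unit_interval, summarize_replicates)
from .subsample import replicate_subsamples
from .synthetic import (CommunitySpec, SurfaceSpec, generate_elevation_surface,
                        generate_plot_network)

log = logging.getLogger("bgscale")

DEFAULT_RADII = (5.0, 10.0, 20.0, 50.0, 100.0)
FORMS = ("alpha", "beta", "gamma")


@dataclass
class RunConfig:
    mode: str = "synthetic"                      # synthetic | files
    plots_path: str | None = None
    raster_path: str | None = None
    region_path: str | None = None               # GeoJSON polygon
    out_dir: str | None = None
    radii_km: tuple[float, ...] = DEFAULT_RADII
    edge_buffer_km: float = 100.0
    min_separation_km: float = 100.0
    n_replicates: int = 1000                     # original analysis scale: 100,000
    dissimilarity_variant: str = "basal_area"    # or "proportion"
    master_seed: int = 0
    crs_mode: str = "projected"
    stride: int = 1
    forms: tuple[str, ...] = FORMS
    n_pred_grid: int = 25
    surface: SurfaceSpec | None = None           # synthetic mode only
    community: CommunitySpec | None = None

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii_km)
        if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValueError("radii_km must be positive and sorted ascending")
        self.radii_km = radii
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        unknown = set(self.forms) - set(FORMS)
        if unknown:
            raise ValueError(f"unknown diversity forms {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        for key, spec_cls in (("surface", SurfaceSpec), ("community", CommunitySpec)):
            if isinstance(raw.get(key), dict):
                sub = dict(raw[key])
                if "region" in sub and isinstance(sub["region"], list):
                    sub["region"] = tuple(sub["region"])
                raw[key] = spec_cls(**sub)
        for key in ("radii_km", "forms"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys {sorted(extra)}")
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("surface", "community"):
            if d[key] is not None:
                d[key] = dict(d[key])
        d["radii_km"] = list(self.radii_km)
        d["forms"] = list(self.forms)
        return d


def _derived_seed(master_seed: int, key: int) -> int:
    state = np.random.SeedSequence(master_seed, spawn_key=(key,)).generate_state(1)
    return int(state[0] % (2**31))


def _load_inputs(cfg: RunConfig):
    if cfg.mode == "synthetic":
        surface = cfg.surface or SurfaceSpec()
        community = cfg.community or CommunitySpec(
            region=(0.0, 0.0, surface.nx * surface.cell_size,
                    surface.ny * surface.cell_size))
        surface = dataclasses.replace(surface, seed=_derived_seed(cfg.master_seed, 1))
        community = dataclasses.replace(community, seed=_derived_seed(cfg.master_seed, 2))
        raster = generate_elevation_surface(surface)
        plots = generate_plot_network(community, raster)
        region = region_polygon(community.region)
        return plots, raster, region
    if not cfg.plots_path or not cfg.raster_path:
        raise ValueError("files mode requires plots_path and raster_path")
    plots = bio.read_plot_table(cfg.plots_path)
    raster = bio.read_elevation_raster(cfg.raster_path, crs_mode=cfg.crs_mode)
    if cfg.region_path:
        with open(cfg.region_path) as fh:
            region = region_polygon(json.load(fh))
    else:
        x0, y0, x1, y1 = raster.bounds()
        region = region_polygon((x0, y0, x1, y1))
    return plots, raster, region


def _fit_one(form: str, x: np.ndarray, y: np.ndarray):
    """Fit the family matched to the diversity form; raises on degenerate input."""
    if form == "beta":
        y_raw = y
        if np.any((y <= 0) | (y >= 1)):
            y = squeeze_unit_interval(y, y.size)
            log.debug("beta response touched 0/1; squeeze applied (n=%d)", y.size)
        return BetaRegression(y, x, y_raw=y_raw).fit()
    return GammaLogGLM(y, x).fit()


def fit_replicates(scale_table: pd.DataFrame, replicates, radius_km: float,
                   form: str, n_pred_grid: int = 25):
    """Per-replicate fits of one diversity form at one radius.

    Each replicate's design is its thinned focal plots' (sd_elev, form)
    rows at this radius; rows where either variable is missing are
    dropped for that form only. Returns (summary, n_failed_total).
    """
    sub = scale_table[scale_table["radius_km"] == radius_km].set_index("plot_id")
    x_all = sub["sd_elev"].dropna()
    if x_all.empty:
        raise PipelineError(f"no defined sd_elev at radius {radius_km}")
    x_grid = np.linspace(float(x_all.min()), float(x_all.max()), n_pred_grid)

    fits = []
    n_degenerate = 0
    for rep in replicates:
        rows = sub.reindex(rep.plot_ids)[["sd_elev", form]].dropna()
        x = rows["sd_elev"].to_numpy()
        y = rows[form].to_numpy()
        if x.size < 3 or np.ptp(x) == 0:
            n_degenerate += 1
            continue
        try:
            fits.append(_fit_one(form, x, y))
        except (ValueError, np.linalg.LinAlgError):
            n_degenerate += 1
    if not fits:
        raise PipelineError(
            f"all {len(replicates)} replicates degenerate for form={form!r} "
            f"radius={radius_km}")
    summary = summarize_replicates(fits, x_grid, radius_km=radius_km, form=form)
    summary.n_replicates_failed += n_degenerate
    return summary


def run_pipeline(cfg: RunConfig):
    """Execute the full analysis; returns (scale_table, summaries, report).

    Writes the result CSVs and a JSON run report when ``cfg.out_dir`` is
    set. On a stage failure a manifest naming the failed stage is written
    there before the error propagates.
    """
    report: dict = {"config": cfg.echo(), "counts": {}, "timings_s": {},
                    "seeds": {"master_seed": cfg.master_seed}}
    stage = "load_inputs"
    try:
        t0 = time.perf_counter()
        plots, raster, region = _load_inputs(cfg)
        report["counts"]["plots_read"] = len(plots)
        report["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        log.info("stage=%s seed=%d plots=%d", stage, cfg.master_seed, len(plots))

        stage = "edge_filter"
        t0 = time.perf_counter()
        retained = filter_edge_plots(plots, region, cfg.edge_buffer_km, cfg.crs_mode)
        report["counts"]["plots_retained"] = len(retained)
        report["counts"]["plots_edge_dropped"] = len(plots) - len(retained)
        report["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        log.info("stage=%s retained=%d dropped=%d", stage, len(retained),
                 len(plots) - len(retained))

        stage = "scale_table"
        t0 = time.perf_counter()
        table = build_scale_table(retained, raster, cfg.radii_km, cfg.crs_mode,
                                  cfg.dissimilarity_variant, cfg.stride)
        report["counts"]["scale_table_rows"] = len(table)
        report["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "subsample"
        t0 = time.perf_counter()
        replicates = replicate_subsamples(retained, cfg.min_separation_km,
                                          cfg.n_replicates, cfg.master_seed,
                                          cfg.crs_mode)
        sizes = [len(r.plot_ids) for r in replicates]
        report["counts"]["n_replicates"] = len(replicates)
        report["counts"]["mean_replicate_size"] = float(np.mean(sizes))
        report["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        log.info("stage=%s replicates=%d mean_size=%.1f", stage, len(replicates),
                 float(np.mean(sizes)))

        stage = "fit"
        t0 = time.perf_counter()
        summaries: list[ScalingSummary] = []
        fit_counts = {}
        for radius in cfg.radii_km:
            for form in cfg.forms:
                s = fit_replicates(table, replicates, radius, form, cfg.n_pred_grid)
                summaries.append(s)
                fit_counts[f"{form}@{radius:g}km"] = {
                    "converged": s.n_replicates_used,
                    "failed": s.n_replicates_failed,
                }
        report["counts"]["fits"] = fit_counts
        report["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "write"
        if cfg.out_dir:
            bio.write_results(table, summaries, cfg.out_dir, report=report)
        return table, summaries, report
    except Exception as exc:
        if cfg.out_dir:
            os.makedirs(cfg.out_dir, exist_ok=True)
            manifest = {"failed_stage": stage, "error": str(exc),
                        "config": cfg.echo()}
            with open(os.path.join(cfg.out_dir, "failure_manifest.json"), "w") as fh:
                json.dump(manifest, fh, indent=2)
        if isinstance(exc, (PipelineError, ValueError, bio.FormatError)):
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        raise
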