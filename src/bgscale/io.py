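"""Readers and writers for the formats the pipeline touches.

Plot communities travel as a long-format CSV (one row per plot x species,
basal area in m^2); elevation comes in as an ESRI ASCII grid or a GeoTIFF.
The raster convention is fixed once here: origin at the upper-left corner,
rows stored north to south, and every cell addressed at its centre.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected dialect; message locates the problem."""


@dataclass
class PlotCommunity:
    """One inventory plot: location plus a species -> basal-area (m^2) map.

    Coordinates are metres in projected mode, degrees lon/lat (x=lon, y=lat)
    in geographic mode. Basal areas must be strictly positive; a retained
    plot has at least one species.
    """

    plot_id: str
    x: float
    y: float
    abundances: dict[str, float] = field(default_factory=dict)

    def total_basal_area(self) -> float:
        return float(sum(self.abundances.values()))


@dataclass
class ElevationRaster:
    """Georeferenced elevation grid.

    ``origin`` is the (x, y) of the *upper-left corner* of the grid;
    ``values`` is a (ny, nx) float array with NaN marking nodata; row 0 is
    northernmost. ``cell_size`` is in CRS units (metres when projected,
    degrees when geographic). Cell (i, j) has its centre at
    ``(origin[0] + (j + 0.5) * cell_size, origin[1] - (i + 0.5) * cell_size)``.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0
    crs_mode: str = "projected"  # or "geographic"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.crs_mode not in ("projected", "geographic"):
            raise ValueError(f"unknown crs_mode {self.crs_mode!r}")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        ox, oy = self.origin
        return (ox + (j + 0.5) * self.cell_size, oy - (i + 0.5) * self.cell_size)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        ox, oy = self.origin
        return (ox, oy - self.ny * self.cell_size, ox + self.nx * self.cell_size, oy)

    def value_at(self, x: float, y: float) -> float:
        """Elevation of the cell containing (x, y); NaN outside or on nodata."""
        ox, oy = self.origin
        j = int(np.floor((x - ox) / self.cell_size))
        i = int(np.floor((oy - y) / self.cell_size))
        if not (0 <= i < self.ny and 0 <= j < self.nx):
            return float("nan")
        return float(self.values[i, j])

    def equals(self, other: "ElevationRaster", rtol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.origin, other.origin, rtol=rtol)
            and np.isclose(self.cell_size, other.cell_size, rtol=rtol)
            and np.allclose(self.values, other.values, rtol=rtol, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# Plot CSV (long format: plot_id, x, y, species, basal_area)
# ---------------------------------------------------------------------------

PLOT_COLUMNS = ("plot_id", "x", "y", "species", "basal_area")


def read_plot_table(path: str | os.PathLike) -> list[PlotCommunity]:
    """Read a long-format plot CSV into PlotCommunity records.

    Rows are grouped by plot_id; duplicate (plot, species) rows are summed
    (subplot stems aggregate to plot totals). Zero or negative basal areas
    are rejected with the offending row number.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in PLOT_COLUMNS:
            if col not in header:
                raise FormatError(f"plot table {path}: missing required column {col!r}")
        plots: dict[str, PlotCommunity] = {}
        for rownum, row in enumerate(reader, start=2):  # 1-based incl. header
            pid = row["plot_id"]
            try:
                x, y = float(row["x"]), float(row["y"])
            except (TypeError, ValueError):
                raise FormatError(f"plot table {path} row {rownum}: non-numeric coordinate")
            try:
                ba = float(row["basal_area"])
            except (TypeError, ValueError):
                raise FormatError(
                    f"plot table {path} row {rownum}: non-numeric basal_area {row['basal_area']!r}"
                )
            if not ba > 0:
                raise FormatError(
                    f"plot table {path} row {rownum}: basal_area must be > 0, got {ba}"
                )
            sp = row["species"]
            if pid not in plots:
                plots[pid] = PlotCommunity(plot_id=pid, x=x, y=y)
            plot = plots[pid]
            plot.abundances[sp] = plot.abundances.get(sp, 0.0) + ba
    return list(plots.values())


def write_plot_table(plots: list[PlotCommunity], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLOT_COLUMNS)
        for p in plots:
            for sp in sorted(p.abundances):
                writer.writerow([p.plot_id, repr(p.x), repr(p.y), sp, repr(p.abundances[sp])])


# ---------------------------------------------------------------------------
# Rasters: ESRI ASCII grid and GeoTIFF
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | os.PathLike, crs_mode: str = "projected") -> ElevationRaster:
    """Parse an ESRI ASCII grid (.asc). Nodata cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in header_keys:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"ASCII grid {path}: missing header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    for line in lines[i:]:
        if not line.strip():
            continue
        try:
            rows.append([float(v) for v in line.split()])
        except ValueError:
            raise FormatError(f"ASCII grid {path}: non-numeric data value")
        if len(rows[-1]) != ncols:
            raise FormatError(
                f"ASCII grid {path}: row {len(rows)} has {len(rows[-1])} values, expected {ncols}"
            )
    if len(rows) != nrows:
        raise FormatError(f"ASCII grid {path}: found {len(rows)} data rows, header says {nrows}")
    values = np.array(rows, dtype=float)
    values[values == nodata] = np.nan
    cs = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cs)
    return ElevationRaster(origin=origin, cell_size=cs, values=values, nodata=nodata,
                           crs_mode=crs_mode)


def write_ascii_grid(raster: ElevationRaster, path: str | os.PathLike) -> None:
    v = raster.values.copy()
    v[np.isnan(v)] = raster.nodata
    ox, oy = raster.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.nx}\n")
        fh.write(f"nrows {raster.ny}\n")
        fh.write(f"xllcorner {ox!r}\n")
        fh.write(f"yllcorner {oy - raster.ny * raster.cell_size!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in v:
            fh.write(" ".join(repr(float(x)) for x in row))
            fh.write("\n")


# GeoTIFF georeferencing tag codes (standard GeoTIFF / GDAL conventions)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def read_geotiff(path: str | os.PathLike, crs_mode: str = "projected") -> ElevationRaster:
    """Read a single-band GeoTIFF with ModelPixelScale/ModelTiepoint tags."""
    import tifffile

    try:
        with tifffile.TiffFile(str(path)) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            scale = tags.get(_TAG_PIXEL_SCALE)
            tie = tags.get(_TAG_TIEPOINT)
            nd_tag = tags.get(_TAG_GDAL_NODATA)
            if scale is None or tie is None:
                raise FormatError(f"GeoTIFF {path}: missing georeferencing tags")
            scale_v = [float(v) for v in scale.value]
            tv = [float(v) for v in tie.value]
            nd_raw = None if nd_tag is None else str(nd_tag.value)
    except (tifffile.TiffFileError, OSError) as exc:
        raise FormatError(f"GeoTIFF {path}: unreadable ({exc})")
    sx, sy = scale_v[0], scale_v[1]
    if not np.isclose(sx, sy):
        raise FormatError(f"GeoTIFF {path}: non-square cells ({sx} x {sy}) unsupported")
    # tiepoint maps raster point (I,J) to model point (X,Y); written at (0,0)
    origin = (tv[3] - tv[0] * sx, tv[4] + tv[1] * sy)
    nodata = -9999.0
    if nd_raw is not None:
        try:
            nodata = float(nd_raw.strip("\x00 "))
        except ValueError:
            pass
    if values.ndim != 2:
        raise FormatError(f"GeoTIFF {path}: expected a single band")
    values[values == nodata] = np.nan
    return ElevationRaster(origin=origin, cell_size=sx, values=values, nodata=nodata,
                           crs_mode=crs_mode)


def write_geotiff(raster: ElevationRaster, path: str | os.PathLike) -> None:
    import tifffile

    v = raster.values.astype(np.float64).copy()
    v[np.isnan(v)] = raster.nodata
    ox, oy = raster.origin
    cs = raster.cell_size
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(raster.nodata)),
    ]
    tifffile.imwrite(str(path), v, extratags=extratags)


def read_elevation_raster(path: str | os.PathLike, crs_mode: str = "projected") -> ElevationRaster:
    """Dispatch on extension: .asc/.txt -> ASCII grid, .tif/.tiff -> GeoTIFF."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".asc", ".txt", ".grd"):
        return read_ascii_grid(path, crs_mode=crs_mode)
    if ext in (".tif", ".tiff"):
        return read_geotiff(path, crs_mode=crs_mode)
    raise FormatError(f"unrecognised raster extension {ext!r} for {path}")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ["plot_id", "radius_km", "alpha", "beta", "gamma", "sd_elev",
                  "n_plots_in_radius", "truncated_window"]
SUMMARY_COLUMNS = ["radius_km", "form", "slope_p2.5", "slope_p25", "slope_p50",
                   "slope_p75", "slope_p97.5", "median_pseudo_r2", "n_replicates"]


def write_results(scale_table: pd.DataFrame, scaling_summaries, out_dir: str | os.PathLike,
                  report: dict | None = None) -> dict[str, str]:
    """Write the per-plot-per-radius metrics and per-radius summaries as CSV.

    Returns the paths written. Missing values serialize as empty fields.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    metrics_path = os.path.join(out_dir, "scale_metrics.csv")
    df = scale_table.reindex(columns=METRIC_COLUMNS) if len(scale_table) else \
        pd.DataFrame(columns=METRIC_COLUMNS)
    df.to_csv(metrics_path, index=False, float_format="%.10g")
    paths["metrics"] = metrics_path

    summary_path = os.path.join(out_dir, "scaling_summaries.csv")
    rows = []
    for s in scaling_summaries:
        rows.append({
            "radius_km": s.radius_km, "form": s.form,
            "slope_p2.5": s.slope_percentiles[2.5], "slope_p25": s.slope_percentiles[25],
            "slope_p50": s.slope_percentiles[50], "slope_p75": s.slope_percentiles[75],
            "slope_p97.5": s.slope_percentiles[97.5],
            "median_pseudo_r2": s.median_pseudo_r2, "n_replicates": s.n_replicates_used,
        })
    sdf = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    sdf.to_csv(summary_path, index=False, float_format="%.10g")
    paths["summaries"] = summary_path

    if report is not None:
        report_path = os.path.join(out_dir, "run_report.json")
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        paths["report"] = report_path
    return paths
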