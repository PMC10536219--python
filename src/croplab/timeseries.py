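"""Seasonal index time series: gap restoration, anomaly screening, maxima.

A season of per-date index rasters becomes, per field pixel, one time
series on the day-of-year (DOY) grid of the acquisition plan (nominally 16
dates at a 12-day cadence).  Dates lost to acquisition gaps are restored by
a least-squares cubic polynomial fitted to the observed season; anomalous
pixels are screened per field by the 2-sigma rule; the seasonal maximum and
its DOY summarize each trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely

from croplab.polarimetry import IndexRaster

__all__ = [
    "DateGrid",
    "SeasonalSummary",
    "SeriesDataset",
    "FieldPolygon",
    "TimeSeriesError",
    "InsufficientDataError",
    "ExtrapolationError",
    "fit_seasonal_cubic",
    "restore_gaps",
    "restore_gaps_matrix",
    "two_sigma_filter",
    "two_sigma_mask",
    "seasonal_max",
    "field_maxima",
    "class_maxima_summary",
    "build_dataset",
]


class TimeSeriesError(ValueError):
    """Invalid input to a time-series operation."""


class InsufficientDataError(TimeSeriesError):
    """Too few observed dates to fit the restoration polynomial."""


class ExtrapolationError(TimeSeriesError):
    """A restoration target lies outside the observed DOY span."""


@dataclass(frozen=True)
class DateGrid:
    """Ordered seasonal DOY grid; ``restored`` flags gap-filled dates."""

    doys: np.ndarray
    restored: frozenset = frozenset()

    def __post_init__(self):
        doys = np.asarray(self.doys, dtype=int)
        if doys.ndim != 1 or len(doys) == 0:
            raise TimeSeriesError("DOY grid must be a nonempty 1-D sequence")
        if np.any(np.diff(doys) <= 0):
            raise TimeSeriesError("DOYs must be strictly increasing")
        if doys.min() < 1 or doys.max() > 366:
            raise TimeSeriesError("DOYs must lie in [1, 366]")
        if not frozenset(self.restored) <= set(doys.tolist()):
            raise TimeSeriesError("restored DOYs must belong to the grid")
        object.__setattr__(self, "doys", doys)
        object.__setattr__(self, "restored", frozenset(self.restored))

    def __len__(self) -> int:
        return len(self.doys)

    @property
    def observed_doys(self) -> np.ndarray:
        return np.array([d for d in self.doys if d not in self.restored])


@dataclass(frozen=True)
class SeasonalSummary:
    """Seasonal maximum of one series: value and the (first) DOY reaching it."""

    max_value: float
    max_doy: int


@dataclass(frozen=True)
class FieldPolygon:
    """A labeled agricultural field: polygon plus class and partition tags."""

    field_id: str
    class_label: str
    geometry: shapely.Geometry
    partition: str = "train"


@dataclass
class SeriesDataset:
    """Pixel series table: one row per pixel, one value column per DOY.

    ``frame`` columns: pixel_id, field_id, class_label, partition, row, col,
    then ``d<doy>`` value columns aligned with ``grid.doys``.
    """

    frame: pd.DataFrame
    grid: DateGrid

    @property
    def value_columns(self) -> list[str]:
        return [f"d{d}" for d in self.grid.doys]

    @property
    def values(self) -> np.ndarray:
        return self.frame[self.value_columns].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, partition: str) -> "SeriesDataset":
        return SeriesDataset(
            self.frame[self.frame["partition"] == partition].reset_index(drop=True), self.grid
        )

    def to_wide_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_long(self) -> pd.DataFrame:
        """Long format (pixel_id, field_id, class_label, doy, value)."""
        long = self.frame.melt(
            id_vars=["pixel_id", "field_id", "class_label", "partition"],
            value_vars=self.value_columns,
            var_name="doy",
            value_name="value",
        )
        long["doy"] = long["doy"].str.removeprefix("d").astype(int)
        return long

    @classmethod
    def from_wide_csv(cls, path) -> "SeriesDataset":
        frame = pd.read_csv(path)
        doys = sorted(int(c[1:]) for c in frame.columns if c.startswith("d") and c[1:].isdigit())
        return cls(frame, DateGrid(np.array(doys)))


# --- gap restoration --------------------------------------------------------

def fit_seasonal_cubic(doys: np.ndarray, values: np.ndarray) -> np.polynomial.Polynomial:
    """Least-squares cubic over the season, DOY as the independent variable."""
    doys = np.asarray(doys, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(doys) < 5:
        raise InsufficientDataError(
            f"need >= 5 observed dates to fit a cubic, got {len(doys)}"
        )
    return np.polynomial.Polynomial.fit(doys, values, deg=3)


def restore_gaps(
    observed_doys: Sequence[int],
    observed_values: Sequence[float],
    target_doys: Sequence[int],
) -> np.ndarray:
    """Restore missing dates with one global least-squares cubic.

    A cubic polynomial is fitted to all observed (DOY, value) pairs of the
    season and evaluated at each target DOY.  Targets must lie within the
    observed span (interpolation only); observed values are never altered —
    the caller merges the returned values into the full grid.

    Returns the restored values, one per target DOY.
    """
    obs_d = np.asarray(observed_doys, dtype=float)
    targets = np.asarray(target_doys, dtype=float)
    if targets.size and (targets.min() < obs_d.min() or targets.max() > obs_d.max()):
        raise ExtrapolationError(
            f"restoration targets {target_doys} outside observed span "
            f"[{obs_d.min():.0f}, {obs_d.max():.0f}]"
        )
    poly = fit_seasonal_cubic(obs_d, observed_values)
    return poly(targets)


def restore_gaps_matrix(
    observed_doys: np.ndarray, values: np.ndarray, target_doys: Sequence[int]
) -> np.ndarray:
    """Vectorized cubic restoration for many pixels sharing one date grid.

    ``values`` is (n_pixels, n_observed); returns (n_pixels, n_targets).
    One pseudoinverse of the shared cubic design matrix restores all pixels.
    """
    obs_d = np.asarray(observed_doys, dtype=float)
    targets = np.asarray(target_doys, dtype=float)
    if len(obs_d) < 5:
        raise InsufficientDataError(
            f"need >= 5 observed dates to fit a cubic, got {len(obs_d)}"
        )
    if targets.size and (targets.min() < obs_d.min() or targets.max() > obs_d.max()):
        raise ExtrapolationError("restoration targets outside observed span")
    # center/scale DOY for conditioning, as Polynomial.fit does
    mid = (obs_d.min() + obs_d.max()) / 2.0
    half = (obs_d.max() - obs_d.min()) / 2.0
    design = np.vander((obs_d - mid) / half, 4, increasing=True)
    coeffs = np.linalg.lstsq(design, np.asarray(values, float).T, rcond=None)[0]
    target_design = np.vander((targets - mid) / half, 4, increasing=True)
    return (target_design @ coeffs).T


# --- anomaly screening ------------------------------------------------------

def two_sigma_mask(values: np.ndarray) -> np.ndarray:
    """Per-field 2-sigma anomaly rule; True marks pixels to keep.

    For each date the mean and standard deviation over the field's pixels
    define the 2-sigma interval; a pixel is anomalous iff strictly more than
    half of its dates fall outside that interval.  A single-pixel field is
    kept unconditionally (the dispersion is undefined) with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise TimeSeriesError("expected (n_pixels, n_dates) array")
    n_pixels, n_dates = v.shape
    if n_pixels == 0:
        raise TimeSeriesError("empty field")
    if n_pixels == 1:
        warnings.warn("single-pixel field: 2-sigma screen skipped", stacklevel=2)
        return np.array([True])
    mu = v.mean(axis=0)
    sigma = v.std(axis=0)
    outside = np.abs(v - mu) > 2.0 * sigma
    return outside.sum(axis=1) <= n_dates / 2.0


def two_sigma_filter(
    field_pixels: "SeriesDataset | np.ndarray",
) -> tuple:
    """Partition one field's pixel series into (kept, removed).

    Accepts either a :class:`SeriesDataset` whose rows share one field, or a
    raw (n_pixels, n_dates) array.  Returns objects of the same kind; the
    two parts are disjoint and together restore the input.
    """
    if isinstance(field_pixels, SeriesDataset):
        if field_pixels.frame["field_id"].nunique() > 1:
            raise TimeSeriesError("two_sigma_filter operates on a single field")
        keep = two_sigma_mask(field_pixels.values)
        kept = SeriesDataset(field_pixels.frame[keep].reset_index(drop=True), field_pixels.grid)
        removed = SeriesDataset(
            field_pixels.frame[~keep].reset_index(drop=True), field_pixels.grid
        )
        return kept, removed
    keep = two_sigma_mask(field_pixels)
    return field_pixels[keep], field_pixels[~keep]


# --- seasonal maxima --------------------------------------------------------

def seasonal_max(values: Sequence[float], grid: DateGrid | np.ndarray) -> SeasonalSummary:
    """Seasonal maximum and its DOY (earliest DOY on ties)."""
    doys = grid.doys if isinstance(grid, DateGrid) else np.asarray(grid, int)
    v = np.asarray(values, dtype=float)
    if v.shape != doys.shape:
        raise TimeSeriesError("values and DOY grid lengths differ")
    idx = int(np.argmax(v))  # argmax returns the first maximum: earliest DOY
    return SeasonalSummary(float(v[idx]), int(doys[idx]))


def field_maxima(dataset: SeriesDataset) -> pd.DataFrame:
    """Seasonal maximum of each field's mean series.

    Returns one row per field: field_id, class_label, max_value, max_doy.
    """
    rows = []
    for (fid, label), group in dataset.frame.groupby(["field_id", "class_label"], sort=True):
        mean_series = group[dataset.value_columns].to_numpy(float).mean(axis=0)
        s = seasonal_max(mean_series, dataset.grid)
        rows.append({"field_id": fid, "class_label": label,
                     "max_value": s.max_value, "max_doy": s.max_doy})
    return pd.DataFrame(rows)


def class_maxima_summary(dataset: SeriesDataset) -> pd.DataFrame:
    """Per-class mean +- std of field-level maxima and their DOYs."""
    fm = field_maxima(dataset)
    out = fm.groupby("class_label").agg(
        mean_max=("max_value", "mean"),
        std_max=("max_value", "std"),
        mean_doy=("max_doy", "mean"),
        std_doy=("max_doy", "std"),
        n_fields=("field_id", "count"),
    )
    return out.fillna(0.0).reset_index()


# --- dataset assembly -------------------------------------------------------

def _pixel_centers(shape: tuple, transform: tuple) -> tuple[np.ndarray, np.ndarray]:
    x0, dx, y0, dy = transform
    rows, cols = np.indices(shape)
    return x0 + (cols + 0.5) * dx, y0 + (rows + 0.5) * dy


def build_dataset(
    index_rasters: Sequence[IndexRaster],
    fields: Iterable[FieldPolygon],
    grid: DateGrid | None = None,
    filter_partitions: Sequence[str] = ("train",),
) -> SeriesDataset:
    """Extract labeled per-pixel series from index rasters and field polygons.

    Pixels belong to a field when their center falls inside the polygon
    (zonal-statistics convention).  Dates present in ``grid`` but absent
    from the rasters are restored per pixel by the seasonal cubic; observed
    values are kept verbatim.  The 2-sigma anomaly screen is applied
    per field, only to partitions named in ``filter_partitions`` — screening
    the training sample while leaving test samples intact mirrors standard
    evaluation practice.

    Pixels with any nodata date are dropped before restoration.
    """
    rasters = sorted(index_rasters, key=lambda r: r.doy)
    if not rasters:
        raise TimeSeriesError("no index rasters supplied")
    observed_doys = np.array([r.doy for r in rasters], dtype=int)
    if len(set(observed_doys.tolist())) != len(observed_doys):
        raise TimeSeriesError("duplicate DOYs in raster stack")
    shape = rasters[0].values.shape
    transform = rasters[0].transform
    for r in rasters:
        if r.values.shape != shape or r.transform != transform:
            raise TimeSeriesError("index rasters are not co-registered")
    if grid is None:
        grid = DateGrid(observed_doys)
    missing = np.array([d for d in grid.doys if d not in set(observed_doys.tolist())], int)
    if set(grid.doys.tolist()) - set(observed_doys.tolist()) != set(missing.tolist()):
        raise TimeSeriesError("grid/raster DOY mismatch")

    cube = np.stack([r.values for r in rasters])  # (n_obs, H, W)
    xs, ys = _pixel_centers(shape, transform)

    parts = []
    for f in fields:
        minx, miny, maxx, maxy = f.geometry.bounds
        x0, dx, y0, dy = transform
        # candidate pixel window from polygon bounds (either axis orientation)
        cc = ((np.array([minx, maxx]) - x0) / dx - 0.5).astype(int)
        rr = ((np.array([miny, maxy]) - y0) / dy - 0.5).astype(int)
        c_lo, c_hi = max(min(cc) - 1, 0), min(max(cc) + 2, shape[1])
        r_lo, r_hi = max(min(rr) - 1, 0), min(max(rr) + 2, shape[0])
        if c_lo >= c_hi or r_lo >= r_hi:
            warnings.warn(f"field {f.field_id} outside raster extent", stacklevel=2)
            continue
        sub_rows, sub_cols = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        inside = shapely.contains_xy(
            f.geometry, xs[r_lo:r_hi, c_lo:c_hi].ravel(), ys[r_lo:r_hi, c_lo:c_hi].ravel()
        )
        if not inside.any():
            warnings.warn(f"field {f.field_id} covers no pixel centers", stacklevel=2)
            continue
        rows_f = sub_rows.ravel()[inside]
        cols_f = sub_cols.ravel()[inside]
        series = cube[:, rows_f, cols_f].T  # (n_pix, n_obs)
        valid = ~np.isnan(series).any(axis=1)
        rows_f, cols_f, series = rows_f[valid], cols_f[valid], series[valid]
        if len(series) == 0:
            warnings.warn(f"field {f.field_id} has no valid pixels", stacklevel=2)
            continue

        if missing.size:
            restored = restore_gaps_matrix(observed_doys, series, missing)
        full = np.empty((len(series), len(grid)))
        obs_pos = {d: i for i, d in enumerate(observed_doys.tolist())}
        mis_pos = {d: i for i, d in enumerate(missing.tolist())}
        for j, d in enumerate(grid.doys.tolist()):
            full[:, j] = series[:, obs_pos[d]] if d in obs_pos else restored[:, mis_pos[d]]

        if f.partition in filter_partitions and len(series) > 1:
            keep = two_sigma_mask(full)
        else:
            keep = np.ones(len(series), dtype=bool)

        part = pd.DataFrame(full[keep], columns=[f"d{d}" for d in grid.doys])
        part.insert(0, "col", cols_f[keep])
        part.insert(0, "row", rows_f[keep])
        part.insert(0, "partition", f.partition)
        part.insert(0, "class_label", f.class_label)
        part.insert(0, "field_id", f.field_id)
        part.insert(
            0, "pixel_id",
            [f"{f.field_id}:{r}:{c}" for r, c in zip(rows_f[keep], cols_f[keep])],
        )
        parts.append(part)

    if not parts:
        raise TimeSeriesError("no fields produced any pixel series")
    grid_out = DateGrid(grid.doys, frozenset(missing.tolist()))
    return SeriesDataset(pd.concat(parts, ignore_index=True), grid_out)
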