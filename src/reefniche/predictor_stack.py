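"""Derivation of the environmental predictor rasters.

Eight candidate predictors drive the niche models: bathymetry (m), mean,
variance and range of daily SST (deg C), mean chlorophyll-a (mg m^-3), mean
K490 turbidity (m^-1), mean daily wave energy (kJ m^-2) and distance from
coast (km). This module aggregates the daily stacks, computes distance from
coast, harmonizes every layer onto a common 1-km reef-buffer grid, extracts
values at survey sites, applies the pairwise-correlation predictor
exclusion, and removes sites with incomplete predictor records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .raster import RasterGrid, RasterStack

logger = logging.getLogger(__name__)

#: higher-priority predictors are kept when a pair is too correlated;
#: SST variance is deliberately last so the range/variance pair resolves
#: in favour of SST range.
PREDICTOR_PRIORITY = (
    "bathymetry",
    "sst_mean",
    "sst_range",
    "chla_mean",
    "k490_mean",
    "wave_energy",
    "dist_coast",
    "sst_variance",
)


class InputError(ValueError):
    pass


@dataclass
class PredictorStack:
    """Named predictor layers sharing one grid geometry."""

    layers: dict[str, RasterGrid]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        if not grids:
            raise InputError("empty predictor stack")
        g0 = grids[0]
        for g in grids[1:]:
            if not g0.same_geometry(g):
                raise InputError("predictor layers must share geometry")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.valid_mask()
        return mask


def aggregate_daily(stack: RasterStack, statistic: str) -> RasterGrid:
    """Per-pixel mean / variance / range over a daily stack.

    Per-day nodata is ignored; a pixel is nodata only if every day is
    nodata. Variance is the population variance (ddof = 0); the choice is
    recorded by the caller in layer metadata.
    """
    if len(stack) == 0:
        raise InputError("empty daily stack")
    data = stack.masked()
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-nodata pixels legitimately yield NaN -> nodata below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if statistic == "mean":
            out = np.nanmean(data, axis=0)
        elif statistic == "variance":
            out = np.nanvar(data, axis=0, ddof=0)
        elif statistic == "range":
            out = np.nanmax(data, axis=0) - np.nanmin(data, axis=0)
        else:
            raise InputError(f"unknown statistic {statistic!r}")
    out = np.where(np.isnan(out), stack.nodata, out)
    return RasterGrid(out, stack.cell_size_km, stack.nodata)


def distance_from_coast(land_mask: RasterGrid) -> RasterGrid:
    """Euclidean center-to-center distance (km) from each sea cell to land.

    Computed with the exact Euclidean distance transform, so it equals the
    brute-force minimum over all land-cell centers. Land cells are nodata.
    """
    land = land_mask.data > 0
    if land.all() or not land.any():
        raise InputError("mask needs at least one land and one sea cell")
    dist = ndimage.distance_transform_edt(~land) * land_mask.cell_size_km
    out = dist.copy()
    out[land] = land_mask.nodata
    return RasterGrid(out, land_mask.cell_size_km, land_mask.nodata)


def _resample(layer: RasterGrid, target: RasterGrid, kernel: str) -> np.ndarray:
    """Resample layer data onto the target geometry (planar km coords)."""
    if layer.same_geometry(target):
        return layer.data.copy()
    xs, ys = target.cell_centers()
    # fractional source indices of the target cell centers
    ci = xs / layer.cell_size_km - 0.5
    ri = ys / layer.cell_size_km - 0.5
    src = layer.masked()
    if kernel == "nearest":
        order = 0
    elif kernel == "bilinear":
        order = 1
    else:
        raise InputError(f"unknown resampling kernel {kernel!r}")
    out = ndimage.map_coordinates(
        np.nan_to_num(src, nan=layer.nodata),
        [ri, ci], order=order, mode="nearest",
    )
    # poison any target cell whose source neighbourhood touched nodata
    bad = ndimage.map_coordinates(
        np.isnan(src).astype(float), [ri, ci], order=order, mode="nearest"
    ) > 0
    out[bad] = layer.nodata
    return out


def reef_buffer_mask(
    target: RasterGrid,
    reef_polygons: BaseGeometry | list[BaseGeometry],
    buffer_km: float = 1.0,
) -> np.ndarray:
    """Boolean mask of target cells whose centers fall in the buffered reef."""
    if isinstance(reef_polygons, (list, tuple)):
        reef_polygons = unary_union(list(reef_polygons))
    buffered = reef_polygons.buffer(buffer_km)
    xs, ys = target.cell_centers()
    return contains_xy(buffered, xs.ravel(), ys.ravel()).reshape(target.shape)


def harmonize(
    layers: dict[str, RasterGrid],
    target: RasterGrid,
    reef_polygons: BaseGeometry | list[BaseGeometry],
    buffer_km: float = 1.0,
    kernels: dict[str, str] | None = None,
) -> PredictorStack:
    """Resample every layer to the target grid and clip to the reef buffer.

    Continuous layers are resampled bilinearly, masks by nearest neighbour
    (override per layer via ``kernels``). Cells outside the buffered reef
    polygons are nodata in every layer. Idempotent: harmonizing an already
    harmonized stack changes nothing.
    """
    mask = reef_buffer_mask(target, reef_polygons, buffer_km)
    if not mask.any():
        raise InputError("reef buffer does not intersect the target grid")
    out: dict[str, RasterGrid] = {}
    meta: dict[str, dict] = {}
    for name, layer in layers.items():
        kernel = (kernels or {}).get(name, "bilinear")
        data = _resample(layer, target, kernel)
        data = np.where(mask, data, target.nodata)
        out[name] = RasterGrid(data, target.cell_size_km, target.nodata)
        meta[name] = {"resampling": kernel, "buffer_km": buffer_km}
    return PredictorStack(out, meta)


def extract_at_sites(
    stack: PredictorStack | dict[str, RasterGrid],
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Attach the containing-cell value of every layer to each site.

    Sites outside the grid extent, or on nodata cells, get NaN for that
    layer (NaN doubles as the missing-value flag downstream).
    """
    layers = stack.layers if isinstance(stack, PredictorStack) else stack
    out = sites.copy()
    n_outside = 0
    for name, grid in layers.items():
        row, col = grid.cell_of(out["x"].to_numpy(), out["y"].to_numpy())
        inside = grid.in_bounds(row, col)
        n_outside = max(n_outside, int((~inside).sum()))
        vals = np.full(len(out), np.nan)
        r, c = row[inside], col[inside]
        v = grid.data[r, c]
        v = np.where(np.isclose(v, grid.nodata), np.nan, v)
        vals[inside] = v
        out[name] = vals
    if n_outside:
        logger.warning("%d sites fall outside the grid extent", n_outside)
    return out


def exclude_correlated(
    sites: pd.DataFrame,
    predictors: list[str] | None = None,
    threshold: float = 0.70,
    priority: tuple[str, ...] = PREDICTOR_PRIORITY,
) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Drop the lower-priority member of each over-correlated predictor pair.

    Pearson correlations are computed on complete-case sites. For every
    pair with |r| >= threshold the member further down the priority list is
    dropped. Zero-variance predictors make the correlation undefined; they
    are flagged (returned in the third element) but not silently dropped.

    Returns (retained names, correlation matrix, flagged names).
    """
    if predictors is None:
        predictors = [p for p in priority if p in sites.columns]
    if len(predictors) < 2:
        raise InputError("need at least two predictors")
    complete = sites[predictors].dropna()
    if len(complete) < 3:
        raise InputError("need at least three complete sites")

    flagged = [p for p in predictors if complete[p].nunique() <= 1]
    corr = complete.corr(method="pearson")

    rank = {name: i for i, name in enumerate(priority)}
    dropped: set[str] = set()
    names = [p for p in predictors if p not in flagged]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if a in dropped or b in dropped:
                continue
            if abs(corr.loc[a, b]) >= threshold:
                loser = a if rank.get(a, 1e9) > rank.get(b, 1e9) else b
                dropped.add(loser)
                logger.info(
                    "dropping %s (|r|=%.3f with %s)", loser, corr.loc[a, b],
                    a if loser == b else b)
    retained = [p for p in predictors if p not in dropped]
    return retained, corr, flagged


def drop_incomplete_sites(
    sites: pd.DataFrame,
    predictors: list[str],
) -> tuple[pd.DataFrame, dict]:
    """Remove sites missing any retained predictor; report the accounting.

    The report gives per-predictor missing counts and the size of their
    union (the number of sites actually removed), which is at most the sum
    of the per-predictor counts because one site can miss several layers.
    """
    missing = sites[predictors].isna()
    per_predictor = {p: int(missing[p].sum()) for p in predictors}
    union = missing.any(axis=1)
    report = {
        "n_input": int(len(sites)),
        "per_predictor_missing": per_predictor,
        "n_removed": int(union.sum()),
        "n_retained": int((~union).sum()),
    }
    return sites.loc[~union].reset_index(drop=True), report


def derive_predictors(reefscape, wave_energy_grid: RasterGrid) -> dict[str, RasterGrid]:
    """Assemble the eight raw predictor layers from a generated reef-scape."""
    env = reefscape.env
    return {
        "bathymetry": reefscape.bathymetry,
        "sst_mean": aggregate_daily(env.sst, "mean"),
        "sst_variance": aggregate_daily(env.sst, "variance"),
        "sst_range": aggregate_daily(env.sst, "range"),
        "chla_mean": aggregate_daily(env.chla, "mean"),
        "k490_mean": aggregate_daily(env.k490, "mean"),
        "wave_energy": wave_energy_grid,
        "dist_coast": reefscape.dist_coast,
    }
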