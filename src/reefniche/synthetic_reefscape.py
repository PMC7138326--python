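"""Seeded synthetic reef-scape and virtual-species occurrence generator.

Real coral survey programmes record presence/absence of many species at
hundreds of dive sites strung along a coast-parallel reef tract, together
with satellite-derived daily environmental fields. This module emulates that
statistical shape end-to-end from a single seed: a coastline on the western
grid edge, an offshore reef band split into contiguous subregions,
bathymetry deepening away from the coast, daily SST with a seasonal
sinusoid and a spatial gradient, daily chlorophyll-a and K490 turbidity
decaying offshore, a daily wind climate, and virtual species whose
occurrence probabilities are known logistic functions of the predictors.

Because the true species-environment response is known by construction,
downstream model-recovery tests have an exact ground truth: a fitted niche
model should rank a species' true driver predictors above the unused ones
and recover the shape of each response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .raster import NODATA, RasterGrid, RasterStack

TermShape = Literal["linear", "unimodal", "step"]

#: canonical predictor layer names used throughout the pipeline
PREDICTOR_NAMES = (
    "bathymetry",
    "sst_mean",
    "sst_variance",
    "sst_range",
    "chla_mean",
    "k490_mean",
    "wave_energy",
    "dist_coast",
)


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class ReefScapeConfig:
    """Knobs of the synthetic reef-scape.

    Defaults mirror the scale of the emulated survey: ~1000 sites on a
    1-km grid, a daily environmental record, ten subregions.
    """

    grid_nrows: int = 80
    grid_ncols: int = 120
    cell_size_km: float = 1.0
    n_days: int = 365
    n_sites: int = 1000
    n_subregions: int = 10
    seed: int = 0
    missingness_rates: dict[str, float] = field(default_factory=dict)
    # environmental shape parameters
    sst_base: float = 26.0            # deg C at the northern (top) edge
    sst_lat_gradient: float = 1.5     # deg C added from top row to bottom row
    sst_amplitude: float = 3.0        # seasonal sinusoid amplitude, deg C
    sst_amplitude_spatial_sd: float = 0.25  # relative spatial spread of amplitude
    sst_noise_sd: float = 0.0         # per-day, per-pixel noise, deg C
    wind_mean_speed: float = 8.0      # m/s
    wind_prevailing_deg: float = 90.0  # meteorological "blowing from" bearing
    wind_direction_kappa: float = 0.8  # von Mises concentration
    wind_speed_spatial_sd: float = 0.25  # persistent exposure modulation
    coast_width_cells: int = 6
    reef_inner_km: float = 4.0
    reef_outer_km: float = 10.0

    def validate(self) -> None:
        if min(self.grid_nrows, self.grid_ncols, self.n_days, self.n_sites,
               self.n_subregions) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.cell_size_km <= 0:
            raise ConfigurationError("cell_size_km must be positive")
        for name, rate in self.missingness_rates.items():
            if not 0 <= rate < 1:
                raise ConfigurationError(
                    f"missingness rate for {name!r} must be in [0, 1)")


@dataclass
class ResponseTerm:
    """One additive term of a species' logit response to a predictor."""

    predictor: str
    shape: TermShape
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTOR_NAMES:
            raise ConfigurationError(f"unknown predictor {self.predictor!r}")
        required = {
            "linear": {"coef"},
            "unimodal": {"optimum", "width", "height"},
            "step": {"cut", "height"},
        }[self.shape]
        if not required <= set(self.params):
            raise ConfigurationError(
                f"{self.shape} term needs parameters {sorted(required)}")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.shape == "linear":
            return p["coef"] * x
        if self.shape == "unimodal":
            return p["height"] * np.exp(
                -((x - p["optimum"]) ** 2) / (2.0 * p["width"] ** 2))
        return p["height"] * (x >= p["cut"]).astype(float)


@dataclass
class SpeciesResponseSpec:
    """Ground-truth logistic response of one virtual species.

    ``logit p = intercept + sum(term(x))``; the intercept is normally left
    ``None`` and calibrated so the mean occurrence probability over the
    generated sites equals ``target_prevalence``.
    """

    species_name: str
    terms: list[ResponseTerm]
    target_prevalence: float
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ConfigurationError("target_prevalence must be in (0, 1)")

    def linear_predictor(self, predictors: pd.DataFrame) -> np.ndarray:
        score = np.zeros(len(predictors), dtype=float)
        for term in self.terms:
            score += term.evaluate(predictors[term.predictor].to_numpy())
        return score

    def probabilities(self, predictors: pd.DataFrame) -> np.ndarray:
        if self.intercept is None:
            raise GenerationError("intercept not calibrated")
        return expit(self.intercept + self.linear_predictor(predictors))


@dataclass
class DailyEnvironmentalSeries:
    """Daily raster stacks of the raw environmental inputs."""

    sst: RasterStack            # deg C
    chla: RasterStack           # mg m^-3
    k490: RasterStack           # m^-1
    wind_speed: RasterStack     # m s^-1
    wind_direction: RasterStack  # degrees, meteorological ("blowing from")


@dataclass
class ReefScape:
    """Bundle of the generated static layers."""

    config: ReefScapeConfig
    land_mask: RasterGrid       # 1 = land, 0 = sea
    reef_mask: RasterGrid       # 1 = reef band cell
    subregions: RasterGrid      # integer label 1..n on reef band, nodata off
    bathymetry: RasterGrid      # depth in m, positive down; land = nodata
    dist_coast: RasterGrid      # km from nearest land-cell center
    env: DailyEnvironmentalSeries

    @property
    def subregion_names(self) -> list[str]:
        n = self.config.n_subregions
        return [f"subregion_{i:02d}" for i in range(1, n + 1)]


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float = 3.0
) -> np.ndarray:
    """Standardized smooth Gaussian random field (mean 0, sd 1).

    Each environmental layer gets its own independent field so that the
    predictors are only moderately inter-correlated, as in real reef
    tracts where only SST variance and SST range are near-collinear.
    """
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.normal(size=shape), sigma_cells, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def _coast_columns(cfg: ReefScapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Width of the western land strip per row (contiguous coast).

    Stationary smoothed noise around the base width — a random-walk coast
    would drift systematically along the tract and induce spurious
    along-shore trends in fetch and wave energy.
    """
    from scipy.ndimage import gaussian_filter1d

    wiggle = gaussian_filter1d(
        rng.normal(0.0, 1.0, size=cfg.grid_nrows), 2.0, mode="nearest")
    sd = wiggle.std() or 1.0
    width = np.rint(cfg.coast_width_cells + 2.0 * wiggle / sd).astype(int)
    hi = max(2, min(cfg.coast_width_cells + 3, cfg.grid_ncols - 12))
    return np.clip(width, 1, hi)


def generate_reefscape(config: ReefScapeConfig) -> ReefScape:
    """Generate all static and daily layers from the seeded configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nr, nc, cs = config.grid_nrows, config.grid_ncols, config.cell_size_km

    width = _coast_columns(config, rng)
    land = np.zeros((nr, nc), dtype=float)
    for r in range(nr):
        land[r, : width[r]] = 1.0
    land_mask = RasterGrid(land, cs)

    # distance from coast (km), land cells nodata
    from .predictor_stack import distance_from_coast  # local: avoids cycle

    dist = distance_from_coast(land_mask)
    dist_arr = dist.masked()

    reef = (
        (dist_arr >= config.reef_inner_km) & (dist_arr <= config.reef_outer_km)
    ).astype(float)
    reef[np.isnan(dist_arr)] = 0.0
    if reef.sum() == 0:
        raise GenerationError("reef band is empty; widen the grid")
    reef_mask = RasterGrid(reef, cs)

    # subregions: contiguous row blocks of the reef band
    sub = np.full((nr, nc), NODATA)
    reef_rows = np.where(reef.any(axis=1))[0]
    if len(reef_rows) < config.n_subregions:
        raise GenerationError("fewer reef rows than requested subregions")
    blocks = np.array_split(reef_rows, config.n_subregions)
    for i, block in enumerate(blocks, start=1):
        for r in block:
            sub[r, reef[r] > 0] = i
    subregions = RasterGrid(sub, cs)

    # bathymetry: deepens with distance from coast, plus a smooth seeded
    # relief field so depth is not a deterministic function of distance
    relief = _smooth_field(rng, (nr, nc))
    depth = 0.8 * dist_arr + 4.0 + 3.5 * relief
    depth = np.clip(depth, 0.3, None)
    depth[np.isnan(dist_arr)] = NODATA
    bathymetry = RasterGrid(np.nan_to_num(depth, nan=NODATA), cs)

    # daily SST: base with latitudinal gradient; seasonal amplitude varies
    # smoothly across the tract so per-pixel range differs cell to cell
    rows = np.arange(nr)[:, None] / max(nr - 1, 1)
    base = config.sst_base + config.sst_lat_gradient * rows
    base = np.broadcast_to(base, (nr, nc)).copy()
    amp_field = _smooth_field(rng, (nr, nc))
    amp = config.sst_amplitude * np.clip(
        1.0 + config.sst_amplitude_spatial_sd * amp_field, 0.1, None)
    # the seasonal cycle spans the record when it is shorter than a year,
    # so short test records still see the full per-pixel range
    period = min(config.n_days, 365)
    days = np.arange(config.n_days)
    phase = np.sin(2.0 * np.pi * days / period)
    sst = base[None] + amp[None] * phase[:, None, None]
    if config.sst_noise_sd > 0:
        sst = sst + rng.normal(0.0, config.sst_noise_sd, size=sst.shape)
    sst = np.clip(sst, 10.0, 35.0)
    sea = land == 0
    sst[:, ~sea] = NODATA

    # chlorophyll-a and K490: offshore exponential decay modulated by
    # independent smooth water-quality fields, plus daily lognormal flutter
    d0 = np.nan_to_num(dist_arr, nan=0.0)
    chla_base = (0.05 + 0.45 * np.exp(-d0 / 8.0)) * np.exp(
        0.6 * _smooth_field(rng, (nr, nc)))
    k490_base = (0.04 + 0.15 * np.exp(-d0 / 6.0)) * np.exp(
        0.5 * _smooth_field(rng, (nr, nc)))
    chla = chla_base[None] * rng.lognormal(0.0, 0.25, size=(config.n_days, 1, 1))
    k490 = k490_base[None] * rng.lognormal(0.0, 0.20, size=(config.n_days, 1, 1))
    chla = np.broadcast_to(chla, (config.n_days, nr, nc)).copy()
    k490 = np.broadcast_to(k490, (config.n_days, nr, nc)).copy()
    chla[:, ~sea] = NODATA
    k490[:, ~sea] = NODATA

    # wind: one (speed, direction) pair per day; daily speeds are modulated
    # by a persistent spatial exposure field (sheltered vs exposed water)
    speeds = rng.gamma(4.0, config.wind_mean_speed / 4.0, size=config.n_days)
    dirs = np.degrees(
        rng.vonmises(math.radians(config.wind_prevailing_deg) - math.pi,
                     config.wind_direction_kappa, size=config.n_days)
        + math.pi
    ) % 360.0
    exposure = np.clip(
        1.0 + config.wind_speed_spatial_sd * _smooth_field(rng, (nr, nc)),
        0.1, None)
    wind_speed = speeds[:, None, None] * exposure[None]
    wind_dir = np.broadcast_to(
        dirs[:, None, None], (config.n_days, nr, nc)).copy()

    env = DailyEnvironmentalSeries(
        sst=RasterStack(sst, cs),
        chla=RasterStack(chla, cs),
        k490=RasterStack(k490, cs),
        wind_speed=RasterStack(wind_speed, cs),
        wind_direction=RasterStack(wind_dir, cs),
    )
    return ReefScape(
        config=config,
        land_mask=land_mask,
        reef_mask=reef_mask,
        subregions=subregions,
        bathymetry=bathymetry,
        dist_coast=dist,
        env=env,
    )


def calibrate_intercept(
    spec: SpeciesResponseSpec,
    predictors: pd.DataFrame,
    tol: float = 1e-8,
) -> float:
    """Solve for the intercept that hits the target mean probability.

    Bisection on c in ``mean(expit(c + score)) = target_prevalence``; the
    mean probability is strictly increasing in c, so the root is unique.
    """
    score = spec.linear_predictor(predictors)

    def mean_p(c: float) -> float:
        return float(np.mean(expit(c + score)))

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < spec.target_prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def sample_reef_sites(
    config: ReefScapeConfig,
    reef_mask: RasterGrid,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Uniform site locations within the reef band (jittered in-cell)."""
    rows, cols = np.where(reef_mask.data > 0)
    if len(rows) == 0:
        raise GenerationError("empty reef band")
    pick = rng.integers(0, len(rows), size=config.n_sites)
    cs = config.cell_size_km
    x = (cols[pick] + rng.random(config.n_sites)) * cs
    y = (rows[pick] + rng.random(config.n_sites)) * cs
    return pd.DataFrame(
        {"site_id": np.arange(config.n_sites), "x": x, "y": y}
    )


def generate_sites(
    config: ReefScapeConfig,
    reef_mask: RasterGrid,
    predictor_layers: dict[str, RasterGrid],
    specs: Sequence[SpeciesResponseSpec],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw survey sites and species presence/absence with known truth.

    Sites are uniform over the reef band; each species' presence is
    Bernoulli with logit p given by its response spec evaluated at the
    site's (true, pre-missingness) predictor values. Missing values are
    then injected into the *recorded* predictor columns at the configured
    per-predictor rates (as NaN), leaving the presence draws untouched.
    """
    if not specs:
        raise GenerationError("no species response specs supplied")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    sites = sample_reef_sites(config, reef_mask, rng)

    from .predictor_stack import extract_at_sites  # local: avoids cycle

    sites = extract_at_sites(predictor_layers, sites)

    truth = sites[list(predictor_layers)].copy()
    # sites can straddle the band edge after jitter; fill for the truth only
    truth = truth.fillna(truth.mean(numeric_only=True))

    for spec in specs:
        if spec.intercept is None:
            spec.intercept = calibrate_intercept(spec, truth)
        p = spec.probabilities(truth)
        sites[spec.species_name] = (
            rng.random(len(sites)) < p).astype(int)

    for name, rate in config.missingness_rates.items():
        if name in sites.columns and rate > 0:
            hit = rng.random(len(sites)) < rate
            sites.loc[hit, name] = np.nan

    return sites


def two_driver_site_table(
    n_sites: int = 1000,
    n_predictors: int = 7,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Stand-alone virtual species driven by exactly two predictors.

    Predictors are iid standard normals (columns ``pred_0..pred_k``); the
    species responds linearly to ``pred_0`` (coefficient 3) and unimodally
    to ``pred_1`` (Gaussian bump of height 5 at 0.5, width 0.6), logit
    intercept -3. The construction is strongly separable (true-model AUC
    ~0.93), so a sound model-fitting procedure must recover both drivers
    at the top of the influence ranking and score well out of sample.

    Returns the site table (predictors plus a ``species`` 0/1 column) and
    the two driver column names.
    """
    rng = np.random.default_rng(seed)
    cols = [f"pred_{j}" for j in range(n_predictors)]
    X = pd.DataFrame(rng.normal(size=(n_sites, n_predictors)), columns=cols)
    logit_p = (
        3.0 * X["pred_0"]
        + 5.0 * np.exp(-((X["pred_1"] - 0.5) ** 2) / (2 * 0.6**2))
        - 3.0
    )
    X["species"] = (rng.random(n_sites) < expit(logit_p)).astype(int)
    return X, ["pred_0", "pred_1"]


def default_species_specs() -> list[SpeciesResponseSpec]:
    """Virtual species with contrasting drivers, shapes and prevalences."""
    return [
        SpeciesResponseSpec(
            "virtual_generalist",
            [ResponseTerm("dist_coast", "linear", {"coef": 0.25})],
            target_prevalence=0.60,
        ),
        SpeciesResponseSpec(
            "virtual_thermal_specialist",
            [
                ResponseTerm("sst_range", "unimodal",
                             {"optimum": 4.5, "width": 0.8, "height": 4.0}),
                ResponseTerm("k490_mean", "unimodal",
                             {"optimum": 0.20, "width": 0.05, "height": 3.0}),
            ],
            target_prevalence=0.15,
        ),
        SpeciesResponseSpec(
            "virtual_deep_step",
            [ResponseTerm("bathymetry", "step", {"cut": 12.0, "height": 3.0})],
            target_prevalence=0.35,
        ),
    ]
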