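import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefniche.predictor_stack import (
    InputError,
    aggregate_daily,
    distance_from_coast,
    drop_incomplete_sites,
    exclude_correlated,
    extract_at_sites,
    harmonize,
    reef_buffer_mask,
)
from reefniche.raster import NODATA, RasterGrid, RasterStack
from shapely.geometry import box


# --- daily aggregation -----------------------------------------------------

def test_constant_series_has_zero_range_and_variance():
    day = np.full((4, 5), 23.5)
    stack = RasterStack(np.stack([day] * 6))
    assert np.all(aggregate_daily(stack, "range").data == 0)
    assert np.all(aggregate_daily(stack, "variance").data == 0)
    np.testing.assert_array_equal(aggregate_daily(stack, "mean").data, day)


def test_pixel_range_is_max_minus_min():
    stack = RasterStack(np.array([[[24.0]], [[26.0]], [[31.0]]]))
    assert aggregate_daily(stack, "range").data[0, 0] == pytest.approx(7.0)


def test_sampled_sinusoid_matches_closed_forms():
    """365-day sinusoid of amplitude a: range = 2a, variance = a^2/2."""
    a = 2.7
    days = np.arange(365)
    series = a * np.sin(2 * np.pi * days / 365)
    stack = RasterStack(series[:, None, None] * np.ones((1, 3, 3)))
    assert aggregate_daily(stack, "range").data[0, 0] == pytest.approx(
        2 * a, rel=1e-3)
    assert aggregate_daily(stack, "variance").data[0, 0] == pytest.approx(
        a**2 / 2, rel=0.01)


def test_per_day_nodata_ignored_until_all_days_missing():
    data = np.ones((3, 1, 2))
    data[0, 0, 0] = NODATA          # one missing day -> still valid
    data[:, 0, 1] = NODATA          # all days missing -> nodata
    out = aggregate_daily(RasterStack(data), "mean")
    assert out.data[0, 0] == pytest.approx(1.0)
    assert not out.valid_mask()[0, 1]


def test_empty_stack_rejected():
    with pytest.raises(InputError):
        aggregate_daily(RasterStack(np.empty((0, 2, 2))), "mean")


# --- distance from coast ---------------------------------------------------

def test_straight_coast_distance_counts_columns():
    land = np.zeros((5, 8))
    land[:, 0] = 1
    out = distance_from_coast(RasterGrid(land, cell_size_km=1.0))
    for k in range(1, 8):
        np.testing.assert_allclose(out.data[:, k], float(k))
    assert not out.valid_mask()[:, 0].any()


def test_single_land_cell_gives_euclidean_center_distances():
    land = np.zeros((9, 9))
    land[4, 4] = 1
    out = distance_from_coast(RasterGrid(land, cell_size_km=2.0))
    rr, cc = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
    expected = 2.0 * np.hypot(rr - 4, cc - 4)
    sea = land == 0
    np.testing.assert_allclose(out.data[sea], expected[sea])


def test_distance_matches_bruteforce_oracle_exactly():
    rng = np.random.default_rng(12)
    land = (rng.random((50, 50)) < 0.07).astype(float)
    land[0, 0] = 1  # ensure at least one land cell
    grid = RasterGrid(land, cell_size_km=1.5)
    out = distance_from_coast(grid)
    lr, lc = np.where(land > 0)
    sr, sc = np.where(land == 0)
    brute = np.min(
        np.hypot(sr[:, None] - lr[None, :], sc[:, None] - lc[None, :]),
        axis=1) * 1.5
    np.testing.assert_allclose(out.data[sr, sc], brute)


@pytest.mark.parametrize("fill", [0.0, 1.0])
def test_degenerate_masks_rejected(fill):
    with pytest.raises(InputError):
        distance_from_coast(RasterGrid(np.full((4, 4), fill)))


# --- harmonization ---------------------------------------------------------

@pytest.fixture()
def checker_layer():
    rng = np.random.default_rng(3)
    return RasterGrid(rng.normal(size=(12, 12)))


def test_identity_resample_preserves_values_inside_buffer(checker_layer):
    poly = box(2, 2, 9, 9)
    stack = harmonize({"a": checker_layer}, checker_layer, poly,
                      buffer_km=1.0)
    mask = reef_buffer_mask(checker_layer, poly, 1.0)
    np.testing.assert_array_equal(stack["a"].data[mask],
                                  checker_layer.data[mask])
    assert not stack["a"].valid_mask()[~mask].any()


def test_harmonize_is_idempotent(checker_layer):
    poly = box(3, 3, 8, 8)
    once = harmonize({"a": checker_layer}, checker_layer, poly)
    twice = harmonize(dict(once.layers), checker_layer, poly)
    np.testing.assert_array_equal(once["a"].data, twice["a"].data)


def test_constant_layer_survives_resampling():
    coarse = RasterGrid(np.full((6, 6), 4.2), cell_size_km=2.0)
    target = RasterGrid(np.zeros((12, 12)), cell_size_km=1.0)
    stack = harmonize({"c": coarse}, target, box(0, 0, 12, 12))
    valid = stack["c"].valid_mask()
    np.testing.assert_allclose(stack["c"].data[valid], 4.2)


def test_covering_polygon_masks_nothing(checker_layer):
    stack = harmonize({"a": checker_layer}, checker_layer,
                      box(-1, -1, 13, 13))
    assert stack["a"].valid_mask().all()


# --- site extraction -------------------------------------------------------

def test_extraction_reads_containing_cell_and_flags_nodata():
    data = np.arange(12, dtype=float).reshape(3, 4)
    data[1, 2] = NODATA
    grid = RasterGrid(data, cell_size_km=1.0)
    sites = pd.DataFrame({
        "site_id": [0, 1, 2],
        "x": [0.5, 2.5, 10.0],   # third site out of bounds
        "y": [0.5, 1.5, 0.5],
    })
    out = extract_at_sites({"layer": grid}, sites)
    assert out.loc[0, "layer"] == 0.0
    assert np.isnan(out.loc[1, "layer"])   # masked cell
    assert np.isnan(out.loc[2, "layer"])   # outside extent


def test_extraction_equals_direct_index_lookup(small_layers, small_sites):
    grid = small_layers["bathymetry"]
    row, col = grid.cell_of(small_sites["x"].to_numpy(),
                            small_sites["y"].to_numpy())
    expected = grid.data[row, col]
    expected = np.where(np.isclose(expected, grid.nodata), np.nan, expected)
    got = extract_at_sites({"bathymetry": grid},
                           small_sites[["site_id", "x", "y"]])
    np.testing.assert_allclose(got["bathymetry"].to_numpy(), expected)


# --- correlation exclusion -------------------------------------------------

def _noise_sites(n=1000, k=4, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, k)),
                        columns=[f"v{j}" for j in range(k)])


def test_duplicated_predictor_is_dropped_by_priority():
    sites = _noise_sites()
    sites["v_dup"] = sites["v0"]
    retained, corr, flagged = exclude_correlated(
        sites, predictors=["v0", "v_dup", "v1"],
        priority=("v0", "v1", "v_dup"))
    assert corr.loc["v0", "v_dup"] == pytest.approx(1.0)
    assert retained == ["v0", "v1"]
    assert not flagged


def test_independent_noise_keeps_everything():
    sites = _noise_sites(n=1000, k=6, seed=5)
    retained, _, _ = exclude_correlated(
        sites, predictors=list(sites.columns),
        priority=tuple(sites.columns))
    assert retained == list(sites.columns)


def test_variance_range_pair_resolves_to_seven_predictors(small_sites):
    """An eight-layer stack whose only strong pair is SST variance/range."""
    retained, corr, flagged = exclude_correlated(small_sites)
    assert corr.loc["sst_variance", "sst_range"] >= 0.70
    assert "sst_variance" not in retained
    assert len(retained) == 7
    assert not flagged


def test_zero_variance_predictor_flagged_not_dropped():
    sites = _noise_sites()
    sites["flat"] = 1.0
    retained, _, flagged = exclude_correlated(
        sites, predictors=["v0", "v1", "flat"],
        priority=("v0", "v1", "flat"))
    assert flagged == ["flat"]
    assert "v0" in retained and "v1" in retained


# --- incomplete-site removal ------------------------------------------------

def test_overlapping_missingness_accounting():
    """22 missing SST, 20 missing K490, 7 missing wave (6 also missing SST)
    out of 1028 sites -> 43 removed, 985 retained."""
    n = 1028
    sites = pd.DataFrame({
        "site_id": np.arange(n),
        "sst_mean": 1.0, "k490_mean": 1.0, "wave_energy": 1.0,
    })
    sites.loc[:21, "sst_mean"] = np.nan                   # 22 sites
    sites.loc[22:41, "k490_mean"] = np.nan                # 20 disjoint sites
    sites.loc[[0, 1, 2, 3, 4, 5, 42], "wave_energy"] = np.nan  # 7, 6 overlap
    kept, report = drop_incomplete_sites(
        sites, ["sst_mean", "k490_mean", "wave_energy"])
    assert report["per_predictor_missing"] == {
        "sst_mean": 22, "k490_mean": 20, "wave_energy": 7}
    assert report["n_removed"] == 43
    assert report["n_retained"] == 985
    assert len(kept) == 985


def test_complete_sites_all_retained():
    sites = _noise_sites(n=50, k=3)
    kept, report = drop_incomplete_sites(sites, list(sites.columns))
    assert report["n_removed"] == 0
    assert len(kept) == 50


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_union_never_exceeds_sum_of_marginals(seed):
    rng = np.random.default_rng(seed)
    sites = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
    mask = rng.random((60, 3)) < 0.15
    sites[mask] = np.nan
    expected_union = int(mask.any(axis=1).sum())
    _, report = drop_incomplete_sites(sites, list("abc"))
    assert report["n_removed"] == expected_union
    assert report["n_removed"] <= sum(
        report["per_predictor_missing"].values())
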