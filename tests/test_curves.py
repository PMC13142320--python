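"""Curve engine: percentiles, inversion, masking, AUC, polynomial, residualization."""

import numpy as np
import pytest
from _oracles import brute_auc, brute_curve
from hypothesis import given, settings
from hypothesis import strategies as st

from fcenrich import (
    Connectome,
    DegenerateMapError,
    FcEnrichError,
    GridError,
    InsufficientRegionsError,
    ReferenceAtlas,
    auc_score,
    delta_score,
    enrichment_curve,
    invert_atlas,
    masked_mean_fc,
    poly_coefficient,
    residualize_atlas,
    to_percentiles,
)
from fcenrich.curves import score_rows
from conftest import TOY_IDS, TOY_STRUCT


@pytest.mark.parametrize(
    "values, expected",
    [
        ([10.0, 20.0, 30.0, 40.0], [25.0, 50.0, 75.0, 100.0]),
        ([1.0, 2.0, 2.0, 4.0], [25.0, 62.5, 62.5, 100.0]),
    ],
)
def test_percentiles_average_rank(values, expected):
    atlas = ReferenceAtlas("a", TOY_IDS, values, TOY_STRUCT)
    assert to_percentiles(atlas).percentiles.tolist() == expected


def test_percentiles_invariant_under_monotone_transform(toy_atlas):
    base = to_percentiles(toy_atlas).percentiles
    for f in (lambda v: 3.0 * v + 1.0, np.exp, lambda v: v**3):
        transformed = toy_atlas.with_values(f(toy_atlas.values))
        assert np.array_equal(to_percentiles(transformed).percentiles, base)


def test_percentiles_constant_atlas_errors():
    atlas = ReferenceAtlas("c", TOY_IDS, [2.0] * 4, TOY_STRUCT)
    with pytest.raises(DegenerateMapError):
        to_percentiles(atlas)


def test_invert_atlas_around_mean(toy_atlas):
    inv = invert_atlas(toy_atlas)
    assert inv.values.tolist() == [4.0, 3.0, 2.0, 1.0]
    # involution
    assert np.allclose(invert_atlas(inv).values, toy_atlas.values, atol=1e-12)
    # rank reversal: percentile of inverted tie-free atlas is 100*(N+1-r)/N
    n = toy_atlas.n_regions
    orig_ranks = np.argsort(np.argsort(toy_atlas.values)) + 1
    expected = 100.0 * (n + 1 - orig_ranks) / n
    assert np.array_equal(to_percentiles(inv).percentiles, expected)


@pytest.mark.parametrize("threshold, expected", [(0.0, 0.35), (25.0, 0.5), (50.0, 0.6)])
def test_masked_mean_hand_worked(toy_conn, toy_atlas, threshold, expected):
    perc = to_percentiles(toy_atlas)
    assert masked_mean_fc(toy_conn, perc, threshold) == pytest.approx(expected, abs=1e-12)


def test_masked_mean_insufficient_regions(toy_conn, toy_atlas):
    perc = to_percentiles(toy_atlas)
    with pytest.raises(InsufficientRegionsError):
        masked_mean_fc(toy_conn, perc, 80.0)


def test_curve_hand_worked(toy_conn, toy_atlas):
    curve = enrichment_curve(toy_conn, toy_atlas, thresholds=(0.0, 25.0, 50.0))
    assert curve.values[0] == 0.0
    assert np.allclose(curve.values, [0.0, 0.15, 0.25], atol=1e-12)
    assert curve.n_regions_included.tolist() == [4, 3, 2]
    assert auc_score(curve) == pytest.approx(6.875, abs=1e-12)


def test_constant_connectome_gives_flat_curve(toy_atlas):
    m = np.full((4, 4), 0.7)
    np.fill_diagonal(m, 0.0)
    conn = Connectome(TOY_IDS, m)
    curve = enrichment_curve(conn, toy_atlas, thresholds=(0.0, 25.0, 50.0))
    assert np.allclose(curve.values, 0.0, atol=1e-15)


def test_minus_direction_is_plus_on_inverted_atlas(toy_conn, toy_atlas):
    grid = (0.0, 25.0, 50.0)
    minus = enrichment_curve(toy_conn, toy_atlas, "minus", grid)
    plus_inv = enrichment_curve(toy_conn, invert_atlas(toy_atlas), "plus", grid)
    assert np.array_equal(minus.values, plus_inv.values)
    assert auc_score(minus) == auc_score(plus_inv)


def test_default_grid_requires_40_regions(toy_conn, toy_atlas):
    with pytest.raises(GridError):
        enrichment_curve(toy_conn, toy_atlas)  # N=4 with default {0,...,95}


def test_auc_max_percentile_off_grid_errors(toy_conn, toy_atlas):
    curve = enrichment_curve(toy_conn, toy_atlas, thresholds=(0.0, 25.0, 50.0))
    with pytest.raises(GridError):
        auc_score(curve, max_percentile=30.0)


def test_auc_linear_curve_closed_form(toy_conn, toy_atlas):
    curve = enrichment_curve(toy_conn, toy_atlas, thresholds=(0.0, 25.0, 50.0))
    slope = 0.004
    linear = type(curve)(
        thresholds=curve.thresholds,
        values=slope * curve.thresholds,
        global_mean=0.0,
        direction="plus",
        n_regions_included=curve.n_regions_included,
        atlas_name="lin",
    )
    assert auc_score(linear) == pytest.approx(slope * 50.0**2 / 2.0, abs=1e-12)


@pytest.mark.parametrize(
    "make_vals, expected",
    [
        (lambda t: 2.0 * t**2, 2.0),
        (lambda t: 3.0 * t, 0.0),
        (lambda t: 5.0 - t + 0.01 * t**2, 0.01),
    ],
)
def test_poly_coefficient_recovers_exact_polynomials(toy_conn, toy_atlas, make_vals, expected):
    curve = enrichment_curve(toy_conn, toy_atlas, thresholds=(0.0, 25.0, 50.0))
    synthetic = type(curve)(
        thresholds=curve.thresholds,
        values=make_vals(curve.thresholds),
        global_mean=0.0,
        direction="plus",
        n_regions_included=curve.n_regions_included,
        atlas_name="poly",
    )
    assert poly_coefficient(synthetic) == pytest.approx(expected, abs=1e-10)


def test_delta_score_antisymmetry():
    assert delta_score(6.875, 6.875) == 0.0
    assert delta_score(1.0, -0.5) == 1.5
    assert delta_score(-0.5, 1.0) == -1.5
    with pytest.raises(FcEnrichError):
        delta_score(np.nan, 0.0)


def test_residualize_orthogonal_covariate_keeps_scores(toy_conn, toy_atlas):
    # covariate orthogonal to the centered atlas and to the intercept
    centered = toy_atlas.values - toy_atlas.values.mean()
    cov_vals = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to [-1.5,-.5,.5,1.5]
    assert abs(np.dot(cov_vals, centered)) < 1e-12 and abs(cov_vals.sum()) < 1e-12
    cov = toy_atlas.with_values(cov_vals, name="cov")
    resid = residualize_atlas(toy_atlas, cov)
    assert np.allclose(resid.values, centered, atol=1e-12)
    assert np.array_equal(
        to_percentiles(resid).percentiles, to_percentiles(toy_atlas).percentiles
    )
    grid = (0.0, 25.0, 50.0)
    assert auc_score(enrichment_curve(toy_conn, resid, "plus", grid)) == auc_score(
        enrichment_curve(toy_conn, toy_atlas, "plus", grid)
    )


def test_residualize_collinear_covariate_errors(toy_atlas):
    with pytest.raises((DegenerateMapError, FcEnrichError)):
        residualize_atlas(toy_atlas, toy_atlas)
    affine = toy_atlas.with_values(2.0 * toy_atlas.values - 7.0, name="affine")
    with pytest.raises((DegenerateMapError, FcEnrichError)):
        residualize_atlas(toy_atlas, affine)


def test_curve_and_auc_match_brute_force_oracle():
    """20 random small systems against explicit subset enumeration, to 1e-12."""
    rng = np.random.default_rng(42)
    grid = [0.0, 20.0, 40.0, 60.0]
    for _ in range(20):
        n = int(rng.integers(5, 7))
        a = rng.normal(size=(n, n))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 0.0)
        values = rng.normal(size=n)
        ids = tuple(f"p{i}" for i in range(n))
        struct = ("cortex_left",) * (n // 2) + ("cortex_right",) * (n - n // 2)
        atlas = ReferenceAtlas("r", ids, values, struct)
        conn = Connectome(ids, a)
        for direction in ("plus", "minus"):
            curve = enrichment_curve(conn, atlas, direction, grid)
            oracle = brute_curve(a, values, grid, direction)
            assert np.allclose(curve.values, oracle, atol=1e-12)
            assert auc_score(curve) == pytest.approx(
                brute_auc(a, values, grid, direction), abs=1e-12
            )


def test_global_offset_invariance(toy_conn, toy_atlas):
    grid = (0.0, 25.0, 50.0)
    base = enrichment_curve(toy_conn, toy_atlas, "plus", grid)
    shifted = Connectome(TOY_IDS, toy_conn.matrix + 3.7 - 3.7 * np.eye(4))
    moved = enrichment_curve(shifted, toy_atlas, "plus", grid)
    assert np.allclose(base.values, moved.values, atol=1e-12)
    assert auc_score(base) == pytest.approx(auc_score(moved), abs=1e-12)


def test_batch_engine_matches_single_map_path():
    rng = np.random.default_rng(3)
    grid = (0.0, 20.0, 40.0, 60.0)
    n = 10
    a = rng.normal(size=(n, n))
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)
    ids = tuple(f"p{i}" for i in range(n))
    struct = ("cortex_left",) * 5 + ("cortex_right",) * 5
    conn = Connectome(ids, a)
    maps = rng.normal(size=(6, n))
    for direction in ("plus", "minus"):
        batch = score_rows(a, maps, grid, direction, "auc")
        for k in range(maps.shape[0]):
            atlas = ReferenceAtlas("m", ids, maps[k], struct)
            single = auc_score(enrichment_curve(conn, atlas, direction, grid))
            assert batch[k] == pytest.approx(single, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=5, max_size=12, unique=True))
def test_monotone_inclusion_counts(values):
    """n_regions_included(t) equals #{i : percentile_i > t} and is non-increasing."""
    n = len(values)
    ids = tuple(f"p{i}" for i in range(n))
    struct = ("cortex_left",) * n
    atlas = ReferenceAtlas("h", ids, values, struct)
    rng = np.random.default_rng(0)
    a = rng.normal(size=(n, n))
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)
    grid = (0.0, 20.0, 40.0)
    curve = enrichment_curve(Connectome(ids, a), atlas, "plus", grid)
    perc = to_percentiles(atlas).percentiles
    expected = [int(np.count_nonzero(perc > t)) for t in grid]
    assert curve.n_regions_included.tolist() == expected
    assert np.all(np.diff(curve.n_regions_included) <= 0)
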