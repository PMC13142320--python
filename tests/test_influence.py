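"""Leave-one-out influence, bounded-AUC emergence, sliding windows."""

import numpy as np
import pytest
from _oracles import brute_loco, brute_loro

from fcenrich import (
    Connectome,
    FcEnrichError,
    InsufficientRegionsError,
    ReferenceAtlas,
    TimeSeriesTable,
    auc_score,
    bounded_auc_emergence,
    build_connectome,
    combined_nulls,
    enrichment_curve,
    leave_one_connection_out,
    leave_one_region_out,
    sliding_window_auc,
)
from fcenrich.synth import make_atlas, make_coupled_timeseries
from conftest import TOY_IDS


def test_loro_hand_worked(toy_conn, toy_atlas):
    """Removing region 4: reduced global .23333, t25 mean .4, AUC 2.08333."""
    imp = leave_one_region_out(toy_conn, toy_atlas, thresholds=(0.0, 25.0))
    assert imp.basis == pytest.approx(1.875, abs=1e-12)
    assert imp.importance[3] == pytest.approx(1.875 - 2.083333333333333, abs=1e-10)


def test_loco_hand_worked(toy_conn, toy_atlas):
    """Removing edge e34: reduced global .3, t25 mean .45, AUC 1.875 -> importance 0."""
    imp = leave_one_connection_out(toy_conn, toy_atlas, "r3", thresholds=(0.0, 25.0))
    assert imp.importance[3] == pytest.approx(0.0, abs=1e-12)
    assert imp.importance[2] == 0.0  # focal region's own entry


def test_constant_connectome_zero_importance(toy_atlas):
    m = np.full((4, 4), 0.4)
    np.fill_diagonal(m, 0.0)
    conn = Connectome(TOY_IDS, m)
    imp = leave_one_region_out(conn, toy_atlas, thresholds=(0.0, 25.0))
    assert np.allclose(imp.importance, 0.0, atol=1e-12)
    loco = leave_one_connection_out(conn, toy_atlas, "r1", thresholds=(0.0, 25.0))
    assert np.allclose(loco.importance, 0.0, atol=1e-12)


def test_single_subject_equals_unaveraged_difference(toy_conn, toy_atlas):
    single = leave_one_region_out(toy_conn, toy_atlas, thresholds=(0.0, 25.0))
    listed = leave_one_region_out([toy_conn], toy_atlas, thresholds=(0.0, 25.0))
    assert np.array_equal(single.importance, listed.importance)


def test_multi_subject_importance_is_mean(toy_conn, toy_atlas):
    doubled = Connectome(TOY_IDS, 2.0 * toy_conn.matrix)
    both = leave_one_region_out([toy_conn, doubled], toy_atlas, thresholds=(0.0, 25.0))
    one = leave_one_region_out(toy_conn, toy_atlas, thresholds=(0.0, 25.0))
    two = leave_one_region_out(doubled, toy_atlas, thresholds=(0.0, 25.0))
    assert np.allclose(both.importance, 0.5 * (one.importance + two.importance), atol=1e-12)


def test_loro_loco_match_brute_force_oracle():
    rng = np.random.default_rng(21)
    grid = [0.0, 20.0, 40.0]
    for _ in range(10):
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
            imp = leave_one_region_out(conn, atlas, direction, grid)
            for r in range(n):
                assert imp.importance[r] == pytest.approx(
                    brute_loro(a, values, grid, r, direction), abs=1e-12
                )
            loco = leave_one_connection_out(conn, atlas, ids[0], direction, grid)
            for j in range(1, n):
                assert loco.importance[j] == pytest.approx(
                    brute_loco(a, values, grid, 0, j, direction), abs=1e-12
                )


def test_strict_mode_raises_when_threshold_loses_all_edges(toy_conn, toy_atlas):
    # grid {0, 50}: threshold 50 keeps only regions {3, 4} (edge e34);
    # removing region 4 empties that mask
    with pytest.raises(InsufficientRegionsError, match="r4|50"):
        leave_one_region_out(toy_conn, toy_atlas, thresholds=(0.0, 50.0), mode="strict")


def test_tolerant_mode_uses_matched_grid(toy_conn, toy_atlas):
    imp = leave_one_region_out(toy_conn, toy_atlas, thresholds=(0.0, 25.0, 50.0), mode="tolerant")
    # for region 4 the 50-threshold is dropped from both AUCs: the difference
    # must equal the hand computation on the reduced grid {0, 25}
    small = leave_one_region_out(toy_conn, toy_atlas, thresholds=(0.0, 25.0))
    assert imp.importance[3] == pytest.approx(small.importance[3], abs=1e-12)


def test_emergence_detects_planted_effect(desk_geom, desk_atlas):
    ns = combined_nulls(desk_atlas, desk_geom, n=99, seed=2)
    conns = [
        build_connectome(
            make_coupled_timeseries(desk_atlas, beta=2.0, n_timepoints=200, seed=40 + s)
        )
        for s in range(8)
    ]
    bound = bounded_auc_emergence(conns, desk_atlas, ns)
    assert bound is not None and bound <= 50.0


def test_emergence_none_without_coupling(desk_geom):
    """beta = 0 cohorts rarely show continuously emerging significance."""
    rng = np.random.default_rng(17)
    none_count = 0
    n_cohorts = 40
    for _ in range(n_cohorts):
        atlas = make_atlas(desk_geom, 0.5, seed=int(rng.integers(2**31)), name="t")
        conns = [
            build_connectome(
                make_coupled_timeseries(
                    atlas, beta=0.0, n_timepoints=200, seed=int(rng.integers(2**31))
                )
            )
            for _ in range(6)
        ]
        ns = combined_nulls(atlas, desk_geom, n=99, seed=int(rng.integers(2**31)))
        if bounded_auc_emergence(conns, atlas, ns) is None:
            none_count += 1
    assert none_count >= 0.9 * n_cohorts


def test_emergence_boundary_returns_lowest_bound(desk_geom, desk_atlas):
    """With overwhelming coupling, significance holds at every bound -> 5."""
    ns = combined_nulls(desk_atlas, desk_geom, n=99, seed=3)
    conns = [
        build_connectome(
            make_coupled_timeseries(desk_atlas, beta=4.0, n_timepoints=400,
                                    noise_sd=0.5, seed=70 + s)
        )
        for s in range(10)
    ]
    assert bounded_auc_emergence(conns, desk_atlas, ns) == 5.0


def test_window_count_arithmetic(desk_atlas):
    """600 s at 1 s sampling, 60 s windows, 10 s steps -> 55 windows."""
    ts = make_coupled_timeseries(desk_atlas, beta=0.5, n_timepoints=600, seed=1)
    ws = sliding_window_auc(ts, desk_atlas)
    assert ws.scores.size == 55
    assert ws.window_starts[0] == 0.0
    assert np.all(np.diff(ws.window_starts) == 10.0)
    assert ws.window_length == 60.0


def test_windowed_scores_fluctuate_around_static_value(desk_atlas):
    ts = make_coupled_timeseries(desk_atlas, beta=1.5, n_timepoints=1200, seed=9)
    static = auc_score(enrichment_curve(build_connectome(ts), desk_atlas))
    ws = sliding_window_auc(ts, desk_atlas)
    se = ws.scores.std(ddof=1) / np.sqrt(ws.scores.size)
    # windows overlap, so the effective SE is larger than the naive one;
    # a generous multiple still pins the mean near the static value
    assert abs(ws.scores.mean() - static) <= 6.0 * se


def test_change_point_raises_windowed_auc(desk_atlas):
    """Coupling switched on halfway: later windows score higher on average."""
    off = make_coupled_timeseries(desk_atlas, beta=0.0, n_timepoints=300, seed=5)
    on = make_coupled_timeseries(desk_atlas, beta=2.0, n_timepoints=300, seed=6)
    ts = TimeSeriesTable(
        desk_atlas.region_ids, np.vstack([off.samples, on.samples]), 1.0
    )
    ws = sliding_window_auc(ts, desk_atlas)
    before = ws.scores[ws.window_starts + 60.0 <= 300.0]
    after = ws.scores[ws.window_starts >= 300.0]
    assert after.mean() > before.mean()


def test_zero_variance_window_names_window_and_region(desk_atlas):
    ts = make_coupled_timeseries(desk_atlas, beta=0.0, n_timepoints=200, seed=4)
    samples = np.array(ts.samples)
    samples[:60, 0] = 5.0  # flat first region in the first window only
    flat = TimeSeriesTable(desk_atlas.region_ids, samples, 1.0)
    with pytest.raises(FcEnrichError, match="window 0"):
        sliding_window_auc(flat, desk_atlas)


def test_windows_never_straddle_segment_boundary(desk_atlas):
    """Window/step dividing the segment lengths -> no window crosses the seam."""
    ts = make_coupled_timeseries(desk_atlas, beta=0.5, n_timepoints=240, seed=2)
    ws = sliding_window_auc(ts, desk_atlas, window_s=60.0, step_s=60.0)
    assert ws.scores.size == 4
    starts = ws.window_starts
    assert all(s % 60 == 0 for s in starts)
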