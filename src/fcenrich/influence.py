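"""Regional influence, bounded-AUC emergence, and time-resolved scores.

Influence analyses ask which regions (or which single connections of a focal
region) drive an aggregate enrichment score: the AUC is recomputed with the
corresponding edges removed and the importance is the drop relative to the
full AUC, averaged across subjects.  Percentile ranks are frozen from the
full atlas — only connections are removed, the atlas itself is untouched —
so the perturbation is purely connectomic.

The emergence analysis varies the maximum percentile bound of the AUC and
reports the lowest bound above which group-level significance holds
continuously, probing whether an effect is carried by the very densest
regions only.

Sliding-window scoring recomputes the Pearson + Fisher-z connectome and the
AUC inside rectangular windows (default 60 s length, 10 s step) to resolve
enrichment over time, e.g. across a drug infusion.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np

from .connectome import DEFAULT_CLIP, build_connectome
from .curves import DEFAULT_GRID, invert_atlas, to_percentiles, _validate_grid
from .errors import FcEnrichError, GridError, InsufficientRegionsError
from .nulls import NullSet, default_tail
from .types import Connectome, ReferenceAtlas, TimeSeriesTable

BOUNDS_DEFAULT = tuple(float(b) for b in range(5, 95, 5))  # {5, 10, ..., 90}


@dataclass(frozen=True)
class InfluenceMap:
    """Per-region (or per-edge of a focal region) importance for an aggregate score."""

    region_ids: tuple[str, ...]
    importance: np.ndarray
    basis: float  # full-sample mean AUC
    direction: str
    atlas_name: str


@dataclass(frozen=True)
class WindowedScores:
    """AUC per sliding window."""

    window_starts: np.ndarray  # seconds
    window_length: float  # seconds
    scores: np.ndarray
    direction: str
    atlas_name: str


def _masked_auc(matrix, perc, thresholds, edge_valid, strict_label=None):
    """Trapezoidal AUC of the global-subtracted curve restricted to valid edges.

    Returns (auc, ok_mask) where ok_mask flags thresholds that retained at
    least one valid edge.  In strict mode (strict_label not None) an empty
    threshold raises instead.
    """
    t = thresholds
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    valid_u = edge_valid[iu]
    weights_u = matrix[iu]
    means = np.empty(t.size)
    ok = np.ones(t.size, dtype=bool)
    global_sel = valid_u
    if not global_sel.any():
        raise InsufficientRegionsError("no valid edges at all")
    # fsum keeps means invariant under region reordering
    global_mean = math.fsum(weights_u[global_sel]) / np.count_nonzero(global_sel)
    for k, thr in enumerate(t):
        incl = perc > thr
        sel = valid_u & incl[iu[0]] & incl[iu[1]]
        cnt = np.count_nonzero(sel)
        if cnt == 0:
            if strict_label is not None:
                raise InsufficientRegionsError(
                    f"no surviving edges at threshold {thr:g} after removing {strict_label}"
                )
            ok[k] = False
            means[k] = np.nan
            continue
        means[k] = math.fsum(weights_u[sel]) / cnt - global_mean
    if np.count_nonzero(ok) < 2:
        raise InsufficientRegionsError("fewer than 2 usable thresholds")
    return float(np.trapezoid(means[ok], t[ok])), ok


def _prepare(conns, atlas, direction, thresholds):
    conn_list = [conns] if isinstance(conns, Connectome) else list(conns)
    if not conn_list:
        raise FcEnrichError("need at least one connectome")
    work_atlas = invert_atlas(atlas) if direction == "minus" else atlas
    t = _validate_grid(thresholds, atlas.n_regions)
    perc = to_percentiles(work_atlas).percentiles
    for c in conn_list:
        if c.region_ids != atlas.region_ids:
            raise FcEnrichError("connectome and atlas region orderings differ")
    return conn_list, perc, t


def leave_one_region_out(
    conns,
    atlas: ReferenceAtlas,
    direction: str = "plus",
    thresholds=DEFAULT_GRID,
    mode: str = "strict",
) -> InfluenceMap:
    """Importance of each region: full AUC minus AUC with all its edges removed.

    ``mode="strict"`` raises if any reduced system loses all edges at some
    threshold; ``mode="tolerant"`` drops such thresholds from both the full
    and the reduced AUC so the difference is computed on a matched grid.
    """
    if mode not in ("strict", "tolerant"):
        raise FcEnrichError("mode must be 'strict' or 'tolerant'")
    conn_list, perc, t = _prepare(conns, atlas, direction, thresholds)
    n = atlas.n_regions
    full_edges = ~np.eye(n, dtype=bool)
    importance = np.zeros(n)
    basis = 0.0
    for conn in conn_list:
        a = conn.matrix
        full_auc, _ = _masked_auc(a, perc, t, full_edges, strict_label="nothing")
        basis += full_auc
        for r in range(n):
            edges = full_edges.copy()
            edges[r, :] = False
            edges[:, r] = False
            label = atlas.region_ids[r] if mode == "strict" else None
            red_auc, ok = _masked_auc(a, perc, t, edges, strict_label=label)
            if mode == "tolerant" and not ok.all():
                matched_full, _ = _masked_auc(
                    a, perc, t[ok], full_edges, strict_label="nothing"
                )
                importance[r] += matched_full - red_auc
            else:
                importance[r] += full_auc - red_auc
    s = len(conn_list)
    return InfluenceMap(
        region_ids=atlas.region_ids,
        importance=importance / s,
        basis=basis / s,
        direction=direction,
        atlas_name=atlas.name,
    )


def leave_one_connection_out(
    conns,
    atlas: ReferenceAtlas,
    region: str,
    direction: str = "plus",
    thresholds=DEFAULT_GRID,
    mode: str = "strict",
) -> InfluenceMap:
    """Importance of each single connection of a focal region.

    Returns an InfluenceMap over the focal region's partners; entry j is the
    mean over subjects of full AUC minus the AUC with edge (region, j)
    removed.  The focal region's own entry is 0.
    """
    if mode not in ("strict", "tolerant"):
        raise FcEnrichError("mode must be 'strict' or 'tolerant'")
    conn_list, perc, t = _prepare(conns, atlas, direction, thresholds)
    if region not in atlas.region_ids:
        raise FcEnrichError(f"unknown focal region {region!r}")
    r = atlas.region_ids.index(region)
    n = atlas.n_regions
    full_edges = ~np.eye(n, dtype=bool)
    importance = np.zeros(n)
    basis = 0.0
    for conn in conn_list:
        a = conn.matrix
        full_auc, _ = _masked_auc(a, perc, t, full_edges, strict_label="nothing")
        basis += full_auc
        for j in range(n):
            if j == r:
                continue
            edges = full_edges.copy()
            edges[r, j] = False
            edges[j, r] = False
            label = f"edge ({region}, {atlas.region_ids[j]})" if mode == "strict" else None
            red_auc, ok = _masked_auc(a, perc, t, edges, strict_label=label)
            if mode == "tolerant" and not ok.all():
                matched_full, _ = _masked_auc(
                    a, perc, t[ok], full_edges, strict_label="nothing"
                )
                importance[j] += matched_full - red_auc
            else:
                importance[j] += full_auc - red_auc
    s = len(conn_list)
    return InfluenceMap(
        region_ids=atlas.region_ids,
        importance=importance / s,
        basis=basis / s,
        direction=direction,
        atlas_name=atlas.name,
    )


def bounded_auc_emergence(
    conns,
    atlas: ReferenceAtlas,
    nulls: NullSet,
    bounds=BOUNDS_DEFAULT,
    alpha: float = 0.05,
    direction: str = "plus",
    thresholds=DEFAULT_GRID,
    tail: str | None = None,
) -> float | None:
    """Lowest max-percentile bound above which significance holds continuously.

    For each bound b the AUC is truncated at b and the group-level exact p is
    computed; the result is the smallest b* such that p(b) < alpha for every
    bound >= b*, or None if even the largest bound is not significant.

    Curves are computed once on the full grid; truncated AUCs are trapezoid
    prefixes, so the per-bound tests reuse the same curve values.
    """
    from .curves import common_grid, curve_values_from_percentiles, directed_percentiles
    from .nulls import exact_p
    from .types import Connectome

    t = np.asarray(thresholds, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    if not np.all(np.isin(bounds, t)):
        raise GridError("every bound must lie on the threshold grid")
    if tail is None:
        tail = default_tail("auc")
    conn_list = [conns] if isinstance(conns, Connectome) else list(conns)
    rows = np.vstack([atlas.values, nulls.null_values])
    perc = directed_percentiles(rows, direction)
    # matched truncation: every map must survive every scanned bound
    t = common_grid(perc, t)
    bounds = bounds[bounds <= t[-1]]
    if bounds.size == 0:
        raise InsufficientRegionsError("no testable bounds on the usable grid")
    curves = np.stack(
        [curve_values_from_percentiles(c.matrix, perc, t) for c in conn_list]
    )  # subjects x maps x thresholds
    sig = np.empty(bounds.size, dtype=bool)
    for i, b in enumerate(bounds):
        stop = int(np.flatnonzero(t == b)[0]) + 1
        aucs = np.trapezoid(curves[:, :, :stop], t[:stop], axis=2)
        group = aucs.mean(axis=0)  # mean over subjects, per map
        sig[i] = exact_p(group[0], group[1:], tail) < alpha
    if not sig[-1]:
        return None
    # walk down from the top; stop at the first non-significant bound
    k = sig.size - 1
    while k > 0 and sig[k - 1]:
        k -= 1
    return float(bounds[k])


def sliding_window_auc(
    ts: TimeSeriesTable,
    atlas: ReferenceAtlas,
    direction: str = "plus",
    window_s: float = 60.0,
    step_s: float = 10.0,
    thresholds=DEFAULT_GRID,
    clip: float = DEFAULT_CLIP,
) -> WindowedScores:
    """AUC in rectangular sliding windows over a regional time-series table.

    Each window gets its own Pearson + Fisher-z connectome and its own global
    connectivity subtraction, exactly as in the static analysis.
    """
    from .curves import auc_score, enrichment_curve

    dt = ts.sampling_interval
    win = int(round(window_s / dt))
    step = int(round(step_s / dt))
    if win < 3:
        raise FcEnrichError("window must contain at least 3 samples")
    if step < 1:
        raise FcEnrichError("step must be at least one sample")
    if ts.n_samples < win:
        raise FcEnrichError("time series shorter than one window")
    starts = np.arange(0, ts.n_samples - win + 1, step)
    scores = np.empty(starts.size)
    for w, s0 in enumerate(starts):
        chunk = TimeSeriesTable(
            region_ids=ts.region_ids,
            samples=ts.samples[s0 : s0 + win],
            sampling_interval=dt,
        )
        try:
            conn = build_connectome(chunk, clip=clip)
        except FcEnrichError as exc:
            raise FcEnrichError(f"window {w} (start {s0 * dt:g} s): {exc}") from exc
        curve = enrichment_curve(conn, atlas, direction=direction, thresholds=thresholds)
        scores[w] = auc_score(curve)
    return WindowedScores(
        window_starts=starts * dt,
        window_length=win * dt,
        scores=scores,
        direction=direction,
        atlas_name=atlas.name,
    )
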