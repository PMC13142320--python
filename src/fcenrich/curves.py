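"""Percentile-threshold enrichment curves and aggregate scores.

The central object is the FC-percentile curve: convert a reference atlas to
percentile ranks, mask the connectome at each threshold of a grid (default
{0, 5, ..., 95}) keeping only edges between regions whose percentile exceeds
the threshold, average the surviving edges, and subtract the global
connectivity (the mean over all edges, i.e. the threshold-0 value).  The
curve is summarized either by its trapezoidal area (AUC) or by the leading
coefficient of a second-degree polynomial fit.

Direction "plus" tests enrichment among high-density regions; "minus"
inverts the atlas around its mean first, so the lowest-density regions
become the highest ranked (AUC-).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateMapError, FcEnrichError, GridError, InsufficientRegionsError
from .types import Connectome, ReferenceAtlas

DEFAULT_GRID = tuple(float(t) for t in range(0, 100, 5))
DIRECTIONS = ("plus", "minus")


@dataclass(frozen=True)
class PercentileAtlas:
    """Atlas values converted to average-rank percentiles in (0, 100]."""

    region_ids: tuple[str, ...]
    percentiles: np.ndarray
    source_atlas: str


@dataclass(frozen=True)
class EnrichmentCurve:
    """Global-connectivity-subtracted mean FC over a percentile-threshold grid."""

    thresholds: np.ndarray
    values: np.ndarray
    global_mean: float
    direction: str
    n_regions_included: np.ndarray
    atlas_name: str


def to_percentiles(atlas: ReferenceAtlas) -> PercentileAtlas:
    """Convert atlas values to percentiles of their own distribution.

    Percentile of region i is ``100 * (average ascending rank) / N``: a
    tie-free maximum sits at exactly 100, the minimum at 100/N > 0, and tied
    regions share the average-rank percentile so they enter and leave
    threshold masks together.
    """
    v = atlas.values
    if np.ptp(v) == 0.0:
        raise DegenerateMapError(f"atlas {atlas.name!r} is constant; percentiles undefined")
    ranks = rankdata(v, method="average")
    perc = 100.0 * ranks / v.size
    return PercentileAtlas(atlas.region_ids, perc, atlas.name)


def invert_atlas(atlas: ReferenceAtlas) -> ReferenceAtlas:
    """Mirror the atlas around its mean: v -> 2*mean(v) - v.

    The highest-density regions become the lowest ranked and vice versa; this
    is how the "minus" direction (enrichment among low-density regions) is
    produced.  Applying it twice restores the original values.
    """
    v = atlas.values
    return atlas.with_values(2.0 * v.mean() - v, name=atlas.name + "_inv")


def _check_alignment(conn_ids, atlas_ids) -> None:
    if tuple(conn_ids) != tuple(atlas_ids):
        raise FcEnrichError("connectome and atlas region orderings differ")


def masked_mean_fc(conn: Connectome, perc: PercentileAtlas, threshold: float) -> float:
    """Mean FC over edges between regions with percentile strictly above threshold.

    At threshold 0 every region is included (the minimum percentile is
    100/N > 0), so this is the global connectivity.
    """
    _check_alignment(conn.region_ids, perc.region_ids)
    keep = np.flatnonzero(perc.percentiles > threshold)
    if keep.size < 2:
        raise InsufficientRegionsError(
            f"threshold {threshold:g} leaves {keep.size} region(s); need >= 2"
        )
    sub = conn.matrix[np.ix_(keep, keep)]
    iu = np.triu_indices(keep.size, k=1)
    edges = sub[iu]
    # fsum: correctly rounded, so the mean is invariant under region reordering
    return math.fsum(edges) / edges.size


def _validate_grid(thresholds, n_regions: int) -> np.ndarray:
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise GridError("threshold grid must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise GridError("threshold grid must be strictly increasing")
    if t[0] < 0 or t[-1] > 95:
        raise GridError("thresholds must lie in [0, 95]")
    # the top mask keeps ~N*(100-t_max)/100 regions; require >= 2 up front
    needed = math.ceil(2.0 * 100.0 / (100.0 - t[-1]))
    if n_regions < needed:
        raise GridError(
            f"grid with max threshold {t[-1]:g} needs >= {needed} regions, got {n_regions}"
        )
    return t


def enrichment_curve(
    conn: Connectome,
    atlas: ReferenceAtlas,
    direction: str = "plus",
    thresholds=DEFAULT_GRID,
) -> EnrichmentCurve:
    """FC-percentile curve with global connectivity subtracted.

    ``values[k] = masked_mean_fc(thresholds[k]) - masked_mean_fc(0)``; the
    threshold-0 entry (if present) is exactly 0.
    """
    if direction not in DIRECTIONS:
        raise FcEnrichError(f"direction must be one of {DIRECTIONS}")
    if direction == "minus":
        atlas = invert_atlas(atlas)
    t = _validate_grid(thresholds, atlas.n_regions)
    perc = to_percentiles(atlas)
    global_mean = masked_mean_fc(conn, perc, 0.0)
    values = np.empty(t.size)
    n_incl = np.empty(t.size, dtype=int)
    for k, thr in enumerate(t):
        values[k] = masked_mean_fc(conn, perc, thr) - global_mean
        n_incl[k] = int(np.count_nonzero(perc.percentiles > thr))
    return EnrichmentCurve(
        thresholds=t,
        values=values,
        global_mean=global_mean,
        direction=direction,
        n_regions_included=n_incl,
        atlas_name=atlas.name,
    )


def auc_score(curve: EnrichmentCurve, max_percentile: float | None = None) -> float:
    """Trapezoidal area under the curve up to ``max_percentile``.

    The x-axis is in raw percentile units (default grid spacing 5); the
    integral is not normalized, because scores are only ever compared with
    null scores computed on the identical grid.
    """
    t = curve.thresholds
    if max_percentile is None:
        max_percentile = float(t[-1])
    hits = np.flatnonzero(t == float(max_percentile))
    if hits.size != 1:
        raise GridError(f"max_percentile {max_percentile:g} is not on the threshold grid")
    stop = hits[0] + 1
    if stop < 2:
        raise GridError("AUC needs at least two grid points below the bound")
    return float(np.trapezoid(curve.values[:stop], t[:stop]))


def poly_coefficient(curve: EnrichmentCurve) -> float:
    """Leading (quadratic) coefficient of a 2nd-degree fit to the curve.

    An alternative aggregate that captures curve shape (acceleration of the
    masked mean with threshold) rather than overall area.
    """
    if curve.thresholds.size < 3:
        raise GridError("polynomial fit needs at least 3 grid points")
    return float(np.polyfit(curve.thresholds, curve.values, 2)[0])


def delta_score(auc_plus: float, auc_minus: float) -> float:
    """AUC+ minus AUC-: a contrast that cancels shared spatial structure."""
    if not (np.isfinite(auc_plus) and np.isfinite(auc_minus)):
        raise FcEnrichError("delta_score requires finite inputs")
    return float(auc_plus) - float(auc_minus)


def residualize_atlas(atlas: ReferenceAtlas, covariates) -> ReferenceAtlas:
    """Replace atlas values by OLS residuals on intercept + covariate maps.

    Used to ask whether an enrichment effect survives removal of spatially
    confounding maps.
    """
    covs = [covariates] if isinstance(covariates, ReferenceAtlas) else list(covariates)
    if not covs:
        raise FcEnrichError("need at least one covariate map")
    for c in covs:
        if c.region_ids != atlas.region_ids:
            raise FcEnrichError(f"covariate {c.name!r} region ordering differs from atlas")
    X = np.column_stack([np.ones(atlas.n_regions)] + [c.values for c in covs])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FcEnrichError("covariate design is rank deficient (collinear maps)")
    beta, *_ = np.linalg.lstsq(X, atlas.values, rcond=None)
    resid = atlas.values - X @ beta
    if np.ptp(resid) < 1e-12:
        raise DegenerateMapError("residual map is numerically constant")
    return atlas.with_values(resid, name=atlas.name + "_resid")


# ---------------------------------------------------------------------------
# Batch engine: many maps against one connectome.
#
# Null inference scores hundreds of surrogate maps against each connectome;
# doing that through quadratic forms (sum over the included block equals
# m' A m with zero diagonal) is orders of magnitude faster than masking.
# Observed and null maps always go through this same code path so they are
# strictly comparable.
# ---------------------------------------------------------------------------


def percentile_rows(value_rows: np.ndarray) -> np.ndarray:
    """Row-wise average-rank percentiles for a stack of maps."""
    v = np.atleast_2d(np.asarray(value_rows, dtype=float))
    if np.any(np.ptp(v, axis=1) == 0.0):
        raise DegenerateMapError("a map row is constant; percentiles undefined")
    ranks = rankdata(v, method="average", axis=1)
    return 100.0 * ranks / v.shape[1]


def directed_percentiles(
    value_rows: np.ndarray, direction: str = "plus"
) -> np.ndarray:
    """Row-wise percentiles after applying the direction (minus = mean inversion)."""
    if direction not in DIRECTIONS:
        raise FcEnrichError(f"direction must be one of {DIRECTIONS}")
    v = np.atleast_2d(np.asarray(value_rows, dtype=float))
    if direction == "minus":
        v = 2.0 * v.mean(axis=1, keepdims=True) - v
    return percentile_rows(v)


def mask_survives(perc: np.ndarray, thresholds=DEFAULT_GRID) -> np.ndarray:
    """Which percentile rows keep >= 2 regions at every grid threshold.

    With average-rank ties a heavily duplicated map (as spin surrogates can
    be at coarse parcellations) may have no region above the top threshold;
    such rows cannot be scored on this grid.
    """
    t = np.asarray(thresholds, dtype=float)
    return np.count_nonzero(perc > t[-1], axis=1) >= 2


def common_grid(perc: np.ndarray, thresholds=DEFAULT_GRID) -> np.ndarray:
    """Longest grid prefix on which every percentile row keeps >= 2 regions.

    Surrogate maps built by nearest-neighbour reassignment can tie so many
    values at coarse parcellations that the top thresholds empty their masks.
    Truncating the grid to the longest prefix every map in the ensemble
    survives keeps observed and null maps on the identical statistic without
    discarding any surrogate (inclusion counts are non-increasing in the
    threshold, so survival at the last kept threshold implies survival below).
    At realistic parcellation sizes no truncation occurs.
    """
    t = np.asarray(thresholds, dtype=float)
    min_counts = np.array(
        [np.min(np.count_nonzero(perc > thr, axis=1)) for thr in t]
    )
    ok = np.flatnonzero(min_counts >= 2)
    if ok.size < 2:
        raise InsufficientRegionsError(
            "fewer than 2 usable thresholds remain for this map ensemble"
        )
    return t[: ok[-1] + 1]


def curve_values_from_percentiles(
    matrix: np.ndarray, perc: np.ndarray, thresholds=DEFAULT_GRID
) -> np.ndarray:
    """Global-subtracted curve values per percentile row; (n_maps, n_thresholds)."""
    a = np.asarray(matrix, dtype=float)
    n = a.shape[0]
    if perc.shape[1] != n:
        raise FcEnrichError("map rows and connectome dimension differ")
    t = _validate_grid(thresholds, n)
    out = np.empty((perc.shape[0], t.size))
    # global connectivity: same quadratic form with the all-ones mask
    g = _masked_means(a, np.ones_like(perc, dtype=bool))
    for k, thr in enumerate(t):
        incl = perc > thr
        counts = incl.sum(axis=1)
        if np.any(counts < 2):
            raise InsufficientRegionsError(
                f"threshold {thr:g} leaves < 2 regions for some map"
            )
        out[:, k] = _masked_means(a, incl) - g
    return out


def curve_values_rows(
    matrix: np.ndarray,
    value_rows: np.ndarray,
    thresholds=DEFAULT_GRID,
    direction: str = "plus",
) -> np.ndarray:
    """Global-subtracted curve values for each map row; returns (n_maps, n_thresholds)."""
    perc = directed_percentiles(value_rows, direction)
    return curve_values_from_percentiles(matrix, perc, thresholds)


def _masked_means(a: np.ndarray, incl: np.ndarray) -> np.ndarray:
    """Mean off-diagonal edge weight inside each row's included region set."""
    inc = incl.astype(float)
    s = np.einsum("mi,mi->m", inc @ a, inc)  # m' A m, diagonal of A is 0
    k = incl.sum(axis=1)
    return s / (k * (k - 1.0))


def score_from_percentiles(
    matrix: np.ndarray,
    perc: np.ndarray,
    thresholds=DEFAULT_GRID,
    metric: str = "auc",
    max_percentile: float | None = None,
) -> np.ndarray:
    """Aggregate score per percentile row (auc or poly) against one connectome."""
    t = np.asarray(thresholds, dtype=float)
    vals = curve_values_from_percentiles(matrix, perc, t)
    if metric == "auc":
        if max_percentile is None:
            max_percentile = float(t[-1])
        hits = np.flatnonzero(t == float(max_percentile))
        if hits.size != 1:
            raise GridError(f"max_percentile {max_percentile:g} is not on the grid")
        stop = hits[0] + 1
        return np.trapezoid(vals[:, :stop], t[:stop], axis=1)
    if metric == "poly":
        if t.size < 3:
            raise GridError("polynomial fit needs at least 3 grid points")
        return np.atleast_1d(np.polyfit(t, vals.T, 2)[0])
    raise FcEnrichError(f"unknown metric {metric!r}")


def score_rows(
    matrix: np.ndarray,
    value_rows: np.ndarray,
    thresholds=DEFAULT_GRID,
    direction: str = "plus",
    metric: str = "auc",
    max_percentile: float | None = None,
) -> np.ndarray:
    """Aggregate score (auc / poly / delta) for each map row against one connectome."""
    if metric == "delta":
        plus = score_rows(matrix, value_rows, thresholds, "plus", "auc", max_percentile)
        minus = score_rows(matrix, value_rows, thresholds, "minus", "auc", max_percentile)
        return plus - minus
    perc = directed_percentiles(value_rows, direction)
    return score_from_percentiles(matrix, perc, thresholds, metric, max_percentile)
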