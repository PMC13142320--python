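"""Spatial-autocorrelation-preserving null models and non-parametric inference.

Associations between a map and a connectome can be inflated by spatial
structure shared across brain maps.  Inference is therefore run against
surrogate reference maps that preserve spatial autocorrelation while
destroying the specific topography:

* cortex — a symmetric "spin test": a uniformly random rotation of the
  spherical parcel centroids, with the mirrored rotation applied to the
  opposite hemisphere so interhemispheric symmetry is preserved, followed by
  nearest-neighbour reassignment of parcel values;
* subcortex — Moran Spectral Randomization (MSR, singleton procedure) on an
  inverse-Euclidean-distance weight matrix, which preserves the map's mean,
  variance and Moran spectrum exactly.

The connectomes are never perturbed; only the reference maps are.  Exact
p-values use the add-one estimator (1 + #{null >= obs}) / (1 + n_nulls),
and effect sizes are robust z-scores (obs - median) / (1.4826 * MAD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .curves import DEFAULT_GRID
from .errors import DegenerateNullError, FcEnrichError, InsufficientRegionsError
from .types import Connectome, ParcelGeometry, ReferenceAtlas

MAD_SCALE = 1.4826  # consistency factor for a normal distribution
TAILS = ("upper", "lower", "two_sided")
_MIRROR = np.diag([-1.0, 1.0, 1.0])  # reflection of the left-right (x) axis


@dataclass(frozen=True)
class NullSet:
    """Ensemble of surrogate maps with provenance."""

    atlas_name: str
    region_ids: tuple[str, ...]
    null_values: np.ndarray  # n_nulls x N
    method: dict  # per-structure tag, e.g. {"cortex": "spin", "subcortex": "msr"}
    seed: int
    geometry_digest: str = ""  # sha256 of the centroid table the surrogates used

    @property
    def n_nulls(self) -> int:
        return self.null_values.shape[0]


@dataclass(frozen=True)
class TestResult:
    """Observed score against its null distribution."""

    observed: float
    null_scores: np.ndarray
    p: float
    z: float
    tail: str
    level: str  # "individual" | "group"


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n rotation matrices drawn uniformly from SO(3).

    QR-orthogonalization of a standard-normal 3x3 matrix, with the R-diagonal
    sign fix to make the distribution Haar; reflections are turned into
    rotations by flipping the last column.
    """
    out = np.empty((n, 3, 3))
    for i in range(n):
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q = q * np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 2] = -q[:, 2]
        out[i] = q
    return out


def spin_nulls(
    geom: ParcelGeometry, n: int, seed=None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-null nearest-neighbour index mappings for cortical parcels.

    Returns an ``(n, n_cortex)`` integer array ``assign`` whose columns follow
    the cortical parcels in geometry order: under null k, cortical parcel i
    takes the value of cortical parcel ``assign[k, i]``.  The left hemisphere
    is rotated by R and the right by the centerline-mirrored rotation M R M,
    so the two hemispheres spin symmetrically and values never cross the
    midline.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    return spin_assignments(geom, random_rotations(n, rng))


def spin_assignments(geom: ParcelGeometry, rotations: np.ndarray) -> np.ndarray:
    """Nearest-neighbour cortical index mappings for given left-hemisphere rotations."""
    struct = np.asarray(geom.structure)
    cortex = geom.cortex_indices
    left_mask = struct[cortex] == "cortex_left"
    right_mask = struct[cortex] == "cortex_right"
    if not left_mask.any() or not right_mask.any():
        raise FcEnrichError("spin nulls need at least one parcel in each hemisphere")
    rotations = np.asarray(rotations, dtype=float)
    n = rotations.shape[0]
    assign = np.empty((n, cortex.size), dtype=np.intp)
    for hemi_mask, mirror in ((left_mask, False), (right_mask, True)):
        coords = geom.coords[cortex[hemi_mask]]
        rots = rotations
        if mirror:
            rots = _MIRROR @ rotations @ _MIRROR
        # rotated[k, j] = R_k @ coords[j]
        rotated = np.einsum("kab,jb->kja", rots, coords)
        # unit vectors: nearest neighbour = largest dot product
        dots = np.einsum("ia,kja->kij", coords, rotated)
        nearest = np.argmax(dots, axis=2)
        hemi_idx = np.flatnonzero(hemi_mask)
        assign[:, hemi_idx] = hemi_idx[nearest]
    return assign


def _moran_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal Moran eigenvector basis of the 1-orthogonal subspace.

    Spatial weights are inverse Euclidean distances (zero diagonal); the
    basis diagonalizes the doubly centered weight matrix, ordering spatial
    patterns from smooth to rough.
    """
    k = coords.shape[0]
    d = cdist(coords, coords)
    off = ~np.eye(k, dtype=bool)
    if np.any(d[off] == 0.0):
        raise FcEnrichError("coincident subcortical coordinates (zero distance)")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    h = np.eye(k) - 1.0 / k
    _, vecs = np.linalg.eigh(h @ w @ h)
    ones = np.full(k, 1.0 / np.sqrt(k))
    # drop the trivial constant direction, then re-orthonormalize the rest
    # against 1 exactly so surrogates preserve the mean to machine precision
    overlap = np.abs(vecs.T @ ones)
    keep = np.delete(np.arange(k), int(np.argmax(overlap)), axis=0)
    v = vecs[:, keep]
    v = v - np.outer(ones, ones @ v)
    q, _ = np.linalg.qr(v)
    return q


def msr_nulls(
    values: np.ndarray,
    coords: np.ndarray,
    n: int,
    seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Moran Spectral Randomization surrogates (singleton procedure).

    The observed map is expanded in the Moran eigenvector basis and the
    expansion coefficients are re-signed at random, which preserves the mean,
    the variance and Moran's I of the map exactly while scrambling its
    orientation in space.  Returns an ``(n, K)`` matrix of surrogate values.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if x.size < 3:
        raise FcEnrichError("MSR needs at least 3 subcortical regions")
    basis = _moran_basis(coords)
    mean = x.mean()
    a = basis.T @ (x - mean)
    signs = rng.choice([-1.0, 1.0], size=(n, a.size))
    return mean + (signs * a) @ basis.T


def combined_nulls(
    atlas: ReferenceAtlas, geom: ParcelGeometry, n: int = 1000, seed: int = 0
) -> NullSet:
    """Full-brain surrogate maps: spin for cortex, MSR for subcortex.

    Cortical and subcortical surrogates are generated independently and
    concatenated into complete maps; the percentile conversion downstream is
    always applied to the complete map, never per structure.
    """
    if atlas.region_ids != geom.region_ids:
        raise FcEnrichError("atlas and geometry region orderings differ")
    if atlas.structure != geom.structure:
        raise FcEnrichError("atlas and geometry structure labels differ")
    rng = np.random.default_rng(seed)
    nulls = np.tile(atlas.values, (n, 1))
    method: dict[str, str] = {}
    cortex = geom.cortex_indices
    if cortex.size:
        assign = spin_nulls(geom, n, rng=rng)
        cort_vals = atlas.values[cortex]
        nulls[:, cortex] = cort_vals[assign]
        method["cortex"] = "spin"
    sub = geom.subcortex_indices
    if sub.size:
        nulls[:, sub] = msr_nulls(atlas.values[sub], geom.coords[sub], n, rng=rng)
        method["subcortex"] = "msr"
    import hashlib

    digest = hashlib.sha256(
        np.ascontiguousarray(geom.coords).tobytes()
        + "|".join(geom.region_ids).encode()
    ).hexdigest()
    return NullSet(
        atlas_name=atlas.name,
        region_ids=atlas.region_ids,
        null_values=nulls,
        method=method,
        seed=int(seed) if np.isscalar(seed) else 0,
        geometry_digest=digest,
    )


def exact_p(observed: float, null_scores, tail: str = "upper") -> float:
    """Add-one exact p-value against an empirical null distribution.

    Never returns 0: with n nulls the smallest attainable p is 1/(n+1).
    Ties between the observed score and nulls count toward the tail.
    """
    nulls = np.asarray(null_scores, dtype=float)
    if nulls.size == 0:
        raise FcEnrichError("empty null distribution")
    if tail not in TAILS:
        raise FcEnrichError(f"tail must be one of {TAILS}")
    n = nulls.size
    upper = (1.0 + np.count_nonzero(nulls >= observed)) / (1.0 + n)
    lower = (1.0 + np.count_nonzero(nulls <= observed)) / (1.0 + n)
    if tail == "upper":
        return float(upper)
    if tail == "lower":
        return float(lower)
    return float(min(1.0, 2.0 * min(upper, lower)))


def robust_z(observed: float, null_scores) -> float:
    """(observed - median(nulls)) / (1.4826 * MAD(nulls))."""
    nulls = np.asarray(null_scores, dtype=float)
    if nulls.size == 0:
        raise FcEnrichError("empty null distribution")
    med = np.median(nulls)
    mad = np.median(np.abs(nulls - med))
    if mad == 0.0:
        raise DegenerateNullError("null distribution has zero MAD")
    return float((observed - med) / (MAD_SCALE * mad))


def individual_test(observed: float, null_scores, tail: str = "upper") -> TestResult:
    nulls = np.asarray(null_scores, dtype=float)
    return TestResult(
        observed=float(observed),
        null_scores=nulls,
        p=exact_p(observed, nulls, tail),
        z=robust_z(observed, nulls),
        tail=tail,
        level="individual",
    )


def group_level_test(scores_obs, scores_null, tail: str = "upper") -> TestResult:
    """Group-level inference: mean observed score vs per-null-map mean score.

    ``scores_null[s, k]`` must be subject s scored against the *same* null
    map k for every subject; the null distribution is then the across-subject
    mean per null map.
    """
    obs = np.asarray(scores_obs, dtype=float)
    nulls = np.asarray(scores_null, dtype=float)
    if nulls.ndim != 2 or nulls.shape[0] != obs.size:
        raise FcEnrichError(
            f"scores_null must be (n_subjects={obs.size}) x n_nulls, got {nulls.shape}"
        )
    # fsum: the group means do not depend on subject ordering, even in the last ulp
    group_obs = math.fsum(obs) / obs.size
    group_nulls = np.array([math.fsum(col) / obs.size for col in nulls.T])
    return TestResult(
        observed=group_obs,
        null_scores=group_nulls,
        p=exact_p(group_obs, group_nulls, tail),
        z=robust_z(group_obs, group_nulls),
        tail=tail,
        level="group",
    )


def default_tail(metric: str) -> str:
    """Directional (upper) tails for auc/poly; two-sided for the delta contrast."""
    return "two_sided" if metric == "delta" else "upper"


def enrichment_test(
    conns,
    atlas: ReferenceAtlas,
    nulls: NullSet,
    direction: str = "plus",
    thresholds=DEFAULT_GRID,
    metric: str = "auc",
    max_percentile: float | None = None,
    tail: str | None = None,
) -> TestResult:
    """Score one or more connectomes against an atlas and its null set.

    A single connectome yields an individual-level test; a sequence yields
    the group-level test (all subjects share the null maps).  Observed and
    null maps are scored through the identical batch code path.

    Surrogate maps built by nearest-neighbour reassignment can tie so many
    values at coarse parcellations that no region exceeds the top grid
    thresholds; the grid is then truncated to the longest prefix that every
    map in the ensemble (observed and nulls) survives, so all maps are scored
    with the identical statistic and none is discarded.  The truncation
    depends only on the maps, never on the connectomes, and is shared across
    subjects at group level.  At realistic parcellation sizes no truncation
    occurs.
    """
    from .curves import common_grid, directed_percentiles, score_from_percentiles

    if isinstance(conns, Connectome):
        conn_list = [conns]
        level = "individual"
    else:
        conn_list = list(conns)
        level = "group" if len(conn_list) > 1 else "individual"
    if not conn_list:
        raise FcEnrichError("need at least one connectome")
    if tail is None:
        tail = default_tail(metric)
    if nulls.region_ids != atlas.region_ids:
        raise FcEnrichError("null set and atlas region orderings differ")
    for conn in conn_list:
        if conn.region_ids != atlas.region_ids:
            raise FcEnrichError("connectome and atlas region orderings differ")
    rows = np.vstack([atlas.values, nulls.null_values])
    directions = ("plus", "minus") if metric == "delta" else (direction,)
    percs = {d: directed_percentiles(rows, d) for d in directions}
    grid = np.asarray(thresholds, dtype=float)
    for p in percs.values():
        grid = common_grid(p, grid)
    if max_percentile is not None and max_percentile > grid[-1]:
        raise InsufficientRegionsError(
            f"requested max_percentile {max_percentile:g} exceeds the usable "
            f"grid bound {grid[-1]:g} for this map ensemble"
        )
    obs = np.empty(len(conn_list))
    null_scores = np.empty((len(conn_list), nulls.n_nulls))
    for s, conn in enumerate(conn_list):
        base_metric = "auc" if metric == "delta" else metric
        parts = [
            score_from_percentiles(
                conn.matrix, percs[d], grid, base_metric, max_percentile
            )
            for d in directions
        ]
        scores = parts[0] - parts[1] if metric == "delta" else parts[0]
        obs[s] = scores[0]
        null_scores[s] = scores[1:]
    if level == "individual":
        return individual_test(obs[0], null_scores[0], tail)
    return group_level_test(obs, null_scores, tail)
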