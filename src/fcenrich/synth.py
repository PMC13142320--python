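"""Synthetic fixtures: geometry, smooth atlases, coupled time series, score tables.

These generators provide everything the framework needs, at desk scale and
fully seeded:

* a two-hemisphere spherical parcel geometry (Fibonacci lattice restricted
  to one hemisphere, exactly mirrored to the other) plus subcortical
  centroids near the origin;
* spatially autocorrelated reference atlases: zero-mean Gaussian fields with
  exponential covariance exp(-d/rho) over centroid chord distances,
  standardized to unit variance;
* regional time series with a planted coupling: every region mixes a shared
  signal with loading beta * logistic(z_i), z_i the standardized atlas value,
  so pairwise correlation grows with the joint atlas density of the pair —
  the synchronization structure the enrichment statistic is built to detect;
* subjects x runs score tables with controllable between/within-subject
  variance for reliability metrics.

Defaults emulate a small whole-brain parcellation (30 parcels per cortical
hemisphere + 8 subcortical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import FcEnrichError
from .types import ParcelGeometry, ReferenceAtlas, ScoreTable, TimeSeriesTable

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort fixture."""

    n_per_hemisphere: int = 30
    n_subcortex: int = 8
    atlas_smoothness: float = 0.5  # exponential correlation length, chord units
    effect_size: float = 0.0  # beta: shared-signal loading scale
    n_timepoints: int = 200
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_hemisphere < 1 or self.n_subcortex < 0:
            raise FcEnrichError("invalid region counts")
        if self.atlas_smoothness <= 0 or self.noise_sd <= 0 or self.effect_size < 0:
            raise FcEnrichError("invalid smoothness / noise / effect parameters")


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n points of a Fibonacci lattice on the unit sphere with x < 0."""
    m = 2 * n + 8
    while True:
        i = np.arange(m)
        z = 1.0 - 2.0 * (i + 0.5) / m
        r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
        phi = i * GOLDEN_ANGLE
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        left = pts[pts[:, 0] < 0.0]
        if left.shape[0] >= n:
            return left[:n]
        m += n


def make_geometry(spec: SyntheticSpec) -> ParcelGeometry:
    """Mirror-symmetric spherical cortex plus subcortical centroids.

    Right-hemisphere centroids are the exact x-reflection of the left, which
    is what the mirrored spin test expects.  Subcortical centroids lie in a
    ball of radius 0.2 around the origin, mirrored in pairs when their count
    is even.
    """
    rng = np.random.default_rng(spec.seed)
    left = _fibonacci_hemisphere(spec.n_per_hemisphere)
    right = left * np.array([-1.0, 1.0, 1.0])
    coords = [left, right]
    ids = [f"L{i + 1:03d}" for i in range(spec.n_per_hemisphere)]
    ids += [f"R{i + 1:03d}" for i in range(spec.n_per_hemisphere)]
    structure = ["cortex_left"] * spec.n_per_hemisphere + [
        "cortex_right"
    ] * spec.n_per_hemisphere
    if spec.n_subcortex:
        k = spec.n_subcortex
        half = k // 2 if k % 2 == 0 else k
        raw = rng.standard_normal((half, 3))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        radii = 0.2 * rng.uniform(size=(half, 1)) ** (1.0 / 3.0)
        pts = raw * radii
        if k % 2 == 0:
            pts = np.vstack([pts, pts * np.array([-1.0, 1.0, 1.0])])
        coords.append(pts)
        ids += [f"S{i + 1:02d}" for i in range(k)]
        structure += ["subcortex"] * k
    return ParcelGeometry(
        region_ids=tuple(ids),
        coords=np.vstack(coords),
        structure=tuple(structure),
    )


def make_atlas(
    geom: ParcelGeometry, rho: float, seed=None, name: str = "synthetic"
) -> ReferenceAtlas:
    """Spatially autocorrelated Gaussian field over the parcel centroids.

    Covariance exp(-d/rho) with d the 3-D chord distance; small rho gives
    near-white maps, large rho gives very smooth maps.  Values are
    standardized to zero mean and unit variance.
    """
    if rho <= 0:
        raise FcEnrichError("rho must be positive")
    rng = np.random.default_rng(seed)
    c = geom.coords
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    cov = np.exp(-d / rho) + 1e-10 * np.eye(len(d))
    lam, vecs = np.linalg.eigh(cov)
    if lam.min() < -1e-8:
        raise FcEnrichError("atlas covariance not positive definite after jitter")
    root = vecs * np.sqrt(np.clip(lam, 0.0, None))
    values = root @ rng.standard_normal(len(d))
    values = (values - values.mean()) / values.std()
    return ReferenceAtlas(
        name=name,
        region_ids=geom.region_ids,
        values=values,
        structure=geom.structure,
    )


def make_coupled_timeseries(
    atlas: ReferenceAtlas,
    beta: float,
    n_timepoints: int,
    noise_sd: float = 1.0,
    seed=None,
    sampling_interval: float = 1.0,
) -> TimeSeriesTable:
    """Regional time series whose synchronization tracks atlas density.

    Region i follows ``w_i * s(t) + noise_sd * eps_i(t)`` with s a shared
    standard-normal signal and loading ``w_i = beta * logistic(z_i)`` for the
    standardized atlas value z_i; the expected Pearson correlation of a pair
    grows with w_i * w_j, i.e. with the joint atlas density.  beta = 0 gives
    independent noise (the calibration condition).
    """
    if n_timepoints < 50:
        raise FcEnrichError("need at least 50 time points")
    if beta < 0 or noise_sd <= 0:
        raise FcEnrichError("beta must be >= 0 and noise_sd > 0")
    rng = np.random.default_rng(seed)
    z = (atlas.values - atlas.values.mean()) / atlas.values.std()
    w = beta * expit(z)
    shared = rng.standard_normal(n_timepoints)
    noise = rng.standard_normal((n_timepoints, atlas.n_regions))
    samples = shared[:, None] * w[None, :] + noise_sd * noise
    return TimeSeriesTable(
        region_ids=atlas.region_ids,
        samples=samples,
        sampling_interval=sampling_interval,
    )


def atlas_loadings(atlas: ReferenceAtlas, beta: float) -> np.ndarray:
    """The shared-signal loadings w_i used by :func:`make_coupled_timeseries`."""
    z = (atlas.values - atlas.values.mean()) / atlas.values.std()
    return beta * expit(z)


def make_score_table(
    n_subjects: int,
    n_runs: int,
    between_sd: float,
    within_sd: float,
    seed=None,
    mu: float = 1.0,
    atlas: str = "synthetic",
    direction: str = "plus",
    metric: str = "auc",
) -> ScoreTable:
    """Random-effects score table: score(s, r) = mu + b_s + e_{s,r}.

    b ~ N(0, between_sd^2) per subject, e ~ N(0, within_sd^2) per run; the
    classical two-way model whose reliability has a closed form, used to
    exercise ICC and WCV.
    """
    if between_sd < 0 or within_sd < 0:
        raise FcEnrichError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, between_sd, size=n_subjects)
    e = rng.normal(0.0, within_sd, size=(n_subjects, n_runs))
    rows = []
    for s in range(n_subjects):
        for r in range(n_runs):
            rows.append(
                [f"sub-{s + 1:04d}", f"run-{r + 1}", atlas, direction, metric,
                 mu + b[s] + e[s, r]]
            )
    import pandas as pd

    return ScoreTable(
        pd.DataFrame(rows, columns=("subject", "session", "atlas", "direction", "metric", "score"))
    )
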