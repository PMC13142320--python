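"""Simulation studies: null calibration and planted-effect power.

These are whole-pipeline experiments on synthetic cohorts (geometry ->
atlas -> coupled time series -> connectome -> nulls -> test).  They are the
package's own validation instruments: calibration checks that the exact
p-value is uniform when nothing is planted, power checks that a planted
atlas-coupled synchronization is detected and that the mean score grows
with the planted effect size.

Problem sizes default to the desk-scale fixture (30 parcels per hemisphere
+ 8 subcortical, 199 nulls, 200 time points) so a full study runs in minutes
on one CPU.
"""

from __future__ import annotations

import numpy as np

from .connectome import build_connectome
from .curves import DEFAULT_GRID, auc_score, enrichment_curve
from .nulls import combined_nulls, enrichment_test
from .synth import SyntheticSpec, make_atlas, make_coupled_timeseries, make_geometry

_SEED_MAX = 2**31 - 1


def _spawn(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, _SEED_MAX, size=n)


def calibration_study(
    n_subjects: int = 500,
    n_nulls: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> dict:
    """False-positive calibration of the individual-level exact p for AUC+.

    Every subject gets uncoupled (beta = 0) time series, an independently
    drawn smooth test atlas, and a fresh null set, so subjects are i.i.d.
    and the rejection count at level alpha is exactly binomial when the test
    is calibrated.
    """
    spec = spec or SyntheticSpec()
    geom = make_geometry(spec)
    rng = np.random.default_rng(seed)
    seeds = _spawn(rng, 4 * n_subjects).reshape(n_subjects, 4)
    p_values = np.empty(n_subjects)
    for s in range(n_subjects):
        gen_atlas = make_atlas(geom, spec.atlas_smoothness, seed=seeds[s, 0], name="gen")
        test_atlas = make_atlas(geom, spec.atlas_smoothness, seed=seeds[s, 1], name="test")
        ts = make_coupled_timeseries(
            gen_atlas, beta=0.0, n_timepoints=spec.n_timepoints,
            noise_sd=spec.noise_sd, seed=seeds[s, 2],
        )
        conn = build_connectome(ts)
        nulls = combined_nulls(test_atlas, geom, n=n_nulls, seed=int(seeds[s, 3]))
        res = enrichment_test(conn, test_atlas, nulls, direction="plus", metric="auc")
        p_values[s] = res.p
    rejections = int(np.count_nonzero(p_values < alpha))
    return {
        "n_subjects": n_subjects,
        "n_nulls": n_nulls,
        "alpha": alpha,
        "rejections": rejections,
        "rejection_rate": rejections / n_subjects,
        "p_values": p_values,
    }


def power_study(
    n_cohorts: int = 100,
    n_subjects: int = 20,
    n_nulls: int = 199,
    beta: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> dict:
    """Group-level detection rate of a planted atlas-coupled synchronization.

    Each cohort shares one generating atlas (which is also the test map) and
    one null set; subjects differ only in their noise realizations.
    """
    spec = spec or SyntheticSpec()
    geom = make_geometry(spec)
    rng = np.random.default_rng(seed)
    seeds = _spawn(rng, n_cohorts * (2 + n_subjects)).reshape(n_cohorts, 2 + n_subjects)
    hits = 0
    p_values = np.empty(n_cohorts)
    for c in range(n_cohorts):
        atlas = make_atlas(geom, spec.atlas_smoothness, seed=seeds[c, 0], name="gen")
        conns = [
            build_connectome(
                make_coupled_timeseries(
                    atlas, beta=beta, n_timepoints=spec.n_timepoints,
                    noise_sd=spec.noise_sd, seed=seeds[c, 2 + s],
                )
            )
            for s in range(n_subjects)
        ]
        nulls = combined_nulls(atlas, geom, n=n_nulls, seed=int(seeds[c, 1]))
        res = enrichment_test(conns, atlas, nulls, direction="plus", metric="auc")
        p_values[c] = res.p
        hits += res.p < alpha
    return {
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
        "beta": beta,
        "alpha": alpha,
        "hits": int(hits),
        "power": hits / n_cohorts,
        "p_values": p_values,
    }


def mean_auc_by_beta(
    betas=(0.0, 0.5, 1.0, 2.0),
    n_replicates: int = 50,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> dict:
    """Mean single-subject AUC+ for the generating atlas across effect sizes."""
    spec = spec or SyntheticSpec()
    geom = make_geometry(spec)
    rng = np.random.default_rng(seed)
    seeds = _spawn(rng, n_replicates * 2).reshape(n_replicates, 2)
    means = {}
    for beta in betas:
        aucs = np.empty(n_replicates)
        for r in range(n_replicates):
            atlas = make_atlas(geom, spec.atlas_smoothness, seed=seeds[r, 0], name="gen")
            ts = make_coupled_timeseries(
                atlas, beta=float(beta), n_timepoints=spec.n_timepoints,
                noise_sd=spec.noise_sd, seed=seeds[r, 1],
            )
            conn = build_connectome(ts)
            curve = enrichment_curve(conn, atlas, direction="plus", thresholds=DEFAULT_GRID)
            aucs[r] = auc_score(curve)
        means[float(beta)] = float(aucs.mean())
    return {
        "betas": [float(b) for b in betas],
        "n_replicates": n_replicates,
        "mean_auc": means,
    }
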