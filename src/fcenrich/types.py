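"""Parcel-level domain containers.

All analyses operate on parcellated data: a brain is a fixed ordered list of
regions (parcels), and every container carries that ordering explicitly as
``region_ids``.  Structures are labelled ``cortex_left`` / ``cortex_right`` /
``subcortex``; the split matters because cortical surrogate maps are built by
spherical rotation while subcortical ones use Moran spectral randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FcEnrichError, FormatError

STRUCTURES = ("cortex_left", "cortex_right", "subcortex")
CORTEX = ("cortex_left", "cortex_right")

SYMMETRY_TOL = 1e-10  # accepted asymmetry in a Connectome matrix
UNIT_NORM_TOL = 1e-6  # accepted deviation of cortical centroids from the unit sphere


def _as_ids(region_ids) -> tuple[str, ...]:
    ids = tuple(str(r) for r in region_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({r for r in ids if ids.count(r) > 1})
        raise FormatError(f"duplicate region_ids: {dupes}")
    return ids


def _check_structures(structure, n) -> tuple[str, ...]:
    s = tuple(str(x) for x in structure)
    if len(s) != n:
        raise FcEnrichError(f"structure has {len(s)} labels for {n} regions")
    bad = sorted(set(s) - set(STRUCTURES))
    if bad:
        raise FormatError(f"unknown structure labels {bad}; allowed: {list(STRUCTURES)}")
    return s


@dataclass(frozen=True)
class ReferenceAtlas:
    """One real-valued density per brain region for a molecular/network annotation.

    The values are in arbitrary units; only their ranks enter the enrichment
    statistic, which is what makes the method robust to atlas scaling.
    """

    name: str
    region_ids: tuple[str, ...]
    values: np.ndarray
    structure: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "region_ids", _as_ids(self.region_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != len(self.region_ids):
            raise FcEnrichError("values must be one number per region")
        if len(self.region_ids) < 2:
            raise FormatError("an atlas needs at least 2 regions")
        if not np.all(np.isfinite(values)):
            bad = [self.region_ids[i] for i in np.flatnonzero(~np.isfinite(values))]
            raise FormatError(f"non-finite atlas values at regions {bad}")
        object.__setattr__(
            self, "structure", _check_structures(self.structure, len(self.region_ids))
        )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def with_values(self, values, name: str | None = None) -> "ReferenceAtlas":
        return replace(self, values=np.asarray(values, float), name=name or self.name)


@dataclass(frozen=True)
class Connectome:
    """Symmetric region x region functional-connectivity matrix.

    Edge weights are conventionally Fisher-z transformed Pearson correlations.
    The diagonal is stored as 0 and excluded from every mean.
    """

    region_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "region_ids", _as_ids(self.region_ids))
        m = np.array(self.matrix, dtype=float)
        n = len(self.region_ids)
        if m.shape != (n, n):
            raise FcEnrichError(f"matrix shape {m.shape} does not match {n} regions")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(m[off])):
            raise FormatError("non-finite off-diagonal connectome entries")
        asym = np.max(np.abs(m - m.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise FormatError(f"connectome asymmetry {asym:.3e} exceeds {SYMMETRY_TOL}")
        np.fill_diagonal(m, 0.0)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass(frozen=True)
class ParcelGeometry:
    """Parcel centroid coordinates.

    Cortical centroids live on the unit sphere (a spherical surface
    projection), which is what spherical-rotation null models require;
    subcortical centroids are ordinary Euclidean points.
    """

    region_ids: tuple[str, ...]
    coords: np.ndarray
    structure: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "region_ids", _as_ids(self.region_ids))
        c = np.array(self.coords, dtype=float)
        if c.ndim != 2 or c.shape != (len(self.region_ids), 3):
            raise FcEnrichError("coords must be an N x 3 array")
        if not np.all(np.isfinite(c)):
            raise FormatError("non-finite coordinates")
        object.__setattr__(
            self, "structure", _check_structures(self.structure, len(self.region_ids))
        )
        s = np.asarray(self.structure)
        cortical = np.isin(s, CORTEX)
        if cortical.any():
            norms = np.linalg.norm(c[cortical], axis=1)
            if np.max(np.abs(norms - 1.0)) > UNIT_NORM_TOL:
                raise FormatError(
                    "cortical centroids must have unit norm "
                    f"(max deviation {np.max(np.abs(norms - 1.0)):.2e})"
                )
        c.flags.writeable = False
        object.__setattr__(self, "coords", c)

    def indices(self, structure: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.structure) == structure)

    @property
    def cortex_indices(self) -> np.ndarray:
        return np.flatnonzero(np.isin(np.asarray(self.structure), CORTEX))

    @property
    def subcortex_indices(self) -> np.ndarray:
        return self.indices("subcortex")


@dataclass(frozen=True)
class TimeSeriesTable:
    """Regional time series (T samples x N regions) with a sampling interval in seconds."""

    region_ids: tuple[str, ...]
    samples: np.ndarray
    sampling_interval: float

    def __post_init__(self):
        object.__setattr__(self, "region_ids", _as_ids(self.region_ids))
        x = np.array(self.samples, dtype=float)
        if x.ndim != 2 or x.shape[1] != len(self.region_ids):
            raise FcEnrichError("samples must be T x N with N = number of regions")
        if x.shape[0] < 3:
            raise FcEnrichError("need at least 3 time points")
        if not np.all(np.isfinite(x)):
            raise FormatError("non-finite samples")
        if not self.sampling_interval > 0:
            raise FcEnrichError("sampling_interval must be positive")
        x.flags.writeable = False
        object.__setattr__(self, "samples", x)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_interval


SCORE_COLUMNS = ("subject", "session", "atlas", "direction", "metric", "score")


@dataclass
class ScoreTable:
    """Long-format table of per-subject/session enrichment scores.

    Rows are keyed by (subject, session); score columns by
    (atlas, direction in {plus, minus}, metric in {auc, poly, delta}).
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SCORE_COLUMNS))

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        missing = [c for c in SCORE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"score table missing columns {missing}")
        df = df.loc[:, list(SCORE_COLUMNS)].reset_index(drop=True)
        keys = df[list(SCORE_COLUMNS[:-1])]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate score key {dup}")
        self.data = df

    def add(self, subject, session, atlas, direction, metric, score) -> None:
        row = pd.DataFrame(
            [[subject, session, atlas, direction, metric, float(score)]],
            columns=SCORE_COLUMNS,
        )
        merged = pd.concat([self.data, row], ignore_index=True)
        self.data = ScoreTable(merged).data

    def matrix(self, atlas: str, direction: str = "plus", metric: str = "auc") -> np.ndarray:
        """Subjects x sessions score matrix for one (atlas, direction, metric)."""
        sel = self.data[
            (self.data["atlas"] == atlas)
            & (self.data["direction"] == direction)
            & (self.data["metric"] == metric)
        ]
        wide = sel.pivot(index="subject", columns="session", values="score")
        return wide.to_numpy(dtype=float)
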