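"""Connectome construction from regional time series.

Edges are Pearson correlations between regional signals, variance-stabilized
with the Fisher z-transform (atanh).  Correlations are clipped just inside
(-1, 1) before the transform so duplicated signals yield large finite edges
rather than infinities.
"""

from __future__ import annotations

import numpy as np

from .errors import FcEnrichError
from .types import Connectome, TimeSeriesTable

DEFAULT_CLIP = 1.0 - 1e-7


def build_connectome(ts: TimeSeriesTable, clip: float = DEFAULT_CLIP) -> Connectome:
    """Pearson + Fisher-z connectome of a time-series table.

    Parameters
    ----------
    ts
        Regional time series, T x N.
    clip
        Correlations are clipped to [-clip, +clip] before atanh.

    Raises
    ------
    FcEnrichError
        If any region has zero temporal variance (its correlation is undefined).
    """
    if not 0.0 < clip < 1.0:
        raise FcEnrichError("clip must lie in (0, 1)")
    x = ts.samples
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        names = [ts.region_ids[i] for i in dead]
        raise FcEnrichError(f"zero-variance region(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = 0.5 * (z + z.T)  # corrcoef is symmetric up to rounding; make it exact
    return Connectome(region_ids=ts.region_ids, matrix=z)
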