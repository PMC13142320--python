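"""Tab-separated I/O for all parcel-level containers.

Every file is UTF-8 TSV with a header line and "." as the decimal mark.
Floats are written with Python's shortest round-trip representation, so a
write/read cycle reproduces finite doubles bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .types import Connectome, ParcelGeometry, ReferenceAtlas, ScoreTable, TimeSeriesTable



def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap for uniform error type
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def _floats(df: pd.DataFrame, col: str, path) -> np.ndarray:
    # python float() is correctly rounded, so shortest-repr output parses back
    # bit-exactly (pandas' default parser does not guarantee that)
    raw = df[col]
    out = np.empty(len(raw))
    for i, v in enumerate(raw):
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            out[i] = np.nan
    bad = np.flatnonzero(~np.isfinite(out))
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise FormatError(
            f"{path}: non-numeric value {raw.iloc[bad[0]]!r} in column "
            f"{col!r} at line {bad[0] + 2}"
        )
    return out


def read_atlas(path) -> ReferenceAtlas:
    """Read a reference atlas table (columns region_id, value, structure)."""
    df = _read_tsv(path, ["region_id", "value", "structure"])
    if len(df) < 2:
        raise FormatError(f"{path}: an atlas needs at least 2 rows")
    return ReferenceAtlas(
        name=Path(path).stem,
        region_ids=tuple(df["region_id"]),
        values=_floats(df, "value", path),
        structure=tuple(df["structure"]),
    )


def write_atlas(atlas: ReferenceAtlas, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region_id\tvalue\tstructure\n")
        for rid, v, s in zip(atlas.region_ids, atlas.values, atlas.structure):
            fh.write(f"{rid}\t{float(v)!r}\t{s}\n")


def read_geometry(path) -> ParcelGeometry:
    """Read a centroid table (columns region_id, x, y, z, structure)."""
    df = _read_tsv(path, ["region_id", "x", "y", "z", "structure"])
    coords = np.column_stack([_floats(df, c, path) for c in ("x", "y", "z")])
    return ParcelGeometry(
        region_ids=tuple(df["region_id"]),
        coords=coords,
        structure=tuple(df["structure"]),
    )


def write_geometry(geom: ParcelGeometry, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region_id\tx\ty\tz\tstructure\n")
        for rid, (x, y, z), s in zip(geom.region_ids, geom.coords, geom.structure):
            fh.write(f"{rid}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\t{s}\n")


def read_connectome(path, region_ids) -> Connectome:
    """Read a square matrix TSV and reorder it to ``region_ids``.

    The file carries region identifiers in the header row and first column.
    Asymmetry below 1e-8 is repaired by averaging the two triangles; larger
    asymmetry is an error.
    """
    path = Path(path)
    df = _read_tsv(path, [])
    file_ids = [str(x) for x in df.iloc[:, 0]]
    col_ids = [str(c) for c in df.columns[1:]]
    if file_ids != col_ids:
        raise FormatError(f"{path}: header ids and row ids differ")
    if len(file_ids) != len(df.columns) - 1:
        raise FormatError(f"{path}: matrix is not square")
    want = [str(r) for r in region_ids]
    if sorted(file_ids) != sorted(want):
        raise FormatError(f"{path}: region identifiers do not match the atlas")
    try:
        m = np.array(
            [[float(v) for v in row] for row in df.iloc[:, 1:].to_numpy()], dtype=float
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    if not np.all(np.isfinite(m)):
        raise FormatError(f"{path}: non-finite matrix entry")
    order = [file_ids.index(r) for r in want]
    m = m[np.ix_(order, order)]
    asym = np.max(np.abs(m - m.T))
    if asym >= 1e-8:
        raise FormatError(f"{path}: matrix asymmetry {asym:.3e} >= 1e-8")
    m = 0.5 * (m + m.T)
    return Connectome(region_ids=tuple(want), matrix=m)


def write_connectome(conn: Connectome, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region_id\t" + "\t".join(conn.region_ids) + "\n")
        for rid, row in zip(conn.region_ids, conn.matrix):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_timeseries(path, sampling_interval: float) -> TimeSeriesTable:
    """Read a time-series table: first column time index, one column per region."""
    df = _read_tsv(path, [])
    ids = tuple(str(c) for c in df.columns[1:])
    cols = [_floats(df, c, path) for c in df.columns[1:]]
    return TimeSeriesTable(
        region_ids=ids,
        samples=np.column_stack(cols),
        sampling_interval=sampling_interval,
    )


def write_timeseries(ts: TimeSeriesTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("t\t" + "\t".join(ts.region_ids) + "\n")
        for i, row in enumerate(ts.samples):
            fh.write(str(i) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_scores(path) -> ScoreTable:
    df = _read_tsv(path, list(("subject", "session", "atlas", "direction", "metric", "score")))
    df["score"] = _floats(df, "score", path)
    return ScoreTable(df)


def write_scores(table: ScoreTable, path) -> None:
    df = table.data.copy()
    df["score"] = df["score"].map(lambda v: repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def write_null_set(null_set, path_tsv, path_json) -> None:
    """Persist a NullSet as a values TSV plus a JSON provenance sidecar."""
    vals = null_set.null_values
    with open(path_tsv, "w", encoding="utf-8") as fh:
        fh.write("\t".join(null_set.region_ids) + "\n")
        for row in vals:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    meta = {
        "atlas_name": null_set.atlas_name,
        "n_nulls": int(null_set.n_nulls),
        "method": dict(null_set.method),
        "seed": int(null_set.seed),
        "geometry_digest": getattr(null_set, "geometry_digest", ""),
    }
    with open(path_json, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
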