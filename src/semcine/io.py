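"""Readers and writers for the on-disk formats.

All tables are plain text (CSV/TSV) with an optional ``#`` provenance
comment line; parcel time-series matrices additionally support a compressed
NPZ container for bulk data.  Floats are written with 17 significant digits
so every writer/reader pair round-trips losslessly.

CIFTI/NIfTI dtseries files are *not* read here: export parcel-averaged
matrices externally (e.g. with connectome-workbench ``-cifti-parcellate``
followed by ``-cifti-convert -to-text``) and feed the resulting
parcels x TRs text matrix to :func:`read_parcel_timeseries`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    COGNITION_NAMES,
    DEFAULT_SCHEMA,
    FeatureSchema,
    PipelineConfig,
    provenance_line,
)
from .segmentation import ClipManifest, ClipRecord, Interval, RunTiming, TimingError

_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# run timing
# ---------------------------------------------------------------------------

def read_timing(path: str | Path, tr_seconds: float = 1.0) -> list[RunTiming]:
    """Parse a timing CSV (run_id, start_s, end_s, label) into RunTiming records.

    Rows must be sorted and non-overlapping within each run; violations
    raise :class:`~semcine.segmentation.TimingError` naming the run and row.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"run_id", "start_s", "end_s", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"timing file {path} missing columns {sorted(missing)}")
    timings = []
    for run_id, sub in df.groupby("run_id", sort=False):
        intervals = [
            Interval(float(r.start_s), float(r.end_s), str(r.label))
            for r in sub.itertuples()
        ]
        timings.append(RunTiming(str(run_id), intervals, tr_seconds=tr_seconds))
    return timings


def write_timing(
    path: str | Path, timings: list[RunTiming], config: PipelineConfig | None = None
) -> None:
    rows = [
        {
            "run_id": t.run_id,
            "start_s": iv.start_s,
            "end_s": iv.end_s,
            "label": iv.label,
        }
        for t in timings
        for iv in t.intervals
    ]
    _write_csv(path, pd.DataFrame(rows), config)


# ---------------------------------------------------------------------------
# clip manifest
# ---------------------------------------------------------------------------

def write_manifest(
    path: str | Path, manifest: ClipManifest, config: PipelineConfig | None = None
) -> None:
    df = pd.DataFrame(
        [
            {
                "clip_id": c.clip_id,
                "run_id": c.run_id,
                "start_s": c.start_s,
                "end_s": c.end_s,
                "duration_s": c.duration_s,
            }
            for c in manifest
        ],
        columns=["clip_id", "run_id", "start_s", "end_s", "duration_s"],
    )
    _write_csv(path, df, config)


def read_manifest(path: str | Path) -> ClipManifest:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    clips = [
        ClipRecord(str(r.clip_id), str(r.run_id), float(r.start_s), float(r.end_s))
        for r in df.itertuples()
    ]
    manifest = ClipManifest(clips=clips)
    manifest.validate()
    return manifest


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def read_feature_table(
    path: str | Path, schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Read a clip x feature CSV, validate ranges, and order columns by schema.

    Returns a DataFrame indexed by clip_id with exactly ``schema.names``
    columns (in schema order, regardless of on-disk order).
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "clip_id" not in df.columns:
        raise FormatError(f"feature table {path} missing clip_id column")
    missing = set(schema.names) - set(df.columns)
    if missing:
        raise FormatError(f"feature table {path} missing columns {sorted(missing)}")
    extra = set(df.columns) - set(schema.names) - {"clip_id"}
    if extra:
        raise FormatError(f"feature table {path} has unknown columns {sorted(extra)}")
    if df["clip_id"].duplicated().any():
        dup = df.loc[df["clip_id"].duplicated(), "clip_id"].iloc[0]
        raise FormatError(f"duplicate clip_id {dup!r} in feature table")
    df = df.set_index("clip_id")[list(schema.names)].astype(float)
    bad = (df.values < 0) | (df.values > 1) | ~np.isfinite(df.values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"feature value out of [0,1]: clip {df.index[i]!r}, "
            f"column {df.columns[j]!r} = {df.values[i, j]}"
        )
    return df


def write_feature_table(
    path: str | Path, table: pd.DataFrame, config: PipelineConfig | None = None
) -> None:
    df = table.reset_index()
    _write_csv(path, df, config)


def align_features_to_manifest(
    table: pd.DataFrame, manifest: ClipManifest
) -> pd.DataFrame:
    """Reorder feature rows to manifest clip order; every clip must be present."""
    missing = [c for c in manifest.clip_ids if c not in table.index]
    if missing:
        raise FormatError(f"feature table missing clips: {missing[:5]}")
    return table.loc[manifest.clip_ids]


# ---------------------------------------------------------------------------
# parcel time series
# ---------------------------------------------------------------------------

def write_parcel_timeseries(path: str | Path, ts) -> None:
    """Write a ParcelTimeSeries as TSV (``.tsv``) or compressed NPZ (``.npz``).

    Both containers carry subject_id, run_id and tr_seconds in the header.
    """
    from .responses import ParcelTimeSeries  # local import avoids a cycle

    assert isinstance(ts, ParcelTimeSeries)
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            data=ts.data,
            subject_id=np.str_(ts.subject_id),
            run_id=np.str_(ts.run_id),
            tr_seconds=np.float64(ts.tr_seconds),
        )
        return
    buf = _io.StringIO()
    buf.write(f"# subject_id={ts.subject_id}\n")
    buf.write(f"# run_id={ts.run_id}\n")
    buf.write(f"# tr_seconds={_FLOAT_FMT % ts.tr_seconds}\n")
    np.savetxt(buf, ts.data, fmt=_FLOAT_FMT, delimiter="\t")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_parcel_timeseries(path: str | Path, expected_parcels: int | None = None):
    """Read a parcels x TRs matrix written by :func:`write_parcel_timeseries`."""
    from .responses import ParcelTimeSeries

    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            data = z["data"]
            meta = {
                "subject_id": str(z["subject_id"]),
                "run_id": str(z["run_id"]),
                "tr_seconds": float(z["tr_seconds"]),
            }
    else:
        meta = {}
        with path.open(encoding="utf-8") as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        meta = {
            "subject_id": meta.get("subject_id", ""),
            "run_id": meta.get("run_id", ""),
            "tr_seconds": float(meta.get("tr_seconds", 1.0)),
        }
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: time series contains NaN/inf")
    if expected_parcels is not None and data.shape[0] != expected_parcels:
        raise FormatError(
            f"{path}: expected {expected_parcels} parcels, found {data.shape[0]}"
        )
    return ParcelTimeSeries(data=data, **meta)


# ---------------------------------------------------------------------------
# generic labeled matrices (TSV) and cognition table
# ---------------------------------------------------------------------------

def write_matrix_tsv(
    path: str | Path,
    data: np.ndarray,
    row_labels,
    col_labels,
    index_name: str = "id",
    config: PipelineConfig | None = None,
) -> None:
    df = pd.DataFrame(np.asarray(data), index=list(row_labels), columns=list(col_labels))
    df.index.name = index_name
    _write_csv(path, df, config, sep="\t", index=True)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=0, float_precision="round_trip"
    )


def parcel_labels(n_parcels: int) -> list[str]:
    return [f"parcel_{i:04d}" for i in range(n_parcels)]


def read_cognition(path: str | Path) -> pd.DataFrame:
    """Read the subject x 7 cognition score CSV (subject_id + fixed columns)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise FormatError(f"cognition table {path} missing subject_id")
    missing = set(COGNITION_NAMES) - set(df.columns)
    if missing:
        raise FormatError(f"cognition table {path} missing columns {sorted(missing)}")
    df = df.set_index("subject_id")[list(COGNITION_NAMES)].astype(float)
    if df.isna().any().any():
        raise FormatError(f"cognition table {path} contains missing values")
    return df


def write_cognition(
    path: str | Path, table: pd.DataFrame, config: PipelineConfig | None = None
) -> None:
    _write_csv(path, table.reset_index(), config)


# ---------------------------------------------------------------------------

def _write_csv(
    path: str | Path,
    df: pd.DataFrame,
    config: PipelineConfig | None,
    sep: str = ",",
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if config is not None:
            fh.write(provenance_line(config, config.rng_seed) + "\n")
        df.to_csv(fh, sep=sep, index=index, float_format=_FLOAT_FMT)
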