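"""Clip-wise parcel responses from parcel-averaged BOLD time series.

Per run the pipeline is: mask out rest TRs, z-score each parcel using
non-rest frames only (n-1 denominator), subtract the frame-wise mean
across parcels, then average each clip's lagged half-open window.  Subject
matrices are stacked into a per-tail trimmed group mean.

A TR belongs to a window iff its *onset* lies inside the half-open window;
this rule is exact for any TR length and non-integer lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .segmentation import ClipManifest, ClipRecord, RunTiming

_EPS = 1e-9
_SD_FLOOR = 1e-12


class ResponseError(ValueError):
    pass


@dataclass
class ParcelTimeSeries:
    """parcels x TRs matrix for one subject and run."""

    subject_id: str
    run_id: str
    data: np.ndarray
    tr_seconds: float = 1.0
    zero_variance_parcels: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ResponseError("parcel time series must be 2-D (parcels x TRs)")
        if not np.all(np.isfinite(self.data)):
            raise ResponseError(
                f"non-finite values in time series (subject={self.subject_id}, "
                f"run={self.run_id})"
            )

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_tr(self) -> int:
        return self.data.shape[1]


@dataclass
class ClipResponseMatrix:
    """n_clips x parcels mean responses, rows aligned to the manifest."""

    level: str  # "subject" | "group"
    data: np.ndarray
    clip_ids: list[str]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.clip_ids):
            raise ResponseError("row count does not match clip_ids")


def nonrest_mask(
    timing: RunTiming, n_tr: int, tr_seconds: float | None = None
) -> np.ndarray:
    """Boolean vector: TR t is non-rest iff onset t*TR lies in a movie interval."""
    tr = timing.tr_seconds if tr_seconds is None else tr_seconds
    if n_tr * tr + tr < timing.end_s - _EPS:
        raise ResponseError(
            f"run {timing.run_id!r}: TR grid ({n_tr} x {tr}s) shorter than timing "
            f"(ends {timing.end_s}s)"
        )
    onsets = np.arange(n_tr) * tr
    mask = np.zeros(n_tr, dtype=bool)
    for iv in timing.movie_intervals():
        mask |= (onsets >= iv.start_s - _EPS) & (onsets < iv.end_s - _EPS)
    return mask


def standardize_nonrest(ts: ParcelTimeSeries, mask: np.ndarray) -> ParcelTimeSeries:
    """z-score each parcel with mean/sd over masked TRs, applied to all TRs.

    Parcels whose masked sd falls below 1e-12 are zeroed out and flagged in
    ``zero_variance_parcels`` instead of dividing by ~0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ResponseError("need at least 2 non-rest TRs to standardize")
    sub = ts.data[:, mask]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] < _SD_FLOOR
    safe_sd = np.where(flat[:, None], 1.0, sd)
    out = (ts.data - mean) / safe_sd
    out[flat, :] = 0.0
    return ParcelTimeSeries(
        subject_id=ts.subject_id,
        run_id=ts.run_id,
        data=out,
        tr_seconds=ts.tr_seconds,
        zero_variance_parcels=np.flatnonzero(flat),
    )


def remove_global_mean(ts: ParcelTimeSeries) -> ParcelTimeSeries:
    """Subtract the across-parcel mean signal at each TR."""
    out = ts.data - ts.data.mean(axis=0, keepdims=True)
    return ParcelTimeSeries(
        subject_id=ts.subject_id,
        run_id=ts.run_id,
        data=out,
        tr_seconds=ts.tr_seconds,
        zero_variance_parcels=ts.zero_variance_parcels.copy(),
    )


def clip_response(
    ts: ParcelTimeSeries, clip: ClipRecord, config: PipelineConfig
) -> np.ndarray:
    """Mean over TRs whose onsets fall in the lagged window
    [start + lag, end + lag)."""
    tr = ts.tr_seconds
    w_start = clip.start_s + config.lag_seconds
    w_end = clip.end_s + config.lag_seconds
    if w_end > ts.n_tr * tr + _EPS:
        raise ResponseError(
            f"clip {clip.clip_id!r}: lagged window ends at {w_end}s, beyond the "
            f"run ({ts.n_tr * tr}s)"
        )
    onsets = np.arange(ts.n_tr) * tr
    sel = (onsets >= w_start - _EPS) & (onsets < w_end - _EPS)
    if not sel.any():
        raise ResponseError(f"clip {clip.clip_id!r}: empty lagged window")
    return ts.data[:, sel].mean(axis=1)


def preprocess_run(
    ts: ParcelTimeSeries, timing: RunTiming, config: PipelineConfig
) -> ParcelTimeSeries:
    """nonrest z-scoring followed by frame-wise global mean removal."""
    mask = nonrest_mask(timing, ts.n_tr, ts.tr_seconds)
    return remove_global_mean(standardize_nonrest(ts, mask))


def subject_clip_matrix(
    run_series: dict[str, ParcelTimeSeries],
    manifest: ClipManifest,
    timings: list[RunTiming],
    config: PipelineConfig,
) -> ClipResponseMatrix:
    """Clip x parcel matrix for one subject, rows in manifest order."""
    timing_by_run = {t.run_id: t for t in timings}
    processed: dict[str, ParcelTimeSeries] = {}
    subject_id = None
    for run_id, ts in run_series.items():
        if run_id not in timing_by_run:
            raise ResponseError(f"no timing provided for run {run_id!r}")
        subject_id = ts.subject_id
        processed[run_id] = preprocess_run(ts, timing_by_run[run_id], config)
    rows = []
    for clip in manifest:
        if clip.run_id not in processed:
            raise ResponseError(
                f"manifest references run {clip.run_id!r} absent from subject data"
            )
        rows.append(clip_response(processed[clip.run_id], clip, config))
    n_parcels = next(iter(processed.values())).n_parcels if processed else 0
    data = np.asarray(rows) if rows else np.empty((0, n_parcels))
    return ClipResponseMatrix(
        level="subject",
        data=data,
        clip_ids=manifest.clip_ids,
        subject_id=subject_id,
    )


def group_aggregate(
    subject_matrices: list[ClipResponseMatrix], trim_fraction: float
) -> ClipResponseMatrix:
    """Per-cell trimmed mean across subjects.

    ``k = floor(trim_fraction * N)`` values are dropped from *each* tail
    before averaging (k = 0 degrades to the plain mean).
    """
    if not subject_matrices:
        raise ResponseError("group_aggregate needs at least one subject")
    shapes = {m.data.shape for m in subject_matrices}
    if len(shapes) != 1:
        raise ResponseError(f"subject matrix shapes differ: {sorted(shapes)}")
    stack = np.stack([m.data for m in subject_matrices], axis=0)  # S x C x P
    n = stack.shape[0]
    k = int(np.floor(trim_fraction * n))
    if k > 0:
        stack = np.sort(stack, axis=0)[k : n - k]
    data = stack.mean(axis=0)
    return ClipResponseMatrix(
        level="group", data=data, clip_ids=list(subject_matrices[0].clip_ids)
    )
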