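"""Sliding-window segmentation of labeled run timing into a clip manifest.

Each continuous movie interval of a run is cut into overlapping clips:
candidate starts are placed every ``clip_step_s`` seconds from the interval
onset, each candidate takes ``min(clip_target_s, usable_end - start)``
seconds where ``usable_end`` reserves ``end_buffer_s`` at the interval tail,
and enumeration halts at the first candidate shorter than ``clip_min_s``.
Clips never cross a rest block or the terminal buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig

VALID_LABELS = ("movie", "rest")

_EPS = 1e-9


class TimingError(ValueError):
    """Malformed run timing (overlap, ordering, or label problems)."""


@dataclass(frozen=True)
class Interval:
    start_s: float
    end_s: float
    label: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class RunTiming:
    """Labeled, ordered, non-overlapping half-open intervals of one run."""

    run_id: str
    intervals: list[Interval]
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = None
        for i, iv in enumerate(self.intervals):
            if iv.label not in VALID_LABELS:
                raise TimingError(
                    f"run {self.run_id!r} row {i}: unknown label {iv.label!r}"
                )
            if iv.end_s <= iv.start_s:
                raise TimingError(
                    f"run {self.run_id!r} row {i}: empty or inverted interval"
                )
            if prev_end is not None and iv.start_s < prev_end - _EPS:
                raise TimingError(
                    f"run {self.run_id!r} row {i}: intervals overlap or are unsorted"
                )
            prev_end = iv.end_s
        if self.tr_seconds <= 0:
            raise TimingError(f"run {self.run_id!r}: tr_seconds must be positive")

    @property
    def end_s(self) -> float:
        return self.intervals[-1].end_s if self.intervals else 0.0

    def movie_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == "movie"]


@dataclass(frozen=True)
class ClipRecord:
    """One stimulus window: half-open [start_s, end_s) inside a movie interval."""

    clip_id: str
    run_id: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ClipManifest:
    clips: list[ClipRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.clips)

    def __iter__(self):
        return iter(self.clips)

    @property
    def clip_ids(self) -> list[str]:
        return [c.clip_id for c in self.clips]

    def validate(self) -> None:
        ids = self.clip_ids
        if len(ids) != len(set(ids)):
            raise TimingError("duplicate clip_id in manifest")


def segment_run(timing: RunTiming, config: PipelineConfig) -> list[ClipRecord]:
    """Enumerate clips for every movie interval of one run.

    Returns clip records in temporal order with ids ``{run_id}:{index}``.
    A movie interval whose usable window is shorter than ``clip_min_s``
    contributes no clips (this is not an error).
    """
    clips: list[ClipRecord] = []
    for iv in timing.movie_intervals():
        usable_end = iv.end_s - config.end_buffer_s
        start = iv.start_s
        while True:
            length = min(config.clip_target_s, usable_end - start)
            if length < config.clip_min_s - _EPS:
                break
            clips.append(
                ClipRecord(
                    clip_id=f"{timing.run_id}:{len(clips)}",
                    run_id=timing.run_id,
                    start_s=start,
                    end_s=start + length,
                )
            )
            start += config.clip_step_s
    return clips


def build_manifest(
    timings: list[RunTiming], config: PipelineConfig
) -> ClipManifest:
    """Concatenate per-run segmentations in run order into one manifest."""
    run_ids = [t.run_id for t in timings]
    if len(run_ids) != len(set(run_ids)):
        raise TimingError("duplicate run_id in timing list")
    clips: list[ClipRecord] = []
    for timing in timings:
        clips.extend(segment_run(timing, config))
    manifest = ClipManifest(clips=clips, provenance=f"config_hash={config.hash()}")
    manifest.validate()
    return manifest
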