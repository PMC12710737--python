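"""Synthetic data with planted structure for parameter-recovery testing.

The study this pipeline implements is empirical and publishes no generative
model; everything in this module is therefore an artifact choice, built so
that each downstream stage has a known ground truth to recover:

* Latent semantic courses are smoothed Gaussian noise squashed to [0, 1]
  and then *exactly* re-pinned, per run, to mean 0.5 and a fixed sd over
  movie TRs.  Because each active parcel loads on exactly one feature, the
  per-run z-scoring step downstream preserves an exactly linear clip-level
  relation between feature scores and responses, so a noiseless run of the
  full pipeline recovers R^2 ~ 1 on active parcels.
* Per feature, active-parcel signs are balanced (+/- in equal numbers) so
  the frame-wise global mean carries no stimulus signal and inactive
  parcels stay at chance.
* A subject gain ``a_s`` scales stimulus-locked signal (hence encoding
  R^2 via SNR), a subject trait ``u_s`` scales a rank-one perturbation of
  resting connectivity strength along a planted unit-norm loading ``w``,
  and the two are coupled through a bivariate-normal copula with
  correlation ``rho_axis`` -- the single dial for the PLS effect size.
* Cognition scores are noisy linear readouts of either ``a_s`` or ``u_s``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .config import COGNITION_NAMES, DEFAULT_SCHEMA, FeatureSchema, PipelineConfig
from .responses import ParcelTimeSeries, nonrest_mask
from .segmentation import ClipManifest, Interval, RunTiming


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class CognitionLink:
    """How one cognitive score reads out a subject-level latent."""

    trait: str  # "gain" (a_s) or "trait" (u_s)
    strength: float
    noise_sd: float


DEFAULT_COGNITION_LINK: dict[str, CognitionLink] = {
    "PMAT24": CognitionLink("gain", 0.5, 0.87),
    "PicSeq": CognitionLink("trait", 0.3, 0.95),
    "ListSort": CognitionLink("gain", 0.4, 0.92),
    "CardSort": CognitionLink("trait", 0.2, 0.98),
    "Flanker": CognitionLink("trait", 0.0, 1.0),
    "CogFluidComp": CognitionLink("gain", 0.5, 0.87),
    "CogCrystalComp": CognitionLink("gain", 0.4, 0.92),
}


@dataclass
class GroundTruth:
    """Planted parameters shared by all synthetic generators."""

    B: np.ndarray  # parcels x 11 true encoding weights
    active_parcels: np.ndarray  # rows of B with any non-zero entry
    gain: np.ndarray  # a_s > 0, one per subject
    trait: np.ndarray  # u_s, one per subject
    w: np.ndarray  # unit-norm planted FC-strength loading
    rho_axis: float
    cognition_link: dict[str, CognitionLink]
    planted_cognition_parcels: np.ndarray
    gain_parcels: np.ndarray  # parcels whose signal is scaled by a_s
    noise_sd: float
    latent_sd: float
    fc_base: float
    fc_coupling: float
    seed: int

    @property
    def n_parcels(self) -> int:
        return self.B.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.gain.shape[0]

    @property
    def n_features(self) -> int:
        return self.B.shape[1]

    def signal_sd(self) -> float:
        """Mean movie-signal sd across active parcels at unit gain.

        Exact because each latent course has per-run sd ``latent_sd`` and
        each active parcel loads a single feature.
        """
        mags = np.abs(self.B[self.active_parcels]).sum(axis=1)
        return float(self.latent_sd * mags.mean())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "B": self.B.tolist(),
            "active_parcels": self.active_parcels.tolist(),
            "gain": self.gain.tolist(),
            "trait": self.trait.tolist(),
            "w": self.w.tolist(),
            "rho_axis": self.rho_axis,
            "cognition_link": {
                k: [v.trait, v.strength, v.noise_sd]
                for k, v in self.cognition_link.items()
            },
            "planted_cognition_parcels": self.planted_cognition_parcels.tolist(),
            "gain_parcels": self.gain_parcels.tolist(),
            "noise_sd": self.noise_sd,
            "latent_sd": self.latent_sd,
            "fc_base": self.fc_base,
            "fc_coupling": self.fc_coupling,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            B=np.asarray(d["B"], dtype=float),
            active_parcels=np.asarray(d["active_parcels"], dtype=int),
            gain=np.asarray(d["gain"], dtype=float),
            trait=np.asarray(d["trait"], dtype=float),
            w=np.asarray(d["w"], dtype=float),
            rho_axis=float(d["rho_axis"]),
            cognition_link={
                k: CognitionLink(v[0], float(v[1]), float(v[2]))
                for k, v in d["cognition_link"].items()
            },
            planted_cognition_parcels=np.asarray(
                d["planted_cognition_parcels"], dtype=int
            ),
            gain_parcels=np.asarray(d["gain_parcels"], dtype=int),
            noise_sd=float(d["noise_sd"]),
            latent_sd=float(d["latent_sd"]),
            fc_base=float(d["fc_base"]),
            fc_coupling=float(d["fc_coupling"]),
            seed=int(d["seed"]),
        )


@dataclass
class LatentFeatureCourse:
    """Per-run 11 x n_TR instantaneous semantic intensities in [0, 1]."""

    courses: dict[str, np.ndarray]
    tr_seconds: float
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)


def make_ground_truth(
    n_subjects: int = 24,
    n_parcels: int = 360,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    parcels_per_feature: int = 6,
    dominant_feature: str = "dialogue",
    dominant_parcels: int = 16,
    magnitude_range: tuple[float, float] = (0.5, 1.5),
    gain_sd: float = 0.4,
    rho_axis: float = 0.0,
    noise_sd: float = 0.05,
    latent_sd: float = 0.1,
    n_fc_parcels: int = 60,
    fc_base: float = 0.3,
    fc_coupling: float = 1.0,
    n_cognition_parcels: int = 20,
    gain_scope: str = "active",
    cognition_link: dict[str, CognitionLink] | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw a GroundTruth with block-sparse single-feature loadings.

    Each feature owns ``parcels_per_feature`` active parcels (the dominant
    feature owns ``dominant_parcels``); counts must be even so signs can be
    balanced exactly.  ``gain_scope`` selects which parcels the subject gain
    scales: ``"active"`` (all active parcels; default) or ``"cognition"``
    (only the planted cognition parcels, localizing R^2-behaviour coupling).
    """
    rng = np.random.default_rng(seed)
    n_features = schema.n_features
    if dominant_feature not in schema.names:
        raise SynthError(f"unknown dominant feature {dominant_feature!r}")
    counts = np.full(n_features, parcels_per_feature)
    counts[schema.names.index(dominant_feature)] = dominant_parcels
    if np.any(counts % 2):
        raise SynthError("per-feature parcel counts must be even (balanced signs)")
    n_active = int(counts.sum())
    if n_active > n_parcels:
        raise SynthError("more active parcels requested than parcels available")

    active = np.sort(rng.choice(n_parcels, size=n_active, replace=False))
    order = rng.permutation(n_active)
    B = np.zeros((n_parcels, n_features))
    pos = 0
    for f in range(n_features):
        idx = active[order[pos : pos + counts[f]]]
        pos += counts[f]
        signs = np.ones(counts[f])
        signs[: counts[f] // 2] = -1.0
        rng.shuffle(signs)
        mags = rng.uniform(*magnitude_range, size=counts[f])
        B[idx, f] = signs * mags

    # coupled subject latents: a_s = exp(gain_sd * z1), u_s = z2
    z = rng.standard_normal((n_subjects, 2))
    z2 = rho_axis * z[:, 0] + np.sqrt(max(0.0, 1 - rho_axis**2)) * z[:, 1]
    gain = np.exp(gain_sd * z[:, 0])
    trait = z2

    if n_fc_parcels % 2:
        raise SynthError("n_fc_parcels must be even (balanced signs)")
    fc_parcels = np.sort(rng.choice(n_parcels, size=n_fc_parcels, replace=False))
    w = np.zeros(n_parcels)
    # exactly balanced signs: the summed perturbation of the shared factor is
    # zero, so unplanted parcels' strength stays (to first order) trait-free
    signs = np.ones(n_fc_parcels)
    signs[: n_fc_parcels // 2] = -1.0
    rng.shuffle(signs)
    w[fc_parcels] = signs / np.sqrt(n_fc_parcels)

    cog_parcels = np.sort(rng.choice(active, size=n_cognition_parcels, replace=False))
    if gain_scope == "active":
        gain_parcels = active.copy()
    elif gain_scope == "cognition":
        gain_parcels = cog_parcels.copy()
    else:
        raise SynthError(f"unknown gain_scope {gain_scope!r}")

    link = dict(DEFAULT_COGNITION_LINK if cognition_link is None else cognition_link)
    unknown = set(link) - set(COGNITION_NAMES)
    if unknown:
        raise SynthError(f"unknown cognition score names: {sorted(unknown)}")
    for name in COGNITION_NAMES:
        if name not in link:
            raise SynthError(f"cognition_link missing score {name!r}")
        if link[name].trait not in ("gain", "trait"):
            raise SynthError(f"unknown linked trait {link[name].trait!r}")

    return GroundTruth(
        B=B,
        active_parcels=active,
        gain=gain,
        trait=trait,
        w=w,
        rho_axis=rho_axis,
        cognition_link=link,
        planted_cognition_parcels=cog_parcels,
        gain_parcels=gain_parcels,
        noise_sd=noise_sd,
        latent_sd=latent_sd,
        fc_base=fc_base,
        fc_coupling=fc_coupling,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

def make_timing(
    n_runs: int,
    segments_per_run: int,
    segment_length_range: tuple[float, float],
    config: PipelineConfig,
    seed: int = 0,
) -> list[RunTiming]:
    """Alternating movie/rest schedules with uniform segment lengths.

    Segment lengths are drawn uniformly in ``segment_length_range`` and
    rounded to whole TRs; rest blocks of ``rest_block_s`` separate segments
    (none after the last).  Deterministic given the seed.
    """
    s_min, s_max = segment_length_range
    if s_min < config.clip_min_s + config.end_buffer_s:
        raise SynthError(
            f"segment_length_range min {s_min} < clip_min_s + end_buffer_s "
            f"({config.clip_min_s + config.end_buffer_s}); segments would be unusable"
        )
    if s_max < s_min:
        raise SynthError("segment_length_range must be (min, max) with min <= max")
    rng = np.random.default_rng(seed)
    tr = config.tr_seconds
    timings = []
    for r in range(n_runs):
        t = 0.0
        intervals = []
        for s in range(segments_per_run):
            length = float(np.round(rng.uniform(s_min, s_max) / tr) * tr)
            intervals.append(Interval(t, t + length, "movie"))
            t += length
            if s < segments_per_run - 1:
                intervals.append(Interval(t, t + config.rest_block_s, "rest"))
                t += config.rest_block_s
        timings.append(RunTiming(f"run{r + 1}", intervals, tr_seconds=tr))
    return timings


# ---------------------------------------------------------------------------
# latent semantic courses and clip scores
# ---------------------------------------------------------------------------

def make_latent_features(
    timings: list[RunTiming],
    smoothness_s: float = 8.0,
    seed: int = 0,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    latent_sd: float = 0.1,
    pin_tail_s: float = 5.0,
) -> LatentFeatureCourse:
    """Smooth, bounded, feature-independent intensity courses.

    Gaussian noise is smoothed (kernel sd = ``smoothness_s``), squashed
    through a logistic, then affinely re-pinned per run so each feature has
    *exactly* mean 0.5 and sd ``latent_sd`` (n-1 denominator) over the
    movie TRs that downstream stages actually read.  Rest TRs are exactly 0.

    ``pin_tail_s`` excludes the final stretch of each movie interval from
    the pinning statistics: with a hemodynamic lag of the same length, the
    BOLD signal at movie TRs reads the latent course shifted backwards, so
    the last ``lag`` seconds of a segment influence only post-segment rest
    TRs (and the terminal clip buffer keeps clip windows out of them too).
    Pinning exactly the *read* set keeps every run's z-scored response an
    identical linear function of the clip scores, which is what makes
    noiseless end-to-end recovery exact.  Set it to the pipeline's
    ``lag_seconds``.
    """
    if smoothness_s <= 0:
        raise SynthError("smoothness_s must be positive")
    rng = np.random.default_rng(seed)
    courses: dict[str, np.ndarray] = {}
    tr = timings[0].tr_seconds if timings else 1.0
    for timing in timings:
        n_tr = int(round(timing.end_s / timing.tr_seconds))
        mask = nonrest_mask(timing, n_tr)
        onsets = np.arange(n_tr) * timing.tr_seconds
        pin = np.zeros(n_tr, dtype=bool)
        for iv in timing.movie_intervals():
            pin |= (onsets >= iv.start_s - 1e-9) & (
                onsets < iv.end_s - pin_tail_s - 1e-9
            )
        if pin.sum() < 2:
            raise SynthError(f"run {timing.run_id!r} has fewer than 2 usable TRs")
        g = rng.standard_normal((schema.n_features, n_tr))
        g = gaussian_filter1d(g, sigma=smoothness_s / timing.tr_seconds, axis=1)
        g = g / g[:, pin].std(axis=1, ddof=1, keepdims=True)
        p = expit(g)
        m = p[:, pin].mean(axis=1, keepdims=True)
        s = p[:, pin].std(axis=1, ddof=1, keepdims=True)
        course = 0.5 + latent_sd * (p - m) / s
        course = np.clip(course, 0.0, 1.0)  # safety; pinning keeps values inside
        course[:, ~mask] = 0.0
        courses[timing.run_id] = course
    return LatentFeatureCourse(courses=courses, tr_seconds=tr, schema=schema)


def clip_scores_from_latent(
    latent: LatentFeatureCourse,
    manifest: ClipManifest,
    timings: list[RunTiming],
) -> pd.DataFrame:
    """Clip scores as window means of the latent course (unlagged window).

    Guarantees exact consistency between the feature table and the quantity
    the response-averaging stage sees after the hemodynamic shift.
    """
    timing_by_run = {t.run_id: t for t in timings}
    rows = []
    for clip in manifest:
        timing = timing_by_run[clip.run_id]
        course = latent.courses[clip.run_id]
        tr = timing.tr_seconds
        onsets = np.arange(course.shape[1]) * tr
        sel = (onsets >= clip.start_s - 1e-9) & (onsets < clip.end_s - 1e-9)
        inside = any(
            iv.start_s - 1e-9 <= clip.start_s and clip.end_s <= iv.end_s + 1e-9
            for iv in timing.movie_intervals()
        )
        if not inside:
            raise SynthError(f"clip {clip.clip_id!r} not inside a movie interval")
        rows.append(course[:, sel].mean(axis=1))
    df = pd.DataFrame(rows, index=manifest.clip_ids, columns=list(latent.schema.names))
    df.index.name = "clip_id"
    return df


# ---------------------------------------------------------------------------
# BOLD-like time series
# ---------------------------------------------------------------------------

def make_movie_timeseries(
    truth: GroundTruth,
    latent: LatentFeatureCourse,
    timings: list[RunTiming],
    config: PipelineConfig,
    subject: int,
    seed: int | None = None,
) -> dict[str, ParcelTimeSeries]:
    """Movie runs for one subject: gain-scaled linear readout of the lagged
    centered latent plus iid Gaussian noise; rest TRs carry noise only."""
    if truth.B.shape[1] != latent.schema.n_features:
        raise SynthError("truth feature count does not match latent schema")
    shortest = min(
        (iv.duration_s for t in timings for iv in t.movie_intervals()),
        default=np.inf,
    )
    if config.lag_seconds > shortest:
        raise SynthError(
            f"lag {config.lag_seconds}s exceeds shortest movie segment ({shortest}s)"
        )
    base_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, 1000, subject])
    lag_trs = int(round(config.lag_seconds / config.tr_seconds))
    gains = np.ones(truth.n_parcels)
    gains[truth.gain_parcels] = truth.gain[subject]
    out: dict[str, ParcelTimeSeries] = {}
    for timing in timings:
        course = latent.courses[timing.run_id]
        n_tr = course.shape[1]
        mask = nonrest_mask(timing, n_tr)
        mean = course[:, mask].mean(axis=1, keepdims=True)
        shifted = np.zeros_like(course)
        if lag_trs < n_tr:
            shifted[:, lag_trs:] = course[:, : n_tr - lag_trs]
        signal = (gains[:, None] * truth.B) @ (shifted - mean)
        signal[:, ~mask] = 0.0
        noise = rng.normal(0.0, truth.noise_sd, size=signal.shape)
        out[timing.run_id] = ParcelTimeSeries(
            subject_id=f"sub{subject:03d}",
            run_id=timing.run_id,
            data=signal + noise,
            tr_seconds=timing.tr_seconds,
        )
    return out


def make_rest_timeseries(
    truth: GroundTruth,
    n_tr_rest: int,
    subject: int,
    seed: int | None = None,
    tr_seconds: float = 1.0,
) -> ParcelTimeSeries:
    """Resting run with a planted rank-one strength perturbation.

    A single global factor with parcel-specific loading ``sqrt(c_i)`` yields
    pairwise correlations ``sqrt(c_i c_j)``; with
    ``c_i = fc_base + u_s * fc_coupling * w_i`` the across-subject variation
    of nodewise strength is (to first order) proportional to ``u_s * w``.
    """
    if n_tr_rest < 100:
        raise SynthError("n_tr_rest must be at least 100")
    base_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, 2000, subject])
    c = truth.fc_base + truth.trait[subject] * truth.fc_coupling * truth.w
    c = np.clip(c, 0.02, 0.93)
    g = rng.standard_normal(n_tr_rest)
    # pin the shared factor's realized moments: its sampling variance would
    # otherwise shift every parcel's strength coherently per subject, adding
    # a large common mode across columns that masks the planted rank-one axis
    g = (g - g.mean()) / g.std(ddof=1)
    e = rng.standard_normal((truth.n_parcels, n_tr_rest))
    data = np.sqrt(c)[:, None] * g[None, :] + np.sqrt(1.0 - c)[:, None] * e
    return ParcelTimeSeries(
        subject_id=f"sub{subject:03d}",
        run_id="rest",
        data=data,
        tr_seconds=tr_seconds,
    )


# ---------------------------------------------------------------------------
# cognition
# ---------------------------------------------------------------------------

def make_cognition(truth: GroundTruth, seed: int | None = None) -> pd.DataFrame:
    """Subjects x 7 score table, each column standardized to mean 0 / sd 1."""
    base_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, 3000])
    traits = {"gain": truth.gain, "trait": truth.trait}
    cols = {}
    for name in COGNITION_NAMES:
        link = truth.cognition_link[name]
        t = traits[link.trait]
        t_std = (t - t.mean()) / t.std(ddof=1)
        score = link.strength * t_std + rng.normal(0.0, link.noise_sd, truth.n_subjects)
        sd = score.std(ddof=1)
        cols[name] = (score - score.mean()) / sd if sd > 1e-12 else score * 0.0
    df = pd.DataFrame(
        cols, index=[f"sub{s:03d}" for s in range(truth.n_subjects)]
    )
    df.index.name = "subject_id"
    return df
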