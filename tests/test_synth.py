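import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semcine import synth
from semcine.config import COGNITION_NAMES, PipelineConfig
from semcine.responses import nonrest_mask
from semcine.segmentation import build_manifest
from semcine.synth import (
    CognitionLink,
    SynthError,
    clip_scores_from_latent,
    make_cognition,
    make_ground_truth,
    make_latent_features,
    make_movie_timeseries,
    make_rest_timeseries,
    make_timing,
)


# -- make_timing ------------------------------------------------------------

def test_timing_durations_add_up(cfg):
    timings = make_timing(4, 8, (60.0, 60.0), cfg, seed=0)
    assert len(timings) == 4
    for t in timings:
        assert t.end_s == pytest.approx(8 * 60 + 7 * 20)  # 620 s


def test_single_segment_no_rest(cfg):
    timings = make_timing(1, 1, (60.0, 60.0), cfg, seed=0)
    assert len(timings[0].intervals) == 1
    assert timings[0].intervals[0].label == "movie"


def test_timing_deterministic(cfg):
    a = make_timing(3, 4, (40.0, 80.0), cfg, seed=5)
    b = make_timing(3, 4, (40.0, 80.0), cfg, seed=5)
    assert [t.intervals for t in a] == [t.intervals for t in b]


def test_timing_segment_too_short_rejected(cfg):
    with pytest.raises(SynthError, match="unusable"):
        make_timing(1, 2, (10.0, 60.0), cfg, seed=0)


def test_timing_lengths_snap_to_tr_grid():
    cfg = PipelineConfig(tr_seconds=2.0)
    timings = make_timing(2, 3, (41.0, 79.0), cfg, seed=1)
    for t in timings:
        for iv in t.intervals:
            assert (iv.duration_s / 2.0) == pytest.approx(round(iv.duration_s / 2.0))


# -- make_latent_features ---------------------------------------------------

@pytest.fixture(scope="module")
def latent_setup():
    cfg = PipelineConfig()
    timings = make_timing(2, 4, (60.0, 60.0), cfg, seed=2)
    latent = make_latent_features(timings, smoothness_s=8.0, seed=2)
    return cfg, timings, latent


def test_latent_values_bounded(latent_setup):
    _, _, latent = latent_setup
    for course in latent.courses.values():
        assert course.min() >= 0.0 and course.max() <= 1.0


def test_latent_rest_trs_exactly_zero(latent_setup):
    _, timings, latent = latent_setup
    for t in timings:
        mask = nonrest_mask(t, latent.courses[t.run_id].shape[1])
        assert (latent.courses[t.run_id][:, ~mask] == 0).all()


def test_latent_lag1_autocorrelation_high(latent_setup):
    _, timings, latent = latent_setup
    course = latent.courses["run1"]
    iv = timings[0].movie_intervals()[0]
    seg = course[:, int(iv.start_s) : int(iv.end_s)]
    for f in range(seg.shape[0]):
        ac = np.corrcoef(seg[f, :-1], seg[f, 1:])[0, 1]
        assert ac > 0.8


def test_latent_deterministic(latent_setup):
    cfg, timings, latent = latent_setup
    again = make_latent_features(timings, smoothness_s=8.0, seed=2)
    for run_id in latent.courses:
        np.testing.assert_array_equal(latent.courses[run_id], again.courses[run_id])


def test_latent_exact_pinning(latent_setup):
    """Mean 0.5 / sd latent_sd exactly over the read TR set of every run."""
    _, timings, latent = latent_setup
    for t in timings:
        course = latent.courses[t.run_id]
        onsets = np.arange(course.shape[1]) * t.tr_seconds
        pin = np.zeros(course.shape[1], dtype=bool)
        for iv in t.movie_intervals():
            pin |= (onsets >= iv.start_s) & (onsets < iv.end_s - 5.0)
        np.testing.assert_allclose(course[:, pin].mean(axis=1), 0.5, atol=1e-12)
        np.testing.assert_allclose(
            course[:, pin].std(axis=1, ddof=1), 0.1, atol=1e-12
        )


# -- clip_scores_from_latent ------------------------------------------------

def test_clip_scores_constant_latent(cfg):
    timings = make_timing(1, 1, (65.0, 65.0), cfg, seed=0)
    latent = make_latent_features(timings, seed=0)
    latent.courses["run1"][3, :] = 0.7
    manifest = build_manifest(timings, cfg)
    scores = clip_scores_from_latent(latent, manifest, timings)
    np.testing.assert_allclose(scores.iloc[:, 3], 0.7, atol=1e-12)


def test_clip_scores_linear_ramp_midpoint(cfg):
    timings = make_timing(1, 1, (65.0, 65.0), cfg, seed=0)
    latent = make_latent_features(timings, seed=0)
    n = latent.courses["run1"].shape[1]
    # ramp 0 -> 1 across the first clip's 20 TR onsets
    latent.courses["run1"][0, :] = 0.0
    latent.courses["run1"][0, :20] = np.linspace(0, 1, 20)
    manifest = build_manifest(timings, cfg)
    scores = clip_scores_from_latent(latent, manifest, timings)
    assert scores.iloc[0, 0] == pytest.approx(0.5)


def test_clip_scores_identical_latent_stretches(cfg):
    timings = make_timing(1, 2, (60.0, 60.0), cfg, seed=1)
    latent = make_latent_features(timings, seed=1)
    course = latent.courses["run1"]
    course[:, 80:140] = course[:, 0:60]  # copy segment 1 into segment 2
    manifest = build_manifest(timings, cfg)
    scores = clip_scores_from_latent(latent, manifest, timings)
    np.testing.assert_allclose(
        scores.iloc[0].to_numpy(), scores.iloc[4].to_numpy(), atol=1e-12
    )


def test_clip_outside_movie_interval_rejected(cfg):
    from semcine.segmentation import ClipManifest, ClipRecord

    timings = make_timing(1, 1, (65.0, 65.0), cfg, seed=0)
    latent = make_latent_features(timings, seed=0)
    bad = ClipManifest(clips=[ClipRecord("x", "run1", 50.0, 70.0)])
    with pytest.raises(SynthError, match="x"):
        clip_scores_from_latent(latent, bad, timings)


# -- make_ground_truth ------------------------------------------------------

def test_truth_block_sparse_single_feature_rows():
    truth = make_ground_truth(seed=0)
    nonzero = (truth.B != 0).sum(axis=1)
    assert set(nonzero[truth.active_parcels]) == {1}
    assert (nonzero[np.setdiff1d(np.arange(360), truth.active_parcels)] == 0).all()


def test_truth_balanced_signs_per_feature():
    truth = make_ground_truth(seed=1)
    signs = np.sign(truth.B)
    np.testing.assert_array_equal(signs.sum(axis=0), np.zeros(11))


def test_truth_gain_positive_w_unit_norm():
    truth = make_ground_truth(seed=2)
    assert (truth.gain > 0).all()
    assert np.linalg.norm(truth.w) == pytest.approx(1.0)


def test_truth_rho_axis_couples_gain_and_trait():
    truth = make_ground_truth(n_subjects=4000, rho_axis=0.7, seed=3)
    r = np.corrcoef(np.log(truth.gain), truth.trait)[0, 1]
    assert r == pytest.approx(0.7, abs=0.05)


def test_truth_json_round_trip(tmp_path):
    truth = make_ground_truth(seed=4)
    truth.to_json(tmp_path / "truth.json")
    again = synth.GroundTruth.from_json(tmp_path / "truth.json")
    np.testing.assert_array_equal(truth.B, again.B)
    np.testing.assert_array_equal(truth.gain, again.gain)
    assert truth.cognition_link == again.cognition_link


# -- make_movie_timeseries --------------------------------------------------

@pytest.fixture(scope="module")
def movie_setup():
    cfg = PipelineConfig()
    timings = make_timing(1, 2, (60.0, 60.0), cfg, seed=6)
    latent = make_latent_features(timings, seed=6, pin_tail_s=cfg.lag_seconds)
    return cfg, timings, latent


def test_movie_zero_truth_zero_noise_is_silent(movie_setup):
    cfg, timings, latent = movie_setup
    truth = make_ground_truth(noise_sd=0.0, seed=6)
    truth.B[:] = 0.0
    runs = make_movie_timeseries(truth, latent, timings, cfg, subject=0)
    for ts in runs.values():
        assert (ts.data == 0).all()


def test_movie_single_parcel_reconstruction(movie_setup):
    """With one active parcel and zero noise its course equals
    gain * (centered lagged latent) exactly."""
    cfg, timings, latent = movie_setup
    truth = make_ground_truth(noise_sd=0.0, seed=7)
    truth.B[:] = 0.0
    parcel = int(truth.active_parcels[0])
    truth.B[parcel, 0] = 1.0
    truth.gain_parcels = np.array([parcel])
    runs = make_movie_timeseries(truth, latent, timings, cfg, subject=0)
    ts = runs["run1"]
    course = latent.courses["run1"]
    mask = nonrest_mask(timings[0], course.shape[1])
    mean = course[0, mask].mean()
    shifted = np.zeros_like(course[0])
    shifted[5:] = course[0, :-5]
    expected = truth.gain[0] * (shifted - mean)
    expected[~mask] = 0.0
    np.testing.assert_allclose(ts.data[parcel], expected, atol=1e-12)
    # rest TRs are pure noise (here: zero)
    assert (ts.data[:, ~mask] == 0).all()


def test_movie_gain_scales_signal_sd(movie_setup):
    cfg, timings, latent = movie_setup
    truth = make_ground_truth(noise_sd=0.0, seed=8)
    sd1 = {
        r: ts.data[truth.gain_parcels].std()
        for r, ts in make_movie_timeseries(truth, latent, timings, cfg, 0).items()
    }
    truth.gain[0] *= 2.0
    sd2 = {
        r: ts.data[truth.gain_parcels].std()
        for r, ts in make_movie_timeseries(truth, latent, timings, cfg, 0).items()
    }
    for r in sd1:
        assert sd2[r] == pytest.approx(2 * sd1[r], rel=1e-9)


def test_movie_lag_longer_than_segment_rejected(cfg):
    timings = make_timing(1, 2, (25.0, 25.0), cfg, seed=9)
    latent = make_latent_features(timings, seed=9)
    truth = make_ground_truth(seed=9)
    bad_cfg = cfg.replace(lag_seconds=30.0)
    with pytest.raises(SynthError, match="lag"):
        make_movie_timeseries(truth, latent, timings, bad_cfg, 0)


def test_movie_deterministic(movie_setup):
    cfg, timings, latent = movie_setup
    truth = make_ground_truth(seed=10)
    a = make_movie_timeseries(truth, latent, timings, cfg, 3)
    b = make_movie_timeseries(truth, latent, timings, cfg, 3)
    for r in a:
        np.testing.assert_array_equal(a[r].data, b[r].data)


# -- make_rest_timeseries ---------------------------------------------------

def test_rest_requires_100_trs():
    truth = make_ground_truth(seed=11)
    with pytest.raises(SynthError):
        make_rest_timeseries(truth, 99, 0)


def test_rest_deterministic():
    truth = make_ground_truth(seed=12)
    a = make_rest_timeseries(truth, 200, 1)
    b = make_rest_timeseries(truth, 200, 1)
    np.testing.assert_array_equal(a.data, b.data)


def test_rest_strength_difference_recovers_w():
    from semcine.connectivity import fc_matrix, fc_strength

    truth = make_ground_truth(n_subjects=2, seed=13)
    truth.trait[:] = [2.0, -2.0]
    profiles = [
        fc_strength(fc_matrix(make_rest_timeseries(truth, 2000, s)))
        for s in range(2)
    ]
    r = np.corrcoef(profiles[0] - profiles[1], truth.w)[0, 1]
    assert r > 0.8


def test_rest_no_trait_variation_means_noise_floor():
    from semcine.connectivity import fc_matrix, fc_strength

    truth = make_ground_truth(n_subjects=50, seed=14)
    truth.trait[:] = 0.0
    profiles = np.stack(
        [fc_strength(fc_matrix(make_rest_timeseries(truth, 800, s)))
         for s in range(50)]
    )
    # across-subject variance should be pure estimation noise, far below the
    # planted-coupling scale (|w_i| * coupling ~ 0.13 in strength units)
    assert profiles.var(axis=0, ddof=1).mean() < 1e-3


# -- make_cognition ---------------------------------------------------------

def test_cognition_unlinked_score_uncorrelated():
    link = dict(synth.DEFAULT_COGNITION_LINK)
    link["PMAT24"] = CognitionLink("gain", 0.0, 1.0)
    truth = make_ground_truth(n_subjects=500, cognition_link=link, seed=15)
    cog = make_cognition(truth)
    r = np.corrcoef(cog["PMAT24"], truth.gain)[0, 1]
    assert abs(r) < 0.15


def test_cognition_noiseless_link_is_monotone():
    link = {name: CognitionLink("trait", 1.0, 0.0) for name in COGNITION_NAMES}
    truth = make_ground_truth(n_subjects=40, cognition_link=link, seed=16)
    cog = make_cognition(truth)
    rho = stats.spearmanr(cog["PMAT24"], truth.trait).statistic
    assert rho == pytest.approx(1.0)


def test_cognition_schema_and_standardization():
    truth = make_ground_truth(n_subjects=30, seed=17)
    cog = make_cognition(truth)
    assert list(cog.columns) == list(COGNITION_NAMES)
    np.testing.assert_allclose(cog.mean(), 0, atol=1e-10)
    np.testing.assert_allclose(cog.std(ddof=1), 1, atol=1e-10)


def test_cognition_unknown_score_rejected():
    with pytest.raises(SynthError, match="unknown"):
        make_ground_truth(
            cognition_link={**synth.DEFAULT_COGNITION_LINK, "Oops": CognitionLink("gain", 1, 1)},
            seed=18,
        )


def test_subject_gain_ordering_drives_mean_active_r2(session_cfg):
    """Planted ordering: mean R^2 over active parcels increases with a_s."""
    import semcine.encoding as enc
    from semcine.pipeline import SimulationSpec, simulate_inputs, subject_matrices

    sim = SimulationSpec(n_subjects=24, noise_sd=0.05)
    truth, timings, latent, manifest, features = simulate_inputs(
        session_cfg, sim, seed=19
    )
    truth.noise_sd = 0.5 * truth.signal_sd()
    r2 = np.stack(
        [
            enc.loocv_encode(features, mat, session_cfg.ridge_lambda).r2
            for _, mat in subject_matrices(truth, latent, timings, manifest, session_cfg)
        ]
    )
    mean_active = np.nanmean(r2[:, truth.active_parcels], axis=1)
    rho = stats.spearmanr(truth.gain, mean_active).statistic
    assert rho > 0.9
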