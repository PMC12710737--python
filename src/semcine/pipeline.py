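"""End-to-end orchestration: simulate -> segment -> extract -> encode ->
fc -> pls -> cognition, with every intermediate written to disk.

All stages are pure functions of (config, seed), so two runs with the same
arguments produce bitwise-identical output trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, encoding, io, pls, synth
from .cognition import couple
from .config import FEATURE_NAMES, PipelineConfig
from .responses import ClipResponseMatrix, group_aggregate, subject_clip_matrix
from .segmentation import ClipManifest, RunTiming, build_manifest


@dataclass
class SimulationSpec:
    """Desk-scale defaults: 24 subjects, 4 runs of six 60-s segments."""

    n_subjects: int = 24
    n_runs: int = 4
    segments_per_run: int = 6
    segment_length_range: tuple[float, float] = (60.0, 60.0)
    smoothness_s: float = 8.0
    n_tr_rest: int = 1200
    rho_axis: float = 0.6
    gain_sd: float = 0.4
    noise_sd: float = 0.05
    gain_scope: str = "active"


@dataclass
class PipelineOutputs:
    truth: synth.GroundTruth
    timings: list[RunTiming]
    manifest: ClipManifest
    features: pd.DataFrame
    group_responses: ClipResponseMatrix
    group_encoding: encoding.EncodingResult
    subject_r2: np.ndarray  # subjects x parcels
    fc_strength: np.ndarray  # subjects x parcels
    pls_result: pls.PLSResult
    cognition: pd.DataFrame
    coupling: "object"


def simulate_inputs(config: PipelineConfig, sim: SimulationSpec, seed: int):
    """Ground truth, timing, latent courses, manifest, and feature table."""
    truth = synth.make_ground_truth(
        n_subjects=sim.n_subjects,
        n_parcels=config.n_parcels,
        gain_sd=sim.gain_sd,
        rho_axis=sim.rho_axis,
        noise_sd=sim.noise_sd,
        gain_scope=sim.gain_scope,
        seed=seed,
    )
    timings = synth.make_timing(
        sim.n_runs,
        sim.segments_per_run,
        sim.segment_length_range,
        config,
        seed=seed,
    )
    latent = synth.make_latent_features(
        timings,
        smoothness_s=sim.smoothness_s,
        seed=seed,
        pin_tail_s=config.lag_seconds,
    )
    manifest = build_manifest(timings, config)
    features = synth.clip_scores_from_latent(latent, manifest, timings)
    return truth, timings, latent, manifest, features


def subject_matrices(truth, latent, timings, manifest, config):
    """Yield (subject_index, ClipResponseMatrix) without keeping raw series."""
    for s in range(truth.n_subjects):
        runs = synth.make_movie_timeseries(truth, latent, timings, config, s)
        yield s, subject_clip_matrix(runs, manifest, timings, config)


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int,
    sim: SimulationSpec | None = None,
) -> PipelineOutputs:
    sim = sim or SimulationSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config.replace(rng_seed=seed)

    truth, timings, latent, manifest, features = simulate_inputs(config, sim, seed)
    truth.to_json(out / "truth.json")
    io.write_timing(out / "timing.csv", timings, config)
    io.write_manifest(out / "manifest.csv", manifest, config)
    io.write_feature_table(out / "features.csv", features, config)

    parcel_cols = io.parcel_labels(truth.n_parcels)
    subj_ids = [f"sub{s:03d}" for s in range(truth.n_subjects)]

    # movie responses: per-subject clip matrices, trimmed group mean
    subject_mats = []
    resp_dir = out / "responses"
    for s, mat in subject_matrices(truth, latent, timings, manifest, config):
        subject_mats.append(mat)
        io.write_matrix_tsv(
            resp_dir / f"{subj_ids[s]}_responses.tsv",
            mat.data,
            mat.clip_ids,
            parcel_cols,
            index_name="clip_id",
            config=config,
        )
    group = group_aggregate(subject_mats, config.trim_fraction)
    io.write_matrix_tsv(
        out / "group_responses.tsv",
        group.data,
        group.clip_ids,
        parcel_cols,
        index_name="clip_id",
        config=config,
    )

    # encoding: group map + subject R^2 profiles
    group_enc = encoding.loocv_encode(features, group, config.ridge_lambda)
    io.write_matrix_tsv(
        out / "r2.tsv", group_enc.r2[:, None], parcel_cols, ["r2"],
        index_name="parcel", config=config,
    )
    io.write_matrix_tsv(
        out / "beta.tsv", group_enc.beta, parcel_cols, list(FEATURE_NAMES),
        index_name="parcel", config=config,
    )
    importance = encoding.feature_importance(group_enc)
    io.write_matrix_tsv(
        out / "importance.tsv",
        np.stack([importance.mean_abs_beta, importance.weighted_abs_beta]),
        ["mean_abs_beta", "weighted_abs_beta"],
        list(FEATURE_NAMES),
        index_name="metric",
        config=config,
    )
    subject_r2 = np.stack(
        [
            encoding.loocv_encode(features, mat, config.ridge_lambda).r2
            for mat in subject_mats
        ]
    )
    io.write_matrix_tsv(
        out / "subject_r2.tsv", subject_r2, subj_ids, parcel_cols,
        index_name="subject_id", config=config,
    )

    # resting-state strength profiles
    rests = [
        synth.make_rest_timeseries(truth, sim.n_tr_rest, s)
        for s in range(truth.n_subjects)
    ]
    strength = connectivity.subject_strength_profiles(rests)
    io.write_matrix_tsv(
        out / "fc_strength.tsv", strength, subj_ids, parcel_cols,
        index_name="subject_id", config=config,
    )

    # PLS between subject R^2 and FC strength
    x_for_pls = np.nan_to_num(subject_r2, nan=0.0)
    pls_result = pls.pls_full(
        x_for_pls,
        strength,
        K=1,
        n_perm=config.n_permutations,
        n_boot=config.n_bootstrap,
        seed=seed,
        center_only=config.pls_center_only,
    )
    pls_dir = out / "pls"
    io.write_matrix_tsv(
        pls_dir / "saliences.tsv",
        np.column_stack([pls_result.u[:, 0], pls_result.v[:, 0]]),
        parcel_cols, ["u_lv1", "v_lv1"], index_name="parcel", config=config,
    )
    io.write_matrix_tsv(
        pls_dir / "scores.tsv",
        np.column_stack([pls_result.x_scores[:, 0], pls_result.y_scores[:, 0]]),
        subj_ids, ["x_score_lv1", "y_score_lv1"],
        index_name="subject_id", config=config,
    )
    io.write_matrix_tsv(
        pls_dir / "varexp.tsv",
        np.array(
            [
                [
                    pls_result.singular_values[0],
                    pls_result.covariance_explained[0],
                    pls_result.block_variance_explained["x"][0],
                    pls_result.block_variance_explained["y"][0],
                    pls_result.perm_p[0],
                ]
            ]
        ),
        ["lv1"],
        ["singular_value", "cov_explained", "x_var_explained", "y_var_explained",
         "perm_p"],
        index_name="component",
        config=config,
    )
    io.write_matrix_tsv(
        pls_dir / "boot_z.tsv",
        np.column_stack([pls_result.boot_z_u[:, 0], pls_result.boot_z_v[:, 0]]),
        parcel_cols, ["boot_z_u", "boot_z_v"], index_name="parcel", config=config,
    )

    # cognition coupling
    cognition = synth.make_cognition(truth)
    io.write_cognition(out / "cognition.csv", cognition, config)
    coupling = couple(subject_r2, cognition, q=config.fdr_q)
    cog_dir = out / "cognition"
    io.write_matrix_tsv(
        cog_dir / "rho.tsv", coupling.rho, parcel_cols, coupling.score_names,
        index_name="parcel", config=config,
    )
    io.write_matrix_tsv(
        cog_dir / "p.tsv", coupling.p, parcel_cols, coupling.score_names,
        index_name="parcel", config=config,
    )
    io.write_matrix_tsv(
        cog_dir / "significant.tsv",
        coupling.significant.astype(int),
        parcel_cols, coupling.score_names, index_name="parcel", config=config,
    )
    io.write_matrix_tsv(
        cog_dir / "map_similarity.tsv",
        coupling.map_similarity,
        coupling.score_names, coupling.score_names,
        index_name="score", config=config,
    )

    return PipelineOutputs(
        truth=truth,
        timings=timings,
        manifest=manifest,
        features=features,
        group_responses=group,
        group_encoding=group_enc,
        subject_r2=subject_r2,
        fc_strength=strength,
        pls_result=pls_result,
        cognition=cognition,
        coupling=coupling,
    )
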