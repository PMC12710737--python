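import numpy as np
import pytest

from semcine.config import PipelineConfig
from semcine.pipeline import SimulationSpec, simulate_inputs, subject_matrices
from semcine.responses import group_aggregate


@pytest.fixture()
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def session_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def noiseless_run(session_cfg):
    """Desk-scale noiseless simulation shared across tests (expensive-ish)."""
    sim = SimulationSpec(n_subjects=6, noise_sd=0.0)
    truth, timings, latent, manifest, features = simulate_inputs(
        session_cfg, sim, seed=101
    )
    mats = [m for _, m in subject_matrices(truth, latent, timings, manifest, session_cfg)]
    group = group_aggregate(mats, session_cfg.trim_fraction)
    return {
        "truth": truth,
        "timings": timings,
        "latent": latent,
        "manifest": manifest,
        "features": features,
        "subject_mats": mats,
        "group": group,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
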