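"""Per-parcel ridge encoding of clip responses from semantic features.

For every parcel a ridge model (penalty on the standardized scale, no
intercept after centering) is evaluated with leave-one-out cross-validation.
Standardization of predictors and response uses training-fold statistics
only and the held-out prediction is back-transformed to the original
response scale; R^2 pools all held-out predictions around the grand
observed mean, so values may be negative when the model underperforms a
mean-only baseline.  Reported coefficients come from a final all-data fit;
fold-averaged coefficients are retained for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .responses import ClipResponseMatrix

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-12


class EncodingError(ValueError):
    pass


@dataclass
class EncodingResult:
    r2: np.ndarray  # parcels; NaN where undefined
    beta: np.ndarray  # parcels x 11, standardized units, all-data fit
    beta_folds: np.ndarray  # parcels x 11, mean over LOOCV folds
    predictions: np.ndarray  # n_clips x parcels, original response units
    undefined_parcels: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )
    clip_ids: list[str] = field(default_factory=list)


@dataclass
class FeatureImportance:
    mean_abs_beta: np.ndarray  # length 11
    weighted_abs_beta: np.ndarray  # length 11, weights = max(R^2, 0) normalized


def ridge_fit(Xs: np.ndarray, ys: np.ndarray, lam: float) -> np.ndarray:
    """Solve (Xs'Xs + lam*I) b = Xs'ys.

    ``ys`` may be a vector or an n x P matrix (one solve for all parcels).
    Inputs are assumed centered/standardized by the caller; no intercept.
    """
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if not (np.all(np.isfinite(Xs)) and np.all(np.isfinite(ys))):
        raise EncodingError("non-finite values passed to ridge_fit")
    if lam <= 0:
        raise EncodingError("ridge penalty must be positive")
    p = Xs.shape[1]
    A = Xs.T @ Xs + lam * np.eye(p)
    return np.linalg.solve(A, Xs.T @ ys)


def _standardize_train(M: np.ndarray, warn_context: str | None = None):
    """Column mean/sd (ddof=1) with zero-variance columns mapped to z = 0."""
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    flat = sd < _SD_FLOOR
    if flat.any() and warn_context:
        logger.warning(
            "%s: %d zero-variance column(s); their z-scores set to 0",
            warn_context,
            int(flat.sum()),
        )
    safe = np.where(flat, 1.0, sd)
    return mean, safe, flat


def loocv_encode(
    features: pd.DataFrame,
    responses: ClipResponseMatrix,
    lam: float = 1.0,
) -> EncodingResult:
    """LOOCV ridge encoding of every parcel from the clip feature table.

    Rows of ``features`` and ``responses`` are aligned via clip ids; a
    mismatch is an error, never silently reordered.
    """
    clip_ids = list(responses.clip_ids)
    if list(features.index) != clip_ids:
        if set(features.index) != set(clip_ids):
            raise EncodingError("feature table and responses cover different clips")
        features = features.loc[clip_ids]
    X = features.to_numpy(dtype=float)
    Y = np.asarray(responses.data, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise EncodingError(f"need more clips ({n}) than features ({p}) for LOOCV")
    n_parcels = Y.shape[1]

    undefined = np.flatnonzero(Y.var(axis=0) < _SD_FLOOR)
    preds = np.empty_like(Y)
    beta_folds = np.zeros((n_parcels, p))
    for k in range(n):
        train = np.ones(n, dtype=bool)
        train[k] = False
        mx, sx, _ = _standardize_train(X[train], warn_context=f"fold {k} features")
        Xt = (X[train] - mx) / sx
        xk = (X[k] - mx) / sx
        my, sy, flat_y = _standardize_train(Y[train])
        Yt = (Y[train] - my) / sy
        Yt[:, flat_y] = 0.0
        Bf = ridge_fit(Xt, Yt, lam)  # p x parcels
        beta_folds += Bf.T
        preds[k] = (xk @ Bf) * sy + my
    beta_folds /= n

    mx, sx, _ = _standardize_train(X, warn_context="full fit features")
    my, sy, flat_y = _standardize_train(Y)
    Ys = (Y - my) / sy
    Ys[:, flat_y] = 0.0
    beta = ridge_fit((X - mx) / sx, Ys, lam).T  # parcels x p

    ss_res = ((Y - preds) ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2[undefined] = np.nan
    return EncodingResult(
        r2=r2,
        beta=beta,
        beta_folds=beta_folds,
        predictions=preds,
        undefined_parcels=undefined,
        clip_ids=clip_ids,
    )


def feature_importance(result: EncodingResult) -> FeatureImportance:
    """Mean |beta| across parcels and the R^2-weighted variant.

    Weights are ``max(R^2, 0)`` renormalized to sum to 1; parcels with
    undefined R^2 are excluded from both statistics.
    """
    valid = np.setdiff1d(np.arange(result.beta.shape[0]), result.undefined_parcels)
    abs_beta = np.abs(result.beta[valid])
    mean_abs = abs_beta.mean(axis=0)
    w = np.maximum(result.r2[valid], 0.0)
    total = w.sum()
    if total <= 0:
        raise EncodingError(
            "all parcels have R^2 <= 0; the weighted importance is undefined "
            "- inspect the encoding fit before interpreting feature maps"
        )
    weighted = (w / total) @ abs_beta
    return FeatureImportance(mean_abs_beta=mean_abs, weighted_abs_beta=weighted)


def null_encoding(
    features: pd.DataFrame,
    responses: ClipResponseMatrix,
    lam: float,
    n_shuffles: int,
    seed: int = 0,
) -> np.ndarray:
    """Empirical null: re-run LOOCV encoding with clip-permuted feature rows.

    Returns an ``n_shuffles x parcels`` matrix of null R^2 draws (quantile
    summaries are left to the caller).
    """
    if n_shuffles < 100:
        raise EncodingError("n_shuffles must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(features)
    out = np.empty((n_shuffles, responses.data.shape[1]))
    values = features.to_numpy(dtype=float)
    for s in range(n_shuffles):
        perm = rng.permutation(n)
        shuffled = pd.DataFrame(
            values[perm], index=features.index, columns=features.columns
        )
        out[s] = loocv_encode(shuffled, responses, lam).r2
    return out


def null_quantiles(null_r2: np.ndarray, qs=(0.05, 0.5, 0.95)) -> np.ndarray:
    return np.quantile(null_r2, qs, axis=0)
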