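"""Behavioral-style PLS: SVD of the cross-block covariance between two
subjects x parcels matrices, with permutation significance for the singular
values and bootstrap stability (z) maps for the saliences.

Both blocks are column z-scored across subjects by default (a center-only
mode exists for sensitivity analyses); the cross-block matrix is
``C = X'Y / (n - 1)`` and its SVD provides paired saliences and subject
scores.  Each original salience column is oriented so its largest-magnitude
entry is positive; bootstrap draws are aligned to the original by the sign
of their dot product before the standard deviation is taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-12


class PLSError(ValueError):
    pass


@dataclass
class PLSResult:
    u: np.ndarray  # parcels_x x K saliences (X side)
    v: np.ndarray  # parcels_y x K saliences (Y side)
    x_scores: np.ndarray  # subjects x K
    y_scores: np.ndarray  # subjects x K
    singular_values: np.ndarray  # K, non-increasing
    covariance_explained: np.ndarray  # K fractions of total sigma^2
    block_variance_explained: dict  # {"x": K fractions, "y": K fractions}
    perm_p: np.ndarray | None = None
    boot_z_u: np.ndarray | None = None
    boot_z_v: np.ndarray | None = None


def _standardize_block(M: np.ndarray, center_only: bool) -> np.ndarray:
    mean = M.mean(axis=0)
    out = M - mean
    if not center_only:
        sd = M.std(axis=0, ddof=1)
        flat = sd < _SD_FLOOR
        if flat.any():
            logger.warning(
                "PLS block: %d constant column(s) standardized to zero",
                int(flat.sum()),
            )
        out = out / np.where(flat, 1.0, sd)
        out[:, flat] = 0.0
    return out


def _orient(u: np.ndarray, v: np.ndarray):
    """Flip column pairs so each u column's largest-|entry| is positive."""
    for k in range(u.shape[1]):
        if u[np.argmax(np.abs(u[:, k])), k] < 0:
            u[:, k] *= -1.0
            v[:, k] *= -1.0
    return u, v


def pls_svd(
    X: np.ndarray,
    Y: np.ndarray,
    K: int = 1,
    center_only: bool = False,
) -> PLSResult:
    """Top-K singular pairs of the cross-block covariance.

    ``covariance_explained`` is sigma_k^2 over the *full* spectrum's total;
    ``block_variance_explained`` is the score variance of each component as
    a fraction of its block's total column variance (two conventions are
    reported because the literature does not fix one).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise PLSError("X and Y must have the same subject rows")
    n = X.shape[0]
    if n < 5:
        raise PLSError("need at least 5 subjects for PLS")
    if K < 1 or K > min(X.shape[1], Y.shape[1], n):
        raise PLSError(f"invalid number of components K={K}")
    Xs = _standardize_block(X, center_only)
    Ys = _standardize_block(Y, center_only)
    C = Xs.T @ Ys / (n - 1)
    U, S, Vt = np.linalg.svd(C, full_matrices=False)
    u, v = _orient(U[:, :K].copy(), Vt[:K].T.copy())
    x_scores = Xs @ u
    y_scores = Ys @ v
    total_sq = float((S**2).sum())
    cov_explained = S[:K] ** 2 / total_sq if total_sq > 0 else np.zeros(K)
    bx = x_scores.var(axis=0, ddof=1) / max(Xs.var(axis=0, ddof=1).sum(), _SD_FLOOR)
    by = y_scores.var(axis=0, ddof=1) / max(Ys.var(axis=0, ddof=1).sum(), _SD_FLOOR)
    return PLSResult(
        u=u,
        v=v,
        x_scores=x_scores,
        y_scores=y_scores,
        singular_values=S[:K].copy(),
        covariance_explained=cov_explained,
        block_variance_explained={"x": bx, "y": by},
    )


def _singular_values(Xs: np.ndarray, Ys: np.ndarray, K: int) -> np.ndarray:
    C = Xs.T @ Ys / (Xs.shape[0] - 1)
    return np.linalg.svd(C, compute_uv=False)[:K]


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    n_perm: int,
    seed: int = 0,
    center_only: bool = False,
) -> np.ndarray:
    """Permutation p per component: subject rows of Y are shuffled, the
    singular values recomputed, and ``p_k = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise PLSError("n_perm must be at least 100")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    Xs = _standardize_block(X, center_only)
    Ys = _standardize_block(Y, center_only)
    obs = _singular_values(Xs, Ys, K)
    exceed = np.zeros(K)
    n = X.shape[0]
    for _ in range(n_perm):
        # column standardization commutes with row permutation
        perm_s = _singular_values(Xs, Ys[rng.permutation(n)], K)
        exceed += perm_s >= obs - 1e-12
    return (1.0 + exceed) / (n_perm + 1.0)


def bootstrap_stability(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    n_boot: int,
    seed: int = 0,
    center_only: bool = False,
):
    """Bootstrap z maps: original salience / sd of sign-aligned bootstrap
    saliences over subject resamples.  Draws that produce a constant column
    in either block are redrawn (and logged)."""
    if n_boot < 100:
        raise PLSError("n_boot must be at least 100")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise PLSError("need at least 10 subjects for bootstrap stability")
    base = pls_svd(X, Y, K, center_only=center_only)
    rng = np.random.default_rng(seed)
    us = np.empty((n_boot, *base.u.shape))
    vs = np.empty((n_boot, *base.v.shape))
    b = 0
    guard = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        if (X[idx].std(axis=0) < _SD_FLOOR).any() or (
            Y[idx].std(axis=0) < _SD_FLOOR
        ).any():
            guard += 1
            if guard > 100 * n_boot:
                raise PLSError("could not draw bootstrap samples without "
                               "constant columns")
            logger.warning("bootstrap draw with constant column redrawn")
            continue
        res = pls_svd(X[idx], Y[idx], K, center_only=center_only)
        for k in range(K):
            sgn = np.sign(res.u[:, k] @ base.u[:, k] + res.v[:, k] @ base.v[:, k])
            if sgn == 0:
                sgn = 1.0
            us[b, :, k] = sgn * res.u[:, k]
            vs[b, :, k] = sgn * res.v[:, k]
        b += 1
    sd_u = us.std(axis=0, ddof=1)
    sd_v = vs.std(axis=0, ddof=1)
    boot_z_u = base.u / np.where(sd_u < _SD_FLOOR, np.nan, sd_u)
    boot_z_v = base.v / np.where(sd_v < _SD_FLOOR, np.nan, sd_v)
    return boot_z_u, boot_z_v


def pls_full(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    n_perm: int,
    n_boot: int,
    seed: int = 0,
    center_only: bool = False,
) -> PLSResult:
    """SVD + permutation p + bootstrap z in one call (the CLI entry point)."""
    result = pls_svd(X, Y, K, center_only=center_only)
    result.perm_p = permutation_test(
        X, Y, K, n_perm, seed=seed, center_only=center_only
    )
    result.boot_z_u, result.boot_z_v = bootstrap_stability(
        X, Y, K, n_boot, seed=seed + 1, center_only=center_only
    )
    return result
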