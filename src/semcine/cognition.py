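"""Cross-subject Spearman maps between parcel-wise encoding R^2 and
cognitive scores, with Benjamini-Hochberg FDR over the pooled p vector."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class CognitionError(ValueError):
    pass


@dataclass
class CouplingResult:
    rho: np.ndarray  # parcels x n_scores (NaN where undefined)
    p: np.ndarray  # parcels x n_scores
    significant: np.ndarray  # boolean, FDR-corrected over the pooled vector
    q: float
    map_similarity: np.ndarray  # n_scores x n_scores Pearson between rho maps
    score_names: list[str]


def _rank(M: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, M)  # average ranks for ties


def spearman_map(subject_r2: np.ndarray, cognition: pd.DataFrame):
    """Spearman rho and t-approximation p for every parcel x score pair.

    Parcels or score columns that are constant across subjects yield NaN
    (with a warning for score columns); these cells are excluded from FDR
    pooling downstream.
    """
    X = np.asarray(subject_r2, dtype=float)  # subjects x parcels
    S = cognition.to_numpy(dtype=float)  # subjects x scores
    n = X.shape[0]
    if S.shape[0] != n:
        raise CognitionError("subject rows of R^2 matrix and cognition differ")
    if n < 10:
        raise CognitionError("need at least 10 subjects for Spearman maps")
    const_scores = S.std(axis=0) < 1e-12
    if const_scores.any():
        logger.warning(
            "%d constant score column(s); their correlations are NaN",
            int(const_scores.sum()),
        )
    rx = _rank(X)
    rs = _rank(S)
    zx = rx - rx.mean(axis=0)
    zs = rs - rs.mean(axis=0)
    denom = np.sqrt(
        np.outer((zx**2).sum(axis=0), (zs**2).sum(axis=0))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (zx.T @ zs) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


def bh_fdr(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up over a flat p vector; NaNs never rejected.

    Returns a boolean mask of the same shape.  Rejects all p <= p_(i*) where
    i* is the largest i with p_(i) <= i*q/m and m counts finite p only.
    """
    if not (0 < q < 1):
        raise CognitionError("q must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    flat = p.ravel()
    finite = np.isfinite(flat)
    if ((flat[finite] < 0) | (flat[finite] > 1)).any():
        raise CognitionError("p-values must lie in [0, 1]")
    mask = np.zeros(flat.shape, dtype=bool)
    pv = flat[finite]
    m = pv.size
    if m:
        order = np.sort(pv)
        below = order <= (np.arange(1, m + 1) * q / m)
        if below.any():
            threshold = order[np.flatnonzero(below)[-1]]
            mask[finite] = pv <= threshold
    return mask.reshape(p.shape)


def couple(
    subject_r2: np.ndarray,
    cognition: pd.DataFrame,
    q: float = 0.05,
) -> CouplingResult:
    """Spearman maps + pooled BH-FDR + pairwise rho-map similarity."""
    rho, p = spearman_map(subject_r2, cognition)
    significant = bh_fdr(p, q)
    n_scores = rho.shape[1]
    sim = np.full((n_scores, n_scores), np.nan)
    for a in range(n_scores):
        for b in range(n_scores):
            ok = np.isfinite(rho[:, a]) & np.isfinite(rho[:, b])
            if ok.sum() >= 3:
                ca, cb = rho[ok, a], rho[ok, b]
                if ca.std() > 0 and cb.std() > 0:
                    sim[a, b] = np.corrcoef(ca, cb)[0, 1]
    return CouplingResult(
        rho=rho,
        p=p,
        significant=significant,
        q=q,
        map_similarity=sim,
        score_names=list(cognition.columns),
    )
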