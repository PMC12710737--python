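"""Resting-state functional connectivity and nodewise strength.

Pairwise Pearson correlations are Fisher-z transformed (after clipping at
1 - 1e-7 so degenerate, e.g. duplicated, parcels cannot inject infinities);
a parcel's strength is the mean positively-clipped z with the diagonal
excluded.  Negative-edge clipping happens after the z transform, which is
sign-equivalent to clipping r itself.
"""

from __future__ import annotations

import logging

import numpy as np

from .responses import ParcelTimeSeries

logger = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7
_SD_FLOOR = 1e-12


class ConnectivityError(ValueError):
    pass


def fc_matrix(rest: ParcelTimeSeries) -> np.ndarray:
    """Symmetric parcels x parcels Fisher-z matrix with zero diagonal.

    Zero-variance parcels get all-zero rows/columns and a log warning.
    """
    data = rest.data
    if data.shape[1] < 10:
        raise ConnectivityError("need at least 10 rest TRs for FC estimation")
    sd = data.std(axis=1, ddof=1)
    flat = sd < _SD_FLOOR
    if flat.any():
        logger.warning(
            "subject %s: %d zero-variance parcel(s) zeroed in FC matrix",
            rest.subject_id,
            int(flat.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(data)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    n_clipped = int((np.abs(r) > _R_CLIP).sum() - r.shape[0])  # diagonal excluded
    if n_clipped > 0:
        logger.warning(
            "subject %s: %d near-unit correlation(s) clipped before Fisher-z",
            rest.subject_id,
            n_clipped,
        )
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    z[flat, :] = 0.0
    z[:, flat] = 0.0
    np.fill_diagonal(z, 0.0)
    return (z + z.T) / 2.0  # enforce exact symmetry against float asymmetry


def fc_strength(z: np.ndarray) -> np.ndarray:
    """strength[i] = mean over j != i of max(z[i, j], 0)."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ConnectivityError("FC matrix must be square")
    if not np.allclose(z, z.T, atol=1e-10):
        raise ConnectivityError("FC matrix must be symmetric")
    if not np.allclose(np.diag(z), 0.0, atol=1e-12):
        raise ConnectivityError("FC matrix diagonal must be zero")
    pos = np.maximum(z, 0.0)
    np.fill_diagonal(pos, 0.0)
    return pos.sum(axis=1) / (z.shape[0] - 1)


def subject_strength_profiles(rests: list[ParcelTimeSeries]) -> np.ndarray:
    """Stack per-subject strength vectors into a subjects x parcels matrix."""
    return np.stack([fc_strength(fc_matrix(r)) for r in rests], axis=0)
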