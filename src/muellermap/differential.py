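"""Differential (matrix-logarithm) decomposition of Mueller matrices.

L = ln(M) is split with the Minkowski metric G = diag(1, -1, -1, -1) into a
G-antisymmetric part Lm carrying the mean spectroscopic properties (linear
and circular diattenuation and retardance) and a G-symmetric part Lu
carrying their fluctuation variances and covariances.  Everything is per
single traversal (path length z = 1).

Template of Lm (0-based rows/columns):

    [[   0,  -LDH, -LD45,   CD ],
     [-LDH,     0,    CB,  LB45],
     [-LD45,  -CB,     0, -LBH ],
     [  CD, -LB45,   LBH,    0 ]]

The Lu-entry <-> variance/covariance mapping is fixed by a Gaussian
fluctuation model of the birefringence generators and verified against a
Monte-Carlo simulator in the test suite:

    var_LH  = a - b - c      with a = Lu[1,1] - Lu[0,0]
    var_L45 = b - a - c           b = Lu[2,2] - Lu[0,0]
    var_C   = c - a - b           c = Lu[3,3] - Lu[0,0]
    cov(LH, L45) =  2 Lu[1,2]
    cov(LH, C)   = -2 Lu[1,3]
    cov(L45, C)  = -2 Lu[2,3]
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from numpy.typing import ArrayLike, NDArray

from .symmetric import G

#: Row order of the per-wavelength summary table (6 means, 3 variances,
#: 3 covariances).
TABLE_ROWS = (
    "LBH", "LB45", "CB", "LDH", "LD45", "CD",
    "var_LH", "var_L45", "var_C",
    "cov_LH_L45", "cov_LH_C", "cov_L45_C",
)


class LogUndefinedError(ValueError):
    """Raised when the principal matrix logarithm does not exist."""


@dataclass
class DifferentialResult:
    """Log-decomposition of one Mueller matrix."""

    L: NDArray
    Lm: NDArray
    Lu: NDArray
    means: dict[str, float]
    variances: dict[str, float]
    covariances: dict[str, float]
    applicable: bool

    def table_row(self) -> dict[str, float]:
        """All 12 named quantities in the fixed summary order."""
        merged = {**self.means, **self.variances, **self.covariances}
        return {k: merged[k] for k in TABLE_ROWS}


def matrix_log(m: ArrayLike) -> NDArray:
    """Principal real matrix logarithm of a normalized Mueller matrix.

    Raises :class:`LogUndefinedError` when an eigenvalue lies on the closed
    negative real axis (no principal branch); pixel-wise callers flag and
    skip such pixels rather than shifting branches.
    """
    m = np.asarray(m, dtype=float)
    lam = np.linalg.eigvals(m)
    scale = max(np.max(np.abs(lam)), 1.0)
    on_cut = (lam.real <= 1e-12 * scale) & (np.abs(lam.imag) <= 1e-12 * scale)
    if np.any(on_cut):
        raise LogUndefinedError("eigenvalue on the closed negative real axis")
    L = scipy.linalg.logm(m)
    if np.iscomplexobj(L):
        if np.max(np.abs(L.imag)) > 1e-8 * max(np.max(np.abs(L.real)), 1.0):
            raise LogUndefinedError("matrix logarithm is not real")
        L = L.real
    return L


def g_split(L: ArrayLike) -> tuple[NDArray, NDArray]:
    """G-antisymmetric and G-symmetric parts of L (Lm + Lu = L exactly)."""
    L = np.asarray(L, dtype=float)
    Lg = G @ np.swapaxes(L, -1, -2) @ G
    return 0.5 * (L - Lg), 0.5 * (L + Lg)


def spectroscopic_means(Lm: ArrayLike) -> dict[str, float]:
    """Mean spectroscopic properties read off the Lm template."""
    Lm = np.asarray(Lm, dtype=float)
    return {
        "LDH": float(-Lm[..., 0, 1]),
        "LD45": float(-Lm[..., 0, 2]),
        "CD": float(Lm[..., 0, 3]),
        "LBH": float(-Lm[..., 2, 3]),
        "LB45": float(Lm[..., 1, 3]),
        "CB": float(Lm[..., 1, 2]),
    }


def fluctuation_stats(
    Lu: ArrayLike, tol: float = 1e-10
) -> tuple[dict[str, float], dict[str, float]]:
    """Variances and covariances of the spectroscopic fluctuations.

    Negative variances within ``-tol`` are clipped to zero; larger negative
    values are returned as-is (the applicability check is the place where
    such matrices are rejected).
    """
    Lu = np.asarray(Lu, dtype=float)
    a = Lu[1, 1] - Lu[0, 0]
    b = Lu[2, 2] - Lu[0, 0]
    c = Lu[3, 3] - Lu[0, 0]
    var = {"var_LH": a - b - c, "var_L45": b - a - c, "var_C": c - a - b}
    var = {k: 0.0 if -tol < v < 0.0 else float(v) for k, v in var.items()}
    cov = {
        "cov_LH_L45": float(2.0 * Lu[1, 2]),
        "cov_LH_C": float(-2.0 * Lu[1, 3]),
        "cov_L45_C": float(-2.0 * Lu[2, 3]),
    }
    return var, cov


def applicability(L: ArrayLike, tol: float = 1e-9) -> bool:
    """PSD check of the reduced coherency of the G-symmetric fluctuation part.

    The trace-removed G-symmetric component Lu - (trace(Lu)/4) I is mapped
    through the Pauli coherency transform; the decomposition is applicable
    iff all its eigenvalues are >= -tol (the fluctuation covariance
    structure is a valid one).  A zero matrix (pure element) passes.
    """
    from .realizability import coherency

    _, Lu = g_split(L)
    reduced = Lu - (np.trace(Lu) / 4.0) * np.eye(4)
    lam = np.linalg.eigvalsh(coherency(reduced))
    scale = max(np.max(np.abs(lam)), 1.0)
    return bool(np.all(lam >= -tol * scale))


def differential_decompose(m: ArrayLike) -> DifferentialResult:
    """Full differential decomposition of one normalized Mueller matrix."""
    L = matrix_log(m)
    Lm, Lu = g_split(L)
    means = spectroscopic_means(Lm)
    var, cov = fluctuation_stats(Lu)
    return DifferentialResult(L, Lm, Lu, means, var, cov, applicability(L))


def differential_maps(img) -> tuple[dict[str, NDArray], int]:
    """Pixel-wise differential maps plus the count of log-undefined pixels.

    Returns one HxW float map per quantity in :data:`TABLE_ROWS`, NaN where
    the pixel is masked, log-undefined, or fails the applicability check.
    """
    from .core import MuellerImage

    assert isinstance(img, MuellerImage)
    H, W = img.shape
    out = {k: np.full((H, W), np.nan) for k in TABLE_ROWS}
    m00 = img.data[..., 0, 0]
    valid = img.mask & np.isfinite(m00) & (m00 > 0)
    n_undefined = 0
    for i in range(H):
        for j in range(W):
            if not valid[i, j]:
                continue
            try:
                res = differential_decompose(img.data[i, j] / m00[i, j])
            except LogUndefinedError:
                n_undefined += 1
                continue
            if not res.applicable:
                continue
            for k, v in res.table_row().items():
                out[k][i, j] = v
    return out, n_undefined


def differential_table(img) -> dict[str, float]:
    """Masked-pixel means of the 12 named quantities for one wavelength."""
    maps, _ = differential_maps(img)
    return {k: float(np.nanmean(v)) for k, v in maps.items()}
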