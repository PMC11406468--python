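"""Symmetric (five-layer) decomposition M = M_D2 . M_R2 . M_Dd . M_R1^T . M_D1.

All depolarization is confined to a diagonal depolarizer M_Dd =
diag(d0, d1, d2, d3); the flanking pure factors are two diattenuators and
two retarders.  The diattenuation vectors come from the eigenvector (of the
largest eigenvalue) of M^T G M G and M G M^T G respectively, scaled so the
first Stokes component is one; the intermediate matrix
M' = M_D2^{-1} M M_D1^{-1} is factored by SVD with both orthogonal factors
forced to proper rotations (any reflection is pushed into the sign of d3).
The total retarder M_R2 . M_R1^T is invariant to the rotation gauge freedom
of the SVD and reproduces a pure-retarder input exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .core import diattenuator_from_vector

G = np.diag([1.0, -1.0, -1.0, -1.0])


@dataclass
class SymmetricResult:
    """Factors and scalar magnitudes of the symmetric decomposition."""

    M_D1: NDArray
    M_D2: NDArray
    M_R1: NDArray
    M_R2: NDArray
    M_delta_diag: NDArray
    d: NDArray                # (d0, d1, d2, d3)
    D1: float
    D2: float
    delta_total: float        # Delta from the diagonal depolarizer
    M_R: NDArray              # total retarder, gauge-free
    retardance: float
    valid: bool


def check_diagonalizable(M: ArrayLike, tol: float = 1e-8) -> bool:
    """Whether N = G M^T G M admits the decomposition (real eigensystem).

    True iff N has a full set of eigenvectors with real, nonnegative
    eigenvalues within tolerance.  Defective (Jordan-block) or
    Minkowski-type matrices return False.
    """
    M = np.asarray(M, dtype=float)
    N = G @ M.T @ G @ M
    lam, V = np.linalg.eig(N)
    scale = max(np.max(np.abs(lam)), 1.0)
    if np.any(np.abs(lam.imag) > tol * scale) or np.any(lam.real < -tol * scale):
        return False
    # defective N: eigenvector matrix numerically singular
    return np.linalg.matrix_rank(V, tol=1e-6) == 4


def _diattenuation_eigvec(A: NDArray, tol: float) -> tuple[NDArray, bool]:
    """Eigenvector of the largest eigenvalue of A, scaled to first component 1."""
    lam, V = np.linalg.eig(A)
    order = np.argsort(lam.real)[::-1]
    top = lam.real[order[0]]
    # among (near-)degenerate top eigenvectors pick the one with the largest
    # first Stokes component; degenerate pure factors then default to D = 0
    cands = [order[0]] + [i for i in order[1:] if abs(lam.real[i] - top) <= tol * max(abs(top), 1.0)]
    best = max(cands, key=lambda i: abs(V[0, i]))
    v = V[:, best].real
    if abs(v[0]) < 1e-6 * np.linalg.norm(v):
        return np.zeros(3), False
    v = v / v[0]
    return v[1:], True


def symmetric_decompose(m: ArrayLike, tol: float = 1e-8) -> SymmetricResult:
    """Symmetric decomposition of one normalized Mueller matrix.

    Inputs failing :func:`check_diagonalizable`, or yielding D1/D2 > 1, come
    back with ``valid=False`` (callers emit NaN maps for such pixels).
    """
    m = np.asarray(m, dtype=float)
    valid = check_diagonalizable(m, tol=max(tol, 1e-8))

    d1vec, ok1 = _diattenuation_eigvec(m.T @ G @ m @ G, 1e-7)
    d2vec, ok2 = _diattenuation_eigvec(m @ G @ m.T @ G, 1e-7)
    valid = valid and ok1 and ok2
    D1 = float(np.linalg.norm(d1vec))
    D2 = float(np.linalg.norm(d2vec))
    for Dv in (D1, D2):
        if Dv > 1.0 + 1e-6:
            valid = False
    clip = 1.0 - 1e-9
    if D1 > clip:
        d1vec = d1vec * (clip / D1)
    if D2 > clip:
        d2vec = d2vec * (clip / D2)
    M_D1 = diattenuator_from_vector(np.clip(d1vec, -1, 1))
    M_D2 = diattenuator_from_vector(np.clip(d2vec, -1, 1))

    Mp = np.linalg.inv(M_D2) @ m @ np.linalg.inv(M_D1)
    d0 = float(Mp[0, 0])
    U, s, Vt = np.linalg.svd(Mp[1:, 1:])
    V = Vt.T
    s = s.copy()
    # force proper rotations; reflections go into the sign of d3
    if np.linalg.det(U) < 0:
        U[:, 2] *= -1.0
        s[2] *= -1.0
    if np.linalg.det(V) < 0:
        V[:, 2] *= -1.0
        s[2] *= -1.0

    M_R2 = np.eye(4)
    M_R2[1:, 1:] = U
    M_R1 = np.eye(4)
    M_R1[1:, 1:] = V
    d = np.concatenate([[d0], s])
    M_dd = np.diag(d)
    delta_total = 1.0 - abs(np.sum(s) / d0) / 3.0 if d0 != 0 else np.nan

    M_R = total_retarder(M_R1, M_R2)[0]
    R = float(np.arccos(np.clip(np.trace(M_R[1:, 1:]) / 2.0 - 0.5, -1.0, 1.0)))
    return SymmetricResult(
        M_D1, M_D2, M_R1, M_R2, M_dd, d, D1, D2, delta_total, M_R, R, bool(valid)
    )


def total_retarder(M_R1: ArrayLike, M_R2: ArrayLike) -> tuple[NDArray, float]:
    """Gauge-free total retarder of the symmetric decomposition, with R.

    Computed as M_R2 . M_R1^T, which cancels the common rotation freedom of
    the SVD frames and reproduces a pure-retarder input; its retardance R
    (trace formula) is identical to that of the transposed ordering.
    """
    M_R1 = np.asarray(M_R1, dtype=float)
    M_R2 = np.asarray(M_R2, dtype=float)
    M_R = M_R2 @ M_R1.T
    R = float(np.arccos(np.clip(np.trace(M_R[1:, 1:]) / 2.0 - 0.5, -1.0, 1.0)))
    return M_R, R


def reconstruct(res: SymmetricResult) -> NDArray:
    """Product of the five factors (diagnostic residual check)."""
    return res.M_D2 @ res.M_R2 @ res.M_delta_diag @ res.M_R1.T @ res.M_D1


def symmetric_maps(img, progress: bool = False) -> dict[str, NDArray]:
    """Pixel-wise symmetric-decomposition maps (NaN where masked/invalid)."""
    from .core import MuellerImage  # local import to avoid cycle at module load

    assert isinstance(img, MuellerImage)
    H, W = img.shape
    out = {k: np.full((H, W), np.nan) for k in ("delta", "R", "D1", "D2")}
    m00 = img.data[..., 0, 0]
    valid = img.mask & np.isfinite(m00) & (m00 > 0)
    for i in range(H):
        for j in range(W):
            if not valid[i, j]:
                continue
            res = symmetric_decompose(img.data[i, j] / m00[i, j])
            if not res.valid:
                continue
            out["delta"][i, j] = res.delta_total
            out["R"][i, j] = res.retardance
            out["D1"][i, j] = res.D1
            out["D2"][i, j] = res.D2
    return out
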