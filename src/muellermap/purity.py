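"""Indices of polarimetric purity and anisotropy coefficients.

The indices of polarimetric purity (P1 <= P2 <= P3) grade how far a Mueller
matrix is from an ideal depolarizer using the trace-normalized eigenvalues
of its coherency matrix; the degree of polarimetric purity P_Delta combines
them.  The linear and circular anisotropy coefficients (alpha_L, alpha_C)
measure directional preference from the k/r/q vectors of the 3x3 block,
and their quadrature sum P_alpha is bounded above by P_Delta.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .core import diattenuation_vector, polarizance_vector
from .realizability import coherency_eigenvalues


@dataclass
class PurityResult:
    """IPPs and degree of polarimetric purity (arrays broadcast pixel-wise)."""

    P1: NDArray
    P2: NDArray
    P3: NDArray
    P_delta: NDArray


@dataclass
class AnisotropyResult:
    """Anisotropy coefficients plus the intermediate vectors."""

    alpha_L: NDArray
    alpha_C: NDArray
    P_alpha: NDArray
    k: NDArray
    r: NDArray
    q: NDArray
    sigma: NDArray   # denominator Sigma; <= 0 marks undefined pixels (NaN outputs)


def ipps(M: ArrayLike, tol: float = 1e-9) -> PurityResult:
    """Indices of polarimetric purity from a Mueller matrix (stacked OK).

    P1 = l0 - l1, P2 = l0 + l1 - 2 l2, P3 = 1 - 4 l3 on trace-normalized,
    descending coherency eigenvalues (small negatives within ``tol`` are
    clipped to zero).  P_Delta = sqrt((1/3)(2 P1^2 + (2/3) P2^2 + (1/3) P3^2)).
    Zero-trace pixels yield NaN.
    """
    lam = coherency_eigenvalues(M)
    trace = lam.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lhat = np.where(trace[..., None] > 0, lam / trace[..., None], np.nan)
    lhat = np.where((lhat < 0) & (lhat > -tol), 0.0, lhat)
    P1 = lhat[..., 0] - lhat[..., 1]
    P2 = lhat[..., 0] + lhat[..., 1] - 2.0 * lhat[..., 2]
    P3 = 1.0 - 4.0 * lhat[..., 3]
    P_delta = np.sqrt((2.0 * P1**2 + (2.0 / 3.0) * P2**2 + (1.0 / 3.0) * P3**2) / 3.0)
    return PurityResult(P1, P2, P3, P_delta)


def kqr_vectors(m: ArrayLike) -> tuple[NDArray, NDArray, NDArray]:
    """Complementary vectors k, r, q of the normalized 3x3 block.

    With the block written as ``[[k1, r3, r2], [q3, k2, r1], [q2, q1, k3]]``:
    k = (k1, k2, k3)/sqrt(3), r = (r1, r2, r3), q = (q1, q2, q3).
    """
    m = np.asarray(m, dtype=float)
    b = m[..., 1:4, 1:4]
    k = np.stack([b[..., 0, 0], b[..., 1, 1], b[..., 2, 2]], axis=-1) / np.sqrt(3.0)
    r = np.stack([b[..., 1, 2], b[..., 0, 2], b[..., 0, 1]], axis=-1)
    q = np.stack([b[..., 2, 1], b[..., 2, 0], b[..., 1, 0]], axis=-1)
    return k, r, q


def anisotropy(m: ArrayLike, eps: float = 1e-12) -> AnisotropyResult:
    """Linear and circular anisotropy coefficients of a normalized matrix.

    Sigma = 3(1 - ||k||^2) + 2 D.P - 2 r.q normalizes the coefficients; with
    s_i = sqrt((D_i + P_i)^2 + (r_i - q_i)^2),

        alpha_L = sqrt(s_1^2 + s_2^2) / sqrt(Sigma),
        alpha_C = s_3 / sqrt(Sigma).

    This normalization makes P_alpha = sqrt(alpha_L^2 + alpha_C^2) exactly 1
    for every pure (non-depolarizing) matrix and preserves the bound
    P_alpha <= P_Delta; pure anisotropic elements (ideal polarizer, any
    linear retarder) saturate alpha_L = 1.  Pixels with Sigma <= eps
    (vanishing denominator) come back NaN.
    """
    m = np.asarray(m, dtype=float)
    D = diattenuation_vector(m)
    P = polarizance_vector(m)
    k, r, q = kqr_vectors(m)
    sigma = (
        3.0 * (1.0 - np.sum(k**2, axis=-1))
        + 2.0 * np.sum(D * P, axis=-1)
        - 2.0 * np.sum(r * q, axis=-1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        root = np.where(sigma > eps, np.sqrt(np.abs(sigma)), np.nan)
        dp = D + P
        rq = r - q
        alpha_L = np.sqrt(
            dp[..., 0] ** 2 + rq[..., 0] ** 2 + dp[..., 1] ** 2 + rq[..., 1] ** 2
        ) / root
        alpha_C = np.sqrt(dp[..., 2] ** 2 + rq[..., 2] ** 2) / root
    P_alpha = np.sqrt(alpha_L**2 + alpha_C**2)
    return AnisotropyResult(alpha_L, alpha_C, P_alpha, k, r, q, sigma)
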