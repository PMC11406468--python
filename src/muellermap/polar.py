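"""Forward polar (Lu-Chipman) decomposition M = M_Delta . M_R . M_D.

The normalized matrix is factored serially into a diattenuator (built from
the first-row diattenuation vector), a retarder, and a depolarizer whose
3x3 block is the signed square root of m' m'^T.  Scalar maps follow:

    Delta = 1 - |trace(m_Delta)| / 3          (depolarization, [0, 1])
    R     = arccos(trace(M_R)/2 - 1)          (retardance, [0, pi])
    D     = ||D_vec||                         (diattenuation, [0, 1])

The retarder is further split into a linear retarder times a pure rotator,
M_R = M_LR . M_psi, from which the linear-retardance fast axis theta in
(-pi/2, pi/2] is read off with a quadrant-correct half-angle arctangent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .core import MuellerImage, diattenuator_from_vector, rotator

_D_CLIP = 1.0 - 1e-9


@dataclass
class PolarResult:
    """Factors and scalar magnitudes of the forward polar decomposition."""

    M_delta: NDArray
    M_R: NDArray
    M_D: NDArray
    delta_total: NDArray      # depolarization Delta in [0, 1]
    retardance: NDArray       # R in [0, pi] (radians)
    diattenuation: NDArray    # D in [0, 1]
    flags: NDArray            # True where D was clipped near 1 (degenerate M_D)


def _signed_sqrt_block(mprime: NDArray) -> NDArray:
    """3x3 block of the depolarizer: signed square root of m' m'^T.

    Ties and rank deficiency are handled by symmetric eigendecomposition
    with eigenvalues clipped at zero; the overall sign follows det(m').
    """
    mm = mprime @ np.swapaxes(mprime, -1, -2)
    lam, V = np.linalg.eigh(mm)              # ascending
    lam = np.clip(lam, 0.0, None)
    root = np.sqrt(lam)
    mdelta = np.einsum("...ik,...k,...jk->...ij", V, root, V)
    sign = np.where(np.linalg.det(mprime) < 0.0, -1.0, 1.0)
    return sign[..., None, None] * mdelta


def lu_chipman(m: ArrayLike) -> PolarResult:
    """Forward polar decomposition of normalized matrices of shape (..., 4, 4).

    Callers should screen for physical realizability first; rank-deficient
    depolarizers (e.g. the ideal depolarizer) are handled by projecting the
    retarder factor onto the nearest proper rotation.
    """
    m = np.asarray(m, dtype=float)
    batch = m.shape[:-2]

    dvec = m[..., 0, 1:4].copy()
    D = np.linalg.norm(dvec, axis=-1)
    flags = D >= _D_CLIP
    scale = np.where(flags, _D_CLIP / np.where(D == 0, 1.0, D), 1.0)
    dvec = dvec * scale[..., None]

    M_D = diattenuator_from_vector(dvec)
    Mp = m @ np.linalg.inv(M_D)
    mprime = Mp[..., 1:, 1:]
    mdelta = _signed_sqrt_block(mprime)

    M_delta = np.zeros(batch + (4, 4))
    M_delta[..., 0, 0] = 1.0
    M_delta[..., 1:, 0] = Mp[..., 1:, 0]
    M_delta[..., 1:, 1:] = mdelta

    # retarder block: m_R = m_delta^{-1} m'; fall back to the orthogonal
    # Procrustes projection of m' when the depolarizer is singular
    det = np.linalg.det(mdelta)
    singular = np.abs(det) < 1e-12
    safe = np.where(singular[..., None, None], np.eye(3), mdelta)
    mR = np.linalg.solve(safe, mprime)
    if np.any(singular):
        U, _, Vt = np.linalg.svd(np.where(singular[..., None, None], np.eye(3), mprime))
        proj = U @ Vt
        mR = np.where(singular[..., None, None], proj, mR)
    # orthonormality can degrade with ill-conditioned depolarizers; re-project
    U, _, Vt = np.linalg.svd(mR)
    mR = U @ Vt

    M_R = np.zeros(batch + (4, 4))
    M_R[..., 0, 0] = 1.0
    M_R[..., 1:, 1:] = mR

    delta_total = 1.0 - np.abs(np.trace(mdelta, axis1=-2, axis2=-1)) / 3.0
    retardance = np.arccos(np.clip(np.trace(mR, axis1=-2, axis2=-1) / 2.0 - 0.5, -1.0, 1.0))
    return PolarResult(M_delta, M_R, M_D, delta_total, retardance, D, flags)


def retarder_split(
    M_R: ArrayLike, tol: float = 1e-6
) -> tuple[NDArray, NDArray, NDArray, NDArray]:
    """Split a retarder into linear retarder and rotator, M_R = M_LR . M_psi.

    Returns ``(M_LR, M_psi, delta, psi)``.  A retarder within ``tol`` of the
    identity returns delta = psi = 0; at total retardance pi the rotator part
    is ambiguous (psi is still reported from the same formula).
    """
    M_R = np.asarray(M_R, dtype=float)
    b = M_R[..., 1:, 1:]
    two_psi = np.arctan2(b[..., 0, 1] - b[..., 1, 0], b[..., 0, 0] + b[..., 1, 1])
    psi = 0.5 * two_psi
    R = np.arccos(np.clip(np.trace(b, axis1=-2, axis2=-1) / 2.0 - 0.5, -1.0, 1.0))
    psi = np.where(R < tol, 0.0, psi)

    if M_R.ndim == 2:
        M_psi = rotator(float(psi))
    else:
        c, s = np.cos(two_psi), np.sin(two_psi)
        M_psi = np.zeros(M_R.shape)
        M_psi[..., 0, 0] = 1.0
        M_psi[..., 3, 3] = 1.0
        M_psi[..., 1, 1] = c
        M_psi[..., 1, 2] = s
        M_psi[..., 2, 1] = -s
        M_psi[..., 2, 2] = c
    M_LR = M_R @ np.swapaxes(M_psi, -1, -2)
    blr = M_LR[..., 1:, 1:]
    delta = np.arccos(np.clip(np.trace(blr, axis1=-2, axis2=-1) / 2.0 - 0.5, -1.0, 1.0))
    delta = np.where(R < tol, 0.0, delta)
    return M_LR, M_psi, delta, psi


def retardance_axis(M_LR: ArrayLike, tol: float = 1e-6) -> NDArray:
    """Fast-axis orientation theta of a linear retarder, in (-pi/2, pi/2].

    theta = 0.5 atan2(M_LR[3,1] - M_LR[1,3], M_LR[2,3] - M_LR[3,2]); the
    half-angle of atan2 lands in the target range without extra folding.
    Near delta = 0 or pi both arguments vanish and the axis is undefined
    (NaN returned).
    """
    M_LR = np.asarray(M_LR, dtype=float)
    num = M_LR[..., 3, 1] - M_LR[..., 1, 3]
    den = M_LR[..., 2, 3] - M_LR[..., 3, 2]
    theta = 0.5 * np.arctan2(num, den)
    undefined = np.hypot(num, den) < tol
    return np.where(undefined, np.nan, theta)


def polar_maps(img: MuellerImage) -> dict[str, NDArray]:
    """Pixel-wise polar-decomposition maps honoring the realizability mask.

    Returns float maps ``delta`` (depolarization), ``R``, ``D``, ``theta``,
    ``delta_lr`` (linear retardance), ``psi`` with NaN at masked pixels.
    """
    m00 = img.data[..., 0, 0]
    valid = img.mask & np.isfinite(m00) & (m00 > 0)
    m = np.where(valid[..., None, None], img.data / np.where(valid, m00, 1.0)[..., None, None], np.nan)
    safe = np.where(valid[..., None, None], m, np.eye(4))
    res = lu_chipman(safe)
    M_LR, _, delta_lr, psi = retarder_split(res.M_R)
    theta = retardance_axis(M_LR)
    nan = np.where(valid, 1.0, np.nan)
    return {
        "delta": res.delta_total * nan,
        "R": res.retardance * nan,
        "D": res.diattenuation * nan,
        "theta": theta * nan,
        "delta_lr": delta_lr * nan,
        "psi": psi * nan,
    }
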