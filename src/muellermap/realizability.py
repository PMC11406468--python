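"""Physical-realizability screening of Mueller matrices (ensemble criterion).

A measured matrix M is accepted when (1) the coherency matrix H(M) built in
the Pauli basis is positive semi-definite, and (2) the forward and reverse
passivity conditions M00 (1 + ||D||) <= 1 and M00 (1 + ||P||) <= 1 hold, all
within a tolerance (default 1e-5).  The eigenvalue tolerance is relative to
trace(H) so the verdict is invariant to the overall intensity scale.
Failing pixels are excluded from every downstream statistic, never repaired.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .core import MuellerImage, diattenuation_vector, polarizance_vector

#: Default numerical tolerance of the screen.
DEFAULT_TOL = 1e-5

_PAULI = np.array(
    [
        [[1, 0], [0, 1]],
        [[1, 0], [0, -1]],
        [[0, 1], [1, 0]],
        [[0, -1j], [1j, 0]],
    ],
    dtype=complex,
)

# B[i, j] = sigma_i (x) sigma_j*, shape (4, 4, 4, 4); fixed basis order
# (I, diag(1,-1), real off-diagonal, imaginary off-diagonal).  The conjugate
# on the second factor makes H(M) rank one for every Mueller-from-Jones
# matrix.  Eigenvalues of H are independent of the basis ordering (it only
# changes H by a unitary).
_BASIS = np.einsum("iab,jcd->ijacbd", _PAULI, _PAULI.conj()).reshape(4, 4, 4, 4)


def coherency(M: ArrayLike) -> NDArray:
    """Coherency (covariance) matrix H = (1/4) sum_ij M_ij sigma_i (x) sigma_j.

    Hermitian with trace(H) = M00; supports stacked input (..., 4, 4).
    """
    M = np.asarray(M, dtype=float)
    return 0.25 * np.einsum("...ij,ijkl->...kl", M, _BASIS)


def coherency_eigenvalues(M: ArrayLike) -> NDArray:
    """Eigenvalues of H(M), sorted descending along the last axis."""
    lam = np.linalg.eigvalsh(coherency(M))
    return lam[..., ::-1]


@dataclass
class EnsembleVerdict:
    """Outcome of the ensemble criterion for one matrix."""

    passed: bool
    min_eigenvalue: float        # smallest eigenvalue of H, relative to trace(H)
    forward_margin: float        # 1 + tol - M00 (1 + ||D||)
    reverse_margin: float        # 1 + tol - M00 (1 + ||P||)


def ensemble_criterion(
    M: ArrayLike, tol: float = DEFAULT_TOL, reflectance: float | None = None
) -> EnsembleVerdict:
    """Evaluate the ensemble criterion for a single Mueller matrix.

    Parameters
    ----------
    M : array_like (4, 4)
        Mueller matrix, unnormalized (M00 carries the physical intensity
        scale used by the passivity conditions).
    tol : float
        Tolerance for both conditions.
    reflectance : float, optional
        Scene-reflectance scale multiplying the stored M00 in the passivity
        conditions.  Synthetic cubes store m00 = 1, which would make
        passivity vacuous; a scale of e.g. 0.5 restores its physical
        meaning, and anomalously bright pixels (specular saturation) still
        overflow the gain limit.

    Returns
    -------
    EnsembleVerdict
        Always returns a verdict; diagnostic margins included.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    M = np.asarray(M, dtype=float)
    lam = coherency_eigenvalues(M)
    trace = float(np.sum(lam))
    rel_min = float(lam[-1] / trace) if trace > 0 else float(lam[-1])
    m00 = float(M[0, 0])
    m00_phys = m00 * reflectance if reflectance is not None else m00
    dnorm = float(np.linalg.norm(diattenuation_vector(M))) / m00
    pnorm = float(np.linalg.norm(polarizance_vector(M))) / m00
    fwd = 1.0 + tol - m00_phys * (1.0 + dnorm)
    rev = 1.0 + tol - m00_phys * (1.0 + pnorm)
    passed = (rel_min >= -tol) and (fwd >= 0.0) and (rev >= 0.0)
    return EnsembleVerdict(bool(passed), rel_min, fwd, rev)


def realizability_mask(
    img: MuellerImage | NDArray,
    tol: float = DEFAULT_TOL,
    reflectance: float | None = 0.5,
) -> NDArray:
    """Pixel-wise ensemble criterion over an image; returns an H x W mask.

    For a :class:`MuellerImage` the mask is also stored on the image.
    ``reflectance`` rescales the stored M00 in the passivity conditions
    (default 0.5): normalized cubes (m00 = 1) get a physically meaningful
    passive scale, while anomalously bright pixels — specular saturation,
    reconstruction blow-ups — still overflow the gain limit and are masked.
    """
    data = img.data if isinstance(img, MuellerImage) else np.asarray(img, dtype=float)
    lam = coherency_eigenvalues(data)
    trace = lam.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_min = np.where(trace > 0, lam[..., -1] / trace, lam[..., -1])
    m00 = data[..., 0, 0]
    valid00 = np.isfinite(m00) & (m00 > 0)
    safe00 = np.where(valid00, m00, 1.0)
    scale = 1.0 if reflectance is None else reflectance
    m00_phys = np.where(valid00, m00 * scale, np.inf)
    dnorm = np.linalg.norm(data[..., 0, 1:4], axis=-1) / safe00
    pnorm = np.linalg.norm(data[..., 1:4, 0], axis=-1) / safe00
    mask = (
        valid00
        & (rel_min >= -tol)
        & (m00_phys * (1.0 + dnorm) <= 1.0 + tol)
        & (m00_phys * (1.0 + pnorm) <= 1.0 + tol)
    )
    if isinstance(img, MuellerImage):
        img.mask = mask
    return mask
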