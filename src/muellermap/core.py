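"""Core Mueller/Stokes containers, normalization, and canonical optical elements.

A Mueller matrix is a real 4x4 intensity-transfer matrix acting on Stokes
vectors (I, Q, U, V).  Throughout the package the Stokes convention is
0-based with Q = horizontal - vertical, and all angles are in radians.
Retarder and rotator factories follow the Lu-Chipman sign conventions so
that the linear-retardance axis formula recovers the construction axis
exactly; the fast-axis angle theta lives in (-pi/2, pi/2].

Matrix-valued functions accept stacked arrays of shape (..., 4, 4) and
broadcast over the leading axes, so whole images are processed with one call.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray

#: Wavelengths (nm) of the six-filter acquisition protocol.
WAVELENGTHS_NM: tuple[int, ...] = (450, 500, 550, 590, 650, 680)


class DegeneratePixelError(ValueError):
    """Raised when a Mueller matrix cannot be normalized (M00 <= 0)."""


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(M: ArrayLike) -> tuple[NDArray, NDArray]:
    """Split ``M`` into its unnormalized first element and ``m = M / M00``.

    Parameters
    ----------
    M : array_like, shape (..., 4, 4)
        Mueller matrix or stack of Mueller matrices.

    Returns
    -------
    m00 : ndarray, shape (...)
        First element of each matrix.
    m : ndarray, shape (..., 4, 4)
        Normalized matrix with ``m[..., 0, 0] == 1``.

    Raises
    ------
    DegeneratePixelError
        If any ``M00 <= 0`` or is non-finite.  Pixel-wise callers should
        pre-screen and mark such pixels invalid instead.
    """
    M = np.asarray(M, dtype=float)
    m00 = M[..., 0, 0]
    if not np.all(np.isfinite(M)) or np.any(m00 <= 0):
        raise DegeneratePixelError("Mueller matrix has M00 <= 0 or non-finite entries")
    return m00, M / m00[..., None, None]


def diattenuation_vector(m: ArrayLike) -> NDArray:
    """First row (elements 1..3) of a normalized Mueller matrix."""
    return np.asarray(m, dtype=float)[..., 0, 1:4]


def polarizance_vector(m: ArrayLike) -> NDArray:
    """First column (elements 1..3) of a normalized Mueller matrix."""
    return np.asarray(m, dtype=float)[..., 1:4, 0]


# ---------------------------------------------------------------------------
# canonical elements
# ---------------------------------------------------------------------------

def diagonal_depolarizer(a: float, b: float, c: float) -> NDArray:
    """Diagonal depolarizer diag(1, a, b, c) with a, b, c in [-1, 1]."""
    for v in (a, b, c):
        if not -1.0 <= v <= 1.0:
            raise ValueError("depolarizer diagonal entries must lie in [-1, 1]")
    return np.diag([1.0, a, b, c])


def linear_retarder(delta: float, theta: float = 0.0) -> NDArray:
    """Linear retarder with retardance ``delta`` in [0, pi] and fast axis ``theta``.

    ``trace = 2 + 2 cos(delta)`` and the axis is recoverable from the
    standard half-angle arctangent of the off-diagonal elements.
    """
    if not 0.0 <= delta <= np.pi:
        raise ValueError("retardance must lie in [0, pi]")
    C, S = np.cos(2.0 * theta), np.sin(2.0 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    M = np.eye(4)
    M[1:, 1:] = [
        [C * C + S * S * cd, S * C * (1.0 - cd), -S * sd],
        [S * C * (1.0 - cd), S * S + C * C * cd, C * sd],
        [S * sd, -C * sd, cd],
    ]
    return M


def rotator(psi: float) -> NDArray:
    """Pure optical rotator by angle ``psi`` (circular retarder)."""
    c, s = np.cos(2.0 * psi), np.sin(2.0 * psi)
    M = np.eye(4)
    M[1:3, 1:3] = [[c, s], [-s, c]]
    return M


def diattenuator_from_vector(dvec: ArrayLike) -> NDArray:
    """Normalized diattenuator built from a diattenuation vector (||d|| <= 1).

    Standard rank-one + isotropic construction: the 3x3 block is
    ``sqrt(1-D^2) I + (1 - sqrt(1-D^2)) dhat dhat^T``.
    Supports stacked vectors of shape (..., 3).
    """
    d = np.asarray(dvec, dtype=float)
    D = np.linalg.norm(d, axis=-1)
    if np.any(D > 1.0 + 1e-12):
        raise ValueError("diattenuation vector norm exceeds 1")
    Dc = np.minimum(D, 1.0)
    root = np.sqrt(1.0 - Dc**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dhat = np.where(Dc[..., None] > 0, d / np.where(Dc == 0, 1.0, Dc)[..., None], 0.0)
    eye = np.broadcast_to(np.eye(3), d.shape[:-1] + (3, 3))
    mD = root[..., None, None] * eye + (1.0 - root)[..., None, None] * (
        dhat[..., :, None] * dhat[..., None, :]
    )
    M = np.zeros(d.shape[:-1] + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 0, 1:] = d
    M[..., 1:, 0] = d
    M[..., 1:, 1:] = mD
    return M


def linear_diattenuator(D: float, axis: float = 0.0) -> NDArray:
    """Linear diattenuator of magnitude ``D`` in [0, 1] oriented at ``axis``."""
    if not 0.0 <= D <= 1.0:
        raise ValueError("diattenuation must lie in [0, 1]")
    return diattenuator_from_vector([D * np.cos(2.0 * axis), D * np.sin(2.0 * axis), 0.0])


def ideal_polarizer(axis: float = 0.0) -> NDArray:
    """Ideal linear polarizer at ``axis`` (M00 = 0.5, D = P = 1)."""
    c, s = np.cos(2.0 * axis), np.sin(2.0 * axis)
    v = np.array([1.0, c, s, 0.0])
    return 0.5 * np.outer(v, v)


def make_element(kind: str, *args: float) -> NDArray:
    """Factory dispatch by name, mainly for configuration files.

    ``kind`` is one of ``diagonal_depolarizer``, ``linear_retarder``,
    ``rotator``, ``linear_diattenuator``, ``ideal_polarizer``.
    """
    factories = {
        "diagonal_depolarizer": diagonal_depolarizer,
        "linear_retarder": linear_retarder,
        "rotator": rotator,
        "linear_diattenuator": linear_diattenuator,
        "ideal_polarizer": ideal_polarizer,
    }
    try:
        return factories[kind](*args)
    except KeyError:
        raise ValueError(f"unknown element kind {kind!r}") from None


# ---------------------------------------------------------------------------
# Jones bridge and random physical ensembles
# ---------------------------------------------------------------------------

_A = np.array(
    [[1, 0, 0, 1], [1, 0, 0, -1], [0, 1, 1, 0], [0, 1j, -1j, 0]], dtype=complex
)
_A_INV = np.linalg.inv(_A)


def jones_to_mueller(J: ArrayLike) -> NDArray:
    """Mueller matrix of a deterministic (non-depolarizing) Jones element."""
    J = np.asarray(J, dtype=complex)
    M = _A @ np.kron(J, J.conj()) @ _A_INV
    if np.max(np.abs(M.imag)) > 1e-10 * max(np.max(np.abs(M.real)), 1.0):
        raise ValueError("Jones-to-Mueller conversion produced a non-real matrix")
    return M.real


def random_physical_mueller(
    rng: np.random.Generator | int, n_pure_components: int = 4
) -> NDArray:
    """Random physically realizable Mueller matrix.

    A convex combination of ``n_pure_components`` Mueller matrices derived
    from random complex Jones matrices, globally rescaled so both passivity
    conditions hold with margin.  The result passes the ensemble criterion
    by construction.
    """
    if n_pure_components < 1:
        raise ValueError("need at least one pure component")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    weights = rng.dirichlet(np.ones(n_pure_components))
    M = np.zeros((4, 4))
    for w in weights:
        J = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
        Mj = jones_to_mueller(J)
        M += w * Mj / Mj[0, 0]
    gain = M[0, 0] * (1.0 + max(
        np.linalg.norm(diattenuation_vector(M)) / M[0, 0],
        np.linalg.norm(polarizance_vector(M)) / M[0, 0],
    ))
    return M * (rng.uniform(0.3, 0.95) / gain)


# ---------------------------------------------------------------------------
# Stokes helpers
# ---------------------------------------------------------------------------

def degree_of_polarization(s: ArrayLike) -> NDArray:
    """DOP = sqrt(Q^2 + U^2 + V^2) / I for Stokes vectors of shape (..., 4)."""
    s = np.asarray(s, dtype=float)
    return np.linalg.norm(s[..., 1:], axis=-1) / s[..., 0]


# ---------------------------------------------------------------------------
# image container
# ---------------------------------------------------------------------------

@dataclass
class MuellerImage:
    """Per-wavelength Mueller image: H x W x 4 x 4 with a validity mask.

    ``mask`` is True where the pixel is physically realizable (set by the
    realizability screen); downstream statistics honor it.
    """

    data: NDArray
    wavelength: float
    mask: NDArray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-2:] != (4, 4):
            raise ValueError("MuellerImage data must have shape (H, W, 4, 4)")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape must match image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]
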