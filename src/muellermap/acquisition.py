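"""Forward instrument model and least-squares Mueller reconstruction.

The polarimeter is described by a polarization state generator (PSG) whose
columns are the four illumination Stokes states, and a polarization state
analyzer (PSA) whose K = 8 rows are analyzer vectors: a sliding quarter-wave
retarder (out/in) in front of a four-orientation micropolarizer camera
(0/45/90/135 deg).  One Mueller measurement therefore takes
8 x 4 = 32 intensity frames, and the per-pixel intensity matrix obeys

    I = PSA . M . PSG

which is inverted in the least-squares sense, M = pinv(PSA) . I . inv(PSG).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .core import MuellerImage, linear_retarder, rotator

#: PSG quarter-wave-plate fast-axis angles (radians).  The four angles that
#: minimize the condition number of a rotating-quarter-wave-plate generator
#: (the classic +/-15.12, +/-51.69 deg set); documented constants.
PSG_QWP_ANGLES = tuple(np.deg2rad((-51.69, -15.12, 15.12, 51.69)))

#: Micropolarizer orientations on the camera sensor (radians).
PSA_MICROPOLARIZER_ANGLES = tuple(np.deg2rad((0.0, 45.0, 90.0, 135.0)))

#: Fast-axis angle of the slide-in quarter-wave retarder (radians).
PSA_SLIDER_QWP_ANGLE = np.deg2rad(45.0)


class InstrumentConfigError(ValueError):
    """Raised for rank-deficient or otherwise unusable PSA/PSG matrices."""


@dataclass
class InstrumentModel:
    """PSG (4 x N columns = generated Stokes states) and PSA (K x 4 rows)."""

    PSG: NDArray
    PSA: NDArray

    def __post_init__(self) -> None:
        self.PSG = np.asarray(self.PSG, dtype=float)
        self.PSA = np.asarray(self.PSA, dtype=float)
        if self.PSG.shape[0] != 4 or self.PSA.shape[1] != 4:
            raise InstrumentConfigError("PSG must be 4xN and PSA Kx4")

    @property
    def condition_numbers(self) -> tuple[float, float]:
        """(cond PSG, cond PSA) - finite for a usable instrument."""
        return float(np.linalg.cond(self.PSG)), float(np.linalg.cond(self.PSA))

    def validate(self) -> None:
        if np.linalg.matrix_rank(self.PSG) < 4:
            raise InstrumentConfigError("PSG is not invertible")
        if np.linalg.matrix_rank(self.PSA) < 4:
            raise InstrumentConfigError("PSA has rank < 4")


@dataclass
class FrameStack:
    """Intensity frames of one Mueller measurement: (K_psa, N_psg, H, W)."""

    frames: NDArray
    exposure: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must have shape (K_psa, N_psg, H, W)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0] * self.frames.shape[1]


@dataclass
class AcquisitionPlan:
    """Bookkeeping of a multi-filter, multi-region acquisition campaign."""

    frames_per_measurement: int
    total_frames: int
    total_mueller_matrices: int


def ideal_instrument() -> InstrumentModel:
    """Built-in ideal instrument: rotating-QWP PSG, 2 x 4-state PSA.

    PSG column g: horizontal polarizer followed by a QWP at the g-th angle,
    applied to unpolarized unit-intensity light.  PSA rows are ordered
    (slider out, then in) x (micropolarizer 0, 45, 90, 135 deg); the slider
    is a QWP at 45 deg giving the circular sensitivity.
    """
    s_in = np.array([1.0, 0.0, 0.0, 0.0])
    pol_h = 0.5 * np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]])
    cols = [linear_retarder(np.pi / 2, ang) @ pol_h @ s_in for ang in PSG_QWP_ANGLES]
    PSG = np.stack(cols, axis=1)

    qwp = linear_retarder(np.pi / 2, PSA_SLIDER_QWP_ANGLE)
    rows = []
    for slider in (False, True):
        for ang in PSA_MICROPOLARIZER_ANGLES:
            a = 0.5 * np.array([1.0, np.cos(2 * ang), np.sin(2 * ang), 0.0])
            rows.append(a @ qwp if slider else a)
    return InstrumentModel(PSG=PSG, PSA=np.stack(rows, axis=0))


def plan_acquisition(n_filters: int, n_regions: int) -> AcquisitionPlan:
    """Frame and matrix counts for the 32-frame protocol.

    Frames per measurement = 4 PSG retarder positions x 2 slider positions
    x 4 micropolarizer orientations = 32; one Mueller matrix per
    (filter, region) pair.
    """
    if n_filters < 1 or n_regions < 1:
        raise ValueError("need at least one filter and one region")
    instr = ideal_instrument()
    fpm = instr.PSA.shape[0] * instr.PSG.shape[1]
    n_matrices = n_filters * n_regions
    return AcquisitionPlan(fpm, fpm * n_matrices, n_matrices)


def forward_measure(
    img: MuellerImage | ArrayLike,
    instr: InstrumentModel,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> FrameStack:
    """Simulate the intensity frames of a Mueller image through the instrument.

    Noiseless intensity at (analyzer a, generator g) is
    PSA[a] . M . PSG[:, g] per pixel; optional additive Gaussian noise with
    standard deviation ``noise_sigma`` (in units of the maximum noiseless
    intensity) is applied afterwards.  Negative noiseless intensities are
    clamped to zero with a count recorded in the exposure metadata.
    """
    instr.validate()
    data = img.data if isinstance(img, MuellerImage) else np.asarray(img, dtype=float)
    frames = np.einsum("ak,hwkl,lg->aghw", instr.PSA, data, instr.PSG)
    n_clamped = int(np.sum(frames < 0))
    if n_clamped:
        frames = np.clip(frames, 0.0, None)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        frames = frames + rng.normal(0.0, noise_sigma * frames.max(), frames.shape)
    meta: dict[str, Any] = {"n_clamped": n_clamped}
    if isinstance(img, MuellerImage):
        meta["wavelength"] = img.wavelength
        meta.update(img.metadata)
    return FrameStack(frames, meta)


def reconstruct(frames: FrameStack, instr: InstrumentModel) -> MuellerImage:
    """Least-squares Mueller image from an intensity frame stack.

    Per pixel, M = pinv(PSA) . I . inv(PSG); exact two-sided inversion in
    the square K = 4 case.  Raises before any pixel work if the instrument
    is rank-deficient.
    """
    instr.validate()
    psa_inv = np.linalg.pinv(instr.PSA)
    psg_inv = np.linalg.inv(instr.PSG)
    data = np.einsum("ka,aghw,gl->hwkl", psa_inv, frames.frames, psg_inv)
    wl = frames.exposure.get("wavelength", 550.0)
    meta = {k: v for k, v in frames.exposure.items() if k not in ("wavelength",)}
    return MuellerImage(data=data, wavelength=wl, metadata=meta)
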