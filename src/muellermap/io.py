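"""Serialization of Mueller cubes, masks, and frame stacks.

Cubes travel in HDF5 containers (datasets ``/mueller`` H x W x 4 x 4
float64 and ``/mask`` H x W uint8, attributes ``wavelength_nm``,
``specimen``, ``region``) and can be exchanged as 16-page float TIFF stacks
where page k holds element (k // 4, k % 4).  Frame stacks go to multi-page
TIFF (pages ordered analyzer-major: a * N_psg + g) with a JSON sidecar
carrying the instrument matrices and exposure metadata.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .acquisition import FrameStack, InstrumentModel
from .core import MuellerImage


def save_cube(path: str | Path, img: MuellerImage) -> None:
    """Write a Mueller image to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mueller", data=img.data, dtype="float64")
        f.create_dataset("mask", data=img.mask.astype(np.uint8))
        f.attrs["wavelength_nm"] = float(img.wavelength)
        for key in ("specimen", "region"):
            if key in img.metadata:
                f.attrs[key] = img.metadata[key]


def load_cube(path: str | Path) -> MuellerImage:
    """Read a Mueller image from an HDF5 container."""
    with h5py.File(path, "r") as f:
        data = f["mueller"][...]
        mask = f["mask"][...].astype(bool)
        meta = {k: f.attrs[k] for k in ("specimen", "region") if k in f.attrs}
        wl = float(f.attrs["wavelength_nm"])
    return MuellerImage(data=data, wavelength=wl, mask=mask, metadata=meta)


def export_cube_tiff(path: str | Path, img: MuellerImage) -> None:
    """Write the 16 matrix elements as a float TIFF stack (page k = (k//4, k%4))."""
    pages = np.stack(
        [img.data[..., k // 4, k % 4] for k in range(16)], axis=0
    ).astype(np.float32)
    tifffile.imwrite(path, pages, metadata={"wavelength_nm": img.wavelength})


def import_cube_tiff(path: str | Path, wavelength: float) -> MuellerImage:
    """Read a 16-page element stack back into a Mueller image."""
    pages = tifffile.imread(path)
    if pages.shape[0] != 16:
        raise ValueError("expected a 16-page element stack")
    data = np.zeros(pages.shape[1:] + (4, 4))
    for k in range(16):
        data[..., k // 4, k % 4] = pages[k]
    return MuellerImage(data=data, wavelength=wavelength)


def save_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    """Write a realizability mask as single-page uint8 TIFF (255 = valid)."""
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def save_frames(path: str | Path, frames: FrameStack, instr: InstrumentModel) -> None:
    """Write a frame stack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    K, N, H, W = frames.frames.shape
    tifffile.imwrite(path, frames.frames.reshape(K * N, H, W).astype(np.float32))
    sidecar = {
        "psa": instr.PSA.tolist(),
        "psg": instr.PSG.tolist(),
        "k_psa": K,
        "n_psg": N,
        "exposure": {k: v for k, v in frames.exposure.items() if _jsonable(v)},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_frames(path: str | Path) -> tuple[FrameStack, InstrumentModel]:
    """Read a frame stack and its instrument sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(path)
    K, N = sidecar["k_psa"], sidecar["n_psg"]
    frames = FrameStack(
        pages.reshape(K, N, *pages.shape[1:]).astype(float), sidecar.get("exposure", {})
    )
    instr = InstrumentModel(PSG=np.array(sidecar["psg"]), PSA=np.array(sidecar["psa"]))
    return frames, instr


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
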