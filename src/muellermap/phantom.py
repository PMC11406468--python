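"""Synthetic multispectral Mueller phantoms of brain-like tissue.

Each phantom region is a 2-D scene with a cortical grey-matter (GM) field, a
branching white-matter (WM) core, and thin curvilinear vessels, imaged at
the six acquisition wavelengths.  Per-pixel matrices are composed as
depolarizer . retarder . diattenuator, so the forward polar decomposition
is an exact inverse of the generator and every pixel is physically
realizable by construction.

The per-class parameter curves emulate the trends measured on fresh brain
tissue: GM depolarization rising from 0.60 at 450 nm to 0.88 at 680 nm and
WM from just below 0.9 to almost 0.95; a local depolarization dip at 550 nm
(9% below the 500/590 nm trend for GM, 2% for WM — the hemoglobin
absorption signature, imposed phenomenologically); GM retardance doubling
from 0.16 rad at 450 nm to 0.32 rad at 680 nm and WM from 0.42 to 0.72 rad;
diattenuation below 0.04 everywhere with GM roughly half of WM.  Specimens
differ by multiplicative lognormal perturbations of the class curves, which
is what leave-one-specimen-out cross-validation has to generalize across.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.ndimage import gaussian_filter

from .acquisition import FrameStack
from .core import WAVELENGTHS_NM, MuellerImage
from .polar import polar_maps

BACKGROUND, GM, WM, VESSEL = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", GM: "GM", WM: "WM", VESSEL: "vessel"}

#: Anchor curves (wavelength nm -> value) per class and parameter.  The
#: 550 nm value is NOT anchored: it is derived from the 500/590 trend and
#: the class dip fraction.
_ANCHORS = {
    "delta": {
        GM: {450: 0.60, 500: 0.66, 590: 0.78, 650: 0.85, 680: 0.88},
        WM: {450: 0.885, 500: 0.90, 590: 0.92, 650: 0.935, 680: 0.945},
        VESSEL: {450: 0.80, 500: 0.85, 590: 0.89, 650: 0.92, 680: 0.93},
    },
    "R": {
        GM: {450: 0.16, 680: 0.32},
        WM: {450: 0.42, 680: 0.72},
        VESSEL: {450: 0.50, 680: 0.90},
    },
    "D": {
        GM: {450: 0.012, 680: 0.008},
        WM: {450: 0.024, 680: 0.016},
        VESSEL: {450: 0.020, 680: 0.014},
    },
}

_DIP = {GM: 0.09, WM: 0.02, VESSEL: 0.12}


@dataclass
class PhantomConfig:
    """Study conditions of the synthetic phantom generator."""

    shape: tuple[int, int] = (64, 64)
    wavelengths: tuple[float, ...] = WAVELENGTHS_NM
    n_specimens: int = 6
    n_regions: int = 20
    #: lognormal sigma of the per-specimen multiplicative class-curve factors
    #: (coherent across wavelengths) and of the additional per-wavelength
    #: specimen jitter.  Retardance and diattenuation depend on fiber
    #: orientation relative to the view and on tissue state, so their
    #: specimen-to-specimen variability is much larger than that of
    #: depolarization.
    specimen_sd: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.015, "R": 0.18, "D": 0.15}
    )
    specimen_wl_sd: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.03, "R": 0.06, "D": 0.05}
    )
    #: lognormal sigma of per-(region, class) factors.  Retardance medians of
    #: same-class structures differ several-fold between views (fiber bundles
    #: at different inclinations), while depolarization forms a tight
    #: continuum across regions.
    region_sd: dict[str, float] = field(
        default_factory=lambda: {"delta": 0.02, "R": 0.20, "D": 0.20}
    )
    #: SD of the latent tissue axis, in units of the GM-to-WM gap.  One
    #: smooth "myelination" field per region carries the within-class
    #: anatomical variability; every polarimetric parameter at every
    #: wavelength is a noisy monotone channel of this single latent, so the
    #: three parameters fluctuate jointly and no parameter carries class
    #: information beyond the latent itself.
    latent_sd: float = 0.27
    #: per-channel measurement/calibration noise SDs (absolute, anchored at
    #: 450 and 680 nm, linear in wavelength).  Depolarization is measured
    #: cleanly; retardance and diattenuation are dim signals whose noise
    #: widths match the broad overlapping distributions of the measurements
    #: (diattenuation is essentially noise at every wavelength).
    delta_noise: tuple[float, float] = (0.080, 0.060)
    r_noise: tuple[float, float] = (0.18, 0.40)
    d_noise: tuple[float, float] = (0.012, 0.018)
    #: depolarization dip fractions at 550 nm relative to the 500/590 trend
    dip: dict[int, float] = field(default_factory=lambda: dict(_DIP))
    #: retardance-axis rotation per wavelength step (radians)
    axis_shift_per_step: float = 0.05
    #: frame-level Gaussian noise sigma (fraction of max intensity)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1 or self.n_regions < 1:
            raise ValueError("need at least one specimen and one region")
        for frac in self.dip.values():
            if not 0.0 <= frac < 1.0:
                raise ValueError("dip fractions must lie in [0, 1)")
        for lab, anch in _ANCHORS["delta"].items():
            if any(not 0.0 <= v < 1.0 for v in anch.values()):
                raise ValueError("depolarization curve out of [0, 1)")


@dataclass
class PhantomTruth:
    """Ground-truth labels and per-pixel polarimetric parameters."""

    labels: NDArray                                # H x W integer labels
    params: dict[float, dict[str, NDArray]]        # wavelength -> maps
    specimen: int
    region: int


def class_curve(param: str, label: int, wavelength: float, dip: dict[int, float] | None = None) -> float:
    """Class parameter value at one wavelength (anchors + 550 nm dip)."""
    dip = dict(_DIP) if dip is None else dip
    anchors = _ANCHORS[param][label]
    wl = np.array(sorted(anchors))
    vals = np.array([anchors[w] for w in wl])
    base = float(np.interp(wavelength, wl, vals))
    if param == "delta" and abs(wavelength - 550.0) < 5.0:
        trend = float(np.interp(550.0, wl, vals))
        return trend * (1.0 - dip.get(label, 0.0))
    return base


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _segment_distance(px: NDArray, py: NDArray, seg: tuple) -> NDArray:
    x0, y0, x1, y1 = seg
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    t = np.clip(((px - x0) * dx + (py - y0) * dy) / max(L2, 1e-12), 0.0, 1.0)
    return np.hypot(px - (x0 + t * dx), py - (y0 + t * dy))


def _region_labels(shape: tuple[int, int], rng: np.random.Generator) -> NDArray:
    """Procedural scene: elliptical specimen, branching WM core, vessels."""
    H, W = shape
    y, x = np.mgrid[0:H, 0:W]
    px, py = x / (W - 1.0), y / (H - 1.0)

    labels = np.full(shape, BACKGROUND, dtype=np.int8)
    inside = ((px - 0.5) / 0.46) ** 2 + ((py - 0.5) / 0.46) ** 2 <= 1.0
    labels[inside] = GM

    # WM: a main stem plus branches (arbor-vitae-like tree of segments)
    x_top = 0.5 + rng.uniform(-0.08, 0.08)
    x_bot = 0.5 + rng.uniform(-0.08, 0.08)
    segs = [(x_top, 0.2, x_bot, 0.8)]
    n_branch = rng.integers(3, 6)
    for _ in range(n_branch):
        t = rng.uniform(0.25, 0.75)
        bx = x_top + (x_bot - x_top) * (t - 0.2) / 0.6
        ang = rng.uniform(0.4, 1.2) * rng.choice([-1.0, 1.0])
        length = rng.uniform(0.12, 0.25)
        segs.append((bx, t, bx + length * np.sin(ang), t + length * np.cos(ang)))
    wm = np.zeros(shape, dtype=bool)
    widths = [0.07] + [0.035] * n_branch
    for seg, w in zip(segs, widths):
        wm |= _segment_distance(px, py, seg) < w
    labels[wm & inside] = WM

    # vessels: thin sinusoidal curves crossing the specimen
    for _ in range(rng.integers(1, 3)):
        a = rng.uniform(0.25, 0.75)
        b = rng.uniform(0.05, 0.12)
        f = rng.uniform(1.0, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        vessel = np.abs(py - (a + b * np.sin(2 * np.pi * f * px + phase))) < 0.015
        labels[vessel & inside] = VESSEL
    return labels


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, corr: float = 2.5) -> NDArray:
    """Unit-variance smooth Gaussian random field (pixel texture)."""
    f = gaussian_filter(rng.normal(size=shape), corr, mode="wrap")
    return f / f.std()


# ---------------------------------------------------------------------------
# batched element builders (internal; mirror the core factories)
# ---------------------------------------------------------------------------

def _batched_retarder(delta: NDArray, theta: NDArray) -> NDArray:
    C, S = np.cos(2 * theta), np.sin(2 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    M = np.zeros(delta.shape + (4, 4))
    M[..., 0, 0] = 1.0
    M[..., 1, 1] = C * C + S * S * cd
    M[..., 1, 2] = S * C * (1 - cd)
    M[..., 1, 3] = -S * sd
    M[..., 2, 1] = S * C * (1 - cd)
    M[..., 2, 2] = S * S + C * C * cd
    M[..., 2, 3] = C * sd
    M[..., 3, 1] = S * sd
    M[..., 3, 2] = -C * sd
    M[..., 3, 3] = cd
    return M


def _batched_diattenuator(D: NDArray, theta: NDArray) -> NDArray:
    from .core import diattenuator_from_vector

    dvec = np.stack([D * np.cos(2 * theta), D * np.sin(2 * theta), np.zeros_like(D)], axis=-1)
    return diattenuator_from_vector(dvec)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _specimen_factors(config: PhantomConfig, rng: np.random.Generator) -> dict:
    """Multiplicative lognormal class-curve perturbations for one specimen.

    A coherent factor per (parameter, class) shifts the whole spectral curve
    of a specimen; an additional smaller per-wavelength jitter decorrelates
    the shift across channels.
    """
    factors = {}
    for param in ("delta", "R", "D"):
        for lab in (GM, WM, VESSEL):
            coherent = float(rng.lognormal(0.0, config.specimen_sd[param]))
            for wl in config.wavelengths:
                factors[(param, lab, wl)] = coherent * float(
                    rng.lognormal(0.0, config.specimen_wl_sd[param])
                )
    return factors


def _sd_at(anchors: tuple[float, float], wavelength: float) -> float:
    """Linear interpolation of a (450 nm, 680 nm) SD anchor pair."""
    return float(np.interp(wavelength, (450.0, 680.0), anchors))


def generate_phantom(
    config: PhantomConfig,
    specimen: int = 0,
    region: int = 0,
    rng: np.random.Generator | None = None,
    specimen_factors: dict | None = None,
) -> tuple[PhantomTruth, dict[float, MuellerImage]]:
    """One phantom region at all configured wavelengths.

    Returns the ground truth and one normalized :class:`MuellerImage` per
    wavelength.  Deterministic given (config.seed, specimen, region) when no
    generator is supplied.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, specimen, region))
    if specimen_factors is None:
        specimen_factors = _specimen_factors(
            config, np.random.default_rng((config.seed, specimen))
        )
    labels = _region_labels(config.shape, rng)
    region_factors = {
        (p, lab): float(rng.lognormal(0.0, config.region_sd[p]))
        for p in ("delta", "R", "D")
        for lab in (GM, WM, VESSEL)
    }
    H, W = config.shape
    y, x = np.mgrid[0:H, 0:W]
    theta_base = (np.pi / 3) * (x / (W - 1.0) - 0.5) + 0.25 * np.sin(
        2 * np.pi * y / (H - 1.0)
    )

    # one static latent "myelination" field per region; every channel is the
    # class curve plus a latent-driven shift (scaled by that channel's
    # GM-to-WM gap) plus independent channel noise
    anatomy = _smooth_field(config.shape, rng)
    noise_anchors = {"delta": config.delta_noise, "R": config.r_noise, "D": config.d_noise}
    params: dict[float, dict[str, NDArray]] = {}
    images: dict[float, MuellerImage] = {}
    for step, wl in enumerate(config.wavelengths):
        fields = {}
        for p in ("delta", "R", "D"):
            field_p = np.zeros((H, W))
            for lab in (GM, WM, VESSEL):
                sel = labels == lab
                field_p[sel] = (
                    class_curve(p, lab, wl, config.dip)
                    * specimen_factors[(p, lab, wl)]
                    * region_factors[(p, lab)]
                )
            gap = class_curve(p, WM, wl, config.dip) - class_curve(p, GM, wl, config.dip)
            field_p = (
                field_p
                + gap * config.latent_sd * anatomy
                + _sd_at(noise_anchors[p], wl) * _smooth_field(config.shape, rng)
            )
            fields[p] = field_p
        # background = diffuse support plate: strongly depolarizing, well
        # inside the physical cone so measurement noise cannot unmask it
        tissue = labels != BACKGROUND
        delta = np.where(tissue, np.clip(fields["delta"], 0.01, 0.98), 0.95)
        R = np.where(tissue, np.clip(fields["R"], 0.01, np.pi - 0.01), 0.01)
        D = np.where(tissue, np.clip(fields["D"], 0.0, 0.2), 0.0)
        theta = theta_base + config.axis_shift_per_step * step
        # fold into (-pi/2, pi/2]
        theta = np.angle(np.exp(2j * theta)) / 2.0

        a = (1.0 - delta)[..., None, None] * np.eye(4)
        a[..., 0, 0] = 1.0
        M = a @ _batched_retarder(R, theta) @ _batched_diattenuator(D, theta)
        params[wl] = {"delta": delta, "R": R, "D": D, "theta": theta}
        images[wl] = MuellerImage(
            data=M,
            wavelength=wl,
            metadata={"specimen": specimen, "region": region},
        )
    return PhantomTruth(labels, params, specimen, region), images


def corrupt_frames(
    frames: FrameStack,
    sigma_gauss: float = 0.0,
    p_specular: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> FrameStack:
    """Instrument-level corruption: Gaussian noise plus saturated patches.

    ``p_specular`` is the target fraction of pixels covered by specular
    (saturated) disks; reconstructions of those pixels should fail the
    ensemble criterion at elevated rates.  With both parameters zero the
    stack is returned unchanged (new object, same values).
    """
    if sigma_gauss < 0 or not 0.0 <= p_specular < 1.0:
        raise ValueError("invalid corruption parameters")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = frames.frames.copy()
    H, W = out.shape[2:]
    specular = np.zeros((H, W), dtype=bool)
    if p_specular > 0:
        target = p_specular * H * W
        radius = max(2, int(round(np.sqrt(target / max(1, int(target / 30)) / np.pi))))
        while specular.sum() < target:
            cy, cx = rng.integers(0, H), rng.integers(0, W)
            y, x = np.ogrid[0:H, 0:W]
            specular |= (y - cy) ** 2 + (x - cx) ** 2 <= radius**2
        out[:, :, specular] = out.max() * 4.0   # saturate: flat, polarization-free
    if sigma_gauss > 0:
        out = out + rng.normal(0.0, sigma_gauss * out.max(), out.shape)
    exposure = dict(frames.exposure)
    exposure["specular_fraction"] = float(specular.mean())
    return FrameStack(out, exposure)


def generate_study(config: PhantomConfig) -> tuple[list[dict], dict]:
    """Full multi-specimen study: regions round-robin across specimens.

    Returns ``(records, manifest)``.  Each record holds specimen id, region
    id, the :class:`PhantomTruth`, and a wavelength -> MuellerImage dict.
    The manifest counts cubes (regions x wavelengths) and frames under the
    32-frame protocol.
    """
    if config.n_specimens < 2:
        raise ValueError("a study needs at least two specimens")
    records = []
    factors = {
        s: _specimen_factors(config, np.random.default_rng((config.seed, s)))
        for s in range(config.n_specimens)
    }
    for region in range(config.n_regions):
        specimen = region % config.n_specimens
        truth, images = generate_phantom(
            config, specimen, region, specimen_factors=factors[specimen]
        )
        records.append(
            {"specimen": specimen, "region": region, "truth": truth, "images": images}
        )
    n_wl = len(config.wavelengths)
    manifest = {
        "n_specimens": config.n_specimens,
        "n_regions": config.n_regions,
        "wavelengths_nm": list(config.wavelengths),
        "n_cubes": config.n_regions * n_wl,
        "n_mueller_matrices": config.n_regions * n_wl,
        "n_frames": config.n_regions * n_wl * 32,
        "seed": config.seed,
    }
    return records, manifest


def gaussian_fluctuation_medium(
    mean, cov, n_draws: int, rng: np.random.Generator | int = 0
) -> NDArray:
    """Ensemble-averaged Mueller matrix of a Gaussian birefringent medium.

    Draws ``n_draws`` birefringence generator vectors (LBH, LB45, CB
    coefficients) from N(mean, cov), exponentiates each in closed form
    (Rodrigues rotation of the 3x3 block), and averages the resulting pure
    retarders.  Serves as the independent oracle for the differential
    decomposition's fluctuation statistics: the log-decomposition of the
    returned matrix should recover ``mean`` as the spectroscopic means and
    ``cov`` as the variances/covariances.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = rng.multivariate_normal(np.asarray(mean, float), np.asarray(cov, float), size=n_draws)
    # generator blocks matching the Lm template: LBH in the (2,3) plane,
    # LB45 in (1,3), CB in (1,2)
    K = np.zeros((3, 3, 3))
    K[0, 1, 2], K[0, 2, 1] = -1.0, 1.0     # LBH
    K[1, 0, 2], K[1, 2, 0] = 1.0, -1.0     # LB45
    K[2, 0, 1], K[2, 1, 0] = 1.0, -1.0     # CB
    A = np.einsum("nk,kij->nij", draws, K)
    phi = np.maximum(np.linalg.norm(draws, axis=1), 1e-12)
    Ku = A / phi[:, None, None]
    R = (
        np.eye(3)
        + np.sin(phi)[:, None, None] * Ku
        + (1 - np.cos(phi))[:, None, None] * (Ku @ Ku)
    )
    M = np.zeros((n_draws, 4, 4))
    M[:, 0, 0] = 1.0
    M[:, 1:, 1:] = R
    return M.mean(axis=0)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def feature_name(param: str, wavelength: float) -> str:
    """Column-name grammar of the feature table: ``<param>_<wavelength>``."""
    return f"{param}_{int(round(wavelength))}"


def extract_features(records: list[dict], source: str = "polar") -> pd.DataFrame:
    """Pixel feature table (delta, R, D per wavelength) for GM/WM pixels.

    ``source='polar'`` runs the forward polar decomposition on each cube
    (the analysis route); ``source='truth'`` reads the generator ground
    truth (for oracle checks).  Pixels masked at any wavelength are dropped.
    """
    rows = []
    for rec in records:
        truth: PhantomTruth = rec["truth"]
        sel = (truth.labels == GM) | (truth.labels == WM)
        cols: dict[str, NDArray] = {}
        valid = sel.copy()
        for wl, img in rec["images"].items():
            if source == "polar":
                maps = polar_maps(img)
            elif source == "truth":
                maps = truth.params[wl]
            else:
                raise ValueError("source must be 'polar' or 'truth'")
            for param in ("delta", "R", "D"):
                arr = maps[param]
                cols[feature_name(param, wl)] = arr
                valid &= np.isfinite(arr)
        idx = np.where(valid)
        frame = pd.DataFrame({k: v[idx] for k, v in cols.items()})
        frame.insert(0, "specimen", rec["specimen"])
        frame.insert(1, "class", np.where(truth.labels[idx] == GM, "GM", "WM"))
        frame.insert(2, "region", rec["region"])
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
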