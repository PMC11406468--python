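"""Study orchestration: simulate -> (measure/reconstruct) -> screen ->
decompose -> summarize -> classify, as one configurable run.

This is the programmatic driver used by the analysis scripts; each stage is
a thin call into the corresponding module, and the run report records
per-stage pixel-exclusion counts, the configuration, and the seed, so any
output is reproducible byte-for-byte from (config, seed).
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import acquisition, classify, differential, phantom, realizability
from .core import MuellerImage
from .phantom import PhantomConfig, feature_name
from .polar import polar_maps
from .symmetric import symmetric_maps


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0
    tol: float = realizability.DEFAULT_TOL
    reflectance: float = 0.5
    #: simulate intensity frames and reconstruct through the instrument
    through_instrument: bool = False
    frame_noise_sigma: float = 0.0
    screen: bool = True
    methods: tuple[str, ...] = ("polar",)
    classify: bool = True
    kn_all: int = classify.DEFAULT_KN["all"] if hasattr(classify, "DEFAULT_KN") else 8
    max_rows_per_cell: int | None = 2000

    def __post_init__(self) -> None:
        bad = set(self.methods) - {"polar", "symmetric", "differential"}
        if bad:
            raise ValueError(f"unknown decomposition methods: {sorted(bad)}")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a run report with per-stage timings, masked-pixel counts, the
    decomposition summaries, and (optionally) the classification report.
    """
    report: dict = {"config": {"seed": config.seed, "tol": config.tol,
                               "methods": list(config.methods),
                               "through_instrument": config.through_instrument},
                    "stages": {}}
    t0 = time.perf_counter()
    cfg = config.phantom
    records, manifest = phantom.generate_study(cfg)
    report["manifest"] = manifest
    report["stages"]["simulate"] = {"seconds": time.perf_counter() - t0,
                                    "n_regions": len(records)}

    if config.through_instrument:
        t0 = time.perf_counter()
        instr = acquisition.ideal_instrument()
        rng = np.random.default_rng((config.seed, 17))
        for rec in records:
            for wl, img in rec["images"].items():
                frames = acquisition.forward_measure(
                    img, instr, noise_sigma=config.frame_noise_sigma, rng=rng
                )
                rec["images"][wl] = MuellerImage(
                    acquisition.reconstruct(frames, instr).data,
                    wavelength=wl,
                    metadata=img.metadata,
                )
        report["stages"]["reconstruct"] = {"seconds": time.perf_counter() - t0}

    if config.screen:
        t0 = time.perf_counter()
        n_masked = 0
        n_total = 0
        for rec in records:
            for img in rec["images"].values():
                mask = realizability.realizability_mask(
                    img, tol=config.tol, reflectance=config.reflectance
                )
                n_masked += int((~mask).sum())
                n_total += mask.size
        report["stages"]["screen"] = {
            "seconds": time.perf_counter() - t0,
            "masked_fraction": n_masked / n_total,
        }
    else:
        report["stages"]["screen"] = {"skipped": True, "note": "unscreened"}

    summaries = {}
    if "polar" in config.methods or config.classify:
        t0 = time.perf_counter()
        table = phantom.extract_features(records, source="polar")
        summaries["polar"] = _summarize_study(records)
        report["stages"]["polar"] = {"seconds": time.perf_counter() - t0,
                                     "n_pixels": len(table)}
    if "symmetric" in config.methods:
        t0 = time.perf_counter()
        rec = records[0]
        summaries["symmetric"] = {
            wl: {k: float(np.nanmean(v)) for k, v in symmetric_maps(img).items()}
            for wl, img in rec["images"].items()
        }
        report["stages"]["symmetric"] = {"seconds": time.perf_counter() - t0}
    if "differential" in config.methods:
        t0 = time.perf_counter()
        rec = records[0]
        summaries["differential"] = {
            wl: differential.differential_table(img)
            for wl, img in rec["images"].items()
        }
        report["stages"]["differential"] = {"seconds": time.perf_counter() - t0}
    report["summaries"] = summaries

    if config.classify:
        t0 = time.perf_counter()
        balanced = classify.balance(
            table, seed=config.seed, max_per_cell=config.max_rows_per_cell
        )
        features = [
            feature_name(p, wl) for wl in cfg.wavelengths for p in ("delta", "R", "D")
        ]
        cv = classify.losocv_knn(balanced, features, kn=config.kn_all, model_tag="all")
        report["classification"] = {
            "n_rows": len(balanced),
            "test_accuracy": cv.mean_test_accuracy(),
            "train_fraction": cv.train_fraction,
            "summary": cv.summary().to_dict(orient="records"),
        }
        report["stages"]["classify"] = {"seconds": time.perf_counter() - t0}
    return report


def summarize_regions(
    maps: dict[str, np.ndarray],
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
    wavelength: float | None = None,
) -> pd.DataFrame:
    """Per-label statistics of scalar maps, honoring the validity mask.

    One row per (label, quantity): count, mean, median, 25th and 75th
    percentiles.  Labels fully excluded by the mask produce a count-0 row
    with NaN statistics.  Rows can be ordered downstream, e.g. by ascending
    75th percentile of retardance at the longest wavelength.
    """
    label_names = label_names or dict(phantom.LABEL_NAMES)
    mask = np.ones_like(labels, dtype=bool) if mask is None else mask
    rows = []
    for lab, name in label_names.items():
        sel = (labels == lab) & mask
        for qty, arr in maps.items():
            vals = arr[sel]
            vals = vals[np.isfinite(vals)]
            row = {"label": name, "quantity": qty, "count": int(vals.size)}
            if wavelength is not None:
                row["wavelength"] = wavelength
            if vals.size:
                row.update(
                    mean=float(vals.mean()),
                    median=float(np.median(vals)),
                    q25=float(np.percentile(vals, 25)),
                    q75=float(np.percentile(vals, 75)),
                )
            else:
                row.update(mean=np.nan, median=np.nan, q25=np.nan, q75=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def _summarize_study(records: list[dict]) -> pd.DataFrame:
    """Polar-map region summaries for every (region, wavelength)."""
    frames = []
    for rec in records:
        for wl, img in rec["images"].items():
            df = summarize_regions(
                polar_maps(img), rec["truth"].labels, img.mask, wavelength=wl
            )
            df.insert(0, "region", rec["region"])
            df.insert(0, "specimen", rec["specimen"])
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
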