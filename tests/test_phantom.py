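"""Synthetic phantom generator: trends, determinism, realizability, corruption."""
import numpy as np
import pytest

import muellermap as mm
from muellermap.acquisition import ideal_instrument
from muellermap.phantom import GM, WM, class_curve


@pytest.fixture(scope="module")
def small_cfg():
    return mm.PhantomConfig(shape=(32, 32), n_regions=2, n_specimens=2, seed=5)


def test_class_curves_follow_measured_trends():
    wls = mm.WAVELENGTHS_NM
    gm = [class_curve("delta", GM, w) for w in wls]
    wm = [class_curve("delta", WM, w) for w in wls]
    # endpoints and ordering
    assert gm[0] == pytest.approx(0.60) and gm[-1] == pytest.approx(0.88)
    assert 0.88 < wm[0] < 0.9 and 0.94 < wm[-1] < 0.95
    assert all(w > g for g, w in zip(gm, wm))
    # 550 nm dip: below the 500/590 trend line by the configured fractions
    for cls, frac in ((GM, 0.09), (WM, 0.02)):
        trend = 0.5 * (class_curve("delta", cls, 500) + class_curve("delta", cls, 590))
        trend_550 = np.interp(550, [500, 590], [class_curve("delta", cls, 500),
                                                class_curve("delta", cls, 590)])
        assert class_curve("delta", cls, 550) == pytest.approx(trend_550 * (1 - frac))
    # retardance doubles for GM, rises for WM
    assert class_curve("R", GM, 450) == pytest.approx(0.16)
    assert class_curve("R", GM, 680) == pytest.approx(0.32)
    assert class_curve("R", WM, 680) == pytest.approx(0.72)
    # diattenuation negligible, GM about half of WM
    for w in wls:
        assert class_curve("D", WM, w) < 0.04
        assert class_curve("D", GM, w) < 0.6 * class_curve("D", WM, w)


def test_phantom_geometry_and_truth(small_cfg):
    truth, images = mm.generate_phantom(small_cfg, 0, 0)
    assert set(np.unique(truth.labels)) <= {0, 1, 2, 3}
    assert (truth.labels == GM).sum() > (truth.labels == WM).sum() > 0
    assert set(images) == set(small_cfg.wavelengths)
    for wl, img in images.items():
        sel = truth.labels != 0
        for key in ("delta", "R", "D", "theta"):
            assert np.isfinite(truth.params[wl][key][sel]).all()


def test_noiseless_polar_recovery(small_cfg):
    """Decomposing clean cubes reproduces the stored truth to 1e-6."""
    truth, images = mm.generate_phantom(small_cfg, 0, 0)
    for wl in (450, 680):
        maps = mm.polar_maps(images[wl])
        sel = truth.labels != 0
        for key in ("delta", "R", "D"):
            assert np.nanmax(np.abs(maps[key][sel] - truth.params[wl][key][sel])) < 1e-6


def test_all_pixels_physically_realizable(small_cfg):
    _, images = mm.generate_phantom(small_cfg, 0, 0)
    for img in images.values():
        mask = mm.realizability_mask(img, tol=1e-5, reflectance=0.5)
        assert mask.all()


def test_phantom_determinism_and_specimen_effects():
    cfg = mm.PhantomConfig(shape=(24, 24), seed=9)
    t1, im1 = mm.generate_phantom(cfg, 0, 0)
    t2, im2 = mm.generate_phantom(cfg, 0, 0)
    assert np.array_equal(im1[450].data, im2[450].data)
    # different specimens: same geometry rng stream, different class factors
    _, im_other = mm.generate_phantom(cfg, 1, 0)
    assert not np.array_equal(im1[450].data, im_other[450].data)


def test_specimen_effect_magnitude():
    """Specimen-to-specimen spread of class means tracks the configured SD."""
    cfg = mm.PhantomConfig(shape=(48, 48), seed=2)
    means = []
    for sp in range(8):
        truth, images = mm.generate_phantom(cfg, sp, 0)
        sel = truth.labels == GM
        means.append(truth.params[450]["R"][sel].mean())
    cv = np.std(means) / np.mean(means)
    assert 0.05 < cv < 0.45   # R specimen factor sigma ~ 0.19 total


def test_generate_study_manifest():
    cfg = mm.PhantomConfig(shape=(16, 16), seed=1)
    records, manifest = mm.generate_study(cfg)
    assert manifest["n_cubes"] == 120
    assert manifest["n_frames"] == 3840
    assert len(records) == 20
    assert {r["specimen"] for r in records} == set(range(6))
    with pytest.raises(ValueError):
        mm.generate_study(mm.PhantomConfig(n_specimens=1))


def test_study_rerun_identical():
    cfg = mm.PhantomConfig(shape=(16, 16), n_regions=3, seed=4)
    r1, _ = mm.generate_study(cfg)
    r2, _ = mm.generate_study(cfg)
    for a, b in zip(r1, r2):
        assert np.array_equal(a["truth"].labels, b["truth"].labels)
        assert np.array_equal(a["images"][550].data, b["images"][550].data)


def test_extract_features_truth_matches_polar(small_cfg):
    records, _ = mm.generate_study(small_cfg)
    t_truth = mm.extract_features(records, source="truth")
    t_polar = mm.extract_features(records, source="polar")
    assert len(t_truth) == len(t_polar)
    col = mm.feature_name("delta", 450)
    assert np.abs(t_truth[col].to_numpy() - t_polar[col].to_numpy()).max() < 1e-6
    assert set(t_polar["class"].unique()) == {"GM", "WM"}


def test_corrupt_frames_identity_and_monotonicity(small_cfg):
    truth, images = mm.generate_phantom(small_cfg, 0, 0)
    instr = ideal_instrument()
    frames = mm.forward_measure(images[450], instr)
    clean = mm.corrupt_frames(frames, 0.0, 0.0)
    assert np.array_equal(clean.frames, frames.frames)
    rmse = []
    for sigma in (0.005, 0.01, 0.02):
        noisy = mm.corrupt_frames(frames, sigma_gauss=sigma, rng=3)
        rec = mm.reconstruct(noisy, instr)
        rmse.append(np.sqrt(np.mean((rec.data - images[450].data) ** 2)))
    assert rmse[0] < rmse[1] < rmse[2]


def test_specular_patches_fail_screen(small_cfg):
    """Saturated specular patches are caught by the realizability screen."""
    truth, images = mm.generate_phantom(small_cfg, 0, 0)
    instr = ideal_instrument()
    frames = mm.forward_measure(images[450], instr)
    corrupted = mm.corrupt_frames(frames, sigma_gauss=0.0, p_specular=0.05, rng=3)
    frac = corrupted.exposure["specular_fraction"]
    assert frac >= 0.04
    rec = mm.reconstruct(corrupted, instr)
    mask = mm.realizability_mask(rec, reflectance=0.5)
    masked_frac = 1.0 - mask.mean()
    assert masked_frac >= 0.75 * frac


def test_config_validation():
    with pytest.raises(ValueError):
        mm.PhantomConfig(dip={1: 1.5})
    with pytest.raises(ValueError):
        mm.PhantomConfig(n_regions=0)
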