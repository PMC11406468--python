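"""Forward polar (Lu-Chipman) decomposition, retarder split, axis map."""
import numpy as np
import pytest

import muellermap as mm


def _compose(a, b, c, delta, theta, D, axis):
    return (
        mm.diagonal_depolarizer(a, b, c)
        @ mm.linear_retarder(delta, theta)
        @ mm.linear_diattenuator(D, axis)
    )


def test_identity_and_ideal_depolarizer():
    res = mm.lu_chipman(np.eye(4))
    assert res.delta_total == pytest.approx(0.0, abs=1e-12)
    assert res.retardance == pytest.approx(0.0, abs=1e-6)
    assert res.diattenuation == pytest.approx(0.0, abs=1e-12)
    res = mm.lu_chipman(np.diag([1.0, 0, 0, 0]))
    assert res.delta_total == pytest.approx(1.0, abs=1e-12)


def test_half_wave_retarder_full_retardance():
    res = mm.lu_chipman(mm.linear_retarder(np.pi, 0.3))
    assert res.retardance == pytest.approx(np.pi, abs=1e-8)


def test_composition_recovery_grid():
    """Exact parameter recovery on a depolarizer*retarder*diattenuator grid."""
    for a in (0.1, 0.5, 0.9):
        for delta in (0.1, 1.5, 3.0):
            for D in (0.0, 0.45, 0.9):
                m = _compose(a, a * 0.9, a * 0.8, delta, 0.35, D, -0.2)
                res = mm.lu_chipman(m)
                assert abs(res.retardance - delta) < 1e-6
                assert abs(res.diattenuation - D) < 1e-6
                assert abs(res.delta_total - (1 - (a + a * 0.9 + a * 0.8) / 3)) < 1e-6
                recon = res.M_delta @ res.M_R @ res.M_D
                assert np.abs(recon - m).max() < 1e-8


def test_random_composition_residuals(rng):
    """1,000 random tuples: residual < 1e-8 and parameter errors < 1e-6."""
    worst_res, worst_par = 0.0, 0.0
    for _ in range(1000):
        abc = np.sort(rng.uniform(0.05, 0.95, 3))[::-1]
        delta = rng.uniform(0.05, 3.05)
        D = rng.uniform(0.0, 0.9)
        m = _compose(*abc, delta, rng.uniform(-1.5, 1.5), D, rng.uniform(-1.5, 1.5))
        res = mm.lu_chipman(m)
        worst_res = max(worst_res, np.abs(res.M_delta @ res.M_R @ res.M_D - m).max())
        worst_par = max(worst_par, abs(res.retardance - delta), abs(res.diattenuation - D))
    assert worst_res < 1e-8
    assert worst_par < 1e-6


def test_parameter_ranges_on_physical_ensemble(physical_ensemble):
    m = physical_ensemble / physical_ensemble[:, 0, 0][:, None, None]
    res = mm.lu_chipman(m)
    eps = 1e-9
    assert np.all(res.delta_total >= -eps) and np.all(res.delta_total <= 1 + eps)
    assert np.all(res.retardance >= 0) and np.all(res.retardance <= np.pi)
    assert np.all(res.diattenuation >= 0) and np.all(res.diattenuation <= 1 + eps)
    # retarder blocks stay orthogonal
    blocks = res.M_R[:, 1:, 1:]
    eye_err = np.abs(blocks @ np.swapaxes(blocks, -1, -2) - np.eye(3)).max()
    assert eye_err < 1e-8


def test_near_unit_diattenuation_flagged():
    res = mm.lu_chipman(mm.linear_diattenuator(1.0, 0.0))
    assert res.flags
    assert np.isfinite(res.M_delta).all() and np.isfinite(res.retardance)


@pytest.mark.parametrize(
    "MR,exp_delta,exp_psi",
    [
        (mm.rotator(0.3), 0.0, 0.3),
        (mm.linear_retarder(1.2, np.deg2rad(20)), 1.2, 0.0),
    ],
)
def test_retarder_split_pure_cases(MR, exp_delta, exp_psi):
    MLR, Mpsi, delta, psi = mm.retarder_split(MR)
    assert delta == pytest.approx(exp_delta, abs=1e-9)
    assert psi == pytest.approx(exp_psi, abs=1e-9)
    assert np.abs(MLR @ Mpsi - MR).max() < 1e-8


def test_retarder_split_recomposes(rng):
    for _ in range(100):
        MR = mm.linear_retarder(rng.uniform(0.05, 3.0), rng.uniform(-1.5, 1.5)) @ mm.rotator(
            rng.uniform(-0.7, 0.7)
        )
        MLR, Mpsi, _, _ = mm.retarder_split(MR)
        assert np.abs(MLR @ Mpsi - MR).max() < 1e-8
        # the linear factor is a linear retarder: symmetric upper 2x2 block
        assert abs(MLR[1, 2] - MLR[2, 1]) < 1e-8


def test_axis_recovery_dense_grid():
    """Half-angle arctangent recovers the factory axis to < 1e-8 rad."""
    thetas = np.deg2rad(np.arange(-89.0, 90.0, 1.0))
    for delta in (0.2, 1.0, 2.5):
        for theta in thetas:
            rec = mm.retardance_axis(mm.linear_retarder(delta, theta))
            assert abs(rec - theta) < 1e-8


def test_axis_quadrant_against_brute_force(rng):
    """Quadrant check against a brute-force axis search."""
    theta_true = np.deg2rad(-80.0)
    M = mm.linear_retarder(1.0, theta_true)
    grid = np.linspace(-np.pi / 2 + 1e-3, np.pi / 2, 3600)
    errs = [np.abs(mm.linear_retarder(1.0, t) - M).max() for t in grid]
    brute = grid[int(np.argmin(errs))]
    rec = mm.retardance_axis(M)
    assert abs(rec - brute) < 1e-3
    assert abs(rec - theta_true) < 1e-10


def test_axis_undefined_near_zero_retardance():
    assert np.isnan(mm.retardance_axis(np.eye(4)))


def test_polar_maps_honor_mask_and_recover_truth():
    truth, images = mm.generate_phantom(mm.PhantomConfig(shape=(24, 24), n_regions=1), 0, 0)
    img = images[450]
    img.mask[0, 0] = False
    maps = mm.polar_maps(img)
    assert np.isnan(maps["delta"][0, 0])
    sel = (truth.labels != 0) & img.mask
    for key in ("delta", "R", "D"):
        assert np.nanmax(np.abs(maps[key][sel] - truth.params[450][key][sel])) < 1e-6


def test_theta_map_matches_axis_field():
    """Spatially varying axis recovered to < 0.5 degree away from delta ~ 0."""
    truth, images = mm.generate_phantom(mm.PhantomConfig(shape=(24, 24), n_regions=1), 0, 0)
    img = images[550]
    maps = mm.polar_maps(img)
    sel = (truth.labels != 0) & (truth.params[550]["R"] > 0.05)
    err = np.nanmax(np.abs(maps["theta"][sel] - truth.params[550]["theta"][sel]))
    assert err < np.deg2rad(0.5)
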