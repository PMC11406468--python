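"""Matrix-logarithm decomposition: G-split, means, fluctuation statistics."""
import numpy as np
import pytest
from scipy.linalg import expm

import muellermap as mm
from muellermap.differential import LogUndefinedError, TABLE_ROWS
from muellermap.phantom import gaussian_fluctuation_medium


def _mc_medium(mean, cov, n, seed):
    """Gaussian-fluctuation oracle: closed-form averaged retarder ensemble."""
    return gaussian_fluctuation_medium(mean, cov, n, rng=seed)


def test_log_of_diagonal_depolarizer():
    L = mm.matrix_log(np.diag([1.0, 0.5, 0.5, 0.5]))
    assert np.allclose(L, np.diag([0, np.log(0.5), np.log(0.5), np.log(0.5)]), atol=1e-12)


def test_exp_log_round_trip(physical_ensemble):
    count = 0
    for M in physical_ensemble[:200]:
        m = M / M[0, 0]
        try:
            L = mm.matrix_log(m)
        except LogUndefinedError:
            continue
        count += 1
        assert np.abs(expm(L) - m).max() < 1e-9
    assert count > 150   # the log exists for the bulk of physical matrices


def test_log_undefined_on_negative_axis():
    with pytest.raises(LogUndefinedError):
        mm.matrix_log(np.diag([1.0, -0.5, 0.5, 0.5]))
    with pytest.raises(LogUndefinedError):
        mm.matrix_log(np.diag([1.0, 0.0, 0.5, 0.5]))


def test_g_split_definitions(rng):
    G = np.diag([1.0, -1, -1, -1])
    L = rng.normal(size=(4, 4))
    Lm, Lu = mm.g_split(L)
    assert np.abs(Lm + Lu - L).max() < 1e-14
    assert np.abs(G @ Lm.T @ G + Lm).max() < 1e-12   # G-antisymmetric
    assert np.abs(G @ Lu.T @ G - Lu).max() < 1e-12   # G-symmetric


def test_pure_retarder_means_and_zero_fluctuations():
    res = mm.differential_decompose(mm.linear_retarder(0.8, 0.0))
    assert res.means["LBH"] == pytest.approx(-0.8, abs=1e-10)
    for k in ("LB45", "CB", "LDH", "LD45", "CD"):
        assert res.means[k] == pytest.approx(0.0, abs=1e-10)
    for v in res.variances.values():
        assert abs(v) < 1e-10
    for c in res.covariances.values():
        assert abs(c) < 1e-10
    assert res.applicable


def test_rotator_and_diattenuator_means():
    res = mm.differential_decompose(mm.rotator(0.25))
    assert res.means["CB"] == pytest.approx(0.5, abs=1e-10)
    res = mm.differential_decompose(mm.linear_diattenuator(0.3, 0.0))
    assert abs(res.means["LDH"]) == pytest.approx(np.arctanh(0.3), abs=1e-10)


def test_isotropic_depolarizer_fluctuations():
    res = mm.differential_decompose(np.diag([1.0, 0.6, 0.6, 0.6]))
    vals = list(res.variances.values())
    assert np.allclose(vals, -np.log(0.6), atol=1e-10)
    assert all(v > 0 for v in vals)
    assert np.allclose(list(res.covariances.values()), 0.0, atol=1e-10)


def test_commuting_means_additive():
    A = mm.linear_retarder(0.5, 0.0)
    B = mm.linear_retarder(0.7, 0.0)   # same axis: logs commute
    mAB = mm.spectroscopic_means(mm.g_split(mm.matrix_log(A @ B))[0])
    mA = mm.spectroscopic_means(mm.g_split(mm.matrix_log(A))[0])
    mB = mm.spectroscopic_means(mm.g_split(mm.matrix_log(B))[0])
    for k in mAB:
        assert mAB[k] == pytest.approx(mA[k] + mB[k], abs=1e-9)


def test_gaussian_fluctuation_recovery():
    """Monte-Carlo medium: variances within 5% at 1e5 draws, means recovered."""
    mean = np.array([0.3, -0.1, 0.2])
    cov = np.diag([0.20, 0.10, 0.15])
    M = _mc_medium(mean, cov, 100_000, seed=11)
    res = mm.differential_decompose(M)
    assert res.applicable
    assert res.means["LBH"] == pytest.approx(mean[0], rel=0.05)
    assert res.means["LB45"] == pytest.approx(mean[1], rel=0.1, abs=0.02)
    assert res.means["CB"] == pytest.approx(mean[2], rel=0.05)
    assert res.variances["var_LH"] == pytest.approx(0.20, rel=0.05)
    assert res.variances["var_L45"] == pytest.approx(0.10, rel=0.05)
    assert res.variances["var_C"] == pytest.approx(0.15, rel=0.05)


def test_fluctuation_covariance_signs():
    cov = np.array([[0.20, 0.05, -0.03], [0.05, 0.10, 0.02], [-0.03, 0.02, 0.15]])
    M = _mc_medium(np.zeros(3), cov, 100_000, seed=3)
    res = mm.differential_decompose(M)
    assert res.covariances["cov_LH_L45"] == pytest.approx(0.05, rel=0.2)
    assert res.covariances["cov_LH_C"] == pytest.approx(-0.03, rel=0.3)
    assert res.covariances["cov_L45_C"] == pytest.approx(0.02, rel=0.3)


def test_variance_recovery_improves_with_draws():
    errs = []
    for n in (1_000, 10_000, 100_000):
        M = _mc_medium(np.zeros(3), np.diag([0.2, 0.2, 0.2]), n, seed=29)
        res = mm.differential_decompose(M)
        errs.append(abs(res.variances["var_LH"] - 0.2))
    assert errs[2] < errs[0]


def test_applicability():
    assert mm.applicability(mm.matrix_log(np.diag([1.0, 0.7, 0.6, 0.5])))
    assert mm.applicability(mm.matrix_log(mm.linear_retarder(0.9, 0.1)))
    # manufactured negative fluctuation: G-symmetric part with a positive
    # diagonal entry acts like a negative variance
    L = np.diag([0.0, 0.4, -0.1, -0.1])
    assert not mm.applicability(L)


def test_table_row_order():
    res = mm.differential_decompose(np.diag([1.0, 0.7, 0.6, 0.5]))
    assert tuple(res.table_row().keys()) == TABLE_ROWS


def test_differential_maps_counts_undefined():
    data = np.tile(np.diag([1.0, 0.7, 0.6, 0.5]), (3, 3, 1, 1))
    data[0, 0] = np.diag([1.0, -0.5, 0.5, 0.5])   # log-undefined pixel
    img = mm.MuellerImage(data, wavelength=550)
    maps, n_undef = mm.differential_maps(img)
    assert n_undef == 1
    assert np.isnan(maps["var_LH"][0, 0])
    assert np.isfinite(maps["var_LH"][1, 1])
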