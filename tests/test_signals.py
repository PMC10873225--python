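"""Forward signal models: closed forms, the two-pool fixed point, and its oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mtdti.signals import (
    DiffusionTensor,
    QmtParams,
    RestrictedPoolConstants,
    SequenceSpec,
    SignalModelError,
    bssfp_signal,
    dwi_signal,
    mt_bssfp_period_map,
    mt_bssfp_signal,
    mt_bssfp_steady_state,
    saturation_rate,
    spgr_signal,
)

NAWM = dict(F=0.157, kf=4.45, T1=0.779, T2=0.045, M0=1.0)
CONST = RestrictedPoolConstants()


# ---------------------------------------------------------------------------
# closed forms against frozen high-precision evaluations
# ---------------------------------------------------------------------------


def test_spgr_limits_and_value():
    assert spgr_signal(1.0, 0.779, 0.0, 0.01) == 0.0
    # TR >> T1: approaches M0 sin(alpha)
    a = np.deg2rad(17)
    assert spgr_signal(2.0, 0.01, a, 10.0) == pytest.approx(2 * np.sin(a), rel=1e-12)
    # frozen 40-digit evaluation of the Ernst equation
    assert spgr_signal(1.0, 0.779, a, 0.01) == pytest.approx(0.0667201718024115264, abs=1e-15)


def test_spgr_domain_errors():
    with pytest.raises(SignalModelError):
        spgr_signal(1.0, -0.5, 0.1, 0.01)
    with pytest.raises(SignalModelError):
        spgr_signal(1.0, 0.5, 0.1, 0.0)


def test_bssfp_limits_and_value():
    assert bssfp_signal(1.0, 0.779, 0.045, 0.0, 0.003) == 0.0
    E1, E2 = np.exp(-0.003 / 0.779), np.exp(-0.003 / 0.045)
    assert bssfp_signal(1.0, 0.779, 0.045, np.pi / 2, 0.003) == pytest.approx(
        (1 - E1) / (1 - E1 * E2), rel=1e-12
    )
    assert bssfp_signal(1.0, 0.779, 0.045, np.deg2rad(35), 0.003) == pytest.approx(
        0.119767100575795747, rel=1e-12
    )


def test_bssfp_rejects_t2_above_t1():
    with pytest.raises(SignalModelError):
        bssfp_signal(1.0, 0.5, 0.8, 0.3, 0.003)


def test_saturation_rate():
    assert saturation_rate(0.0, 1e-4, 1.4e-5) == 0.0
    # inverse-square scaling with pulse duration
    w1 = saturation_rate(0.6, 1e-4, 1.4e-5)
    assert saturation_rate(0.6, 2e-4, 1.4e-5) == pytest.approx(w1 / 4, rel=1e-12)
    assert saturation_rate(np.deg2rad(35), 1.2e-4, 1.4e-5) == pytest.approx(
        1139.74118027079457, rel=1e-14
    )
    with pytest.raises(SignalModelError):
        saturation_rate(0.6, 0.0, 1.4e-5)


def test_dwi_signal():
    iso = DiffusionTensor(7e-4, 7e-4, 7e-4, S0=2.0)
    assert dwi_signal(iso, 0.0) == pytest.approx(2.0)
    # rotation invariance for isotropic D
    rng = np.random.default_rng(0)
    for _ in range(5):
        g = rng.standard_normal(3)
        g /= np.linalg.norm(g)
        assert dwi_signal(iso, 900.0, g) == pytest.approx(2.0 * np.exp(-900 * 7e-4), rel=1e-12)
    aniso = DiffusionTensor(1.7e-3, 3e-4, 3e-4, S0=1.0)
    assert dwi_signal(aniso, 900.0, (1.0, 0.0, 0.0)) == pytest.approx(
        0.216535667316007062, abs=1e-15
    )
    with pytest.raises(SignalModelError):
        dwi_signal(aniso, 900.0, (1.0, 1.0, 0.0))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def test_qmt_params_invariants():
    p = QmtParams(**NAWM)
    assert p.kr == pytest.approx(4.45 / 0.157)
    assert QmtParams(0.0, 0.0, 1.0, 0.1).kr == 0.0
    with pytest.raises(SignalModelError):
        QmtParams(F=0.1, kf=3.0, T1=0.5, T2=0.8)
    with pytest.raises(SignalModelError):
        QmtParams(F=-0.1, kf=3.0, T1=0.8, T2=0.05)


def test_sequence_spec_invariants():
    SequenceSpec("MT_BSSFP", alpha_nominal=35, TR=3.93e-3, TRF=1.5e-3)
    with pytest.raises(SignalModelError):
        SequenceSpec("MT_BSSFP", alpha_nominal=35, TR=1e-3, TRF=1.5e-3)
    with pytest.raises(SignalModelError):
        SequenceSpec("XYZ", alpha_nominal=10, TR=1e-2)
    with pytest.raises(SignalModelError):
        SequenceSpec("DWI", bval=900.0, bvec=(1.0, 1.0, 0.0))


# ---------------------------------------------------------------------------
# two-pool fixed point
# ---------------------------------------------------------------------------


def _random_param_sets(n, rng):
    F = rng.uniform(0.02, 0.35, n)
    kf = rng.uniform(0.5, 15.0, n)
    T1 = rng.uniform(0.3, 2.5, n)
    T2 = T1 * rng.uniform(0.02, 0.4, n)
    alpha = np.deg2rad(rng.uniform(5, 45, n))
    TR = rng.uniform(2.5e-3, 6e-3, n)
    TRF = TR * rng.uniform(0.03, 0.5, n)
    return F, kf, T1, T2, alpha, TR, TRF


def test_single_pool_collapse():
    """With an empty restricted pool the two-pool model is exactly bSSFP."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        T1 = rng.uniform(0.3, 3.0)
        T2 = T1 * rng.uniform(0.02, 0.9)
        alpha = np.deg2rad(rng.uniform(3, 60))
        TR = rng.uniform(2e-3, 8e-3)
        s2 = mt_bssfp_signal(0.0, 0.0, T1, T2, 1.0, alpha, TR, TR * 0.1)
        s1 = bssfp_signal(1.0, T1, T2, alpha, TR)
        assert abs(s2 - s1) < 1e-10


def test_fixed_point_residual():
    """Applying the period map once must leave the returned state unchanged."""
    rng = np.random.default_rng(2)
    F, kf, T1, T2, alpha, TR, TRF = _random_param_sets(50, rng)
    m = mt_bssfp_steady_state(F, kf, T1, T2, 1.0, alpha, TR, TRF)
    P, q = mt_bssfp_period_map(F, kf, T1, T2, 1.0, alpha, TR, TRF)
    resid = np.einsum("...ij,...j->...i", P, m) + q - m
    assert np.max(np.abs(resid)) < 1e-10


def test_long_run_iteration_oracle():
    """Fixed point agrees with long-run iteration of the period map.

    The affine map is iterated by repeated squaring,
    (P, q) -> (P^2, Pq + q), i.e. 2^40 periods from a cold start —
    far beyond any physical steady-state approach time — without ever
    using the fixed-point linear solve.
    """
    rng = np.random.default_rng(3)
    F, kf, T1, T2, alpha, TR, TRF = _random_param_sets(100, rng)
    s = mt_bssfp_signal(F, kf, T1, T2, 1.0, alpha, TR, TRF)
    P, q = mt_bssfp_period_map(F, kf, T1, T2, 1.0, alpha, TR, TRF)
    for _ in range(40):
        q = np.einsum("...ij,...j->...i", P, q) + q
        P = np.einsum("...ij,...jk->...ik", P, P)
    m = np.stack([np.zeros_like(F), np.ones_like(F), F], axis=-1)
    m = np.einsum("...ij,...j->...i", P, m) + q
    assert np.max(np.abs(s - m[..., 0]) / np.abs(m[..., 0])) < 1e-6


def test_bloch_mcconnell_integration_oracle():
    """Brute-force ODE integration of the relaxation–exchange evolution,
    with discrete RF rotation/saturation events, reaches the same steady state."""
    p = QmtParams(**NAWM)
    alpha, TRF = np.deg2rad(35), 1.2e-4
    TR = 2.55e-3
    W = float(saturation_rate(alpha, TRF, CONST.G0))
    kr = p.kr

    def rhs(_, y):
        my, mzf, mzr = y
        return [
            -my / p.T2,
            (p.M0 - mzf) / p.T1 - p.kf * mzf + kr * mzr,
            (p.F * p.M0 - mzr) / CONST.T1r - kr * mzr + p.kf * mzf,
        ]

    ca, sa = np.cos(alpha), np.sin(alpha)
    y = np.array([0.0, p.M0, p.F * p.M0])
    for _ in range(2500):
        sol = solve_ivp(rhs, (0.0, TR), y, rtol=1e-10, atol=1e-12)
        my, mzf, mzr = sol.y[:, -1]
        my = -my  # alternating RF phase
        y = np.array([my * ca + mzf * sa, -my * sa + mzf * ca, mzr * np.exp(-W * TRF)])
    s = mt_bssfp_signal(p.F, p.kf, p.T1, p.T2, p.M0, alpha, TR, TRF)
    assert abs(s - y[0]) / abs(y[0]) < 1e-6


def test_monotone_in_trf_and_pool_size():
    """Longer, weaker pulses saturate less (signal rises with TRF); a larger
    restricted pool depresses the signal."""
    trfs = np.array([0.12, 0.227, 0.424, 0.8, 1.5]) * 1e-3
    s = mt_bssfp_signal(
        NAWM["F"], NAWM["kf"], NAWM["T1"], NAWM["T2"], 1.0, np.deg2rad(35), 3.93e-3, trfs
    )
    assert np.all(np.diff(s) > 0)
    # non-increasing in F over the physical white/gray-matter pool-size range
    # (holding kf fixed at F -> 0 sends kr -> inf, outside the model's domain)
    Fs = np.linspace(0.05, 0.5, 10)
    sF = mt_bssfp_signal(Fs, 4.45, 0.779, 0.045, 1.0, np.deg2rad(35), 3.93e-3, 1.2e-4)
    assert np.all(np.diff(sF) < 1e-12)


def test_homogeneous_in_m0():
    for fn in (
        lambda m: spgr_signal(m, 0.779, 0.3, 0.01),
        lambda m: bssfp_signal(m, 0.779, 0.045, 0.3, 0.003),
        lambda m: mt_bssfp_signal(0.157, 4.45, 0.779, 0.045, m, 0.5, 3e-3, 3e-4),
    ):
        assert fn(3.7) == pytest.approx(3.7 * fn(1.0), rel=1e-12)
    t = DiffusionTensor(1e-3, 1e-3, 1e-3, S0=5.0)
    t1 = DiffusionTensor(1e-3, 1e-3, 1e-3, S0=1.0)
    assert dwi_signal(t, 900.0, (0, 0, 1.0)) == pytest.approx(
        5.0 * dwi_signal(t1, 900.0, (0, 0, 1.0)), rel=1e-12
    )
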