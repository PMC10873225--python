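"""Voxel-wise two-pool parameter estimation and MTR computation.

The ten MT-weighted bSSFP scans (five pulse durations at 35 deg, five
flip angles at the shortest pulse) enter one joint bounded
nonlinear-least-squares fit for (F, kf, M0), with T1/T2 held fixed from
the relaxometry stage — mirroring the staged processing of the clinical
protocol.  MTR is formed from the extremal-pulse-duration pair at 35
deg, the pair with the largest MT dynamic range (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import least_squares

from .signals import RestrictedPoolConstants, SequenceSpec, mt_bssfp_signal

__all__ = [
    "QmtFitResult",
    "compute_mtr",
    "fit_two_pool",
    "map_volume",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
]

# bounds for (F, kf [1/s]); M0 bounded below by 0
DEFAULT_BOUNDS = ((0.0, 0.5), (0.0, 50.0))
DEFAULT_INIT = (0.1, 3.0)


@dataclass
class QmtFitResult:
    F: float
    kf: float
    M0: float
    residual: float  # root-mean-square misfit
    converged: bool
    iterations: int


def compute_mtr(S_ref, S_mt):
    """Magnetization transfer ratio in percent units: 100 (S_ref - S_mt)/S_ref.

    S_ref is the minimally saturating scan (longest RF pulse), S_mt the
    maximally saturating one.  Non-positive references give NaN.
    """
    S_ref = np.asarray(S_ref, dtype=float)
    S_mt = np.asarray(S_mt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = 100.0 * (S_ref - S_mt) / S_ref
    return np.where(S_ref > 0, mtr, np.nan)


def _model(theta, specs_arr, T1, T2, alpha_scale, constants):
    F, kf, M0 = theta
    alphas, TRs, TRFs = specs_arr
    return mt_bssfp_signal(F, kf, T1, T2, M0, alphas * alpha_scale, TRs, TRFs, constants)


def _specs_arrays(specs: Sequence[SequenceSpec]):
    alphas = np.array([s.alpha_rad for s in specs])
    TRs = np.array([s.TR for s in specs])
    TRFs = np.array([s.TRF for s in specs])
    return alphas, TRs, TRFs


def fit_two_pool(
    signals,
    specs: Sequence[SequenceSpec],
    T1: float,
    T2: float,
    alpha_scale: float = 1.0,
    init=DEFAULT_INIT,
    bounds=DEFAULT_BOUNDS,
    constants: RestrictedPoolConstants = RestrictedPoolConstants(),
) -> QmtFitResult:
    """Bounded trust-region least-squares fit of (F, kf, M0) to MT-bSSFP signals.

    Deterministic given the start point: (F, kf) from ``init`` and M0
    scaled from the maximum observed signal.
    """
    s = np.asarray(signals, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(s > 0)):
        return QmtFitResult(np.nan, np.nan, np.nan, np.nan, False, 0)
    if not (np.isfinite(T1) and np.isfinite(T2) and 0 < T2 <= T1):
        return QmtFitResult(np.nan, np.nan, np.nan, np.nan, False, 0)
    specs_arr = _specs_arrays(specs)
    # M0 start: max signal over the model's max response at the start point
    probe = _model((init[0], init[1], 1.0), specs_arr, T1, T2, alpha_scale, constants)
    m0_start = float(np.max(s) / np.max(probe))
    x0 = np.array([init[0], init[1], m0_start])
    lo = np.array([bounds[0][0], bounds[1][0], 1e-12])
    hi = np.array([bounds[0][1], bounds[1][1], np.inf])
    res = least_squares(
        lambda th: _model(th, specs_arr, T1, T2, alpha_scale, constants) - s,
        x0,
        bounds=(lo, hi),
        method="trf",
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return QmtFitResult(
        float(res.x[0]), float(res.x[1]), float(res.x[2]), rms, bool(res.success), int(res.nfev)
    )


def _fit_chunk(sig_chunk, specs, T1c, T2c, b1c, init, bounds, constants):
    out = np.full((sig_chunk.shape[0], 4), np.nan)
    conv = np.zeros(sig_chunk.shape[0], dtype=bool)
    for i in range(sig_chunk.shape[0]):
        r = fit_two_pool(
            sig_chunk[i], specs, T1c[i], T2c[i], b1c[i], init=init, bounds=bounds,
            constants=constants,
        )
        if r.converged:
            out[i] = (r.F, r.kf, r.M0, r.residual)
            conv[i] = True
    return out, conv


def map_volume(
    volumes,
    specs: Sequence[SequenceSpec],
    T1map,
    T2map,
    b1,
    mask,
    mtr_pair=None,
    n_workers: int = 1,
    init=DEFAULT_INIT,
    bounds=DEFAULT_BOUNDS,
    constants: RestrictedPoolConstants = RestrictedPoolConstants(),
):
    """Two-pool fit plus MTR over the masked voxels of co-registered volumes.

    ``volumes`` is a sequence of 3D arrays matching ``specs``.  Returns a
    dict of maps (F, kf, M0_qmt, MTR, residual) that are NaN outside the
    mask and at non-converged voxels, plus a bookkeeping dict.  The
    result is independent of ``n_workers``.
    """
    vols = [np.asarray(v, dtype=float) for v in volumes]
    shape = vols[0].shape
    for v, name in [(T1map, "T1"), (T2map, "T2"), (b1, "B1"), (mask, "mask")] + [
        (v, f"scan{i}") for i, v in enumerate(vols)
    ]:
        if np.asarray(v).shape != shape:
            raise ValueError(f"grid mismatch: {name} has shape {np.asarray(v).shape}, expected {shape}")
    if len(vols) != len(specs):
        raise ValueError(f"{len(vols)} volumes vs {len(specs)} specs")

    if mtr_pair is None:
        # extremal pulse durations at the maximum flip angle
        amax = max(s.alpha_nominal for s in specs)
        at_amax = [i for i, s in enumerate(specs) if s.alpha_nominal == amax]
        i_ref = max(at_amax, key=lambda i: specs[i].TRF)
        i_mt = min(at_amax, key=lambda i: specs[i].TRF)
    else:
        i_ref, i_mt = mtr_pair
    mtr = np.where(np.asarray(mask, dtype=bool), compute_mtr(vols[i_ref], vols[i_mt]), np.nan)

    sel = np.asarray(mask, dtype=bool)
    idx = np.where(sel.reshape(-1))[0]
    sig = np.stack([v.reshape(-1)[idx] for v in vols], axis=1)
    T1f = np.asarray(T1map, dtype=float).reshape(-1)[idx]
    T2f = np.asarray(T2map, dtype=float).reshape(-1)[idx]
    b1f = np.asarray(b1, dtype=float).reshape(-1)[idx]

    if n_workers <= 1 or idx.size < 2 * n_workers:
        out, conv = _fit_chunk(sig, specs, T1f, T2f, b1f, init, bounds, constants)
    else:
        splits = np.array_split(np.arange(idx.size), n_workers)
        parts = Parallel(n_jobs=n_workers)(
            delayed(_fit_chunk)(sig[s_], specs, T1f[s_], T2f[s_], b1f[s_], init, bounds, constants)
            for s_ in splits
        )
        out = np.concatenate([p[0] for p in parts])
        conv = np.concatenate([p[1] for p in parts])

    maps = {}
    for j, name in enumerate(("F", "kf", "M0_qmt", "residual")):
        m = np.full(np.prod(shape), np.nan)
        m[idx] = out[:, j]
        maps[name] = m.reshape(shape)
    maps["MTR"] = mtr
    info = {
        "n_fitted": int(conv.sum()),
        "n_masked": int(idx.size),
        "n_nonconverged": int(idx.size - conv.sum()),
        "mtr_pair": (int(i_ref), int(i_mt)),
    }
    return maps, info
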