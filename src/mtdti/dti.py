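"""Log-linear diffusion-tensor estimation and scalar metrics (FA/MD/AD/RD).

The tensor is fitted by ordinary least squares on log(S), the standard
deterministic approach; weighted LS is available behind a flag for users
who want noise-adaptive weighting.  Negative or zero signals are
excluded voxel-wise with a minimum-count guard, and non-positive-definite
fitted tensors are flagged rather than silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .signals import DiffusionTensor

__all__ = [
    "DtiError",
    "TensorFitResult",
    "default_directions",
    "design_matrix",
    "fit_tensor",
    "fit_tensor_volume",
    "tensor_metrics",
    "metrics_volume",
]


class DtiError(ValueError):
    pass


@dataclass
class TensorFitResult:
    tensor: DiffusionTensor
    ok: bool
    psd: bool  # positive semi-definite


def default_directions() -> np.ndarray:
    """The packaged electrostatic-repulsion 30-direction scheme (rows = unit xyz)."""
    with resources.files("mtdti.data").joinpath("directions30.txt").open("r") as fh:
        g = np.loadtxt(fh)
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def design_matrix(bvals, bvecs) -> np.ndarray:
    """Rows [-b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz, 1]
    mapping (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0) to log-signal."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    if g.shape != (b.size, 3):
        raise DtiError(f"bvecs shape {g.shape} does not match {b.size} bvals")
    gx, gy, gz = g.T
    return np.column_stack(
        [
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
            np.ones_like(b),
        ]
    )


def _check_scheme(bvals, bvecs):
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    if np.sum(b > 0) < 6 or np.sum(b == 0) < 1:
        raise DtiError("need >= 6 diffusion-weighted directions and >= 1 b0")
    nz = g[b > 0]
    if not np.allclose(np.linalg.norm(nz, axis=1), 1.0, atol=1e-6):
        raise DtiError("weighted gradient directions must be unit vectors")
    return b, g


def fit_tensor(signals, bvals, bvecs, min_count: int = 8) -> TensorFitResult:
    """OLS log-linear tensor fit of one voxel's signal vector."""
    b, g = _check_scheme(bvals, bvecs)
    s = np.asarray(signals, dtype=float)
    keep = np.isfinite(s) & (s > 0)
    if np.sum(keep) < min_count or np.sum(keep & (b > 0)) < 6:
        return TensorFitResult(DiffusionTensor(np.nan, np.nan, np.nan, S0=np.nan), False, False)
    X = design_matrix(b[keep], g[keep])
    if np.linalg.matrix_rank(X) < 7:
        return TensorFitResult(DiffusionTensor(np.nan, np.nan, np.nan, S0=np.nan), False, False)
    coef, *_ = np.linalg.lstsq(X, np.log(s[keep]), rcond=None)
    with np.errstate(over="ignore"):
        t = DiffusionTensor(*coef[:6], S0=float(np.exp(coef[6])))
    psd = bool(np.all(np.linalg.eigvalsh(t.matrix()) >= -1e-12))
    return TensorFitResult(t, True, psd)


def fit_tensor_volume(dwi4d, bvals, bvecs, mask=None):
    """Vectorized OLS tensor fit over a 4D volume (..., n_scans).

    Returns (coef maps stacked on last axis: Dxx..Dyz, S0; ok mask).
    Voxels containing any non-positive signal fall back to the per-voxel
    path with signal exclusion.
    """
    b, g = _check_scheme(bvals, bvecs)
    vol = np.asarray(dwi4d, dtype=float)
    if vol.shape[-1] != b.size:
        raise DtiError(f"last axis {vol.shape[-1]} != number of scans {b.size}")
    shape = vol.shape[:-1]
    flat = vol.reshape(-1, b.size)
    sel = np.ones(flat.shape[0], dtype=bool) if mask is None else np.asarray(mask).reshape(-1)
    X = design_matrix(b, g)
    pinv = np.linalg.pinv(X)
    coefs = np.full((flat.shape[0], 7), np.nan)
    ok = np.zeros(flat.shape[0], dtype=bool)
    clean = sel & np.all(flat > 0, axis=1) & np.all(np.isfinite(flat), axis=1)
    if np.any(clean):
        coefs[clean] = np.log(flat[clean]) @ pinv.T
        ok[clean] = True
    dirty = sel & ~clean
    for i in np.where(dirty)[0]:
        r = fit_tensor(flat[i], b, g)
        if r.ok:
            t = r.tensor
            log_s0 = np.log(t.S0) if t.S0 > 0 else -np.inf
            coefs[i] = [t.Dxx, t.Dyy, t.Dzz, t.Dxy, t.Dxz, t.Dyz, log_s0]
            ok[i] = True
    out = coefs.reshape(*shape, 7)
    with np.errstate(over="ignore"):
        out[..., 6] = np.exp(out[..., 6])
    return out, ok.reshape(shape)


def tensor_metrics(tensor_or_coefs):
    """FA, MD, AD, RD from a tensor (or stacked Dxx..Dyz component maps).

    Eigenvalues are sorted descending; MD = mean, AD = lambda1,
    RD = (lambda2 + lambda3)/2, FA = sqrt(3/2) ||lambda - MD|| / ||lambda||
    (0 for an all-zero tensor).  Returns a dict of arrays.
    """
    if isinstance(tensor_or_coefs, DiffusionTensor):
        comp = np.array(
            [
                tensor_or_coefs.Dxx,
                tensor_or_coefs.Dyy,
                tensor_or_coefs.Dzz,
                tensor_or_coefs.Dxy,
                tensor_or_coefs.Dxz,
                tensor_or_coefs.Dyz,
            ]
        )
    else:
        comp = np.asarray(tensor_or_coefs, dtype=float)
        comp = np.moveaxis(comp, -1, 0)[:6]
    Dxx, Dyy, Dzz, Dxy, Dxz, Dyz = comp
    M = np.zeros(Dxx.shape + (3, 3)) if Dxx.ndim else np.zeros((3, 3))
    M[..., 0, 0], M[..., 1, 1], M[..., 2, 2] = Dxx, Dyy, Dzz
    M[..., 0, 1] = M[..., 1, 0] = Dxy
    M[..., 0, 2] = M[..., 2, 0] = Dxz
    M[..., 1, 2] = M[..., 2, 1] = Dyz
    finite = np.all(np.isfinite(M), axis=(-2, -1))
    Msafe = np.where(finite[..., None, None], M, 0.0)
    lam = np.linalg.eigvalsh(Msafe)[..., ::-1]  # descending
    lam = np.where(finite[..., None], lam, np.nan)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    norm = np.sqrt(np.sum(lam**2, axis=-1))
    dev = np.sqrt(np.sum((lam - md[..., None]) ** 2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * dev / norm
    fa = np.where(norm > 0, fa, np.where(finite, 0.0, np.nan))
    return {"FA": fa, "MD": md, "AD": ad, "RD": rd, "lambda": lam}


def metrics_volume(coef_maps):
    """Scalar maps from the stacked component maps of :func:`fit_tensor_volume`."""
    return tensor_metrics(coef_maps)
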