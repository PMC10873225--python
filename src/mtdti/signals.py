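"""Steady-state MRI signal models.

Closed-form SPGR and balanced-SSFP expressions, the two-pool
(free water / macromolecular) MT-bSSFP steady state, and the
mono-exponential diffusion-tensor signal.  These functions are both the
engine of the synthetic cohort simulator and the model functions of the
voxel-wise fitters, so simulator and fitter are consistent by
construction.

Conventions
-----------
* times in seconds, flip angles in radians, diffusivities in mm^2/s;
* all functions broadcast over numpy arrays and are positively
  homogeneous in ``M0``/``S0``;
* the two-pool steady state is defined as the fixed point of the
  affine once-per-TR period map (see :func:`mt_bssfp_period_map`), not
  as a transcribed closed form.  A long-run iteration of the same map
  — or a brute-force Bloch–McConnell integration — serves as the
  independent oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "QmtParams",
    "RestrictedPoolConstants",
    "SequenceSpec",
    "DiffusionTensor",
    "SignalModelError",
    "FixedPointError",
    "spgr_signal",
    "bssfp_signal",
    "saturation_rate",
    "mt_bssfp_period_map",
    "mt_bssfp_steady_state",
    "mt_bssfp_signal",
    "dwi_signal",
]


class SignalModelError(ValueError):
    """Invalid physical parameter passed to a signal model."""


class FixedPointError(RuntimeError):
    """The period-map fixed point could not be solved (singular I - P)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QmtParams:
    """Per-voxel two-pool state.

    F     pool-size ratio (restricted/free equilibrium magnetization)
    kf    forward exchange rate free -> restricted, 1/s
    T1    free-pool longitudinal relaxation time, s
    T2    free-pool transverse relaxation time, s
    M0    equilibrium free-pool magnetization, arbitrary units
    """

    F: float
    kf: float
    T1: float
    T2: float
    M0: float = 1.0

    def __post_init__(self) -> None:
        if self.F < 0 or self.kf < 0:
            raise SignalModelError(f"F and kf must be >= 0, got F={self.F}, kf={self.kf}")
        if not (0 < self.T2 <= self.T1):
            raise SignalModelError(f"require 0 < T2 <= T1, got T1={self.T1}, T2={self.T2}")
        if self.M0 <= 0:
            raise SignalModelError(f"M0 must be > 0, got {self.M0}")

    @property
    def kr(self) -> float:
        """Reverse exchange rate kr = kf / F (0 when the restricted pool is absent)."""
        return self.kf / self.F if self.F > 0 else 0.0


@dataclass(frozen=True)
class RestrictedPoolConstants:
    """Constants of the restricted (macromolecular) pool, held fixed in fits.

    T1r          restricted-pool longitudinal relaxation time, s
    G0           absorption lineshape at zero offset, s (super-Lorentzian,
                 standard white-matter value at clinical field strengths)
    shape_factor RF pulse shape factor; 1.0 = hard-pulse equivalence
                 omega1 = alpha / TRF
    """

    T1r: float = 1.0
    G0: float = 1.4e-5
    shape_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.T1r <= 0 or self.G0 <= 0:
            raise SignalModelError("T1r and G0 must be strictly positive")


@dataclass(frozen=True)
class SequenceSpec:
    """One acquisition's knobs.

    kind is one of {"SPGR", "BSSFP", "MT_BSSFP", "DWI", "B1MAP"};
    alpha_nominal in degrees; TR and TRF in seconds; bval in s/mm^2.
    """

    kind: str
    alpha_nominal: float = 0.0
    TR: float = 0.0
    TRF: float = 0.0
    bval: float = 0.0
    bvec: Optional[tuple[float, float, float]] = None

    _KINDS = ("SPGR", "BSSFP", "MT_BSSFP", "DWI", "B1MAP")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise SignalModelError(f"unknown sequence kind {self.kind!r}")
        if self.kind != "DWI" and not (0 < self.alpha_nominal <= 90):
            raise SignalModelError(f"alpha_nominal must be in (0, 90], got {self.alpha_nominal}")
        if self.kind in ("SPGR", "BSSFP", "MT_BSSFP") and not (self.TR > self.TRF >= 0):
            raise SignalModelError(f"require TR > TRF >= 0, got TR={self.TR}, TRF={self.TRF}")
        if self.bval > 0:
            v = np.asarray(self.bvec, dtype=float)
            if v.shape != (3,) or not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise SignalModelError("bvec must be a unit 3-vector when bval > 0")

    @property
    def alpha_rad(self) -> float:
        return float(np.deg2rad(self.alpha_nominal))


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric diffusion tensor (mm^2/s) plus the non-weighted signal S0."""

    Dxx: float
    Dyy: float
    Dzz: float
    Dxy: float = 0.0
    Dxz: float = 0.0
    Dyz: float = 0.0
    S0: float = 1.0

    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.Dxx, self.Dxy, self.Dxz],
                [self.Dxy, self.Dyy, self.Dyz],
                [self.Dxz, self.Dyz, self.Dzz],
            ]
        )

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending (lambda1 >= lambda2 >= lambda3)."""
        return np.sort(np.linalg.eigvalsh(self.matrix()))[::-1]

    @classmethod
    def from_eigenvalues(
        cls, lambdas: tuple[float, float, float], R: Optional[np.ndarray] = None, S0: float = 1.0
    ) -> "DiffusionTensor":
        """Build a tensor with principal frame ``R`` (columns = eigenvectors)."""
        L = np.diag(lambdas)
        if R is not None:
            L = R @ L @ R.T
        return cls(L[0, 0], L[1, 1], L[2, 2], L[0, 1], L[0, 2], L[1, 2], S0=S0)


# ---------------------------------------------------------------------------
# closed-form single-pool models
# ---------------------------------------------------------------------------


def spgr_signal(M0, T1, alpha, TR):
    """Ideally spoiled gradient-echo steady state (Ernst equation).

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),  E1 = exp(-TR/T1).
    """
    M0, T1, alpha, TR = map(np.asarray, (M0, T1, alpha, TR))
    if np.any(T1 <= 0) or np.any(TR <= 0):
        raise SignalModelError("T1 and TR must be strictly positive")
    E1 = np.exp(-TR / T1)
    return M0 * np.sin(alpha) * (1.0 - E1) / (1.0 - E1 * np.cos(alpha))


def bssfp_signal(M0, T1, T2, alpha, TR):
    """On-resonance, alternating-phase balanced SSFP steady state.

    S = M0 sin(a) (1 - E1) / (1 - (E1 - E2) cos(a) - E1 E2).
    """
    M0, T1, T2, alpha, TR = map(np.asarray, (M0, T1, T2, alpha, TR))
    if np.any(T1 <= 0) or np.any(T2 <= 0) or np.any(TR <= 0):
        raise SignalModelError("T1, T2 and TR must be strictly positive")
    if np.any(T2 > T1):
        raise SignalModelError("require T2 <= T1")
    E1 = np.exp(-TR / T1)
    E2 = np.exp(-TR / T2)
    return M0 * np.sin(alpha) * (1.0 - E1) / (1.0 - (E1 - E2) * np.cos(alpha) - E1 * E2)


def saturation_rate(alpha, TRF, G0, shape_factor: float = 1.0):
    """Mean restricted-pool saturation rate of a hard-pulse-equivalent RF pulse.

    W = pi * (shape_factor * alpha / TRF)^2 * G0  [1/s], with the pulse
    amplitude omega1 = alpha / TRF.  Longer pulses at fixed flip angle
    saturate less (W ~ TRF^-2).
    """
    alpha, TRF, G0 = map(np.asarray, (alpha, TRF, G0))
    if np.any(TRF <= 0):
        raise SignalModelError("TRF must be strictly positive")
    omega1 = shape_factor * alpha / TRF
    return np.pi * omega1**2 * G0


# ---------------------------------------------------------------------------
# two-pool MT-bSSFP
# ---------------------------------------------------------------------------


def _expm2(a, b, c, d, t):
    """exp(t*A) for a stack of real 2x2 matrices [[a, b], [c, d]].

    Assumes b*c >= 0 (our exchange matrices), hence real eigenvalues.
    Returns the four entries of the exponential.
    """
    tr = a + d
    disc = (a - d) ** 2 + 4.0 * b * c
    delta = np.sqrt(np.maximum(disc, 0.0))
    l1 = 0.5 * (tr + delta)
    l2 = 0.5 * (tr - delta)
    e1 = np.exp(l1 * t)
    e2 = np.exp(l2 * t)
    # Lagrange form expm = (e1 (A - l2 I) - e2 (A - l1 I)) / (l1 - l2);
    # series fallback when the eigenvalues coincide.
    small = delta < 1e-12
    safe = np.where(small, 1.0, delta)
    w1 = np.where(small, 0.0, (e1 - e2) / safe)  # coefficient of A
    w0 = np.where(small, 0.0, (l1 * e2 - l2 * e1) / safe)  # coefficient of I
    # degenerate: exp(tA) = e^{l t} (I + t (A - l I))
    el = np.exp(0.5 * tr * t)
    w1_d = el * t
    w0_d = el * (1.0 - 0.5 * tr * t)
    w1 = np.where(small, w1_d, w1)
    w0 = np.where(small, w0_d, w0)
    return w1 * a + w0, w1 * b, w1 * c, w1 * d + w0


def mt_bssfp_period_map(
    F,
    kf,
    T1,
    T2,
    M0,
    alpha,
    TR,
    TRF,
    constants: RestrictedPoolConstants = RestrictedPoolConstants(),
):
    """Affine once-per-TR map m -> P m + q of the two-pool MT-bSSFP sequence.

    The state is m = (My_f, Mz_f, Mz_r) taken immediately after the RF
    pulse.  One period consists of

    1. relaxation–exchange evolution over TR: the free transverse
       component decays by E2 = exp(-TR/T2); the longitudinal pair
       (Mz_f, Mz_r) evolves under

           dMz_f/dt = (M0 - Mz_f)/T1  - kf Mz_f + kr Mz_r
           dMz_r/dt = (F M0 - Mz_r)/T1r - kr Mz_r + kf Mz_f,

       with kr = kf/F (0 when F = 0), solved exactly via the 2x2
       matrix exponential;
    2. the alternating RF phase (My_f -> -My_f);
    3. the RF pulse: an instantaneous rotation of the free pool by
       alpha, while the restricted longitudinal magnetization is
       attenuated by exp(-W TRF) with W from :func:`saturation_rate`.

    Returns ``(P, q)`` with shapes (..., 3, 3) and (..., 3).
    """
    F, kf, T1, T2, M0, alpha, TR, TRF = np.broadcast_arrays(
        *map(np.asarray, (F, kf, T1, T2, M0, alpha, TR, TRF))
    )
    F = F.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        kr = np.where(F > 0, kf / np.where(F > 0, F, 1.0), 0.0)
    a = -1.0 / T1 - kf
    b = kr
    c = np.asarray(kf, dtype=float)
    d = -1.0 / constants.T1r - kr
    p11, p12, p21, p22 = _expm2(a, b, c, d, TR)
    # psi = A^{-1} (Phi - I) beta, beta = (M0/T1, F M0/T1r)
    beta1 = M0 / T1
    beta2 = F * M0 / constants.T1r
    u1 = (p11 - 1.0) * beta1 + p12 * beta2
    u2 = p21 * beta1 + (p22 - 1.0) * beta2
    detA = a * d - b * c
    psi1 = (d * u1 - b * u2) / detA
    psi2 = (-c * u1 + a * u2) / detA

    E2 = np.exp(-TR / T2)
    W = saturation_rate(alpha, TRF, constants.G0, constants.shape_factor)
    fW = np.exp(-W * TRF)
    ca, sa = np.cos(alpha), np.sin(alpha)

    zeros = np.zeros_like(ca)
    P = np.stack(
        [
            np.stack([-ca * E2, sa * p11, sa * p12], axis=-1),
            np.stack([sa * E2, ca * p11, ca * p12], axis=-1),
            np.stack([zeros, fW * p21, fW * p22], axis=-1),
        ],
        axis=-2,
    )
    q = np.stack([sa * psi1, ca * psi1, fW * psi2], axis=-1)
    return P, q


def mt_bssfp_steady_state(
    F,
    kf,
    T1,
    T2,
    M0,
    alpha,
    TR,
    TRF,
    constants: RestrictedPoolConstants = RestrictedPoolConstants(),
):
    """Fixed point m* = (I - P)^{-1} q of the period map (state after RF)."""
    P, q = mt_bssfp_period_map(F, kf, T1, T2, M0, alpha, TR, TRF, constants)
    A = np.eye(3) - P
    # Cramer's rule on the 3x3 stack: cheap and fully vectorized.
    a00, a01, a02 = A[..., 0, 0], A[..., 0, 1], A[..., 0, 2]
    a10, a11, a12 = A[..., 1, 0], A[..., 1, 1], A[..., 1, 2]
    a20, a21, a22 = A[..., 2, 0], A[..., 2, 1], A[..., 2, 2]
    c00 = a11 * a22 - a12 * a21
    c01 = a12 * a20 - a10 * a22
    c02 = a10 * a21 - a11 * a20
    det = a00 * c00 + a01 * c01 + a02 * c02
    if np.any(~np.isfinite(det)) or np.any(np.abs(det) < 1e-300):
        bad = int(np.sum(~np.isfinite(det) | (np.abs(det) < 1e-300)))
        raise FixedPointError(
            f"singular period map (I - P) in {bad} element(s); "
            "check parameter ranges (T1, T2, TR must be positive and finite)"
        )
    c10 = a02 * a21 - a01 * a22
    c11 = a00 * a22 - a02 * a20
    c12 = a01 * a20 - a00 * a21
    c20 = a01 * a12 - a02 * a11
    c21 = a02 * a10 - a00 * a12
    c22 = a00 * a11 - a01 * a10
    q0, q1, q2 = q[..., 0], q[..., 1], q[..., 2]
    m0 = (c00 * q0 + c10 * q1 + c20 * q2) / det
    m1 = (c01 * q0 + c11 * q1 + c21 * q2) / det
    m2 = (c02 * q0 + c12 * q1 + c22 * q2) / det
    return np.stack([m0, m1, m2], axis=-1)


def mt_bssfp_signal(
    F,
    kf,
    T1,
    T2,
    M0,
    alpha,
    TR,
    TRF,
    constants: RestrictedPoolConstants = RestrictedPoolConstants(),
):
    """Steady-state transverse free-pool signal of the two-pool MT-bSSFP model.

    Collapses to :func:`bssfp_signal` when F = kf = 0.
    """
    return mt_bssfp_steady_state(F, kf, T1, T2, M0, alpha, TR, TRF, constants)[..., 0]


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


def dwi_signal(tensor: DiffusionTensor, bval, bvec=None):
    """Mono-exponential diffusion signal S0 exp(-b g^T D g)."""
    bval = np.asarray(bval, dtype=float)
    if np.any(bval > 0):
        g = np.asarray(bvec, dtype=float)
        if g.shape[-1] != 3:
            raise SignalModelError("bvec must have 3 components")
        norms = np.linalg.norm(g, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise SignalModelError("bvec must be unit-norm when bval > 0")
        D = tensor.matrix()
        adc = np.einsum("...i,ij,...j->...", g, D, g)
    else:
        adc = np.zeros_like(bval)
    return tensor.S0 * np.exp(-bval * adc)
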