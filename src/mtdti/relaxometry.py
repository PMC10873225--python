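"""B1 correction and closed-form DESPOT1/DESPOT2 relaxometry.

The acquisition protocol measures exactly two SPGR flip angles (T1) and
two bSSFP flip angles (T2), so both fits are exact two-point linearized
inversions rather than regressions.  Voxels whose linearized slope falls
outside the physically admissible interval are marked unfittable (NaN)
and counted — never silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RelaxometryError",
    "FitMaps",
    "effective_alpha",
    "despot1_fit",
    "despot2_fit",
    "PLAUSIBLE_T1_RANGE",
    "PLAUSIBLE_T2_RANGE",
]

# raw values are reported untouched; these ranges only drive the
# `implausible` audit flag
PLAUSIBLE_T1_RANGE = (0.05, 10.0)
PLAUSIBLE_T2_RANGE = (0.005, 5.0)


class RelaxometryError(ValueError):
    pass


@dataclass
class FitMaps:
    """Result of a voxel-wise closed-form fit.

    value / m0 carry NaN exactly where the voxel was unfittable.
    """

    value: np.ndarray
    m0: np.ndarray
    valid: np.ndarray
    n_unfittable: int
    n_implausible: int


def effective_alpha(nominal_deg: float, b1) -> np.ndarray:
    """Effective flip angle map in radians: alpha_eff = nominal * relative B1.

    Non-positive B1 voxels are returned as NaN so that downstream fits
    exclude them.
    """
    b1 = np.asarray(b1, dtype=float)
    alpha = np.deg2rad(nominal_deg) * b1
    return np.where(b1 > 0, alpha, np.nan)


def _two_point_slope(S1, S2, a1, a2):
    """Common DESPOT linearization y = slope * x + intercept with
    y_i = S_i/sin(a_i), x_i = S_i/tan(a_i)."""
    y1, y2 = S1 / np.sin(a1), S2 / np.sin(a2)
    x1, x2 = S1 / np.tan(a1), S2 / np.tan(a2)
    dx = x2 - x1
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (y2 - y1) / dx
        intercept = y1 - slope * x1
    return slope, intercept, dx


def despot1_fit(S1, S2, alpha1, alpha2, TR: float) -> FitMaps:
    """Two-point DESPOT1: (T1, M0) from two SPGR signals.

    The linearized slope equals E1 = exp(-TR/T1); voxels with
    slope outside (0, 1) are unfittable.
    """
    S1, S2, alpha1, alpha2 = np.broadcast_arrays(
        *map(lambda x: np.asarray(x, dtype=float), (S1, S2, alpha1, alpha2))
    )
    if TR <= 0:
        raise RelaxometryError("TR must be positive")
    if np.all(np.isclose(alpha1, alpha2)):
        raise RelaxometryError("DESPOT1 needs two distinct flip angles")
    slope, intercept, dx = _two_point_slope(S1, S2, alpha1, alpha2)
    valid = (
        np.isfinite(slope)
        & (slope > 0)
        & (slope < 1)
        & (np.abs(dx) > 0)
        & np.isfinite(S1)
        & np.isfinite(S2)
        & (S1 > 0)
        & (S2 > 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        T1 = np.where(valid, -TR / np.log(np.where(valid, slope, 0.5)), np.nan)
        M0 = np.where(valid, intercept / (1.0 - np.where(valid, slope, 0.5)), np.nan)
    n_bad = int(np.sum(~valid))
    n_impl = int(np.sum(valid & ((T1 < PLAUSIBLE_T1_RANGE[0]) | (T1 > PLAUSIBLE_T1_RANGE[1]))))
    return FitMaps(T1, M0, valid, n_bad, n_impl)


def despot2_fit(S1, S2, alpha1, alpha2, TR: float, T1) -> FitMaps:
    """Two-point DESPOT2: (T2, M0) from two bSSFP signals given T1.

    The linearized slope is (E1 - E2)/(1 - E1 E2); solving for
    E2 = (E1 - slope)/(1 - slope E1) and T2 = -TR/ln(E2).
    Voxels with E2 outside (0, 1) are unfittable.
    """
    S1, S2, alpha1, alpha2, T1 = np.broadcast_arrays(
        *map(lambda x: np.asarray(x, dtype=float), (S1, S2, alpha1, alpha2, T1))
    )
    if TR <= 0:
        raise RelaxometryError("TR must be positive")
    if np.all(np.isclose(alpha1, alpha2)):
        raise RelaxometryError("DESPOT2 needs two distinct flip angles")
    slope, intercept, dx = _two_point_slope(S1, S2, alpha1, alpha2)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        E1 = np.exp(-TR / T1)
        E2 = (E1 - slope) / (1.0 - slope * E1)
    valid = (
        np.isfinite(E2)
        & (E2 > 0)
        & (E2 <= E1)  # T2 <= T1
        & (E2 < 1)
        & (np.abs(dx) > 0)
        & np.isfinite(S1)
        & np.isfinite(S2)
        & (S1 > 0)
        & (S2 > 0)
        & np.isfinite(T1)
        & (T1 > 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        T2 = np.where(valid, -TR / np.log(np.where(valid, E2, 0.5)), np.nan)
        M0 = np.where(
            valid,
            intercept * (1.0 - E1 * np.where(valid, E2, 0.5)) / (1.0 - E1),
            np.nan,
        )
    n_bad = int(np.sum(~valid))
    n_impl = int(np.sum(valid & ((T2 < PLAUSIBLE_T2_RANGE[0]) | (T2 > PLAUSIBLE_T2_RANGE[1]))))
    return FitMaps(T2, M0, valid, n_bad, n_impl)
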