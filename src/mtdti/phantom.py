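"""Synthetic longitudinal multi-contrast cohort with appearing lesions.

The generator produces, for every subject and examination month,
voxel-wise ground-truth parameter maps (two-pool qMT parameters on the
MT grid, diffusion-tensor eigenvalues on the coarser DWI grid), binary
lesion/contralateral analysis masks, a smooth transmit-field (B1) map,
and — via :func:`simulate_acquisition` — the acquired signal volumes of
the full protocol with additive noise.

Lesion biology is encoded as *trajectory anchor tables*: per metric, the
relative difference (%) to contralateral normal-appearing white matter
as a piecewise-linear function of the month relative to the lesion's
appearance on conventional imaging, together with a between-lesion SD
per anchor.  Each lesion draws a single shared "severity" deviate so
that all of its metric trajectories move coherently.  qMT trajectories
(F, kf, T1, T2) and the DTI pair (FA, RD) are imposed on the truth
maps; MTR, MD and AD are emergent quantities of the forward models and
the eigenvalue solution, checked as outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import (
    EFFECT_DIRECTION,
    Anchor,
    PhantomConfig,
    PipelineConfig,
    TissueParams,
    anchor_sd,
)
from .dti import default_directions
from .signals import RestrictedPoolConstants, bssfp_signal, mt_bssfp_signal, spgr_signal

__all__ = [
    "PhantomError",
    "LesionTrajectory",
    "Lesion",
    "SubjectPhantom",
    "Cohort",
    "lesion_effect",
    "build_phantom",
    "simulate_acquisition",
    "mt_affine",
    "dwi_affine",
]

LABELS = {"BG": 0, "NAWM": 1, "GM": 2, "CSF": 3}


class PhantomError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


class LesionTrajectory:
    """Piecewise-linear interpolation of per-metric anchor tables.

    Anchors hold (relative month, mean %, CI half-width %, n); the
    implied between-lesion SD is derived per anchor.  Relative months at
    or before -12 are normal tissue (0% by construction); months beyond
    the last anchor hold its value.
    """

    def __init__(self, anchors: Dict[str, List[Anchor]]):
        self._months: Dict[str, np.ndarray] = {}
        self._means: Dict[str, np.ndarray] = {}
        self._sds: Dict[str, np.ndarray] = {}
        for metric, rows in anchors.items():
            rows = sorted(rows)
            m = np.array([r[0] for r in rows], dtype=float)
            self._months[metric] = m
            self._means[metric] = np.array([r[1] for r in rows], dtype=float)
            self._sds[metric] = np.array([anchor_sd(r[1], r[2], r[3]) for r in rows])

    @property
    def metrics(self) -> List[str]:
        return list(self._months)

    def _interp(self, table, metric, rel_month):
        if metric not in self._months:
            raise KeyError(f"unknown metric {metric!r}")
        m = self._months[metric]
        rel = np.asarray(rel_month, dtype=float)
        out = np.interp(rel, m, table[metric])
        return np.where(rel <= -12.0, 0.0, out)

    def mean(self, metric: str, rel_month):
        """Mean relative difference (%) vs contralateral NAWM."""
        return self._interp(self._means, metric, rel_month)

    def sd(self, metric: str, rel_month):
        """Between-lesion SD (%) implied by the printed CIs."""
        return self._interp(self._sds, metric, rel_month)

    def effect(self, metric: str, rel_month, z: float = 0.0):
        """Per-lesion relative difference: mean + z * sd * canonical direction."""
        return self.mean(metric, rel_month) + z * self.sd(metric, rel_month) * EFFECT_DIRECTION[metric]


def lesion_effect(trajectory: LesionTrajectory, metric: str, rel_month):
    """Mean relative difference (%) of ``metric`` at ``rel_month`` (exact at anchors)."""
    return float(trajectory.mean(metric, rel_month))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def mt_affine(cfg: PhantomConfig) -> np.ndarray:
    """RAS affine of the MT grid, world origin at the volume centre."""
    a = np.diag([cfg.voxel_mm] * 3 + [1.0])
    a[:3, 3] = -(np.array(cfg.grid_shape) - 1) / 2.0 * cfg.voxel_mm
    return a


def dwi_affine(cfg: PhantomConfig) -> np.ndarray:
    a = np.diag([cfg.dwi_voxel_mm] * 3 + [1.0])
    a[:3, 3] = -(np.array(cfg.dwi_grid_shape) - 1) / 2.0 * cfg.dwi_voxel_mm
    return a


_CENTER_CACHE: dict = {}


def _voxel_centers_mm(shape, affine):
    key = (tuple(shape), affine.tobytes())
    if key not in _CENTER_CACHE:
        idx = np.indices(shape).reshape(3, -1).T.astype(float)
        _CENTER_CACHE[key] = idx @ affine[:3, :3].T + affine[:3, 3]
    return _CENTER_CACHE[key]


def _label_volume(shape, affine) -> np.ndarray:
    """Mirror-symmetric head: GM shell around a WM core with two CSF ventricles."""
    p = _voxel_centers_mm(shape, affine).reshape(*shape, 3)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]

    def inside(cx, cy, cz, ax, ay, az):
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    ext = (np.array(shape) - 1) / 2.0 * abs(affine[0, 0])
    brain = inside(0, 0, 0, 0.92 * ext[0], 0.95 * ext[1], 0.88 * ext[2])
    wm = inside(0, 0, 0, 0.70 * ext[0], 0.76 * ext[1], 0.64 * ext[2])
    vent = inside(-6.0, 0, 0, 3.2, 9.0, 3.2) | inside(6.0, 0, 0, 3.2, 9.0, 3.2)
    lab = np.zeros(shape, dtype=np.uint8)
    lab[brain] = LABELS["GM"]
    lab[wm] = LABELS["NAWM"]
    lab[vent & brain] = LABELS["CSF"]
    return lab


def _ellipsoid_mask(shape, affine, center_mm, semi_mm) -> np.ndarray:
    p = _voxel_centers_mm(shape, affine).reshape(*shape, 3)
    d = (p - np.asarray(center_mm)) / np.asarray(semi_mm)
    return np.sum(d**2, axis=-1) <= 1.0


def _smooth_b1(shape, affine, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative transmit field in ~[1 - amp, 1 + amp]."""
    p = _voxel_centers_mm(shape, affine).reshape(*shape, 3)
    ext = np.abs(p).max()
    u = p / ext
    c = rng.uniform(-1.0, 1.0, size=4)
    raw = c[0] * u[..., 0] + c[1] * u[..., 1] + c[2] * u[..., 2] + c[3] * (u**2).sum(-1)
    span = np.abs(raw).max()
    if span < 1e-12:
        return np.ones(shape)
    return 1.0 + amplitude * raw / span


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------


@dataclass
class Lesion:
    lesion_id: str
    subject: str
    appearance_month: int
    volume_mm3: float
    center_mm: np.ndarray
    semi_axes_mm: np.ndarray
    severity_z: float
    region: np.ndarray  # full lesion extent on the MT grid
    region_dwi: np.ndarray  # full lesion extent on the DWI grid
    roi_mask: np.ndarray  # shrunken analysis mask (MT grid)
    contra_mask: np.ndarray  # mirrored reference mask (MT grid)


@dataclass
class SubjectPhantom:
    subject_id: str
    labels: np.ndarray
    labels_dwi: np.ndarray
    b1: np.ndarray
    lesions: List[Lesion] = field(default_factory=list)


@dataclass
class Cohort:
    config: PipelineConfig
    trajectory_mti: LesionTrajectory
    trajectory_dti: LesionTrajectory
    subjects: Dict[str, SubjectPhantom]

    @property
    def lesions(self) -> List[Lesion]:
        return [l for s in self.subjects.values() for l in s.lesions]

    def exam_performed(self, subject: str, month: int) -> bool:
        return (subject, month) not in {tuple(e) for e in self.config.phantom.missed_exams}

    def dti_performed(self, subject: str, month: int) -> bool:
        return self.exam_performed(subject, month) and (subject, month) not in {
            tuple(e) for e in self.config.phantom.missed_dti
        }

    def manifest(self) -> dict:
        cfg = self.config.phantom
        return {
            "subjects": cfg.n_subjects,
            "timepoints": list(cfg.schedule_months),
            "lesions": [
                {
                    "lesion_id": l.lesion_id,
                    "subject": l.subject,
                    "appearance_month": l.appearance_month,
                    "volume_mm3": round(float(l.volume_mm3), 2),
                    "roi_voxels": int(l.roi_mask.sum()),
                    "severity_z": round(float(l.severity_z), 4),
                }
                for l in self.lesions
            ],
            "missed_exams": [list(e) for e in cfg.missed_exams],
            "missed_dti": [list(e) for e in cfg.missed_dti],
        }

    # -- truth ------------------------------------------------------------

    def truth_qmt(self, subject: str, month: int) -> Dict[str, np.ndarray]:
        """Voxel-wise true (F, kf, T1, T2, M0) on the MT grid at one month."""
        cfg = self.config.phantom
        sub = self.subjects[subject]
        maps = _class_qmt_maps(sub.labels, cfg.tissues)
        nawm = cfg.tissues["NAWM"]
        for les in sub.lesions:
            rel = month - les.appearance_month
            if rel <= -12:
                continue
            vals = _lesion_qmt(nawm, self.trajectory_mti, rel, les.severity_z)
            for k, v in vals.items():
                maps[k][les.region] = v
        return maps

    def truth_tensor(self, subject: str, month: int) -> Dict[str, np.ndarray]:
        """Voxel-wise true eigenvalue maps (l1, l2, l3) on the DWI grid."""
        cfg = self.config.phantom
        sub = self.subjects[subject]
        maps = _class_tensor_maps(sub.labels_dwi, cfg.tissues)
        nawm = cfg.tissues["NAWM"]
        for les in sub.lesions:
            rel = month - les.appearance_month
            if rel <= -12:
                continue
            lam = _lesion_eigenvalues(nawm, self.trajectory_dti, rel, les.severity_z)
            for k, v in zip(("l1", "l2", "l3"), lam):
                maps[k][les.region_dwi] = v
        return maps


def _class_qmt_maps(labels, tissues) -> Dict[str, np.ndarray]:
    maps = {k: np.zeros(labels.shape) for k in ("F", "kf", "T1", "T2", "M0")}
    # benign relaxation times in background voxels; M0 = 0 silences them
    maps["T1"][:] = 1.0
    maps["T2"][:] = 0.1
    for name, lab in (("NAWM", 1), ("GM", 2), ("CSF", 3)):
        t = tissues[name]
        sel = labels == lab
        for k in ("F", "kf", "T1", "T2", "M0"):
            maps[k][sel] = getattr(t, k)
    return maps


def _class_tensor_maps(labels, tissues) -> Dict[str, np.ndarray]:
    maps = {k: np.zeros(labels.shape) for k in ("l1", "l2", "l3", "S0")}
    for name, lab in (("NAWM", 1), ("GM", 2), ("CSF", 3)):
        t = tissues[name]
        sel = labels == lab
        for k, v in zip(("l1", "l2", "l3"), t.eigenvalues):
            maps[k][sel] = v
        maps["S0"][sel] = t.M0
    return maps


def _lesion_qmt(nawm: TissueParams, traj: LesionTrajectory, rel_month, z) -> Dict[str, float]:
    """Lesion qMT parameters at a relative month, physically clamped."""
    eff = {k: float(traj.effect(k, rel_month, z)) for k in ("F", "kf", "T1", "T2")}
    F = max(nawm.F * (1 + eff["F"] / 100.0), 1e-3)
    kf = max(nawm.kf * (1 + eff["kf"] / 100.0), 0.0)
    T1 = float(np.clip(nawm.T1 * (1 + eff["T1"] / 100.0), 0.05, 10.0))
    T2 = float(np.clip(nawm.T2 * (1 + eff["T2"] / 100.0), 0.005, T1))
    return {"F": F, "kf": kf, "T1": T1, "T2": T2, "M0": nawm.M0}


def _fa_axially_symmetric(x: float) -> float:
    """FA of eigenvalues (x, 1, 1)."""
    return abs(x - 1.0) / math.sqrt(x * x + 2.0)


def _lesion_eigenvalues(nawm: TissueParams, traj: LesionTrajectory, rel_month, z):
    """Axially-symmetric eigenvalues realizing the FA and RD trajectories.

    RD fixes the transverse eigenvalue; FA then fixes the axial one via
    the closed form x = (1 + f sqrt(3 - 2 f^2)) / (1 - f^2) for the
    eigenvalue ratio x = l1/l_perp at FA = f.  MD and AD follow.
    """
    l1n, l2n, l3n = nawm.eigenvalues
    lperp_n = 0.5 * (l2n + l3n)
    fa_n = _fa_axially_symmetric(l1n / lperp_n)
    rd_eff = float(traj.effect("RD", rel_month, z))
    fa_eff = float(traj.effect("FA", rel_month, z))
    lperp = max(lperp_n * (1 + rd_eff / 100.0), 1e-5)
    f = float(np.clip(fa_n * (1 + fa_eff / 100.0), 0.01, 0.95))
    x = (1.0 + f * math.sqrt(3.0 - 2.0 * f * f)) / (1.0 - f * f)
    return (x * lperp, lperp, lperp)


def _draw_lesion_geometry(cfg: PhantomConfig, rng):
    lo, hi = cfg.lesion_volume_range_mm3
    mu, sd = cfg.lesion_volume_mean_mm3, cfg.lesion_volume_sd_mm3
    for _ in range(10_000):
        v = mu + sd * rng.standard_normal()
        if lo <= v <= hi:
            break
    else:  # pragma: no cover - config pathological
        raise PhantomError("could not draw a lesion volume inside the configured range")
    r2, r3 = rng.uniform(*cfg.lesion_axis_ratio_range, size=2)
    a = (3.0 * v / (4.0 * math.pi * r2 * r3)) ** (1.0 / 3.0)
    semi = np.array([a, a * r2, a * r3])
    rng.shuffle(semi)
    return float(v), semi


def _place_lesions(cfg: PhantomConfig, sub: SubjectPhantom, months: List[int], rng,
                   affine, affine_dwi):
    shape = cfg.grid_shape
    wm = sub.labels == LABELS["NAWM"]
    claimed = np.zeros(shape, dtype=bool)
    nx = shape[0]
    for j, month in enumerate(months):
        vol, semi = _draw_lesion_geometry(cfg, rng)
        placed = False
        for _ in range(4000):
            # centre in the left hemisphere, clear of the midsagittal plane
            ijk = np.array(
                [
                    rng.uniform(1, nx / 2 - semi[0] / cfg.voxel_mm - 1.5),
                    rng.uniform(1, shape[1] - 2),
                    rng.uniform(1, shape[2] - 2),
                ]
            )
            c = ijk * cfg.voxel_mm + affine[:3, 3]
            pad = semi + 0.6 * cfg.voxel_mm  # margin against neighbours
            region = _ellipsoid_mask(shape, affine, c, semi)
            if not region.any():
                continue
            grown = _ellipsoid_mask(shape, affine, c, pad)
            mirror_c = c * np.array([-1.0, 1.0, 1.0])
            mirror_grown = _ellipsoid_mask(shape, affine, mirror_c, pad)
            if np.any(grown & ~wm) or np.any(mirror_grown & ~wm):
                continue
            if np.any((grown | mirror_grown) & claimed):
                continue
            roi = _ellipsoid_mask(shape, affine, c, semi * cfg.mask_shrink)
            if roi.sum() < cfg.min_mask_voxels:
                roi = region
            contra = roi[::-1, :, :]
            region_dwi = _ellipsoid_mask(cfg.dwi_grid_shape, affine_dwi, c, semi)
            claimed |= grown | mirror_grown
            z = float(np.clip(rng.standard_normal(), -cfg.severity_clip, cfg.severity_clip))
            sub.lesions.append(
                Lesion(
                    lesion_id=f"{sub.subject_id}-L{j + 1:02d}",
                    subject=sub.subject_id,
                    appearance_month=month,
                    volume_mm3=vol,
                    center_mm=c,
                    semi_axes_mm=semi,
                    severity_z=z,
                    region=region,
                    region_dwi=region_dwi,
                    roi_mask=roi,
                    contra_mask=contra,
                )
            )
            placed = True
            break
        if not placed:
            raise PhantomError(
                f"could not place a {vol:.0f} mm^3 lesion in white matter for {sub.subject_id}"
            )


def build_phantom(config: PipelineConfig, seed: int) -> Cohort:
    """Deterministically build the cohort (geometry, B1 fields, lesions)."""
    cfg = config.phantom
    rng = np.random.default_rng(seed)
    affine = mt_affine(cfg)
    affine_dwi = dwi_affine(cfg)
    labels = _label_volume(cfg.grid_shape, affine)
    labels_dwi = _label_volume(cfg.dwi_grid_shape, affine_dwi)
    subjects: Dict[str, SubjectPhantom] = {}
    for sid in cfg.subject_ids():
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        sub = SubjectPhantom(
            subject_id=sid,
            labels=labels.copy(),
            labels_dwi=labels_dwi.copy(),
            b1=_smooth_b1(cfg.grid_shape, affine, cfg.b1_amplitude, sub_rng),
        )
        months = cfg.lesions_by_subject.get(sid, [])
        if months:
            _place_lesions(cfg, sub, sorted(months), sub_rng, affine, affine_dwi)
        subjects[sid] = sub
    return Cohort(
        config=config,
        trajectory_mti=LesionTrajectory(cfg.mti_anchors),
        trajectory_dti=LesionTrajectory(cfg.dti_anchors),
        subjects=subjects,
    )


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


@dataclass
class AcquiredExam:
    """Signal volumes of one (subject, month) examination."""

    subject: str
    month: int
    spgr: List[np.ndarray]
    bssfp: List[np.ndarray]
    mt: List[np.ndarray]
    b1_map: np.ndarray
    dwi: Optional[np.ndarray]  # 4D (DWI grid, n_scans) or None if not performed
    bvals: np.ndarray
    bvecs: np.ndarray
    noise_sigma: float
    dwi_noise_sigma: float


def _add_noise(vol, sigma, rng, rician: bool):
    if sigma == 0:
        return vol
    if rician:
        re = vol + sigma * rng.standard_normal(vol.shape)
        im = sigma * rng.standard_normal(vol.shape)
        return np.sqrt(re**2 + im**2)
    return vol + sigma * rng.standard_normal(vol.shape)


def simulate_acquisition(
    cohort: Cohort, subject: str, month: int, rng: np.random.Generator
) -> Optional[AcquiredExam]:
    """Simulate the full protocol for one examination (None if missed).

    Effective flip angles are the nominal angles scaled by the subject's
    smooth B1 field; noise is additive Gaussian (optionally Rician) with
    sigma = (mean NAWM signal of the minimally-saturating MT scan)/SNR on
    the MT grid and sigma = (mean NAWM b0)/SNR_dwi on the DWI grid.  The
    relaxometry bSSFP pair is acquired MT-minimized and follows the
    single-pool model.
    """
    if not cohort.exam_performed(subject, month):
        return None
    config = cohort.config
    cfg, proto = config.phantom, config.protocol
    consts = RestrictedPoolConstants(
        T1r=config.fit.T1r, G0=config.fit.G0, shape_factor=config.fit.rf_shape_factor
    )
    sub = cohort.subjects[subject]
    q = cohort.truth_qmt(subject, month)
    b1 = sub.b1
    brain = q["M0"] > 0
    nawm = sub.labels == LABELS["NAWM"]

    def mt_scan(spec):
        out = np.zeros(cfg.grid_shape)
        out[brain] = mt_bssfp_signal(
            q["F"][brain], q["kf"][brain], q["T1"][brain], q["T2"][brain], q["M0"][brain],
            spec.alpha_rad * b1[brain], spec.TR, spec.TRF, consts,
        )
        return out

    spgr_vols = []
    for spec in proto.spgr_specs():
        out = np.zeros(cfg.grid_shape)
        out[brain] = spgr_signal(q["M0"][brain], q["T1"][brain], spec.alpha_rad * b1[brain], spec.TR)
        spgr_vols.append(out)
    bssfp_vols = []
    for spec in proto.bssfp_specs():
        out = np.zeros(cfg.grid_shape)
        out[brain] = bssfp_signal(
            q["M0"][brain], q["T1"][brain], q["T2"][brain], spec.alpha_rad * b1[brain], spec.TR
        )
        bssfp_vols.append(out)
    mt_specs = proto.mt_specs()
    mt_vols = [mt_scan(s) for s in mt_specs]

    # noise reference: minimally saturating MT scan (longest pulse, 35 deg)
    i_ref = int(np.argmax([s.TRF for s in mt_specs[:5]]))
    sigma = 0.0 if cfg.snr is None else float(np.mean(mt_vols[i_ref][nawm])) / cfg.snr
    spgr_vols = [_add_noise(v, sigma, rng, cfg.rician) for v in spgr_vols]
    bssfp_vols = [_add_noise(v, sigma, rng, cfg.rician) for v in bssfp_vols]
    mt_vols = [_add_noise(v, sigma, rng, cfg.rician) for v in mt_vols]

    b1_map = b1 + (
        cfg.b1_map_noise_sd * rng.standard_normal(cfg.grid_shape)
        if cfg.b1_map_noise_sd and cfg.snr is not None
        else 0.0
    )

    # DWI on its own grid
    g = default_directions()
    bvals = np.concatenate([np.zeros(proto.dwi_n_b0), np.full(len(g), proto.dwi_bval)])
    bvecs = np.vstack([np.zeros((proto.dwi_n_b0, 3)), g])
    dwi = None
    dwi_sigma = 0.0
    if cohort.dti_performed(subject, month):
        t = cohort.truth_tensor(subject, month)
        l1, l2, l3, S0 = t["l1"], t["l2"], t["l3"], t["S0"]
        nawm_d = sub.labels_dwi == LABELS["NAWM"]
        dwi = np.zeros(cfg.dwi_grid_shape + (len(bvals),))
        for i, (b, v) in enumerate(zip(bvals, bvecs)):
            if b == 0:
                dwi[..., i] = S0
            else:
                # principal axis along x; axially-symmetric tensors
                adc = l1 * v[0] ** 2 + l2 * v[1] ** 2 + l3 * v[2] ** 2
                dwi[..., i] = S0 * np.exp(-b * adc)
        dwi_sigma = 0.0 if cfg.dwi_snr is None else float(np.mean(S0[nawm_d])) / cfg.dwi_snr
        dwi = _add_noise(dwi, dwi_sigma, rng, cfg.rician)

    return AcquiredExam(
        subject=subject,
        month=month,
        spgr=spgr_vols,
        bssfp=bssfp_vols,
        mt=mt_vols,
        b1_map=b1_map,
        dwi=dwi,
        bvals=bvals,
        bvecs=bvecs,
        noise_sigma=sigma,
        dwi_noise_sigma=dwi_sigma,
    )
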