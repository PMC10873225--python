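"""End-to-end orchestration: simulate -> fit -> lesion-centered analysis.

The map-fitting stages mirror the staged clinical processing: DESPOT1
T1 from the SPGR pair, DESPOT2 T2 from the bSSFP pair (both with
B1-corrected effective flip angles), the joint two-pool (F, kf) fit of
the ten MT-weighted scans with T1/T2 held fixed, MTR from the
extremal-pulse-duration pair, and the log-linear tensor fit on the DWI
grid with scalar maps resampled onto the MT grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .config import PipelineConfig
from .dti import fit_tensor_volume, metrics_volume
from .longitudinal import (
    DTI_METRICS,
    MTI_METRICS,
    EvolutionTable,
    LesionRecord,
    roi_median,
    run_longitudinal_analysis,
)
from .phantom import (
    AcquiredExam,
    Cohort,
    build_phantom,
    dwi_affine,
    mt_affine,
    simulate_acquisition,
)
from .qmt import map_volume
from .relaxometry import despot1_fit, despot2_fit, effective_alpha
from .signals import RestrictedPoolConstants

__all__ = [
    "ExamMaps",
    "exam_rng",
    "fit_exam_maps",
    "build_lesion_records",
    "run_cohort_pipeline",
]


def exam_rng(seed: int, subject: str, month: int) -> np.random.Generator:
    """Deterministic per-examination generator, independent of which other
    subjects/timepoints are simulated in the same run."""
    sub_idx = int("".join(c for c in subject if c.isdigit()) or 0)
    return np.random.default_rng(np.random.SeedSequence([seed, 917, sub_idx, month]))


@dataclass
class ExamMaps:
    """Fitted parameter maps of one examination, all on the MT grid."""

    subject: str
    month: int
    maps: Dict[str, np.ndarray]  # T1, T2, F, kf, MTR [+ FA, MD, AD, RD if DTI ran]
    info: Dict[str, object]


def resample_to_mt_grid(vol_dwi: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Trilinear resampling of a DWI-grid scalar map onto the MT grid
    through world coordinates (shared RAS frame)."""
    cfg = config.phantom
    A_mt, A_d = mt_affine(cfg), dwi_affine(cfg)
    idx = np.indices(cfg.grid_shape).reshape(3, -1).astype(float)
    world = A_mt[:3, :3] @ idx + A_mt[:3, 3:4]
    dcoords = np.linalg.inv(A_d[:3, :3]) @ (world - A_d[:3, 3:4])
    out = map_coordinates(vol_dwi, dcoords, order=1, mode="constant", cval=np.nan)
    return out.reshape(cfg.grid_shape)


def fit_exam_maps(
    exam: AcquiredExam,
    config: PipelineConfig,
    qmt_mask: Optional[np.ndarray] = None,
    dwi_mask: Optional[np.ndarray] = None,
) -> ExamMaps:
    """All parameter maps of one examination.

    ``qmt_mask`` restricts the expensive voxel-wise two-pool fit (closed
    -form T1/T2/MTR maps are always computed volume-wide); by default it
    is everywhere the DESPOT stage produced valid relaxation times.
    """
    proto, fit = config.protocol, config.fit
    consts = RestrictedPoolConstants(T1r=fit.T1r, G0=fit.G0, shape_factor=fit.rf_shape_factor)
    b1 = exam.b1_map
    a_spgr = [effective_alpha(a, b1) for a in proto.spgr_flip_deg]
    d1 = despot1_fit(exam.spgr[0], exam.spgr[1], a_spgr[0], a_spgr[1], proto.spgr_tr_s)
    a_bssfp = [effective_alpha(a, b1) for a in proto.bssfp_flip_deg]
    d2 = despot2_fit(
        exam.bssfp[0], exam.bssfp[1], a_bssfp[0], a_bssfp[1], proto.bssfp_tr_s, d1.value
    )
    maps: Dict[str, np.ndarray] = {"T1": d1.value, "T2": d2.value}
    info: Dict[str, object] = {
        "t1_unfittable": d1.n_unfittable,
        "t2_unfittable": d2.n_unfittable,
        "noise_sigma": exam.noise_sigma,
    }

    if qmt_mask is None:
        qmt_mask = d1.valid & d2.valid
    qmaps, qinfo = map_volume(
        exam.mt,
        proto.mt_specs(),
        d1.value,
        d2.value,
        b1,
        qmt_mask & d1.valid & d2.valid,
        n_workers=fit.n_workers,
        init=fit.qmt_init,
        bounds=(fit.qmt_bounds_F, fit.qmt_bounds_kf),
        constants=consts,
    )
    maps["F"], maps["kf"], maps["MTR"] = qmaps["F"], qmaps["kf"], qmaps["MTR"]
    info.update({f"qmt_{k}": v for k, v in qinfo.items()})

    if exam.dwi is not None:
        coefs, ok = fit_tensor_volume(exam.dwi, exam.bvals, exam.bvecs, mask=dwi_mask)
        scal = metrics_volume(coefs)
        for k in DTI_METRICS:
            maps[k] = resample_to_mt_grid(scal[k], config)
        info["dti_unfittable"] = int((~ok).sum()) if dwi_mask is None else int(
            (np.asarray(dwi_mask, bool) & ~ok).sum()
        )
    return ExamMaps(subject=exam.subject, month=exam.month, maps=maps, info=info)


def build_lesion_records(
    cohort: Cohort, exam_maps: Sequence[ExamMaps]
) -> List[LesionRecord]:
    """ROI medians of every lesion and its contralateral reference at every
    performed examination."""
    by_key = {(m.subject, m.month): m for m in exam_maps}
    records = []
    for les in cohort.lesions:
        rec = LesionRecord(
            lesion_id=les.lesion_id,
            subject=les.subject,
            appearance_month=les.appearance_month,
            roi_mask=les.roi_mask,
            contra_mask=les.contra_mask,
        )
        for month in cohort.config.phantom.schedule_months:
            em = by_key.get((les.subject, month))
            if em is None:
                continue
            rec.medians[month] = {
                k: (roi_median(v, les.roi_mask), roi_median(v, les.contra_mask))
                for k, v in em.maps.items()
            }
        records.append(rec)
    return records


def run_cohort_pipeline(
    config: PipelineConfig,
    seed: int,
    subjects: Optional[Sequence[str]] = None,
    progress: bool = False,
):
    """Simulate, fit and analyze a cohort.

    By default only lesion-bearing subjects are simulated and fitted —
    subjects without lesions contribute nothing to the lesion-centered
    statistics.  Returns (cohort, exam maps, lesion records, table).
    """
    cohort = build_phantom(config, seed)
    cfg = config.phantom
    if subjects is None:
        subjects = sorted(cfg.lesions_by_subject)
    exam_maps: List[ExamMaps] = []
    for sid in subjects:
        sub = cohort.subjects[sid]
        union = np.zeros(cfg.grid_shape, dtype=bool)
        for les in sub.lesions:
            union |= les.roi_mask | les.contra_mask
        dwi_brain = sub.labels_dwi > 0
        for month in cfg.schedule_months:
            exam = simulate_acquisition(cohort, sid, month, exam_rng(seed, sid, month))
            if exam is None:
                continue
            em = fit_exam_maps(exam, config, qmt_mask=union, dwi_mask=dwi_brain)
            exam_maps.append(em)
            if progress:
                print(f"  fitted {sid} month {month:>2}", flush=True)
    records = build_lesion_records(cohort, exam_maps)
    table = run_longitudinal_analysis(
        records,
        cfg.schedule_months,
        confidence=config.analysis.confidence,
        alpha=config.analysis.alpha,
    )
    return cohort, exam_maps, records, table
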