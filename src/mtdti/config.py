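"""Pipeline configuration: schema-validated settings for every stage.

Defaults encode the full study design — the bimonthly 0–12 month
schedule plus a month-24 follow-up, the two-angle SPGR / two-angle bSSFP
relaxometry pairs, the ten MT-weighted bSSFP scans, the 30-direction
DWI scheme, a 19-subject cohort in which 7 subjects develop 21 new
white-matter lesions, and the missed-examination pattern — so a
``simulate`` run with no overrides emulates the study.

Configs are YAML on disk; unknown keys are rejected (``extra="forbid"``)
before any stage runs.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .signals import SequenceSpec

__all__ = [
    "ProtocolConfig",
    "PhantomConfig",
    "FitConfig",
    "AnalysisConfig",
    "PipelineConfig",
    "load_config",
    "default_config",
]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ProtocolConfig(_Base):
    """Acquisition protocol; angles in degrees, times in the stated units."""

    spgr_flip_deg: Tuple[float, float] = (3.0, 17.0)
    spgr_tr_s: float = 0.010
    bssfp_flip_deg: Tuple[float, float] = (15.0, 35.0)
    bssfp_tr_s: float = 0.00393
    mt_trf_ms: Tuple[float, ...] = (0.12, 0.227, 0.424, 0.8, 1.5)
    mt_trf_flip_deg: float = 35.0
    mt_alpha_flip_deg: Tuple[float, ...] = (5.0, 12.5, 20.0, 27.5, 35.0)
    mt_alpha_trf_ms: float = 0.12
    # TR of an MT scan is linearly interpolated in TRF between these
    # endpoints over the TRF range (shortest pulse -> first endpoint)
    mt_tr_endpoints_ms: Tuple[float, float] = (2.55, 3.93)
    b1map_flip_deg: float = 30.0
    dwi_bval: float = 900.0
    dwi_n_b0: int = 10

    def mt_tr_s(self, trf_ms: float) -> float:
        lo, hi = min(self.mt_trf_ms), max(self.mt_trf_ms)
        t0, t1 = self.mt_tr_endpoints_ms
        frac = 0.0 if hi == lo else (trf_ms - lo) / (hi - lo)
        return (t0 + frac * (t1 - t0)) * 1e-3

    def spgr_specs(self) -> List[SequenceSpec]:
        return [SequenceSpec("SPGR", a, self.spgr_tr_s) for a in self.spgr_flip_deg]

    def bssfp_specs(self) -> List[SequenceSpec]:
        return [SequenceSpec("BSSFP", a, self.bssfp_tr_s) for a in self.bssfp_flip_deg]

    def mt_specs(self) -> List[SequenceSpec]:
        """The ten MT-weighted scans: variable-TRF series then variable-flip series.

        The shared corner scan (max flip at the shortest pulse) appears once in
        each series as acquired; the variable-flip series is listed in full."""
        specs = [
            SequenceSpec("MT_BSSFP", self.mt_trf_flip_deg, self.mt_tr_s(t), t * 1e-3)
            for t in self.mt_trf_ms
        ]
        specs += [
            SequenceSpec("MT_BSSFP", a, self.mt_tr_s(self.mt_alpha_trf_ms), self.mt_alpha_trf_ms * 1e-3)
            for a in self.mt_alpha_flip_deg
        ]
        return specs


# per-anchor printed aggregate: mean relative difference (%), 95% CI
# half-width (%) and the number of lesion observations behind it; the
# between-lesion SD is derived as SD = sqrt(n) * hw / t_{0.975, n-1}
Anchor = Tuple[float, float, float, int]  # (relative month, mean, ci_half_width, n)

MTI_ANCHORS: Dict[str, List[Anchor]] = {
    "F": [(-12, 0.0, 0.0, 21), (-10, -1.2, 2.55, 4), (-4, -12.3, 7.7, 14),
          (-2, -14.7, 4.8, 19), (0, -70.2, 4.7, 21), (2, -55.9, 8.15, 71),
          (8, -55.9, 8.15, 71), (24, -55.9, 8.15, 71)],
    "kf": [(-12, 0.0, 0.0, 21), (-10, -3.7, 12.8, 4), (-4, -12.7, 5.5, 14),
           (-2, -15.3, 5.3, 19), (0, -73.1, 4.25, 21), (2, -59.1, 5.75, 71),
           (8, -59.1, 5.75, 71), (24, -59.1, 5.75, 71)],
    "T1": [(-12, 0.0, 0.0, 21), (-10, 1.9, 7.95, 4), (-4, 6.7, 5.0, 14),
           (-2, 10.3, 4.1, 19), (0, 74.5, 20.8, 21), (2, 42.9, 12.8, 71),
           (8, 42.9, 12.8, 71), (24, 42.9, 12.8, 71)],
    "T2": [(-12, 0.0, 0.0, 21), (-10, -1.1, 5.15, 4), (-4, 6.6, 5.3, 14),
           (-2, 9.9, 4.0, 19), (0, 122.5, 47.6, 21), (2, 60.0, 18.35, 71),
           (8, 60.0, 18.35, 71), (24, 60.0, 18.35, 71)],
    "MTR": [(-12, 0.0, 0.0, 21), (-10, 0.1, 2.85, 4), (-4, -2.3, 1.1, 14),
            (-2, -3.0, 1.15, 19), (0, -27.7, 3.7, 21), (2, -19.1, 3.75, 71),
            (8, -19.1, 3.75, 71), (24, -19.1, 3.75, 71)],
}

DTI_ANCHORS: Dict[str, List[Anchor]] = {
    "FA": [(-12, 0.0, 0.0, 21), (-10, -9.3, 13.45, 39), (-2, -9.3, 13.45, 39),
           (0, -38.5, 6.75, 21), (2, -27.7, 7.05, 60), (8, -27.7, 7.05, 60),
           (24, -27.7, 7.05, 60)],
    "MD": [(-12, 0.0, 0.0, 21), (-10, 6.8, 6.85, 39), (-2, 6.8, 6.85, 39),
           (0, 37.5, 8.65, 21), (2, 29.6, 5.65, 60), (8, 29.6, 5.65, 60),
           (24, 29.6, 5.65, 60)],
    "AD": [(-12, 0.0, 0.0, 21), (-10, 3.6, 5.05, 39), (-2, 3.6, 5.05, 39),
           (0, 18.4, 7.7, 21), (2, 17.8, 7.15, 60), (8, 17.8, 7.15, 60),
           (24, 17.8, 7.15, 60)],
    "RD": [(-12, 0.0, 0.0, 21), (-10, 10.6, 8.9, 39), (-2, 10.6, 8.9, 39),
           (0, 60.6, 12.95, 21), (2, 45.6, 6.55, 60), (8, 45.6, 6.55, 60),
           (24, 45.6, 6.55, 60)],
}

# canonical direction of each metric's change in an active lesion
EFFECT_DIRECTION = {"F": -1, "kf": -1, "T1": 1, "T2": 1, "MTR": -1,
                    "FA": -1, "MD": 1, "AD": 1, "RD": 1}


class TissueParams(_Base):
    F: float
    kf: float
    T1: float
    T2: float
    M0: float = 1.0
    eigenvalues: Tuple[float, float, float]  # mm^2/s, descending


DEFAULT_TISSUES: Dict[str, TissueParams] = {
    "NAWM": TissueParams(F=0.157, kf=4.45, T1=0.779, T2=0.045,
                         eigenvalues=(1.3e-3, 0.45e-3, 0.45e-3)),
    "GM": TissueParams(F=0.10, kf=2.4, T1=1.1, T2=0.08,
                       eigenvalues=(0.95e-3, 0.75e-3, 0.75e-3)),
    "CSF": TissueParams(F=0.0, kf=0.0, T1=4.0, T2=2.0,
                        eigenvalues=(3.0e-3, 3.0e-3, 3.0e-3)),
}


class PhantomConfig(_Base):
    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 1.3
    dwi_grid_shape: Tuple[int, int, int] = (31, 31, 31)
    dwi_voxel_mm: float = 2.0
    snr: Optional[float] = 80.0  # None disables noise
    dwi_snr: Optional[float] = 60.0
    rician: bool = False
    b1_amplitude: float = 0.1  # relative B1 spans ~ [1 - amp, 1 + amp]
    b1_map_noise_sd: float = 0.005

    n_subjects: int = 19
    schedule_months: Tuple[int, ...] = (0, 2, 4, 6, 8, 10, 12, 24)
    # lesion-bearing subjects: per-subject appearance months of their lesions
    lesions_by_subject: Dict[str, List[int]] = Field(
        default_factory=lambda: {
            "S01": [2, 4, 4, 6, 6, 8, 8, 10, 10],
            "S02": [10, 10, 10, 10],
            "S03": [4, 6, 8],
            "S04": [2, 4],
            "S05": [4],
            "S06": [6],
            "S07": [6],
        }
    )
    # whole missed examinations: six, by four subjects, within months 2-12
    missed_exams: List[Tuple[str, int]] = Field(
        default_factory=lambda: [("S03", 2), ("S04", 10), ("S04", 12),
                                 ("S05", 8), ("S06", 8), ("S06", 12)]
    )
    # DTI-only missed examinations: six subjects, one timepoint each
    missed_dti: List[Tuple[str, int]] = Field(
        default_factory=lambda: [("S01", 0), ("S02", 0), ("S03", 12),
                                 ("S04", 6), ("S05", 2), ("S07", 24)]
    )

    lesion_volume_mean_mm3: float = 71.0
    lesion_volume_sd_mm3: float = 60.0
    lesion_volume_range_mm3: Tuple[float, float] = (12.0, 201.0)
    lesion_axis_ratio_range: Tuple[float, float] = (1.0, 2.5)
    # analysis masks are drawn slightly smaller than the lesion to avoid
    # partial-volume contamination at the rim
    mask_shrink: float = 0.8
    min_mask_voxels: int = 3
    severity_clip: float = 2.0  # per-lesion severity z is clipped to +/- this

    tissues: Dict[str, TissueParams] = Field(default_factory=lambda: dict(DEFAULT_TISSUES))
    mti_anchors: Dict[str, List[Anchor]] = Field(default_factory=lambda: dict(MTI_ANCHORS))
    dti_anchors: Dict[str, List[Anchor]] = Field(default_factory=lambda: dict(DTI_ANCHORS))

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or null to disable noise)")
        if self.dwi_snr is not None and self.dwi_snr <= 0:
            raise ValueError("dwi_snr must be positive (or null to disable noise)")
        sched = set(self.schedule_months)
        for subj, months in self.lesions_by_subject.items():
            if not set(months) <= sched:
                raise ValueError(f"appearance months of {subj} not all in the schedule")
            missed = {m for s, m in self.missed_exams if s == subj}
            if missed & set(months):
                raise ValueError(f"{subj} has a lesion appearing at a missed examination")
        lo, hi = self.lesion_volume_range_mm3
        if not 0 < lo < hi:
            raise ValueError("bad lesion volume range")
        return self

    @property
    def n_lesions(self) -> int:
        return sum(len(v) for v in self.lesions_by_subject.values())

    def subject_ids(self) -> List[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


class FitConfig(_Base):
    T1r: float = 1.0
    G0: float = 1.4e-5
    rf_shape_factor: float = 1.0
    qmt_bounds_F: Tuple[float, float] = (0.0, 0.5)
    qmt_bounds_kf: Tuple[float, float] = (0.0, 50.0)
    qmt_init: Tuple[float, float] = (0.1, 3.0)
    n_workers: int = 1


class AnalysisConfig(_Base):
    confidence: float = 0.95
    alpha: float = 0.05


class PipelineConfig(_Base):
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0


def anchor_sd(mean: float, hw: float, n: int) -> float:
    """Between-lesion SD implied by a printed mean +/- CI half-width over n."""
    from scipy.stats import t as tdist

    if hw <= 0 or n < 2:
        return 0.0
    return float(hw / tdist.ppf(0.975, n - 1) * np.sqrt(n))


def default_config() -> PipelineConfig:
    return PipelineConfig()


def load_config(path=None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load a YAML config (missing keys fall back to defaults); schema-validated."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = _deep_merge(data, overrides)
    return PipelineConfig.model_validate(data)


def _deep_merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
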