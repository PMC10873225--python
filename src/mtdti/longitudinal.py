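"""Lesion-centered longitudinal ROI statistics.

From per-timepoint parameter maps and lesion/contralateral masks this
module computes ROI medians, relative differences to contralateral
normal-appearing white matter, re-indexes every lesion's observations by
the month relative to its appearance, aggregates across lesions
(mean, SE, t-based 95% CI), and runs the Bonferroni-corrected family of
paired t-tests comparing pre-lesional tissue with the contralateral
reference.

The family size is derived from the data — (number of metrics) x
(number of pre-lesional relative months with at least two paired
observations) — and not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LesionRecord",
    "EvolutionTable",
    "roi_median",
    "relative_difference",
    "center_on_appearance",
    "aggregate",
    "paired_ttest_family",
    "run_longitudinal_analysis",
]


@dataclass
class LesionRecord:
    """One lesion's masks and per-timepoint per-metric ROI medians.

    ``medians`` maps month -> {metric: (lesion median, reference median)};
    months of missed examinations are simply absent.
    """

    lesion_id: str
    subject: str
    appearance_month: int
    roi_mask: np.ndarray
    contra_mask: np.ndarray
    medians: Dict[int, Dict[str, tuple]] = field(default_factory=dict)

    def __post_init__(self):
        if self.roi_mask.sum() == 0 or self.contra_mask.sum() == 0:
            raise ValueError(f"lesion {self.lesion_id}: empty mask")
        if np.any(self.roi_mask & self.contra_mask):
            raise ValueError(f"lesion {self.lesion_id}: lesion and reference masks overlap")


@dataclass
class EvolutionTable:
    """Long-format rows plus aggregates and test results."""

    rows: pd.DataFrame  # lesion_id, subject, metric, rel_month, lesion_med, ref_med, rel_diff
    aggregates: pd.DataFrame  # metric, rel_month, n, mean, se, ci_low, ci_high
    tests: pd.DataFrame  # modality, metric, rel_month, n, t, p, alpha_corrected, significant


def roi_median(vol: np.ndarray, mask: np.ndarray) -> float:
    """Median over the finite in-mask voxels (NaN if none are finite)."""
    mask = np.asarray(mask, dtype=bool)
    if vol.shape != mask.shape:
        raise ValueError(f"grid mismatch: map {vol.shape} vs mask {mask.shape}")
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(vol)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))


def relative_difference(lesion_med: float, nawm_med: float) -> float:
    """Relative intensity difference in percent: 100 (lesion - ref)/ref."""
    if nawm_med == 0 or not np.isfinite(nawm_med):
        return float("nan")
    return 100.0 * (lesion_med - nawm_med) / nawm_med


def center_on_appearance(
    records: Sequence[LesionRecord], schedule: Sequence[int]
) -> pd.DataFrame:
    """Long-format rows indexed by month relative to lesion appearance.

    Missed examinations produce no row; relative month 0 therefore
    carries exactly one row per lesion and metric with data.
    """
    sched = set(int(m) for m in schedule)
    out = []
    for rec in records:
        if rec.appearance_month not in sched:
            raise ValueError(
                f"lesion {rec.lesion_id}: appearance month {rec.appearance_month} not in schedule"
            )
        for month, by_metric in sorted(rec.medians.items()):
            rel = month - rec.appearance_month
            for metric, (les, ref) in by_metric.items():
                if not (np.isfinite(les) and np.isfinite(ref)):
                    continue
                out.append(
                    {
                        "lesion_id": rec.lesion_id,
                        "subject": rec.subject,
                        "metric": metric,
                        "month": month,
                        "rel_month": rel,
                        "lesion_med": les,
                        "ref_med": ref,
                        "rel_diff": relative_difference(les, ref),
                    }
                )
    return pd.DataFrame(
        out,
        columns=[
            "lesion_id", "subject", "metric", "month", "rel_month",
            "lesion_med", "ref_med", "rel_diff",
        ],
    )


def aggregate(rows: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Across-lesion mean, SE and t-based CI of the relative difference
    per (metric, relative month).  Cells with n < 2 report NaN SE/CI."""
    recs = []
    for (metric, rel), g in rows.groupby(["metric", "rel_month"]):
        x = g["rel_diff"].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        n = x.size
        if n == 0:
            continue
        mean = float(np.mean(x))
        if n >= 2:
            se = float(np.std(x, ddof=1) / np.sqrt(n))
            tq = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
            lo, hi = mean - tq * se, mean + tq * se
        else:
            se = lo = hi = float("nan")
        recs.append(
            {"metric": metric, "rel_month": rel, "n": n, "mean": mean,
             "se": se, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(
        recs, columns=["metric", "rel_month", "n", "mean", "se", "ci_low", "ci_high"]
    )


def paired_ttest_family(
    rows: pd.DataFrame,
    metrics: Sequence[str],
    modality: str = "MTI",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni-corrected family of two-sided paired t-tests, lesion vs
    contralateral reference medians, one test per (metric, pre-lesional
    relative month).

    The family size m = len(metrics) x (number of pre-lesional months at
    which at least two lesions have paired data for every listed metric);
    the corrected per-test threshold is alpha/m.  Identical pairs give
    t = 0 treated as p = 1.
    """
    pre = rows[(rows["rel_month"] < 0) & rows["metric"].isin(metrics)]
    months = []
    for rel, g in pre.groupby("rel_month"):
        counts = g.groupby("metric")["lesion_id"].nunique()
        if len(counts) == len(metrics) and (counts >= 2).all():
            months.append(rel)
    m = len(metrics) * len(months)
    alpha_star = alpha / m if m else float("nan")
    recs = []
    for rel in sorted(months):
        for metric in metrics:
            g = pre[(pre["rel_month"] == rel) & (pre["metric"] == metric)]
            a = g["lesion_med"].to_numpy(dtype=float)
            b = g["ref_med"].to_numpy(dtype=float)
            if np.allclose(a, b):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(a, b)
                if not np.isfinite(p):
                    t_stat, p = 0.0, 1.0
            recs.append(
                {
                    "modality": modality,
                    "metric": metric,
                    "rel_month": rel,
                    "n": a.size,
                    "t": float(t_stat),
                    "p": float(p),
                    "m_family": m,
                    "alpha_corrected": alpha_star,
                    "significant": bool(p < alpha_star),
                }
            )
    return pd.DataFrame(
        recs,
        columns=["modality", "metric", "rel_month", "n", "t", "p",
                 "m_family", "alpha_corrected", "significant"],
    )


MTI_METRICS = ("F", "kf", "T1", "T2", "MTR")
DTI_METRICS = ("FA", "MD", "AD", "RD")


def run_longitudinal_analysis(
    records: Sequence[LesionRecord],
    schedule: Sequence[int],
    confidence: float = 0.95,
    alpha: float = 0.05,
) -> EvolutionTable:
    """Full lesion-centered analysis from populated LesionRecords."""
    rows = center_on_appearance(records, schedule)
    aggs = aggregate(rows, confidence=confidence)
    present = set(rows["metric"])
    tests = []
    mti = [m for m in MTI_METRICS if m in present]
    dti = [m for m in DTI_METRICS if m in present]
    if mti:
        tests.append(paired_ttest_family(rows, mti, "MTI", alpha))
    if dti:
        tests.append(paired_ttest_family(rows, dti, "DTI", alpha))
    tests_df = (
        pd.concat(tests, ignore_index=True)
        if tests
        else pd.DataFrame(
            columns=["modality", "metric", "rel_month", "n", "t", "p",
                     "m_family", "alpha_corrected", "significant"]
        )
    )
    return EvolutionTable(rows=rows, aggregates=aggs, tests=tests_df)


def plot_evolution(table: EvolutionTable, metrics: Sequence[str], path=None, title=None):
    """Mean +/- CI of the relative difference vs relative month, one panel
    per metric (the style of the longitudinal evolution figures)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(metrics)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        g = table.aggregates[table.aggregates["metric"] == metric].sort_values("rel_month")
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.errorbar(
            g["rel_month"], g["mean"],
            yerr=np.vstack([g["mean"] - g["ci_low"], g["ci_high"] - g["mean"]]),
            fmt="o-", ms=3, capsize=2,
        )
        ax.set_title(metric)
        ax.set_xlabel("months from appearance")
        ax.set_ylabel("difference vs contralateral NAWM (%)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
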