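"""Lesion-centered ROI statistics: medians, centering, aggregation, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtdti.longitudinal import (
    LesionRecord,
    aggregate,
    center_on_appearance,
    paired_ttest_family,
    relative_difference,
    roi_median,
    run_longitudinal_analysis,
)

SCHEDULE = (0, 2, 4, 6, 8, 10, 12, 24)


def _mask(n=4):
    m = np.zeros((4, 4, 4), dtype=bool)
    m.reshape(-1)[:n] = True
    return m


def _record(lesion_id="L1", subject="S1", appearance=6, medians=None):
    roi = _mask(4)
    contra = np.zeros_like(roi)
    contra.reshape(-1)[-4:] = True
    rec = LesionRecord(lesion_id, subject, appearance, roi, contra)
    if medians:
        rec.medians.update(medians)
    return rec


def test_roi_median():
    vol = np.zeros((4, 4, 4))
    vol.reshape(-1)[:5] = [1, 2, 3, 4, 5]
    assert roi_median(vol, _mask(5)) == 3.0
    assert roi_median(vol, _mask(4)) == 2.5  # mean-of-middle convention
    assert roi_median(np.full((4, 4, 4), 7.7), _mask(6)) == 7.7
    vol.reshape(-1)[0] = np.nan
    assert roi_median(vol, _mask(2)) == 2.0  # finite voxels only
    with pytest.raises(ValueError, match="empty mask"):
        roi_median(vol, np.zeros((4, 4, 4), dtype=bool))
    with pytest.raises(ValueError, match="grid mismatch"):
        roi_median(vol[:2], _mask(2))


def test_relative_difference():
    assert relative_difference(1.0, 1.0) == 0.0
    assert relative_difference(0.3, 1.0) == pytest.approx(-70.0)
    assert relative_difference(2.225, 1.0) == pytest.approx(122.5)
    assert np.isnan(relative_difference(1.0, 0.0))


def test_center_on_appearance():
    meds = {m: {"F": (0.1, 0.15)} for m in SCHEDULE}
    rec = _record(appearance=6, medians=meds)
    rows = center_on_appearance([rec], SCHEDULE)
    assert sorted(rows["rel_month"]) == [-6, -4, -2, 0, 2, 4, 6, 18]
    # a missed exam produces no row
    meds2 = {m: {"F": (0.1, 0.15)} for m in SCHEDULE if m != 8}
    rows2 = center_on_appearance([_record(medians=meds2)], SCHEDULE)
    assert 2 not in set(rows2["rel_month"])
    with pytest.raises(ValueError, match="not in schedule"):
        center_on_appearance([_record(appearance=5, medians=meds)], SCHEDULE)


def test_count_at_detection_equals_lesions():
    recs = [
        _record(f"L{i}", f"S{i}", app, {m: {"F": (0.1, 0.15)} for m in SCHEDULE})
        for i, app in enumerate((2, 4, 6, 10))
    ]
    rows = center_on_appearance(recs, SCHEDULE)
    assert (rows["rel_month"] == 0).sum() == len(recs)
    # per-relative-month indicator sums reproduce the histogram totals
    hist = rows.groupby("rel_month")["lesion_id"].nunique()
    for rel, n in hist.items():
        assert n == sum(
            1 for r in recs if (rel + r.appearance_month) in SCHEDULE or rel + r.appearance_month == 24
        )


def test_aggregate_hand_values_and_oracle():
    rows = pd.DataFrame(
        {
            "metric": ["F"] * 2 + ["T2"] * 3,
            "rel_month": [0, 0, 0, 0, 0],
            "rel_diff": [-60.0, -80.0, 5.0, 5.0, 5.0],
            "lesion_id": list("abcde"),
        }
    )
    agg = aggregate(rows).set_index("metric")
    assert agg.loc["F", "mean"] == pytest.approx(-70.0)
    assert agg.loc["F", "se"] == pytest.approx(10.0)
    assert agg.loc["T2", "se"] == 0.0
    assert agg.loc["T2", "ci_low"] == agg.loc["T2", "ci_high"] == 5.0
    # independent oracle: statsmodels t-based confidence interval
    from statsmodels.stats.weightstats import DescrStatsW

    rng = np.random.default_rng(0)
    x = rng.normal(-20, 7, size=17)
    rows = pd.DataFrame(
        {"metric": "kf", "rel_month": 0, "rel_diff": x, "lesion_id": np.arange(17)}
    )
    agg = aggregate(rows).iloc[0]
    lo, hi = DescrStatsW(x).tconfint_mean(alpha=0.05)
    assert agg["ci_low"] == pytest.approx(lo, abs=1e-10)
    assert agg["ci_high"] == pytest.approx(hi, abs=1e-10)
    assert agg["se"] == pytest.approx(x.std(ddof=1) / np.sqrt(17), rel=1e-12)


def _rows_for_family(metrics, months, n, shift=0.0, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for met in metrics:
        for rel in months:
            ref = rng.normal(10.0, sd, n)
            les = ref + shift + rng.normal(0.0, sd, n)
            for i in range(n):
                out.append(
                    {
                        "lesion_id": f"L{i}",
                        "metric": met,
                        "rel_month": rel,
                        "lesion_med": les[i],
                        "ref_med": ref[i],
                        "rel_diff": relative_difference(les[i], ref[i]),
                    }
                )
    return pd.DataFrame(out)


def test_family_sizes_and_thresholds():
    """Corrected thresholds: 0.05/25 = 0.002 for the five MT metrics over five
    pre-lesional months; 0.05/16 = 0.003125 (0.003 at three decimals) for the
    four DTI metrics over four months."""
    mti = _rows_for_family(["F", "kf", "T1", "T2", "MTR"], [-10, -8, -6, -4, -2], 6)
    t_mti = paired_ttest_family(mti, ["F", "kf", "T1", "T2", "MTR"], "MTI")
    assert t_mti["m_family"].unique().tolist() == [25]
    assert t_mti["alpha_corrected"].unique()[0] == pytest.approx(0.002)
    dti = _rows_for_family(["FA", "MD", "AD", "RD"], [-8, -6, -4, -2], 6)
    t_dti = paired_ttest_family(dti, ["FA", "MD", "AD", "RD"], "DTI")
    assert t_dti["m_family"].unique().tolist() == [16]
    assert t_dti["alpha_corrected"].unique()[0] == pytest.approx(0.003125)
    assert round(t_dti["alpha_corrected"].unique()[0], 3) == 0.003


def test_ttest_against_independent_oracle():
    """p-values match the t-distribution CDF evaluated on the hand-computed
    paired statistic."""
    rows = _rows_for_family(["F"], [-2], 19, shift=-0.8, seed=3)
    res = paired_ttest_family(rows, ["F"], "MTI").iloc[0]
    g = rows[(rows.metric == "F") & (rows.rel_month == -2)]
    d = (g["lesion_med"] - g["ref_med"]).to_numpy()
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    p_hand = 2.0 * stats.t.sf(abs(t_hand), d.size - 1)
    assert res["t"] == pytest.approx(t_hand, abs=1e-10)
    assert res["p"] == pytest.approx(p_hand, abs=1e-10)


def test_identical_pairs_not_significant():
    rows = _rows_for_family(["F"], [-2, -4], 6, shift=0.0, sd=1.0)
    rows["lesion_med"] = rows["ref_med"]
    res = paired_ttest_family(rows, ["F"])
    assert (res["p"] == 1.0).all()
    assert not res["significant"].any()


def test_small_n_cells_skipped():
    """A pre-lesional month with a single paired observation yields no test."""
    rows = _rows_for_family(["F"], [-2], 1)
    res = paired_ttest_family(rows, ["F"])
    assert len(res) == 0


def test_scale_invariance_of_relative_difference():
    """Scaling a metric's maps by any positive constant leaves the table rows
    unchanged."""
    meds = {m: {"F": (0.08, 0.15)} for m in SCHEDULE}
    scaled = {m: {"F": (0.08 * 3.7, 0.15 * 3.7)} for m in SCHEDULE}
    r1 = center_on_appearance([_record(medians=meds)], SCHEDULE)
    r2 = center_on_appearance([_record(medians=scaled)], SCHEDULE)
    assert np.allclose(r1["rel_diff"], r2["rel_diff"])


def test_null_cohort_no_significance():
    """Zero-effect lesions: aggregates straddle 0 and nothing reaches the
    corrected threshold."""
    rng = np.random.default_rng(7)
    recs = []
    for i, app in enumerate([2, 4, 4, 6, 6, 8, 10, 10]):
        meds = {}
        for m in SCHEDULE:
            meds[m] = {
                met: (10 + 0.5 * rng.standard_normal(), 10 + 0.5 * rng.standard_normal())
                for met in ("F", "kf", "T1", "T2", "MTR")
            }
        recs.append(_record(f"L{i}", f"S{i % 4}", app, meds))
    table = run_longitudinal_analysis(recs, SCHEDULE)
    assert not table.tests["significant"].any()
    m0 = table.aggregates[table.aggregates.rel_month == 0]
    assert ((m0["ci_low"] <= 0) & (0 <= m0["ci_high"])).mean() > 0.6


def test_overlapping_masks_rejected():
    roi = _mask(4)
    with pytest.raises(ValueError, match="overlap"):
        LesionRecord("L", "S", 2, roi, roi)
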