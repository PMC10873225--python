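# mtdti

Longitudinal quantitative magnetization-transfer (qMT) and
diffusion-tensor (DTI) analysis of newly appearing white-matter
lesions, with a synthetic multi-contrast MRI cohort generator.

## The problem

In multiple sclerosis, new lesions become visible on conventional MRI
months after microstructural damage begins.  Magnetization-transfer
imaging is sensitive to the macromolecular (myelin-bound) proton pool
and can detect pre-lesional tissue change earlier than either
conventional MRI or DTI.  Quantifying this requires a chain of
model-based estimation steps:

* **relaxometry** — DESPOT1/DESPOT2: closed-form T1 and T2 of the free
  water pool from two spoiled gradient-echo (3°/17°) and two balanced
  SSFP (15°/35°) acquisitions, with per-voxel B1 flip-angle correction;
* **qMT** — the two-pool balanced-SSFP steady state.  The free pool
  (magnetization `Mz_f`, relaxation T1/T2) exchanges with a restricted
  pool of relative size *F* at forward rate *k_f* (reverse rate
  `k_r = k_f/F`), while each RF pulse of duration TRF saturates the
  restricted pool at the hard-pulse rate `W = π (α/TRF)² G(0)`.  The
  sequence's once-per-TR evolution is an affine map `m → P m + q`; its
  fixed point `m* = (I − P)⁻¹ q` is the steady-state signal.  Fitting
  ten MT-weighted scans (five pulse durations 0.12–1.5 ms at 35°, five
  flip angles 5–35° at 0.12 ms) yields voxel-wise *F* and *k_f*; the
  extremal-pulse-duration pair yields the magnetization-transfer ratio
  MTR = 100·(S_ref − S_MT)/S_ref;
* **DTI** — log-linear tensor fit of a 30-direction b = 900 s/mm²
  acquisition; FA, MD, AD, RD from the sorted eigenvalues;
* **lesion-centered statistics** — per-lesion ROI medians against a
  mirrored contralateral normal-appearing white-matter reference,
  relative differences `100·(lesion − ref)/ref`, re-indexed by month
  relative to each lesion's appearance, aggregated across lesions
  (mean ± SE, t-based 95% CI), with Bonferroni-corrected paired t-tests
  at the pre-lesional timepoints.

Because the underlying clinical cohort is not public, the package
includes a first-class synthetic cohort generator (`mtdti.phantom`)
that emulates the study design — 19 subjects scanned bimonthly for a
year plus a month-24 follow-up, 21 lesions appearing in 7 subjects,
missed examinations — with lesion parameter trajectories anchored to
the published effect tables.  Parameter recovery on this cohort is the
package's validation instrument.  See `docs/methods.md` for the models
and their assumptions.

## Worked example

```python
from mtdti import default_config, run_cohort_pipeline

cfg = default_config()                      # the full study design
cohort, maps, records, table = run_cohort_pipeline(cfg, seed=1)

m0 = table.aggregates.query("rel_month == 0").set_index("metric")
print(m0[["n", "mean", "ci_low", "ci_high"]].round(1))
```

which prints the across-lesion mean relative difference (%) to
contralateral NAWM at the detection timepoint:

```
         n   mean  ci_low  ci_high
metric
AD      21    1.2     0.3      2.2
F       21  -73.0   -78.0    -68.1
FA      21  -33.0   -39.7    -26.4
MD      21   22.4    17.1     27.7
MTR     21  -37.1   -40.9    -33.3
RD      21   53.1    41.3     65.0
T1      21   92.6    71.7    113.6
T2      21  159.9   113.2    206.7
kf      21  -76.2   -80.1    -72.3
```

i.e. at the moment a lesion becomes visible, the restricted-pool
fraction F and exchange rate k_f have dropped by about three quarters,
the relaxation times have roughly doubled, MTR is down by about a
third, and diffusion becomes faster and less anisotropic (RD up ~53%,
FA down ~33%) — the fitted pipeline recovers the trajectories the
cohort was generated with.  `table.tests` holds the corrected pre-lesional test
family: with the default design the qMT parameters are already
significant (α* = 0.05/25 = 0.002) two months before appearance and
MTR four months before, while no DTI metric reaches corrected
significance (α* = 0.05/16) pre-lesionally.

The same workflow is scriptable from a shell:

```
mtdti simulate  --config cfg.yaml --seed 1 --out work/
mtdti fit-relax --out work/   &&   mtdti fit-qmt --out work/
mtdti fit-dti   --out work/   &&   mtdti analyze --out work/
mtdti report    --out work/   # evolution figures, mean ± CI per metric
```

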