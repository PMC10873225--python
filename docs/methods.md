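# Methods

`mtdti` reproduces, on synthetic data, a longitudinal analysis of newly
appearing multiple-sclerosis white-matter lesions with quantitative
magnetization-transfer (qMT) and diffusion-tensor (DTI) imaging.  This
note records the models, the generator's assumptions, the numerical
choices, and the limits of what the synthetic validation can show.

## Signal models

**SPGR.** Ideally spoiled gradient echo, Ernst steady state
`S = M0 sin a (1 - E1) / (1 - E1 cos a)`, `E1 = exp(-TR/T1)`.

**bSSFP.** On-resonance, alternating-phase balanced SSFP,
`S = M0 sin a (1 - E1) / (1 - (E1 - E2) cos a - E1 E2)`.  No
off-resonance profile or banding is modelled: the analysis consumes
on-resonance voxel values only.

**Two-pool MT-bSSFP.** The free (water) pool exchanges longitudinal
magnetization with a restricted (macromolecular) pool.  We do not
transcribe a closed form; the steady state is *defined* as the fixed
point of the affine once-per-TR period map on the state
`m = (My_f, Mz_f, Mz_r)`:

1. relaxation–exchange over TR — transverse decay `E2`, and the
   longitudinal pair evolving under
   `dMz_f/dt = (M0 - Mz_f)/T1 - kf Mz_f + kr Mz_r`,
   `dMz_r/dt = (F M0 - Mz_r)/T1r - kr Mz_r + kf Mz_f`, `kr = kf/F`,
   integrated exactly with the 2x2 matrix exponential;
2. alternating RF phase (`My_f -> -My_f`);
3. the RF pulse: instantaneous rotation of the free pool by the
   effective flip angle, and attenuation of `Mz_r` by `exp(-W TRF)`
   with the hard-pulse mean saturation rate
   `W = pi (alpha/TRF)^2 G(0)`.

The fixed point `m* = (I - P)^{-1} q` is solved per voxel (vectorized
Cramer's rule); the signal is the transverse component after the pulse.
The test-suite verifies the fixed point against (a) a 2^40-period
iteration of the same map and (b) a brute-force ODE integration of the
relaxation–exchange equations with discrete pulse events, and verifies
exact collapse to the single-pool bSSFP formula at `F = kf = 0`.

Assumptions: the RF pulse rotates the free pool instantaneously but
saturates the restricted pool over its finite duration TRF (valid for
TRF << TR); pulse shape factor 1 (hard-pulse equivalence, configurable);
restricted-pool constants fixed at `T1r = 1.0 s` and
`G(0) = 1.4e-5 s` (super-Lorentzian lineshape at zero offset, standard
white-matter values at clinical field strength), configurable but held
fixed in fits.

**DWI.** Mono-exponential tensor signal `S0 exp(-b g^T D g)`.

## Parameter estimation

* **DESPOT1/DESPOT2**: exact two-point linearized inversions (the
  protocol acquires exactly two SPGR and two bSSFP flip angles), with
  per-voxel effective flip angles `alpha_eff = alpha_nominal * B1`.
  Voxels with a linearized slope outside the physical interval are NaN
  and counted, never clipped.  Values outside T1 in [0.05, 10] s or T2
  in [0.005, 5] s are flagged implausible but reported raw.
* **Two-pool fit**: bounded trust-region least squares over
  `(F, kf, M0)` on all ten MT-weighted scans jointly (five pulse
  durations 0.12–1.5 ms at 35 deg; five flip angles 5–35 deg at
  0.12 ms), with T1/T2 fixed from relaxometry (staged processing).
  Start point (0.1, 3 s^-1, scaled from the data), bounds F in [0, 0.5],
  kf in [0, 50] s^-1, parameter tolerance 1e-10 — deterministic.
  The TR of an MT scan is linearly interpolated in TRF between
  2.55 and 3.93 ms (the acquisition reports only this TR range).
* **MTR** = 100 (S_ref - S_MT)/S_ref from the extremal-pulse-duration
  pair at 35 deg (longest pulse = reference, shortest = MT-weighted) —
  the pair with the largest MT dynamic range; configurable.
* **Tensor fit**: ordinary least squares on log-signal (WLS behind a
  flag), non-positive signals excluded voxel-wise with a minimum-count
  guard; eigenvalues are never clipped, non-positive-definite fits are
  flagged.  Scalar maps (FA, MD, AD, RD) are resampled from the 2 mm
  DWI grid onto the 1.3 mm MT grid by trilinear interpolation in world
  coordinates.

Measured single-voxel precision of this protocol at SNR 80 (Monte
Carlo, run in the test-suite): median |dF/F| ~ 8%, median |dkf/kf| ~ 5%,
essentially unbiased; ROI medians over typical lesion masks reduce this
to ~2–3% per lesion.

## Synthetic cohort generator

The generator emulates the *design* of the study, not its anatomy: a
19-subject cohort scanned at months 0, 2, 4, 6, 8, 10, 12 and 24, of
which 7 subjects develop 21 new lesions (1–9 per subject), with six
whole missed examinations by four subjects and six subjects each
missing DTI at one timepoint.  The head model is a mirror-symmetric
ellipsoidal phantom (WM core, GM shell, two CSF ventricles) at
48x48x48 voxels of 1.3 mm (MT grid) and 31^3 voxels of 2 mm (DWI
grid).  Tissue values (NAWM F = 0.157, kf = 4.45 s^-1, T1 = 0.779 s,
T2 = 45 ms; WM eigenvalues (1.3, 0.45, 0.45) um^2/ms) are standard
1.5 T white-matter values.

**Lesions** are ellipsoids (axis ratios 1–2.5) with volumes drawn from
a truncated normal (mean 71, SD 60, range 12–201 mm^3), placed in one
hemisphere's WM with their midsagittal mirror reserved as the
contralateral reference region.  Analysis masks are the lesion scaled
by 0.8 (the study drew masks slightly smaller than the visible lesion
to avoid partial-volume contamination); the reference mask is the
mirrored analysis mask.

**Trajectories.** Each metric's lesion-vs-contralateral relative
difference follows a piecewise-linear function of the month relative to
appearance, anchored at the published aggregate values (0% at and
before month -12; the early/late endpoints of the printed pre-lesional
ranges at months -10 and -4; the printed values at -2, 0 and the
post-detection plateau).  Between-lesion heterogeneity: each lesion
draws one shared "severity" deviate z (clipped to +/-2), and its effect
at any month is `mean(t) + z * sd(t) * direction`, where `sd(t)` is the
between-lesion SD implied by the printed CIs (SE = half-width /
t-quantile at the listed n, SD = SE sqrt(n)).  A single shared z makes
all of a lesion's metrics move coherently, as severity does.

Only F, kf, T1, T2 (qMT) and FA, RD (DTI) are imposed on the truth
maps.  MTR is emergent from the two signal models; MD and AD are
emergent from the axially-symmetric eigenvalue solution (RD fixes the
transverse eigenvalue, FA then fixes the axial one in closed form) —
four DTI metrics cannot be imposed on three eigenvalue degrees of
freedom.  Physical clamps (F > 0, T2 <= T1, eigenvalues > 0) guard
extreme severity draws.

**Acquisition.** Per-voxel signals use effective flip angles
`alpha_nominal * B1` with a smooth random per-subject B1 field spanning
about [0.9, 1.1].  The relaxometry bSSFP pair is simulated with the
single-pool model (acquired MT-minimized), the ten MT scans with the
two-pool model, DWI on its own coarser grid.  Noise is additive
Gaussian (Rician behind a flag; the high-SNR magnitude bias is out of
scope) with sigma = (mean NAWM signal of the minimally saturating MT
scan)/SNR; defaults SNR = 80 for the MT grid and 60 for DWI (two
averages were acquired).  All stages are deterministic given the seed;
the B1 map is "measured" with 0.5% noise.

What the phantom does *not* contain — and hence what passing tests do
not show: real anatomy and registration error, motion, off-resonance
banding, partial-volume mixtures at tissue interfaces beyond the
lesion rim, magnitude-noise bias, scanner drift between sessions, and
any lesion biology beyond the anchor tables (e.g. contrast-enhancement
dynamics).

## Statistics

ROI medians over finite in-mask voxels (mean-of-middle convention);
relative difference `100 (lesion - reference)/reference`; observations
re-indexed by month relative to appearance (missed examinations simply
produce no observation; the month-24 follow-up maps to each lesion's
exact relative month).  Aggregates: mean, SE = SD/sqrt(n), and t-based
95% CI (the published tables print CIs without stating the method; the
t-quantile choice is ours).  Pre-lesional comparison: two-sided paired
t-tests of lesion vs contralateral medians per (metric, pre-lesional
relative month), Bonferroni-corrected with the family size derived
from the data — metrics x months with at least two paired observations
— which under the default design gives 25 MTI hypotheses
(alpha* = 0.002) and 16 DTI hypotheses (alpha* = 0.003125).  Identical
pairs are treated as t = 0, p = 1.  Pairing lesion-vs-reference medians
(rather than testing relative differences against zero) follows the
stated comparison of pre-lesional against contralateral tissue.

## Problem sizes used in the validation suite

The full-pipeline recovery check runs one default 21-lesion cohort
(about 90 s on one core); the sensitivity-ordering check uses five
seeded cohort replicates and requires the published ordering (qMT
significant from month -2, MTR from month -4, DTI never pre-lesional)
in at least 80% of them; the null calibration runs 200 zero-effect
replicates at the ROI-median level through the same statistical stack
(a full-image null pipeline per replicate would add nothing to the
property being calibrated, which is the corrected test family).  These
replicate counts are the package's validation design.

## Known limitations

* The emergent MTR lesion effect at detection is about -31% at the
  anchor point and -36% across lesions once between-lesion
  heterogeneity is drawn (the MTR response is concave in all four qMT
  parameters, so symmetric parameter scatter shifts the mean), versus
  the published -27.7%.  Reproducing the printed MTR effect exactly
  would require either a different (unreported) reference-scan design
  or correlated heterogeneity beyond what printed CIs constrain.  MD
  and AD, also emergent, land at about +22% and +2% versus the printed
  +37.5% and +18.4%: with axially-symmetric tensors the printed FA and
  RD changes are geometrically incompatible with the printed AD/MD
  changes at this baseline anisotropy.
* Single-voxel F precision is protocol-limited (~8% at SNR 80);
  analyses should always aggregate over ROIs.
* The generator shares one head geometry across subjects; only B1,
  lesion placement and noise vary.
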