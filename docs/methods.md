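# Methods

This note documents the models, numerical choices and known limitations of
`laminarhrf`. It is written for a reader who wants to judge what the package
computes and what its tests do and do not establish.

## The measurement problem

Laminar (cortical-depth-resolved) BOLD fMRI confounds neuronal signals with
the vascular architecture: venous blood volume, vessel size and
cerebrovascular reactivity all increase toward the pial surface, inflating
gradient-echo (GE) response amplitudes superficially regardless of neuronal
activity. The analysis implemented here separates these contributions within
a single run that combines (a) a block gas challenge — hypercapnia at +5 and
+10 mmHg end-tidal CO2 and hyperoxia at +350 mmHg end-tidal O2 — probing
purely vascular reactivity, and (b) 71 brief (200 ms) visual stimuli probing
the neurovascular impulse response under each gas state. Spin-echo (SE)
acquisitions, sensitive mainly to microvasculature, are represented as an
alternative planted parameter regime ("SE-like") rather than a separate
physics model.

## Pipeline stages

### Localizer GLM (CVR and CBVvO2)

The run (820 volumes, TR 0.85 s, 697 s) is modeled voxel-wise by OLS with
regressors: constant; the end-tidal traces ΔPetCO2(t), ΔPetO2(t) in mmHg
relative to the pre-task baseline (unconvolved); the visual event train
convolved with a canonical double-gamma HRF; discrete-cosine drift terms
below 7·10⁻⁴ Hz (none exist for a 697 s run — detrending reduces to the
constant term); and motion (6), RVT and BPM nuisance series, detrended with
the same cosine set but never convolved.

Reactivity maps are

    CVR    = 100 · β_CO2 / β_0   [%BOLD / mmHg CO2]
    CBVvO2 = 100 · β_O2  / β_0   [%BOLD / mmHg O2]

where β_0 is the constant-column beta. Because the gas regressors are
referenced to baseline (zero during room air) rather than de-meaned, β_0
estimates the room-air resting signal itself; de-meaned gas regressors would
fold the mean evoked gas response (~3–4% at realistic planted values) into
the denominator and bias both ratios low by that amount. Voxels with β_0 ≤ 0
are flagged invalid.

Voxel selection: two-sided p-values for the CO2 and O2 betas are
Benjamini–Hochberg corrected at q = 0.05; the visual t-map is thresholded
one-sided at t > 1 without correction. The default selection is
(FDR CO2 ∪ FDR O2) ∩ (t_visual > 1) — the "commonly responsive" reading — with
a `union-all` mode available since the literal union reading also appears in
descriptions of this design.

### FIR deconvolution

Selected voxels are deconvolved with a condition-specific FIR basis:
L = ⌈20 s / 0.85 s⌉ = 24 free lag coefficients per gas condition, each event
contributing to the condition containing its onset (onsets rounded to the
nearest TR sample; 200 ms stimuli at 850 ms sampling cannot support sub-TR
modeling). The design additionally carries the 0.01 Hz high-pass cosine set
(13 cosines), the constant, both end-tidal traces and the high-passed
nuisance series; fitting everything jointly is the Frisch–Waugh equivalent
of residualizing data *and* FIR columns against those confounds, and avoids
the bias of filtering only the data. Lag betas are scaled to %BOLD by the
localizer's β_0 so all amplitudes share one scale.

### Laminar aggregation

Each voxel carries a membership-probability vector over six equivolume depth
bins (deep → superficial) plus a pial-vein bin. The laminar HRF of bin b is
the probability-weighted average Σ_v p_vb h_v / Σ_v p_vb over selected
voxels, with vein-flagged voxels (p_vein > 0.5) excluded from the six
laminae and pooled into the vein bin. Aggregation precedes quantification:
curves are averaged per bin, then fitted and quantified (not
quantify-then-average), which is how laminar HRF descriptors are defined
here.

### Inverse-logit quantification

Each laminar curve is fitted with h(t) = Σ_{i=1..5} a_i σ((t−T_i)/D_i),
σ the logistic function: five components can express an initial dip, rise,
peak, post-peak decline and undershoot. The fit is bounded nonlinear least
squares (trf, analytic Jacobian) with |a_i| ≤ 5 × data range, T_i ∈ [−2,
window+2] s, D_i ∈ [0.05, 10] s; 8 multistarts jitter a heuristic start
(T ≈ {1,4,7,11,16} s, alternating-sign amplitudes scaled to the data
extremum) plus a zero-amplitude start that guarantees the final RSS never
exceeds the zero curve's. The parameters are not identifiable individually —
only the fitted curve is interpreted.

Descriptors are read off the fitted curve on a dense 0.01 s grid over
[0, 20] s, first-crossing/first-argmax tie-breaks throughout:

* amplitude — curve maximum;
* TTP — time of that maximum (stimulus at t = 0);
* onset — intercept with the pre-onset baseline (curve mean over
  t ∈ [0, 0.5] s, since "baseline" needs an operational definition) of the
  straight line through the first upward crossings of 20% and 80% of the
  baseline-to-peak height before the peak;
* FWHM — width of the contiguous region around the peak above 50% of the
  baseline-to-peak height; undefined if the curve never falls below half
  height on one side.

Detectability replaces visual rating: a curve counts as detectable when its
baseline-to-peak height exceeds k × residual SD of the fit (k = 2 by
default); otherwise TTP/onset/FWHM are set to NaN. Limitation: because the
flexible IL5 fit absorbs most of the noise in a pure-noise curve, the rule is
conservative only near zero amplitude — a noise-only curve at finite tSNR can
still pass it. In this package's cohorts that is immaterial (planted
amplitudes are ≥ 10× the bin-level noise floor), but the flag should not be
read as a general false-positive control on real data.

### CBVvO2 normalization, depth slopes, group statistics

Amplitude profiles are divided bin-wise by the same subject's CBVvO2 profile
(a.u.), removing the common venous-volume weighting; cells with missing or
non-positive CBVvO2 become missing, never imputed. Depth trends are
summarized participant-wise: OLS slope of the profile against bin index
1..7 (pial-vein bin included by default, excludable by flag) for subjects
with ≥ 3 defined bins, then a one-sample t-test of subject slopes against
zero with a 95% CI. Group centers are mean ± SD for complete profiles and
median with 95% CI when any subject is missing.

Condition and sequence effects use within-block rank tests: Friedman (with
average ranks and tie correction) on complete tables, and the
Skillings–Mack statistic — the missing-cell generalization, a quadratic form
of the block-scaled rank scores against the pseudo-inverse of their null
covariance — when cells are missing. Both reduce to the same statistic on
complete tie-free tables. With fewer than 8 blocks, p-values come from a
seeded within-block permutation null instead of the χ² asymptotics. Post
hocs are Wilcoxon signed-rank tests (normal approximation for the z
statistic) over an explicit comparison family, Holm-adjusted; comparisons
with fewer than 5 usable pairs are flagged underpowered and left unadjusted.
The identity of the original analysis' "post hoc z" is not documented, so the
signed-rank choice is a reconstruction consistent with the rank-based
omnibus tests.

## The synthetic-experiment generator

The generator emulates the study conditions end to end; every parameter
below is a config default, not a constant.

* **Gas traces.** Block targets (+5, +10 mmHg CO2; +350 mmHg O2 over
  baselines of 38 / 100 mmHg) approached with a first-order exponential
  (τ = 10 s, a realistic end-tidal transition for sequential gas delivery),
  plus white breath-to-breath jitter (SD 0.5 mmHg CO2, 5 mmHg O2). The
  protocol's stated blocks cover 590 s of the 697 s run; the remaining 107 s
  are modeled as a terminal room-air period.
* **Events.** 71 events; ISI = 3 s + Exp(7 s) truncated at 28 s, schedules
  rejection-sampled until all events fit in [30, 677] s. The scale 7 s makes
  the task span the run (mean ISI ≈ 9.2 s), which is also what keeps the
  single-amplitude visual regressor's residual from acquiring a block-locked
  mean. Note the implied event counts (~23 in the 200 s room-air block, ~14
  per 120 s challenge block) are what 71 events in this run length force;
  lower printed counts sometimes quoted for this design are not jointly
  consistent with 71 events and a 697 s run.
* **Geometry.** 7 bins × 60 voxels, no spatial structure (the laminar
  analysis pools voxels, it does not smooth). Partial-volume mixing: each
  voxel leaks `mixing` (default 0.25, a realistic level for ~1 mm voxels on
  a ~2 mm ribbon) of its probability to adjacent bins, edge spill folded
  back inward. Mixing attenuates planted depth gradients by a deterministic
  factor through the generate-and-reaggregate round trip (~5–10% for linear
  profiles; pinned by a matrix-product oracle test).
* **Forward model.** S_v(t) = S0_v [1 + CVR_v ΔPetCO2/100 + CBVvO2_v
  ΔPetO2/100 + Σ_k h_{v,cond(k)}(t−t_k)/100] + drift + nuisance coupling +
  AR(1) noise, with S0_v ~ 1000 × (1 ± 5%). Per-voxel parameters are the
  depth-probability mixtures of the per-bin truth, so the generative
  geometry matches the aggregation the estimator performs.
* **Planted HRFs.** A double-gamma template is affinely calibrated per bin
  and condition: time-scaled to the planted FWHM, shifted to the planted
  TTP, scaled to the planted peak amplitude. An affine time map has three
  degrees of freedom, so onset cannot be set independently; the implied
  onset is computed numerically and stored as the planted truth.
* **Noise.** AR(1) (ρ = 0.3) plus white innovation scaled to tSNR 40 at
  baseline; slow drift (0.2% RMS over three low-order shapes, deliberately
  outside the 7e-4 Hz detrending span); motion/RVT/BPM coupling at 0.1% RMS
  per series so the nuisance regression is consequential.

What the generator does **not** emulate: spatial autocorrelation, motion
displacement requiring realignment, EPI distortion/k-space artifacts,
hemodynamic dispersion of the gas response (an optional robustness kernel
notwithstanding), vascular network biophysics, or HRF shape families outside
the calibrated double-gamma. Passing recovery tests therefore demonstrates
estimator correctness and calibration under this generative model, not
robustness to real-scanner artifacts.

## Recovery experiments and their design

The benchmark cohorts (`laminarhrf.experiments`) plant reported group values
and re-estimate them from 9 subjects × 420 voxels at tSNR 40:

* Reactivity cohorts (GE-like and SE-like) plant uniform CVR/CBVvO2 with
  visual amplitudes held **equal across gas conditions**. Condition-locked
  amplitude modulation is a real phenomenon, but it leaks into the
  single-visual-regressor localizer as a block-correlated residual (a ~4%
  CVR bias at the planted modulation depth); the reactivity experiment
  isolates the reactivity estimator, and the modulation is probed by the
  condition cohort instead.
* The condition cohort plants condition-dependent amplitudes (2.17 / 1.77 /
  1.20 / 2.35 %BOLD) with TTP 4.09 s and FWHM 3.66 s and recovers
  per-condition amplitudes and the room-air TTP median.
* The profile cohort plants linear depth profiles (CVR slope 0.21 %/mmHg
  per lamina, amplitude slope 0.31 %BOLD per lamina, CBVvO2 slope 0.0031)
  and recovers participant-wise slopes. This cohort uses one-hot depth maps:
  under nonzero mixing the planted gradient is attenuated by the known
  partial-volume factor while the 9-subject slope CI is far narrower than
  that attenuation, so an unbiasedness-with-coverage check is only coherent
  with the mixing confound removed. The attenuation factor itself is tested
  separately on the depth-map module.

Noiseless consistency checks (bias ≤ 1e-6) additionally snap event onsets to
the TR grid and plant descriptors equal to the canonical kernel's own, so
the forward signal lies exactly in the estimator's model span; they also
lengthen the canonical-kernel truncation from its 32 s default, whose
undershoot tail otherwise contributes an O(1e-6) mismatch of its own.
Problem sizes in the test suite (subjects per cohort, Monte-Carlo draws) are
chosen so the full suite completes in minutes on one core while leaving
every tolerance comfortably non-binding.

## Numerical choices and degenerate inputs

* OLS via pseudo-inverse of the normal matrix; all-zero regressors (e.g. the
  visual column of an empty schedule) are tolerated and estimate zero, but
  genuine collinearity raises immediately.
* Canonical kernel: double-gamma, peak delay 6 (mode ≈ 5 s), undershoot
  delay 16, ratio 1/6, unit peak after TR sampling, truncated at 32 s
  (configurable).
* Rank tests: average ranks for ties; tie-corrected variance in Friedman;
  the Skillings–Mack covariance uses a pseudo-inverse with rank check, and a
  degenerate covariance (no within-block comparisons) is an error.
* Degenerate slope sets (all subjects identical) report a point CI rather
  than dividing by a zero SE.
* Every stochastic step draws from `numpy` Generators fanned out of a single
  run seed via independent substreams, so any subject or stage can be
  regenerated in isolation and reports are byte-identical under a fixed
  seed.

## Known limitations

* The localizer's single visual regressor mis-models condition-dependent
  amplitude modulation; at the modulation depth seen in GE data this leaves
  a few-percent bias on CVR. A condition-split localizer would remove it at
  the cost of deviating from the analysis being reproduced.
* The detectability rule is weak against structured noise (above).
* FWHM is undefined for curves that never drop below half height within the
  window — common for wide responses under strong hypercapnia — and is
  propagated as missing, which is why the group stage switches to
  median/CI and Skillings–Mack in its presence.
* The IL5 parameterization is redundant; only curve-level quantities are
  meaningful.
* SE acquisitions differ from GE in more than their planted parameter
  regime (resolution, T2 weighting, partial-volume behavior); none of that
  physics is modeled.
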