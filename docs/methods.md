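# Methods

## Measurement model

The pulmonary transit time is estimated by the peak-to-peak method:
`PTT = t_peak(LV) − t_peak(RV)`, where each `t_peak` is the time of the
first-pass signal-intensity maximum of the chamber's time–signal curve.
Curves are obtained by arithmetic averaging of the perfusion signal over
all ROI voxels at every frame; averaging (rather than a maximum or a
trimmed statistic) is deliberate — it suppresses voxel noise and mitigates
per-voxel saturation in the bright blood pool. Frame time is the ECG
trigger time; any constant acquisition offset cancels in the peak-to-peak
difference.

Heart-rate normalization follows Bazett: `nPTT = PTT / sqrt(RR)` with `RR`
in seconds, so nPTT is of the same magnitude as PTT for RR near 1 s. `RR`
is the mean successive difference of the trigger times, which equals the
mean R-R interval under ECG triggering (one frame per heartbeat).

### First-pass peak detection and recirculation exclusion

After its first pass the bolus re-arrives, attenuated and dispersed, via
the systemic circulation. Only the first pass defines PTT, so detection is
windowed:

1. Baseline = median of the first `baseline_frames` (default 3) values.
2. Candidate peaks = local maxima whose topographic prominence is at least
   `prominence_fraction` (default 0.3) of (global max − baseline).
3. The earliest candidate is the first-pass peak; later bumps are treated
   as recirculation regardless of height up to the prominence criterion.
4. The search window runs from the last pre-upslope baseline crossing to
   the first local minimum after the peak.

A flat curve raises "no bolus detected". A peak on the first or last frame
sets the `WINDOW_TRUNCATED` QC flag; a first-pass amplitude under
`snr_min` (default 5) baseline noise standard deviations sets `LOW_SNR`.
A negative or near-zero LV−RV difference is flagged (`NEGATIVE_PTT`,
`ZERO_PTT` when |PTT| is below one tenth of the median frame interval)
rather than raised: it marks an implausible measurement for review.

### Sub-frame refinement

Perfusion frames arrive roughly once per heartbeat (median interval about
1.16 s in the motivating cohort), yet PTT is conventionally reported to
0.1 s, which implies sub-frame peak localization. Two refinements are
provided:

* **parabolic** (default): vertex of the exact quadratic through the three
  samples around the discrete maximum. The quadratic is fitted through the
  actual (possibly jittered) sample times, reducing to the classic
  `0.5·(y_l − y_r)/(y_l − 2 y_c + y_r)` offset for uniform spacing. Falls
  back to the discrete sample when the three points are not concave or the
  peak sits on a boundary.
* **gamma_fit**: a gamma-variate `A·(t−t0)^α·e^{−(t−t0)/β}` fitted from the
  last baseline crossing to the first post-peak sample below 50% of peak
  amplitude; the analytic maximum `t0 + α·β` is returned. Falls back to
  parabolic when the window is too short (< 5 samples) or the fit fails.

On noise-free curves sampled at 1.0 s the worst-case recovery error over
transit delays of 4–14 s is ≤ 0.43 s discrete and ≤ 0.05 s parabolic
(recomputed by `scripts/acceptance.py`), comfortably inside the half-frame
and quarter-frame bounds the estimators are designed for.

## Synthetic data

### Curve pairs

The RV first pass is a gamma-variate with arrival `t0`, shape `α`, scale
`β` and unit-peak normalization times `amplitude`; its maximum is at
`t0 + α·β` analytically. The LV first pass is the convolution of the
(baseline-subtracted) RV first pass with a unit-area gamma-density
transport kernel of mean `transport_delay` and shape `transport_shape`;
large shape approaches a pure delay, small shape a strongly dispersed
pulmonary passage. Recirculation adds `recirc_gain` times each chamber's
first pass, delayed by `recirc_delay` (default 12 s) and further dispersed
by a kernel of doubled scale — enough structure to exercise the exclusion
logic without a circulatory loop model. The continuous model is evaluated
on a 1 ms grid; ground-truth peak times come from that grid (RV
analytically), so `ptt_true` is the exact peak-to-peak transit of the
noise-free model. Sampling then mimics ECG triggering: cumulative R-R
intervals drawn `N(rr_mean, rr_sd)` floored at 0.3 s, with independent
Gaussian noise per sample.

Noise is Gaussian, not Rician: blood-pool signals sit far above the noise
floor, and Gaussian noise keeps the truth analytic. Saturation physics,
motion, and coil-profile inhomogeneity are not modelled — passing tests
shows the estimator chain is correct under the stated model, not that it
is robust to those effects.

Defaults (`BolusParams`): `t0` 3 s, `α` 3, `β` 1.2 s (RV peak 6.6 s),
amplitude 100 a.u. over a baseline of 20 a.u., transport delay 7 s
(control-range transit), shape 30, recirculation gain 0.30 at +12 s, noise
2 a.u., `rr_mean` 1.16 s with 0.15 s jitter, 65 beats — one plausible
rest-perfusion acquisition.

### Cohorts

Each patient carries ordinal DD (0–3) and MVR (0–3) grades; "relevant"
disease means grade ≥ 2 on either axis. Grades are drawn independently
with frequencies proportional to the reference cohort counts (DD
36/14/27/6, MVR 34/28/14/5). PTT is log-normal per grade cell:

```
log PTT ~ N( log 7.0 + e_dd[g_dd] + e_mvr[g_mvr], 0.25² )
```

The no-disease cell has median 7.0 s, matching the observed control range
(patients without relevant DD or MVR: median 7.0 s, IQR 6.0–8.5 s). The
grade effects `e_dd = (0, 0.05, 0.24, 0.39)` and
`e_mvr = (0, 0.04, 0.32, 0.47)` were **calibrated, not measured**: no
per-grade summary statistics are published, so the magnitudes were solved
once from the mixture-of-lognormals AUC formula to reproduce the reported
discriminations of PTT (AUC ≈ 0.73 for relevant DD, ≈ 0.80 for relevant
MVR) in expectation, and then frozen. Consequences of this structure worth
knowing:

* DD and MVR grades are independent in the generator; real grades
  co-occur. With independent additive effects the *union* outcome
  (DD or MVR) is discriminated better (expected AUC ≈ 0.81) than the
  reported 0.74.
* R-R intervals (`N(1.16, 0.2²)` s, floored at 0.4 s) are independent of
  disease grade, so nPTT carries no information beyond PTT here and its
  expected AUC equals PTT's. The reported nPTT advantage for DD (0.81 vs
  0.73) would require heart rate to covary with disease severity, which
  the cohort model deliberately does not assume.
* At the study scale of n = 83 the sampling SD of an AUC is ≈ 0.06; single
  simulated cohorts legitimately land anywhere in roughly 0.63–0.90 for DD.

## Diagnostic statistics

* **AUC** is the tie-corrected pairwise probability
  `P(score⁺ > score⁻) + ½·P(tie)`, computed from midranks; it equals the
  normalized Mann–Whitney statistic and the trapezoidal area under the
  empirical ROC curve with the same tie handling. Higher score ⇒ positive
  test throughout (high PTT suggests disease).
* **CI**: stratified percentile bootstrap — resampling within each class
  preserves `n_pos`/`n_neg`, so no resample loses a class. Default 2000
  resamples, seeded. Coverage of the 95% interval verified at 95% ± 3%
  over 500 simulated replicates in the acceptance suite.
* **p-value**: two-sided Mann–Whitney rank-sum against AUC = 0.5, normal
  approximation with tie and continuity correction; a single canonical
  path (no DeLong) keeps the implementation and its null calibration
  simple to verify. Zero rank variance returns p = 1.
* **Thresholds**: candidate cut-points are midpoints between adjacent
  sorted unique scores plus ±∞. `threshold_at_specificity` returns the
  candidate whose specificity is the *smallest* value ≥ the target (ties
  toward higher sensitivity); the sensitivity variant is symmetric.
  Zero-denominator proportions are NaN with an `undefined` flag, never an
  exception.
* **Stratification**: bins `[<e1)`, `[e1,e2)`, `[≥e2)` (default edges 8
  and 12 s); percentages rounded half-up to whole percent (87.5 → 88).
* **Quartiles**: boundaries are the 25th/50th/75th percentiles with linear
  interpolation; assignment is half-open upward (group 1: v ≤ Q1, group 2:
  Q1 < v ≤ Q2, …), so a degenerate all-equal sample lands in group 1. For
  n = 83 and distinct values this yields the 21/21/20/21 split.
* **Group comparisons**: Kruskal–Wallis (tie-corrected) for > 2 groups;
  rank-sum for two by default; Student's t only when requested *and* a
  Kolmogorov–Smirnov normality check (sample-moment reference) passes in
  both groups, otherwise rank-sum with a warning.

## Pipeline and determinism

`run_pipeline` funnels all randomness through the single run seed (cohort
draw, per-patient curve seeds, bootstrap). Output files contain no
timestamps, so a rerun with the same config is byte-identical; the
manifest records the config, its SHA-256 hash and the file list. A failing
stage raises `PipelineError` naming the stage, and the CLI converts it to
a non-zero exit.

In simulate mode each patient's curve pair uses their drawn PTT as the
transport-kernel mean; the dispersion of the kernel shifts the true
peak-to-peak transit slightly and monotonically relative to that mean,
which preserves ranks and therefore every rank-based statistic downstream.
Diagnostics run on the *measured* PTT/nPTT, exercising the whole chain.

## Problem sizes

The test suite simulates at the scales the analyses are defined at: 83
patients for cohort fixtures, 60-frame curves on a 1 s grid for recovery,
500 replicate datasets (n = 200 per class, 500 resamples) for bootstrap
coverage, and 2000 replicates for null-calibration of the nonparametric
p-values. The acceptance script uses a full 2000-resample bootstrap on the
83-patient end-to-end run.

## Known limitations

* Masks are inputs; ventricle segmentation is out of scope.
* No motion correction, DICOM ingestion, or saturation/T1 physics.
* The cohort model is a calibrated stand-in: it reproduces control-range
  PTT and the targeted PTT discriminations in expectation but not the
  joint grade structure or any heart-rate–disease coupling of real
  patients (see above).
* Stress-perfusion PTT, centroid/up-slope transit estimators,
  deconvolution-based transit-time spectra and multivariable modelling are
  intentionally not implemented.
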