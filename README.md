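# pttkit

Pulmonary transit time (PTT) from first-pass perfusion cardiovascular MR,
and its evaluation as a diagnostic biomarker.

PTT is the time a contrast bolus needs to travel from the right-ventricular
(RV) to the left-ventricular (LV) blood pool through the pulmonary
circulation. It integrates preload, biventricular function, valve
competence and the pulmonary microcirculation into a single number that can
be read off a routine rest-perfusion scan, and it is elevated in patients
with relevant diastolic dysfunction (DD) or mitral valve regurgitation
(MVR) — which makes a *short* PTT useful to rule those out.

`pttkit` implements the complete measurement and evaluation chain for
researchers working with perfusion time-series:

* **Curve extraction** — per-frame arithmetic ROI averaging of a 2D+t
  perfusion stack into RV/LV time–signal curves (NIfTI + sidecar JSON or
  CSV in, CSV out).
* **Peak-to-peak PTT** — `PTT = t_peak(LV) − t_peak(RV)` using first-pass
  peaks only: the first sufficiently prominent local maximum wins and the
  search window closes before the recirculation bump. Sub-frame parabolic
  refinement (default) or a gamma-variate fit recovers precision lost to
  the ~1 s per-heartbeat sampling.
* **Bazett normalization** — `nPTT = PTT / √RR` with the mean R-R interval
  (seconds) taken from the ECG-trigger times.
* **Diagnostic statistics** — AUC as the tie-corrected Mann–Whitney
  probability, stratified percentile-bootstrap CIs, rank-sum p-values,
  sensitivity/specificity/PPV/NPV at chosen or target-derived thresholds,
  PTT-bin stratification tables, quartile baseline tables, Kruskal–Wallis /
  rank-sum / t-test comparisons and Pearson/Spearman correlations.
* **Synthetic ground truth** — a gamma-variate indicator-dilution simulator
  (curves with known transit time, recirculation, R-R jitter, noise) and a
  cohort generator with grade-dependent PTT distributions, so every stage
  is testable without patient data.

## Worked example

```bash
python examples/simulate_and_measure.py
```

```
true transit time     : 8.832 s
estimated PTT         : 9.081 s
absolute error        : 0.249 s
mean R-R interval     : 1.166 s
normalized PTT (nPTT) : 8.409
QC flags              : none
```

The simulator placed the LV first-pass peak 8.832 s after the RV peak; from
the noisy curves sampled once per (jittered) heartbeat, parabolic peak
refinement recovers the transit to within a quarter of a frame interval.
nPTT divides the PTT by √RR so tachycardic and bradycardic patients become
comparable.

```bash
python examples/stratify_rule_out.py
```

```
  bin  n  n_positive  pct_positive
  < 8 46          13            28
 8-12 29          16            55
>= 12  8           7            88
pooled positivity above 8 s : 62%
NPV of the PTT < 8 s rule-out: 72%
```

The fraction of patients with relevant DD or MVR climbs from 28% below 8 s
to 88% above 12 s — a PTT under 8 s makes relevant disease unlikely.

`examples/cohort_roc.py` runs the ROC analysis on a simulated 83-patient
cohort and `examples/extract_from_stack.py` demonstrates ROI extraction
from an image stack. The same pipeline is scriptable end to end:

```bash
pttkit run --mode simulate --seed 7 --out out/   # simulate → measure → evaluate
pttkit run --mode cohort --seed 7 --out out/ --cohort-csv cohort.csv
```

## Layout

- `src/pttkit/curves.py` — perfusion series, ROI masks, curve extraction, I/O
- `src/pttkit/ptt.py` — peak detection, PTT, Bazett normalization
- `src/pttkit/synthetic.py` — curve-pair and cohort simulators
- `src/pttkit/diagnostics.py` — ROC/AUC, thresholds, tables, tests, correlations
- `src/pttkit/pipeline.py`, `cli.py` — orchestration and the `pttkit` command
- `docs/methods.md` — model, assumptions, calibration and limitations
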