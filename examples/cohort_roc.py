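"""Evaluate PTT and nPTT as diagnostic markers on a simulated cohort.

Draws an 83-patient cohort whose PTT rises with diastolic-dysfunction (DD)
and mitral-regurgitation (MVR) grade, then computes the AUC (with a
stratified-bootstrap 95% CI and rank-sum p-value) of each marker for
"relevant" disease (grade > 1), plus the PTT threshold reaching 70%
specificity for DD.
"""

import numpy as np

from pttkit import (
    CohortParams,
    cohort_to_dataframe,
    evaluate_auc,
    simulate_cohort,
    threshold_at_specificity,
)

df = cohort_to_dataframe(simulate_cohort(CohortParams(n_total=83, seed=5)))
print(f"cohort: n={len(df)}, relevant DD {int(df.dd_relevant.sum())}, "
      f"relevant MVR {int(df.mvr_relevant.sum())}")

for score in ("ptt_s", "nptt"):
    for outcome in ("dd_relevant", "mvr_relevant"):
        res = evaluate_auc(df[score].to_numpy(), df[outcome].to_numpy(bool),
                           n_boot=2000, seed=5)
        print(f"AUC {score:5s} vs {outcome:12s}: {res.auc:.2f} "
              f"(CI {res.ci_low:.2f}-{res.ci_high:.2f}; p = {res.p_value:.3g})")

thr, m = threshold_at_specificity(df.ptt_s.to_numpy(),
                                  df.dd_relevant.to_numpy(bool), 0.70)
print(f"70% specificity for DD at PTT >= {thr:.1f} s "
      f"(sens {m.sensitivity:.2f}, NPV {m.npv:.2f})")
# AUC ~0.5 would be chance; values near 0.7-0.8 mean PTT separates diseased
# from disease-free patients well. The NPV is the key rule-out figure: the
# fraction of patients below the threshold who are truly disease-free.
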