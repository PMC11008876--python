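"""Response error, the 18-point exclusion threshold, and the trial codings.

A participant answering 50 on every trial has a mean absolute error equal to
the design's mean distance of the normative answers from 50 — which is why
the compliance cut-off sits at 18 percentage points.
"""

import numpy as np

from causalpress import (
    annotate_normative_and_error,
    apply_exclusions,
    code_explaining_away,
    make_noncompliant,
    prepare_trials,
    simulate_cohort,
)
from causalpress.pipeline import preset_params

c50 = simulate_cohort(1, params=make_noncompliant(mode="constant50"), master_seed=0)
ann = annotate_normative_and_error(c50)
print(f"constant-50 responder mean error: {ann['error_pp'].mean():.2f} pp "
      f"(design mean |normative - 50| = "
      f"{np.abs(100 * ann['normative'] - 50).mean():.2f} pp)")
_, report = apply_exclusions(ann)
print(f"excluded participants: {report.excluded_participants} "
      "(just above the 18 pp cut-off)")

params, _ = preset_params("normative")
norm = simulate_cohort(1, params=params, master_seed=0)
coded = code_explaining_away(annotate_normative_and_error(norm))
sub = coded[coded["away_var"].notna()]
print("\nnormative responder, recoded explaining-away responses by AwayVar:")
print(sub.groupby("away_var")["recoded_response"].mean().round(1).to_string())
print("-> flat at 71.4: the -28.6/+11.4 recoding makes normative explaining "
      "away a zero effect.")

trials = simulate_cohort(4, master_seed=7)
prepared, rep = prepare_trials(trials)
print(f"\npaper-like cohort: {rep.n_retained} retained trials, "
      f"{rep.pct_fast:.1f}% removed as faster than {rep.rt_floor_s} s; "
      f"mean conservatism "
      f"{prepared['conservatism'].mean():.2f} pp (positive = toward 50).")
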