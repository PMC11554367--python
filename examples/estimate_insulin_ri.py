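"""Estimate a fasting-insulin reference interval and score it against truth.

Runs the full indirect pipeline (outlier removal, Box-Cox selection,
Gaussian-mixture deconvolution, truncation, truncated nonparametric
percentiles, bootstrap CIs) on the filtered synthetic cohort, then compares
the recovered bounds with the generator's analytic healthy 2.5th/97.5th
percentiles -- the exercise that is impossible with real data, where truth
is unknown.
"""

import numpy as np

from refrange import (CohortSpec, apply_exclusions, generate_cohort,
                      run_indirect_ri, true_healthy_quantiles)

spec = CohortSpec(seed=7)                     # n = 20,000, 25% contamination
cohort = generate_cohort(spec)
retained, _ = apply_exclusions(cohort)

est = run_indirect_ri(retained["insulin_uU_mL"].to_numpy(), seed=7)
print(f"pipeline: {est.n_input} -> {est.n_after_outliers} after outliers "
      f"-> {est.n_in_window} in window")
print(f"transform: {est.transform.family} (lambda={est.transform.lam}), "
      f"mixture k={est.mixture.k}")
print(f"truncation window: ({est.window.lower:.2f}, {est.window.upper:.2f}) "
      f"uU/mL [{est.window.source}]")
print(f"estimated RI: {est.lower:.2f}-{est.upper:.2f} uU/mL")
print(f"  90% CI lower bound: {est.lower_ci[0]:.2f}-{est.lower_ci[1]:.2f}")
print(f"  90% CI upper bound: {est.upper_ci[0]:.2f}-{est.upper_ci[1]:.2f}")

true_lo, true_hi = true_healthy_quantiles(spec, "all", [0.025, 0.975])
naive = np.quantile(cohort["insulin_uU_mL"], [0.025, 0.975], method="weibull")
print(f"true healthy percentiles: {true_lo:.2f}-{true_hi:.2f} uU/mL")
print(f"recovery error: {100 * (est.lower / true_lo - 1):+.1f}% / "
      f"{100 * (est.upper / true_hi - 1):+.1f}%")
print(f"naive percentiles of the raw mixed sample: "
      f"{naive[0]:.2f}-{naive[1]:.2f} uU/mL "
      f"({100 * (naive[1] / true_hi - 1):+.0f}% upper bias)")
# The naive upper bound is inflated by the pathological tail; filtering plus
# truncation brings the estimate back to within a few percent of truth.
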