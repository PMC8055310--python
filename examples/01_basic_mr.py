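"""Simulate a well-powered two-sample MR dataset and estimate the causal
effect with every core method.

The generator plants a true causal effect of 0.2 (per exposure unit) with
no horizontal pleiotropy, so all estimators should agree near 0.2 and the
heterogeneity test should be quiet.
"""

from mrpipe import (
    Pleiotropy,
    SimulationScenario,
    cochran_q,
    ivw,
    mr_egger,
    orient_exposure_increasing,
    simulate_summary_stats,
    weighted_median,
)
from mrpipe.synthetic_data import to_harmonized

exposure, outcome, truth = simulate_summary_stats(SimulationScenario(
    J=100, beta_true=0.2, seed=7, min_abs_gamma=0.02,
    pleiotropy=Pleiotropy(kind="none"),
))
h = orient_exposure_increasing(to_harmonized(exposure, outcome))

e_ivw = ivw(h)
e_med = weighted_median(h, n_boot=1000, seed=7)
egger = mr_egger(h)
Q, df, q_p = cochran_q(h)

print(f"true causal effect : {truth['beta_true']}")
print(f"IVW                : {e_ivw.beta:.4f} (95% CI {e_ivw.ci_low:.4f} to "
      f"{e_ivw.ci_high:.4f}, p={e_ivw.pvalue:.2e})")
print(f"weighted median    : {e_med.beta:.4f} (se {e_med.se:.4f})")
print(f"MR-Egger slope     : {egger.slope.beta:.4f} "
      f"(intercept {egger.intercept:.5f}, intercept p={egger.intercept_p:.2f})")
print(f"Cochran Q          : {Q:.1f} on {df} df (p={q_p:.2f})")
print()
print("All point estimates sit near the planted 0.2; the near-zero Egger")
print("intercept and non-significant Q indicate no directional pleiotropy.")
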