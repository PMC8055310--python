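"""Multivariable MR over endophenotype clusters of disease variants.

Variants are partitioned (softly, via weights) into mechanism clusters —
the setting where disease-associated variants act through distinct
pathways such as obesity-mediated insulin resistance or high-proinsulin
beta-cell dysfunction.  Joint weighted least squares recovers each
cluster's direct effect on the outcome; an adjustment trait can be
appended as one more exposure column.
"""

import numpy as np
import pandas as pd

from mrpipe import build_cluster_exposures, mvmr_ivw

rng = np.random.default_rng(9)
J = 150
truth = {"obesity_ir": 0.2, "lipid_ir": 0.0, "high_proinsulin_bcd": -0.1}

variants = pd.DataFrame({
    "variant_id": [f"rs{i}" for i in range(J)],
    "beta": rng.uniform(0.02, 0.2, J),
    "se": 0.01,
})
weights = pd.DataFrame(
    [(f"rs{i}", c, float(rng.random() * (rng.random() < 0.6)))
     for i in range(J) for c in truth],
    columns=["variant_id", "cluster_label", "weight"])

design = build_cluster_exposures(variants, weights)
X = design[[f"gamma_{c}" for c in truth]].to_numpy()
se_G = np.full(J, 0.004)
design["Gamma"] = X @ np.array(list(truth.values())) + rng.normal(0, se_G)
design["se_Gamma"] = se_G

for name, est in mvmr_ivw(design).items():
    print(f"{name:22s} estimate {est.beta:+.4f} "
          f"(95% CI {est.ci_low:+.4f} to {est.ci_high:+.4f}, "
          f"p={est.pvalue:.2e}) | truth {truth[name]:+.2f}")
print()
print("Each cluster's direct effect is recovered; the null cluster's CI")
print("covers zero.")
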