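"""Longitudinal mixed-effects age effects with node-wise FDR correction.

Simulates an accelerated-longitudinal cohort (305 subjects, 491 scans, ages
6-14) in which 3 of 12 node measures carry a true age slope of 0.04/yr,
fits linear and quadratic mixed models per node, selects by AIC, and
corrects the fixed-age p-values across nodes with Benjamini-Hochberg FDR.
"""

import numpy as np

from overlapnet.devstats import fit_mixed_linear, nodewise_age_effects
from overlapnet.synthdata import gen_longitudinal_cohort

slopes = np.zeros(12)
slopes[:3] = 0.04
panel, truth = gen_longitudinal_cohort(node_slopes=slopes, seed=11)
print(f"cohort: {panel.n_subjects} subjects, {len(panel)} scans, "
      f"ages {panel.data['age'].min():.1f}-{panel.data['age'].max():.1f} yr")

fit = fit_mixed_linear(panel, "node0")
lo, hi = fit.ci95("age")
print(f"node0 fixed age slope: {fit.fixed['age']['beta']:.4f}/yr "
      f"(95% CI {lo:.4f}..{hi:.4f}; planted 0.04)")

table = nodewise_age_effects(panel, q=0.05)
sig = table[table["significant"]]
print(f"FDR-significant nodes (q = 0.05): {sorted(sig['measure'])}")
print(table.head(4).to_string(index=False))
print("-> the planted nodes (node0-2) survive FDR; t's sign gives the")
print("   direction of developmental change.")
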