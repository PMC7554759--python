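"""Mixed-model contrasts of a clinical feature between burden groups.

Simulates a non-motor symptom score (higher = worse) for two groups of
patients over visits at 0/12/24/36 months, with the high-burden group
diverging at the final visit, then fits the random-intercept model and
reports estimated marginal means and per-visit group contrasts.
"""

import pandas as pd

import l1burden as lb
from l1burden.synth import SimulationConfig, generate_longitudinal

groups = pd.Series(["le8"] * 150 + ["ge9"] * 150,
                   index=[f"P{i:03d}" for i in range(300)])
cell_means = {("le8", 0): 5.3, ("le8", 12): 6.7, ("le8", 24): 7.5, ("le8", 36): 7.7,
              ("ge9", 0): 5.6, ("ge9", 12): 6.7, ("ge9", 24): 7.6, ("ge9", 36): 9.1}
config = SimulationConfig(sigma_patient=2.0, sigma_residual=1.5, visit_missing_rate=0.05)
records = generate_longitudinal(groups, config, seed=8, cell_means=cell_means,
                                feature_name="updrs_part1")

fit = lb.fit_lmm(records, groups, group_levels=("le8", "ge9"))
print(f"fitted {fit.n_obs} observations from {fit.n_patients} patients; "
      f"sigma2_patient={fit.sigma2_patient:.2f}, sigma2_residual={fit.sigma2_residual:.2f}")

emms = lb.estimated_marginal_means(fit)
print("\nestimated marginal means (model-based group x visit means):")
print(emms.round(2).to_string(index=False))

contrasts = lb.pairwise_contrasts(fit)
print("\nper-visit contrast (high-burden minus low-burden group):")
print(contrasts.round(3).to_string(index=False))
# A significant contrast at one visit but not earlier ones is the
# progression signature of interest: the groups start together and
# diverge as the disease advances.
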