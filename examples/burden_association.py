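"""Burden scoring and threshold-sweep association on a synthetic cohort.

Simulates a cohort at the study's scale (550 individuals, ~68% cases) in
which carrying nine or more highly active L1 alleles multiplies the odds
of disease by 1.6, then recovers that effect with the constrained
threshold sweep and covariate-adjusted logistic regression.
"""

import numpy as np

import l1burden as lb
from l1burden.synth import SimulationConfig

catalog, polymorphic = lb.make_synthetic_study_catalog()
ha_loci = lb.default_ha_set(catalog, polymorphic)

config = SimulationConfig(n_samples=550, log_or=np.log(1.6), threshold=9)
matrix, phenotypes = lb.generate_cohort(catalog, config, seed=42,
                                        polymorphic_ids=polymorphic, ha_locus_ids=ha_loci)

burden = lb.compute_burden(matrix, ha_loci, catalog=catalog, exclude_sex_chromosomes=True)
complete = burden.loc[burden["complete"], "burden"]
print(f"HA burden over {len(ha_loci)} autosomal loci: "
      f"range {complete.min():.0f}-{complete.max():.0f}, mean {complete.mean():.1f} "
      f"({burden['complete'].sum()} complete cases of {len(burden)})")

sweep = lb.sweep_thresholds(burden, phenotypes, min_fraction=0.05)
print(f"admissible thresholds (smallest category >= 5% of each status group): "
      f"{[g.t for g in sweep]}")

table = lb.threshold_association(sweep, phenotypes)
print("\nadjusted odds of disease by burden threshold:")
print(table[["t", "or", "ci_low", "ci_high", "p"]].round(3).to_string(index=False))
row = table.loc[table["t"] == config.threshold].iloc[0]
print(f"\nat the generative threshold >= {config.threshold}: "
      f"OR {row['or']:.2f} (95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), "
      f"true OR {np.exp(config.log_or):.2f}")
# Each row is a logistic fit of case status on the at-or-above indicator
# plus sex, age and family history; ORs above 1 mean higher disease odds
# for carriers of at least t highly active L1 alleles.
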