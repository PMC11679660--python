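"""Per-variant logistic association and the confounding-change statistic.

Each variant is tested additively (dosage 0/1/2), unadjusted and adjusted
for sex plus continuous ancestry covariates. A >10% change in the odds
ratio between the two models flags covariate-driven confounding.
"""

import numpy as np

from hervtriage import ancestry_covariates, significance_threshold
from hervtriage.association import test_variant
from hervtriage.simulate import SimulationConfig, simulate_cohort, simulate_panel

config = SimulationConfig(
    seed=5, n_cases=300, n_controls=600, n_variants=30,
    case_effect_variants=[(0, 1.0)],
    confounded_variants=[1],  # strong frequency divergence across populations
)
panel = simulate_panel(config)
cohort = simulate_cohort(panel, config)

geno = np.vstack([cohort.cases_blood.genotypes, cohort.controls.genotypes])
y = np.r_[np.ones(config.n_cases), np.zeros(config.n_controls)]
sex = np.r_[cohort.cases_blood.samples["sex"], cohort.controls.samples["sex"]]
covs = ancestry_covariates(cohort.truth.q, panel.populations).to_numpy()

threshold = significance_threshold(alpha=0.05, n_variants=config.n_variants)
print(f"per-variant threshold: {threshold.threshold:.2e} "
      f"(-log10 = {threshold.neg_log10:.2f})")
for j, label in [(0, "planted effect"), (1, "ancestry-confounded")]:
    res = test_variant(geno[:, j], y, sex, covs, threshold=threshold.threshold)
    print(
        f"variant {j} ({label}): OR_unadj={res.or_unadj:.2f} "
        f"OR_adj={res.or_adj:.2f} p_adj={res.p_adj:.2e} "
        f"dOR={res.delta_or_fraction:.1%} confounded={res.confounded}"
    )
print(
    "The planted variant stays strongly significant under adjustment. The "
    "confounded variant has no planted effect, yet its OR swings far past "
    "the 10% flag once ancestry enters the model: its allele frequency "
    "tracks ancestry, which itself predicts case status."
)
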