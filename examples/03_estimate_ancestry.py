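"""Estimate admixture proportions from AIM genotypes and classify ancestry.

Genotypes at ancestry-informative markers are modelled as Binomial(2, f)
with f a q-weighted mixture of fixed reference-population frequencies;
EM maximizes the likelihood over the admixture vector q. Threshold rules
then assign a categorical label (EUR / AFR / EAS / HIS / AMR).
"""

import numpy as np

from hervtriage import estimate_admixture, simulate_panel
from hervtriage.simulate import SimulationConfig, draw_admixture

config = SimulationConfig(seed=3)
panel = simulate_panel(config)

rng = np.random.default_rng(3)
q_true = draw_admixture(rng, 5, config.n_populations, config)
genotypes = rng.binomial(2, q_true @ panel.frequencies)

profiles = estimate_admixture(genotypes, panel)
print("pop order:", panel.populations)
for truth, prof in zip(q_true, profiles):
    est = ", ".join(f"{v:.2f}" for v in prof.q)
    tru = ", ".join(f"{v:.2f}" for v in truth)
    print(f"true q = [{tru}]  estimated = [{est}]  label = {prof.label}")
print(
    "Estimates track the simulated admixture; the label applies the "
    "threshold rules (>90% EUR, >=70% AFR/EAS, >=10% dominant NAT -> HIS)."
)
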