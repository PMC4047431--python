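"""Parameter sensitivity of the forward response, and data-error stability.

Varies each Ogden parameter one at a time by +/-25% about the reference
specimen-2 material and ranks the parameters by how much the
displacement-pressure curve at a mid-segment point moves.  Then shows the
structure of the stability protocol (perturb displacements with up-to-10%
random error, re-identify, tabulate relative parameter changes) on a tiny
optimizer budget.
"""

import numpy as np

from irisid import MIGAConfig, generate_experiment, sensitivity_analysis, \
    stability_analysis
from irisid.datasets import (reference_mean_parameters,
                             reference_specimen_parameters)

baseline = reference_specimen_parameters(2)
report = sensitivity_analysis(baseline)

print(f"baseline (specimen 2): mu = {baseline.mu}, alpha = {baseline.alpha}")
print("mean |curve deviation| per parameter under +/-25% variation:")
for name, val in report.metrics.items():
    print(f"  {name:7s} {val:.4f} mm")
print("ranking (most to least influential):", " > ".join(report.ranking))
print()

experiment = generate_experiment(reference_mean_parameters(),
                                 noise_level=0.0, n_points=3, seed=3)
tiny = MIGAConfig(n_generations=4, population_size=10)     # fast demo
stab = stability_analysis(experiment, noise_level=0.10, n_replicates=3,
                          miga_config=tiny, master_seed=11)
print("stability: relative parameter changes (%) after re-identifying")
print("perturbed data (up-to-10% multiplicative error), vs the baseline:")
print(stab.relative_changes.round(2).to_string(index=False))
print()
print("(Demo uses a 40th of the standard optimizer budget, so optimizer")
print("scatter dominates these changes; the full studies run 500")
print("evaluations per identification.)  The forward response is most")
print("sensitive to alpha1 and mu1; parameters the data constrain weakly")
print("wander most between re-identifications.")
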