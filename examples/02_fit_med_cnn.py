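"""Fit the iterative CNN mediation estimator on one simulated dataset.

Uses a reduced sample size and short training schedule so the example
finishes in about a minute on a laptop; the estimates are therefore
noisier than a full-size run (n = 1000, longer training).
"""

import medcnn
from medcnn.fitting import FitConfig
from medcnn.harness import FAST_FIT

config = medcnn.make_scenario("alternative", beta1_override=5.0,
                              n=400, seed=7)
data = medcnn.generate_dataset(config)

result = medcnn.fit(data, FitConfig(seed=0, **FAST_FIT))

e = result.effects
print(f"converged: {result.converged} after {result.iterations_used} iterations")
for rec in result.trace:
    print(f"  max parameter change {rec.max_pct_change:8.3f}%   "
          f"CNN loss {rec.train_loss:.4f}")
print(f"NIE = {e.nie:.2f} (SE {e.se_nie:.2f})   [truth {config.true_nie}]")
print(f"NDE = {e.nde:.2f} (SE {e.se_nde:.2f})   [truth {config.true_nde}]")
print(f"TE  = {e.te:.2f}  proportion mediated {e.proportion_mediated:.1%}")
# The NIE is the exposure effect transmitted through the mediator networks;
# the NDE is the remainder. SEs are first-order delta-method approximations.
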