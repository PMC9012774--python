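"""Cross-validate the expected-SFS solver against coalescent simulation.

The deterministic moment-system solver and the stochastic genealogy
simulator implement the same size-history model by entirely different
routes; their spectra must agree within Monte-Carlo error.
"""

import math

import numpy as np

from rangeedge import MODELS, expected_sfs, simulate_coalescent_sfs

model, params = "two_epoch", [25.0, 0.05]
n, theta, reps = 20, 10.0, 50_000

hist = MODELS[model].history(np.asarray(params))
per_rep = simulate_coalescent_sfs(hist, n, theta, reps, seed=1, per_rep=True)
mc_mean = per_rep.mean(axis=0)
mc_se = per_rep.std(axis=0) / math.sqrt(reps)
solver = theta * expected_sfs(model, params, n).values

print(f"{model} nu={params[0]} T={params[1]}, n={n} copies, theta={theta}")
print(f"{'class':>5} {'solver':>8} {'simulated':>10} {'z':>6}")
for i in range(n - 1):
    z = (mc_mean[i] - solver[i]) / mc_se[i]
    print(f"{i + 1:>5} {solver[i]:>8.3f} {mc_mean[i]:>10.3f} {z:>6.2f}")
print(f"\nmax |z| = {np.max(np.abs((mc_mean - solver) / mc_se)):.2f} "
      f"over {reps} genealogies (should stay within ~3)")
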