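"""Fit competing coupling models to a synthetic doping experiment.

Generates triplicate activity measurements on an r grid from a known truth
(one dead protomer poisons the complex), normalizes to the r=0 group, and
selects among the threshold models m = 1..7 by residual sum of squares with
bootstrap selection frequencies.
"""

import numpy as np

from ringmotor import (
    CouplingModel,
    fit_threshold_model,
    gen_doping_dataset,
    normalize_and_aggregate,
)

r_grid = np.arange(0.0, 1.0, 0.1)
data = gen_doping_dataset(CouplingModel(1), r_grid, reps=3, noise_sd=0.02,
                          seed=11)

curve = normalize_and_aggregate(data)
print("   r    mean activity   SD")
for r, a, s in zip(curve.r_values, curve.activity, curve.stderr):
    print(f"  {r:.1f}   {a:12.4f}   {s:.4f}")

fit = fit_threshold_model(data, n_bootstrap=200, seed=12)
print("\nRSS by threshold m:",
      {m: round(v, 4) for m, v in fit.rss_by_m.items()})
print(f"selected m = {fit.best_m} "
      f"(bootstrap frequency {fit.bootstrap_ci_m[fit.best_m]:.2f})")
print("m=1 means a single dead protomer per hexamer stops the whole motor —")
print("the selection expected for a strictly sequential unfolding cycle.")
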