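# ringmotor

Quantitative machinery for interpreting subunit-doping experiments on
hexameric AAA+ unfoldases — ring ATPases such as the archaeal CDC48/p97
homologue VAT that thread unfolded protein through their central pore by a
sequential, hand-over-hand cycle. It is a library for biophysicists and
structural biologists who mix wild-type and catalytically dead (Walker-B
mutant) protomers, measure ensemble ATPase or unfolding activity, and want
to ask: *how many dead subunits does it take to stop one motor?*

## The model

Protomers assemble into hexamers randomly, so at mutant fraction *r* the
number of dead protomers per complex is binomial,

```
P(k) = C(6, k) r^k (1 - r)^(6-k).
```

Under a threshold coupling model — the functional sites are unaffected until
*m* dead protomers are present, at which point the complex stops — the
ensemble activity normalized to the all-wild-type rate is

```
A(r) = (1/6) * sum_{j=0}^{m-1} (6 - j) C(6, j) r^j (1 - r)^(6-j)
```

with `A = (1-r)^6` for m = 1 (one dead protomer poisons the ring — the
prediction of a strictly sequential hand-over-hand cycle) and `A = 1 - r`
for the uncoupled model (m = 7). The package provides:

- **ring_model** — these closed forms plus a brute-force enumeration oracle
  over all 2^6 protomer configurations;
- **simulator** — a Gillespie-style kinetic Monte Carlo model of the
  hand-over-hand cycle itself: a staircase of five gripping protomers and
  one seam protomer, 13 Å (two residues) translocated and 2 ATP hydrolyzed
  per transition, permanent stalls at dead seam protomers, and an optional
  escape/re-engagement mechanism for stalled complexes;
- **synthetic** — seeded generators for doping datasets, fluorescence
  unfolding traces, degradation band time courses and pore-loop coordinate
  sets;
- **reduction** — initial-slope extraction, r = 0 normalization,
  RSS-based threshold-model selection with bootstrap confidence, escape-rate
  fitting, degradation-rate fitting;
- **geometry** — helical rise/twist/pitch fitting with leave-one-out seam
  detection, pore aperture, inter-ring pore tilt, grip extent, and filament
  layer-line prediction/measurement.

## Worked example

```python
import numpy as np
from ringmotor import (CouplingModel, gen_doping_dataset, fit_threshold_model)

data = gen_doping_dataset(CouplingModel(1), np.arange(0, 1.0, 0.1),
                          reps=3, noise_sd=0.02, seed=11)
fit = fit_threshold_model(data, n_bootstrap=200, seed=12)
print(fit.best_m, {m: round(v, 4) for m, v in fit.rss_by_m.items()})
```

prints

```
1 {1: 0.0092, 2: 0.9062, 3: 2.4314, 4: 3.7402, 5: 4.5635, 6: 4.8976, 7: 4.8976}
```

the RSS of each threshold hypothesis against the triplicate doping data: the
m = 1 curve fits ~100-fold better than m = 2, i.e. a single dead protomer
per hexamer stops the whole motor. Longer narrative walkthroughs — the
closed-form curves, single-trajectory and ensemble simulation, the escape
elevation, and the pore-loop geometry measurements — live in `examples/`;
each prints the numbers it computes and what they mean.

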