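"""Closed-form subunit-poisoning curves for a doped hexamer.

Evaluates the fractional ATPase activity A(r) of hexamers assembled from a
mixture of active and Walker-B-dead protomers under three coupling
hypotheses — a single dead protomer poisons the complex (m=1, the strictly
sequential hand-over-hand prediction), two are required (m=2), and no
coupling at all — and cross-checks the closed form against brute-force
enumeration of all 2^6 protomer configurations.
"""

import numpy as np

from ringmotor import CouplingModel, activity_threshold, enumeration_oracle

grid = np.arange(0.0, 1.01, 0.2)
print("   r    m=1 (1-r)^6   m=2        uncoupled (1-r)")
for r in grid:
    a1 = activity_threshold(r, CouplingModel(1))
    a2 = activity_threshold(r, CouplingModel(2))
    a7 = activity_threshold(r, CouplingModel(7))
    print(f"  {r:.1f}   {a1:10.6f}  {a2:9.6f}  {a7:9.6f}")

worst = max(
    abs(activity_threshold(r, CouplingModel(m))
        - enumeration_oracle(r, CouplingModel(m)))
    for m in range(1, 8)
    for r in grid
)
print(f"\nmax |closed form - enumeration| over all m, r: {worst:.2e}")
print("The m=1 curve falls far below the others at intermediate r: doping a")
print("sequential motor with even one dead subunit per ring abolishes its"
      " activity.")
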