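"""Wild-type vs katanin-mutant severing, at smoke-test scale.

Runs the shape x severing grid (rectangle and square, P_cross = 0.005
vs 0) with few, short replicates and prints per-condition mean S2 and
the alignment of the rectangle.  The full-scale protocol (t_steps =
2,000, R = 20) is what scripts/acceptance.py runs.
"""

import numpy as np

from mtconfine.protocols import (nematic_circular_mean,
                                 severing_shape_cohort)
from mtconfine.stats import permutation_mean_test

cohort = severing_shape_cohort(seed=7, t_steps=500, r_replicates=4)

for key in ("rect_sev", "rect_nosev", "square_sev", "square_nosev"):
    s2 = cohort.s2[key]
    print(f"{key:14s} mean S2 = {s2.mean():.3f} (+- {s2.std():.3f}, "
          f"R = {len(s2)})")

print(f"rectangle circular-mean ThetaS2 (severing): "
      f"{nematic_circular_mean(cohort.theta['rect_sev']):+.1f} deg "
      f"(0 deg = long axis)")
p = permutation_mean_test(cohort.s2["rect_sev"], cohort.s2["square_sev"],
                          rng=np.random.default_rng(0))
print(f"one-sided permutation p, rect > square (severing): {p:.4f}")
print("The elongated domain orders the array along its long axis; the "
      "square stays weakly ordered with no preferred direction.")
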