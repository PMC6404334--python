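"""Alpha/beta projection scores on a hand-sized 2-gene example.

Centroid A sits at (0, 0), centroid B at (2, 0).  A sample at (1, 1)
projects onto the midpoint of the axis: alpha = 0.5 (halfway between the
groups) with beta = 1 (one log2 unit off the axis).
"""

import numpy as np

from gsepd.projection import Centroids, project_sample

cent = Centroids(("geneX", "geneY"), np.array([0.0, 0.0]), np.array([2.0, 0.0]))

for label, point in [("at A", [0, 0]), ("at B", [2, 0]), ("between", [1, 1]),
                     ("beyond B", [3, 0.5])]:
    s = project_sample(np.array(point, float), cent)
    print(f"sample {label:9s} P={point}:  alpha={s['alpha']:+.3f}  "
          f"alpha_raw={s['alpha_raw']:+.3f}  beta={s['beta']:.3f}")
# alpha < 0 or > 1 flags samples more extreme than either centroid;
# alpha_raw is the same coordinate in log2-expression units.
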