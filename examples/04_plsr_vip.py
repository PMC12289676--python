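"""Screen genus-level mediators of a pharmacological endpoint with NIPALS
partial least squares and VIP scores."""

import numpy as np
import pandas as pd

from udpharm import nipals_plsr, screen_vip, select_ncomp, vip

rng = np.random.default_rng(7)
n = 35  # dosed animals
genera = pd.DataFrame(
    rng.normal(0, 1, (n, 10)), columns=[f"g{j + 1:02d}" for j in range(10)]
)
# genus g01 drives the endpoint with standardized effect 0.9
y = 0.9 * genera["g01"] + rng.normal(0, np.sqrt(1 - 0.81), n)

ncomp = select_ncomp(genera, y, threshold=0.80)
fit = nipals_plsr(genera, y, ncomp=ncomp)
scores = vip(fit)
print(f"components used: {ncomp} "
      "(smallest count whose cumulative explained endpoint variance tops "
      "80%; falls back to the maximum when the threshold is never reached)")
print("\nVIP scores (mean square is 1 by construction):")
for name, v in sorted(zip(fit.x_names, scores), key=lambda t: -t[1]):
    marker = " <-- VIP > 1" if v > 1 else ""
    print(f"  {name}: {v:.3f}{marker}")
print(f"\nscreened mediators: {screen_vip(fit, threshold=1.0)}")
print("(predictors with VIP > 1 are carried into the path model)")
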