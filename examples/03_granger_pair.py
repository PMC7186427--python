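"""Estimate directed influence between two regions with a planted coupling.

Simulates a two-region lag-1 VAR where region 1 drives region 2 with
coefficient 0.4, then fits the bivariate model and prints both directed
measures: the signed path coefficient (the connection strength carried
into group analysis) and the residual-variance-ratio influence.
"""

import numpy as np

from fstgc import fit_bivariate_var, path_coefficient, residual_influence
from fstgc.synthetic import NuisanceSpec, simulate_timeseries

A = np.array([[0.3, 0.0],
              [0.4, 0.3]])  # region1 -> region2 with weight 0.4

ts, _ = simulate_timeseries(
    A, T=160, innovation_sd=1.0,
    nuisance_spec=NuisanceSpec(drift_amplitude=0, n_motion=0), seed=11,
)
x, y = ts.data[:, 0], ts.data[:, 1]

fit = fit_bivariate_var(x, y, p=1)
f_xy, f_yx = residual_influence(x, y, p=1)

print(f"planted coefficient   a(2<-1) = {A[1, 0]:.2f}   (T = 160, p = 1)\n")
print(f"path coefficient  1->2 = {path_coefficient(fit, 'x->y'):+.3f}")
print(f"path coefficient  2->1 = {path_coefficient(fit, 'y->x'):+.3f}")
print(f"residual measure F_1to2 = {f_xy:.4f}")
print(f"residual measure F_2to1 = {f_yx:.4f}")

# The forward path coefficient sits near the planted 0.4 while the
# reverse one hovers near zero; the residual measure shows the same
# asymmetry on a log-variance-ratio scale (always >= 0, sign-blind).
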