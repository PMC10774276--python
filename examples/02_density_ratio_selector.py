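"""Fit a KuLSIF density-ratio estimator and calibrate a selection threshold.

A client's data is a narrow 1-D Gaussian; the reference is uniform on
[-1, 1].  The estimated ratio w(x) = p(x)/u(x) should approach the
closed form at the mode and fall toward zero out of distribution.
"""

import numpy as np
from scipy.stats import truncnorm

import selectivefd as sfd
from selectivefd.density_ratio import KulsifConfig

rng = np.random.default_rng(0)
S_k = truncnorm.rvs(-5, 5, scale=0.2, size=(5000, 1), random_state=rng)
S_u = rng.uniform(-1, 1, size=(5000, 1))

model = sfd.fit_kulsif(S_k, S_u, KulsifConfig(beta=1e-3))
analytic = truncnorm.pdf(0, -5, 5, scale=0.2) / 0.5
w0 = float(sfd.evaluate_ratio(model, [[0.0]])[0])
w_edge = float(sfd.evaluate_ratio(model, [[0.9]])[0])
print(f"w(0)   estimated {w0:.3f}  vs analytic p(0)/u = {analytic:.3f}")
print(f"w(0.9) estimated {w_edge:.3f}  (tail: true ratio {truncnorm.pdf(0.9,-5,5,scale=0.2)/0.5:.5f})")

val = truncnorm.rvs(-5, 5, scale=0.2, size=(200, 1), random_state=rng)
th = sfd.calibrate_threshold(model, val, tau_client=0.25)
print(f"tau_client=0.25 threshold: {th.threshold_value:.3f} "
      "(the 0.25-quantile of validation ratios)")
print("Proxy samples whose ratio falls below this threshold are treated as")
print("out-of-distribution and the client's predictions on them are not shared.")
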