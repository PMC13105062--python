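"""Fit the torsional helical-phasing model to a dimer spacing series.

Simulates mean fluorescence for probes carrying two motifs at spacings
0-32 bp (5% multiplicative noise, 3 replicates), fits the four-parameter
model by multi-start nonlinear least squares, and reports the recovered
helical periodicity and per-spacing phase.
"""

import numpy as np

from snaparray.phasing import (
    PhasingParams,
    fit_phasing,
    helix_projection,
    sigma_bp,
)
from snaparray.simulate import simulate_phasing_series

true = PhasingParams.from_sigma_bp(h_r=5.46, sigma_bp_value=0.15,
                                   K_min=1.0, s_min=1.0)
series = simulate_phasing_series(true, range(0, 33), noise_frac=0.05,
                                 n_reps=3, rng=np.random.default_rng(2))
fit = fit_phasing(series["spacing"], series["mean_intensity"], scale="log")

print(f"recovered helical repeat h_r = {fit.params.h_r:.4f} bp "
      f"(simulated at {true.h_r})")
print(f"s_min = {fit.params.s_min:.3f} bp, K_min = {fit.params.K_min:.3f}, "
      f"sigma_bp = {sigma_bp(fit.params):.4f} bp")
print(f"converged: {fit.converged}, residual sum: {fit.residual_sum:.4f} "
      f"({fit.n_points} spacings used)")

for s in (1, 4, 6):
    angle = np.degrees(helix_projection(s))
    print(f"spacing {s:2d} bp -> phase {fit.phase[s - 1]:.2f}, "
          f"helix-face angle {angle:5.1f} deg")

# Fluorescence oscillates with spacing at roughly half the 10.5-bp B-DNA
# helical repeat; spacings on the same rotational face of the helix bind
# most strongly.
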