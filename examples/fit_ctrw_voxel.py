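"""Fit the CTRW diffusion model to a single synthetic decay curve.

Builds a noiseless 14-b-value signal with known (alpha, beta, Dm), runs the
two-step fit, and prints the recovered parameters next to the truth.
"""

import numpy as np

from crnn_dwi import CTRWParams, ctrw_signal, default_scheme, fit_ctrw_voxel

scheme = default_scheme()
truth = CTRWParams(S0=1.0, Dm=1.0e-3, alpha=0.8, beta=0.9)
signal = ctrw_signal(scheme, truth)

print("b-values (s/mm^2):", [int(b) for b in scheme.bvalues])
print("signal S/S0:      ", np.round(signal, 4))

fit = fit_ctrw_voxel(scheme, signal)
print(f"\ntruth : alpha={truth.alpha}  beta={truth.beta}  Dm={truth.Dm:.2e}")
print(
    f"fitted: alpha={fit.alpha:.6f}  beta={fit.beta:.6f}  Dm={fit.Dm:.6e}  "
    f"(converged={fit.converged}, {fit.n_iter} evaluations)"
)
residual = np.abs(ctrw_signal(scheme, fit) - signal).max()
print(f"max regenerated-signal residual: {residual:.2e}")
print(
    "\nalpha/beta < 1 indicate temporal/spatial diffusion heterogeneity; "
    "the residual shows the fit reproduces the decay to machine precision."
)
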