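# crnn-dwi

Unrolled convolutional-recurrent reconstruction of highly undersampled
multi-b-value diffusion-weighted MRI (DWI), with continuous-time random walk
(CTRW) diffusion-model fitting and a fully synthetic evaluation pipeline.

## The problem

Multi-b-value DWI probes non-Gaussian water diffusion by sampling the signal
decay at many diffusion weightings (here 14 b-values, 0–4000 s/mm², three
directions each), at the cost of long acquisitions. Undersampling k-space by
a factor R shortens the scan but aliases the images. This package
reconstructs such data with an unrolled network that alternates a learned
convolutional-recurrent refinement with hard data consistency:

    X_rec = f_N(f_N-1(... f_1(X_u))),      X_u = zero-filled input series
    f_i:  X -> DC( X + CRNN(X); y )

The CRNN box exploits redundancy across the b-value series: one
bidirectional CRNN-b-i layer whose hidden state evolves over both the
b-sequence and the iteration,

    H_b-> = ReLU(Wc * H_in,b + Wb * H_{b-1}-> + Wr * H_b^(i-1) + B->)
    H_b<- = ReLU(Wc * H_in,b + Wb * H_{b+1}<- + Wr * H_b^(i-1) + B<-)
    H_b   = H_b-> + H_b<-

followed by three iteration-recurrent CRNN-i layers and a linear CNN; DC
re-imposes the acquired k-space lines exactly.

Reconstruction quality is judged both directly (SSIM/PSNR against the fully
sampled series) and through the lens of the downstream science: voxelwise
fits of the CTRW diffusion model

    S(b)/S0 = E_alpha( -(b·Dm)^beta )

(E_alpha the Mittag-Leffler function; alpha, beta temporal/spatial
heterogeneity; Dm an anomalous diffusion coefficient), whose parameter maps
are compared by SSIM against maps fitted from the fully sampled data,
with paired t-tests under Bonferroni correction.

Because no in-vivo data ships with the package, a phantom simulator
generates multi-subject cohorts with exact CTRW ground truth (nested-ellipse
geometry, k-space complex-Gaussian noise → Rician magnitudes), split 7:2:1
into train/validation/test by subject.

## Worked example

Fitting the CTRW model to a noiseless synthetic decay
(`python examples/fit_ctrw_voxel.py`):

```
b-values (s/mm^2): [0, 50, 100, 200, 400, 600, 800, 1000, 1500, 2000, 2500, 3000, 3500, 4000]
signal S/S0:       [1.     0.9306 0.8753 0.7824 0.6396 0.5334 0.4515 0.3869
                    0.2751 0.2062 0.1612 0.1305 0.1087 0.0926]
truth : alpha=0.8  beta=0.9  Dm=1.00e-03
fitted: alpha=0.800000  beta=0.900000  Dm=1.000000e-03  (converged=True, 8 evaluations)
max regenerated-signal residual: 3.14e-14
```

The fit recovers the generating parameters to six decimals and reproduces
the decay to machine precision — the forward model and the fitter agree
exactly on noiseless data.

Undersampling a 64×64 phantom at R = 4
(`python examples/undersample_phantom.py`):

```
mask: 16/64 phase-encode lines (R=4, 6 center lines always sampled)
zero-fill SSIM vs fully sampled: mean 0.760 (b=0 frame 0.531, worst frame 0.531)
```

Zero-filling leaves strong aliasing (SSIM well below 1); training the
unrolled network to remove it is the point of the package
(`python examples/train_small_model.py` shows a one-minute training run).

The full desk-scale experiment — 6 subjects × 4 slices of 64×64 phantoms,
6 b-values, R = 4, 20 epochs, then CTRW fitting on the held-out subject —
runs as

```python
from crnn_dwi import small_experiment
result = small_experiment(seed=0, R=4.0)
```

or from the shell via `crnn-dwi run-experiment --small --out results/`.

## Package layout

| module | contents |
| --- | --- |
| `crnn_dwi.scheme` | b-value/direction schemes, FSL .bval/.bvec IO |
| `crnn_dwi.mittag_leffler` | E_alpha on the nonpositive axis (series + spectral integral) |
| `crnn_dwi.ctrw` | CTRW signal model, trace averaging, voxel/volume fitting, NIfTI maps |
| `crnn_dwi.phantom` | nested-ellipse phantoms, forward simulation, cohort splits |
| `crnn_dwi.kspace` | centered orthonormal FFTs, variable-density masks, zero-fill, hard DC, HDF5 container |
| `crnn_dwi.autodiff` | minimal tape-based reverse-mode engine (conv2d, ReLU, DC node, MSE) |
| `crnn_dwi.network` | CRNN-b-i / CRNN-i layers, unrolled reconstruction, Adam training, checkpoints |
| `crnn_dwi.metrics` | SSIM/PSNR, metric reports, paired t-tests + Bonferroni |
| `crnn_dwi.experiments` | simulate → train → reconstruct → fit → evaluate orchestration |
| `crnn_dwi.config` / `crnn_dwi.cli` | YAML experiment config, `crnn-dwi` command-line interface |

See `docs/methods.md` for the numerical choices, parameter defaults and the
limits of what the synthetic experiments demonstrate.
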