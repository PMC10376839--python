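# Methods

This note records the models the package implements, the numerical choices
behind them, and what the synthetic experiments do and do not demonstrate.

## The CTRW diffusion signal model

Trace-weighted diffusion MRI signal decay over b-values is modelled by the
continuous-time random walk (CTRW) form

    S(b) / S0 = E_alpha( -(b * Dm)^beta ),

where `E_alpha` is the one-parameter Mittag-Leffler function, `Dm` (mm^2/s)
is an anomalous diffusion coefficient, and `alpha, beta` in (0, 1] encode
temporal and spatial diffusion heterogeneity.  `alpha = beta = 1` reduces to
the mono-exponential ADC model.  The model is evaluated only on the
nonpositive argument branch, where `E_alpha(-x)` is completely monotone.

### Mittag-Leffler numerics

Two regimes, switched per argument:

* **Taylor series** `sum_k z^k / Gamma(alpha k + 1)` whenever the largest
  term of the alternating sum stays below 1e5.  The bound certifies that
  float64 cancellation cannot push the absolute error above ~1e-11; the
  series is built in log space (gammaln) and vectorised over both term index
  and argument.
* **Spectral integral** otherwise.  For 0 < alpha < 1, complete
  monotonicity gives, after the substitution `r = u^(1/alpha)` that removes
  the endpoint singularity,

      E_alpha(-x) = sin(alpha pi) / (alpha pi) *
                    int_0^inf exp(-(u x)^(1/alpha)) / (u^2 + 2 u cos(alpha pi) + 1) du.

  In the variable `v = u x` the exponential factor is independent of `x`,
  so a fixed Gauss-Legendre panel rule (8 panels on [0, 35], 40 nodes each)
  evaluates many arguments at once.

A Taylor/asymptotic-series split was considered and rejected: the
asymptotic remainder at optimal truncation behaves like
`exp(-|z|^(1/alpha))`, which is ~2.6e-3 at `z = -5, alpha = 0.9` — orders of
magnitude short of the accuracy the fit requires near the crossover.
Measured against an arbitrary-precision series oracle, the implementation is
accurate to better than 1e-9 absolute for `alpha in [0.3, 1]`,
`x in [0, 60]`; below `alpha ~ 0.1` the integrand develops a near-step and
accuracy degrades gracefully to ~1e-4, which the bounded fit tolerates.

### Voxelwise fitting

Per voxel, `S0` is fixed to the measured b = 0 signal and fitting proceeds
in two steps: (i) `Dm` is initialized by log-linear least squares of
`ln(S/S0)` against `-b` through the origin over all b-values with positive
signal (clamped to [1e-6, 1e-2] mm^2/s); (ii) `(alpha, beta, Dm)` are
refined jointly by damped (Levenberg-Marquardt-type) bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective, bounds
(1e-3, 1] for alpha and beta), initialized at (0.9, 0.9, Dm_init),
terminated at relative cost change < 1e-10 or 80 function evaluations.

`Dm` is *refined*, not held at the mono-exponential estimate: on
non-Gaussian decays the mono-exponential slope is biased by ~30%
(e.g. 6.8e-4 for a true 1e-3 at alpha = 0.8, beta = 0.9), and holding it
fixed makes exact recovery of CTRW-generated signals impossible.  With
refinement, noiseless round trips recover alpha and beta to ~1e-4 and Dm to
~0.01% on a 3x3x3 parameter grid.

Degenerate voxels (nonpositive b = 0 signal, fewer than two positive
samples, non-finite optimizer output) return the initialization flagged
unconverged.  The default fit mask keeps voxels whose b = 0 intensity
exceeds 5% of the volume's 99th percentile.

## Synthetic phantoms

Phantoms are nested ellipses: an outer "skull" ellipse plus n interior
ellipses, each region carrying one parameter tuple drawn uniformly from
S0 in [0.5, 1], Dm in [0.4, 2.5]e-3 mm^2/s, alpha, beta in [0.6, 1] —
ranges bracketing healthy-brain CTRW values.  Signal decay follows the CTRW
model exactly, so ground truth is exact by construction.  Noise is complex
Gaussian in k-space (per-channel sigma; the orthonormal transform maps it to
image-domain complex noise of the same sigma), which makes the magnitude
statistics Rician without further modelling.  The default
`noise_sigma = 0.01` puts the b = 0 SNR near 75 for a mid-range S0, in the
range of a well-tuned clinical acquisition.

Optional anisotropy multiplies Dm by one positive scale per diffusion
direction and region, constrained to geometric mean 1.  The default is
isotropic (spread 0): the geometric (trace) average removes the scales
exactly only at beta = 1, and the exact-recovery contracts are stated for
the isotropic generator.  With anisotropy enabled the trace decay is only
approximately CTRW and small fitting bias is expected.

The full-scale acquisition geometry the simulator mirrors is a 256x256
matrix, 25 slices per subject, 14 b-values 0-4000 s/mm^2 with 3 directions
per nonzero b (b = 0 acquired once), and a 10-subject cohort split 7:2:1
into train/validation/test (175 training slices).  Tests and the shipped
experiment run a 64x64 / 4-slice / 6-subject / 6-b-value scale of the same
construction so the whole pipeline executes in minutes on one CPU core;
the geometry is configurable back to full scale.

## Undersampling and data consistency

Magnitude images are transformed to single-channel pseudo k-space by a
centered orthonormal 2D DFT (origin at index H//2).  Undersampling is 1D
Cartesian: whole phase-encode lines are kept or zeroed, with a fully
sampled block of `n_center` contiguous center lines (24 at H = 256, scaled
to 6 at H = 64) and the remaining budget of `round(H/R)` lines drawn
without replacement with probability proportional to
`(1 - |k|/k_max)^3`.  One mask is shared by all frames and slices of an
experiment.  Hard data consistency replaces the k-space of an estimate with
the acquired lines — an orthogonal projection (idempotent, and exact on
sampled lines by construction).

## The unrolled CRNN reconstruction

The reconstruction unrolls N iterations of
`X -> DC(X + CRNN(X); y)` starting from the zero-filled series.  The CRNN
box stacks one bidirectional CRNN-b-i layer (hidden state evolving over
both the b-value sequence and the iteration), three CRNN-i layers (hidden
state evolving over the iteration only), and a linear CNN projecting back
to 2 channels (real, imaginary).  All convolutions are same-padded; hidden
states start at zero (iteration 0 and both sequence ends); the two
CRNN-b-i directions share Wc, Wb, Wr and differ only in biases.  Weights
are shared across the N iterations by default (the Wr recurrence carries
iteration evolution); a per-iteration-weights mode exists behind a config
flag.

Frames are sequenced by ascending b-value; each diffusion direction forms
its own sequence (batch element) sharing the b = 0 frame, because the
b-recurrence indexes neighbours in b and interleaving directions would put
unrelated frames next to each other.  At reassembly the b = 0 frame is
averaged over the per-direction reconstructions.

The network runs on a small tape-based reverse-mode autodiff engine over
numpy (im2col convolutions via memoized-path einsum; the hard-DC layer is
one linear node whose backward pass reapplies the unsampled-line
projection).  Gradients are pinned against central finite differences in
the test suite, and the whole unrolled network against a hand-written
scalar recursion at 1x1 kernels on 1x1 images.

Training minimizes MSE between the 2-channel output and the fully sampled
magnitude reference (imaginary target 0) with Adam.  The desk-scale
experiment uses N = 3 iterations, 8 hidden channels, 3x3 kernels, lr 1e-3,
batch 8 sequences, 20 epochs, all seeded; the best-validation weights are
retained.  Full-scale defaults (N = 5, 64 channels) follow the dynamic-MRI
CRNN lineage and are exposed in the config.  Checkpoints store weights,
config and training manifest, and reload bit-identically.

## Evaluation

SSIM uses the standard Gaussian-windowed form (11x11 window, sigma 1.5,
K1 = 0.01, K2 = 0.03) via scikit-image, with data range fixed to the
per-volume maximum of the reference magnitude; PSNR is
`10 log10(range^2 / MSE)` in dB with +inf as the identical-pair sentinel.
Image metrics are averaged over frames within a slice and reported per
slice.

Parameter-map quality is scored by SSIM against **reference maps fitted
from the fully sampled series**, background zeroed outside the fit mask —
the protocol a study without simulation truth necessarily uses.  This
choice matters: against the *exact* phantom maps, both undersampled fits
are noise-limited and the comparison direction is uninformative, whereas
fits of reconstructions that are closer to the fully sampled data also
reproduce its fitted-map structure.  The exact maps remain available in the
result object.

Methods are compared with paired t-tests (paired by slice) per metric
group, Bonferroni-corrected at family-wise 0.05 (per-test threshold =
0.05 / number of pairwise tests, reported explicitly).  Zero-variance
difference vectors are flagged degenerate rather than emitting NaN.

## What the synthetic experiments show — and what they don't

Passing tests demonstrate: correct special-function numerics; exact
inversion of the forward model the phantoms share with the fitter; mask,
transform and DC contracts; equivalence of the network to its defining
recursions; and that, at desk scale, the trained unrolled network
reconstructs held-out phantom data substantially better than zero-filling
on image SSIM and PSNR, with the gap statistically significant under the
Bonferroni-corrected paired test.

The fitted-parameter-map comparison behaves differently at phantom scale,
and deliberately so is reported as measured rather than forced.  On
piecewise-constant phantoms, zero-fill aliasing amounts to spatial
averaging that mostly mixes voxels within a region: it *denoises* the
voxelwise fit at essentially zero structural cost.  Measured at the
shipped conditions, zero-fill parameter maps are closer to the exact
simulation truth (alpha RMSE 0.078) than fits of the fully sampled noisy
data themselves (0.131), with the network's maps in between (0.117) — so
zero-fill's map SSIM against the fitted reference exceeds the network's
even though the network wins every per-frame image comparison.  No
reconstruction can reproduce the reference fit's unsampled-noise texture,
and nothing can out-score a benign smoother on constant regions in a
fit-noise-dominated regime.  In tissue, the same aliasing destroys real
anatomical structure, which is why in-vivo studies find the opposite map
ordering; reproducing that ordering in simulation requires phantoms whose
parameter maps carry fine spatial structure, which the nested-ellipse
family intentionally does not.  The package reports both methods' map
SSIMs and leaves the interpretation to this analysis.

They do not demonstrate in-vivo performance.  The phantoms are piecewise-
constant, single-coil, distortion-free, and generated by the same signal
model that is fitted — real tissue heterogeneity, EPI distortion, motion,
multi-coil physics, and model misfit are all absent, and desk-scale
training (hundreds of small frames, a deliberately small network) says
nothing about metric magnitudes at clinical scale.

## Known limitations

* Mittag-Leffler accuracy degrades below `alpha ~ 0.1` (bounded ~1e-4);
  the fit bounds permit such values but realistic tissue does not reach them.
* The two-step fit is local; pathological multi-minima decays could in
  principle converge to a local optimum within the bounds.
* Anisotropic simulation breaks the exact trace/CTRW correspondence at
  beta < 1 (documented approximation).
* The engine is CPU-only and unoptimized for large batches; full-scale
  256x256 training is configurable but slow.
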