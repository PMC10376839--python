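"""Simulate a DWI phantom, undersample its pseudo k-space, and measure the
quality of plain zero-filled reconstruction at R = 4.

Shows the raw-data side of the pipeline without any training: how much
image quality the variable-density undersampling destroys when nothing
cleverer than zero-filling puts it back.
"""

import numpy as np

from crnn_dwi import (
    default_scheme,
    make_phantom_maps,
    make_vd_mask,
    simulate_dwi,
    ssim,
    undersample,
    zero_fill_recon,
)
from crnn_dwi.kspace import series_to_kspace

scheme = default_scheme()
maps = make_phantom_maps(64, 64, n_regions=3, seed=7)
series = simulate_dwi(maps, scheme, noise_sigma=0.01, seed=0)

mask = make_vd_mask(n_lines=64, R=4, n_center=6, seed=0)
print(f"mask: {mask.n_sampled}/{mask.n_lines} phase-encode lines "
      f"(R={mask.R:g}, {mask.n_center} center lines always sampled)")

frames = undersample(series_to_kspace(series), mask, scheme)
zf = zero_fill_recon(frames)

ref = series.magnitude()
rec = zf.magnitude()
rng_val = float(ref.max())
vals = [ssim(ref[f, 0], rec[f, 0], rng_val) for f in range(scheme.n_frames)]
print(f"zero-fill SSIM vs fully sampled: mean {np.mean(vals):.3f} "
      f"(b=0 frame {vals[0]:.3f}, worst frame {min(vals):.3f})")
print("\nSSIM < 1 quantifies the aliasing left by discarding 3 of every 4 "
      "k-space lines; the trained network in train_small_model.py exists "
      "to close this gap.")
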