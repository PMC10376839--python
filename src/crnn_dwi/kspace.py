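"""Pseudo k-space, Cartesian variable-density undersampling and data consistency.

Magnitude DWI images are transformed to a single-channel "pseudo" k-space by
a centered orthonormal 2D DFT.  Undersampling removes whole phase-encode
lines (rows) according to a variable-density pattern whose center block is
always fully sampled; the nominal acceleration factor R fixes the total line
count at round(H / R).  Hard data consistency replaces the k-space of an
estimate with the acquired measurements on every sampled line, which makes
it an orthogonal projection (idempotent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .scheme import BValueScheme
from .series import DWISeries

__all__ = [
    "SamplingMask",
    "KSpaceFrameSet",
    "image_to_kspace",
    "kspace_to_image",
    "make_vd_mask",
    "undersample",
    "zero_fill_recon",
    "data_consistency",
    "series_to_kspace",
]


def image_to_kspace(image: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D DFT over the trailing two axes."""
    shifted = np.fft.ifftshift(image, axes=(-2, -1))
    k = np.fft.fft2(shifted, axes=(-2, -1), norm="ortho")
    return np.fft.fftshift(k, axes=(-2, -1))


def kspace_to_image(kdata: np.ndarray) -> np.ndarray:
    """Inverse of :func:`image_to_kspace`."""
    shifted = np.fft.ifftshift(kdata, axes=(-2, -1))
    img = np.fft.ifft2(shifted, axes=(-2, -1), norm="ortho")
    return np.fft.fftshift(img, axes=(-2, -1))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SamplingMask:
    """Boolean per-phase-encode-line pattern with a fully sampled center block.

    The k-space origin row sits at index H // 2 after centering; the
    ``n_center`` block is centered there.
    """

    line_pattern: np.ndarray
    R: float
    n_center: int
    seed: int
    decay_power: float = 3.0

    @property
    def n_lines(self) -> int:
        return int(self.line_pattern.size)

    @property
    def n_sampled(self) -> int:
        return int(self.line_pattern.sum())

    def as_2d(self, width: int) -> np.ndarray:
        """Broadcastable (H, W) float mask (1 on sampled lines)."""
        return np.repeat(self.line_pattern[:, None].astype(float), width, axis=1)

    def center_slice(self) -> slice:
        h = self.n_lines
        start = h // 2 - self.n_center // 2
        return slice(start, start + self.n_center)


def make_vd_mask(
    n_lines: int,
    R: float,
    n_center: int = 24,
    decay_power: float = 3.0,
    seed: int = 0,
) -> SamplingMask:
    """Variable-density line mask: full center block plus random outer lines.

    Outer lines are drawn without replacement with probability proportional
    to (1 - |k| / k_max) ** decay_power, so sampling density decays away from
    the k-space center.  The total count is round(H / R) (half away from
    zero), of which ``n_center`` contiguous center lines are forced.
    """
    n_keep = _round_half_away(n_lines / R)
    if n_lines < n_center:
        raise ValueError(f"n_lines={n_lines} smaller than n_center={n_center}")
    if n_keep < n_center:
        raise ValueError(
            f"round(n_lines/R)={n_keep} lines cannot contain the "
            f"n_center={n_center} center block; lower R or n_center"
        )
    pattern = np.zeros(n_lines, dtype=bool)
    start = n_lines // 2 - n_center // 2
    pattern[start : start + n_center] = True

    n_extra = n_keep - n_center
    if n_extra > 0:
        rng = np.random.default_rng(seed)
        k = np.arange(n_lines) - n_lines // 2
        k_max = np.abs(k).max()
        weight = (1.0 - np.abs(k) / k_max) ** decay_power
        weight[pattern] = 0.0
        candidates = np.flatnonzero(weight > 0)
        if candidates.size < n_extra:
            # include zero-weight edge lines only when unavoidable
            candidates = np.flatnonzero(~pattern)
            weight[candidates] = np.maximum(weight[candidates], 1e-12)
        p = weight[candidates] / weight[candidates].sum()
        chosen = rng.choice(candidates, size=n_extra, replace=False, p=p)
        pattern[chosen] = True
    return SamplingMask(
        line_pattern=pattern, R=float(R), n_center=int(n_center),
        seed=int(seed), decay_power=float(decay_power),
    )


@dataclass
class KSpaceFrameSet:
    """Complex centered k-space frames sharing one sampling mask."""

    kdata: np.ndarray  # (n_frames, n_slices, H, W), zero off-mask
    mask: SamplingMask
    scheme: BValueScheme

    def __post_init__(self) -> None:
        if self.kdata.shape[-2] != self.mask.n_lines:
            raise ValueError("mask length must equal k-space height")

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("kdata", data=self.kdata.astype(np.complex64))
            f.create_dataset("mask", data=self.mask.line_pattern.astype(np.uint8))
            f.create_dataset("bvals", data=self.scheme.frame_bvals())
            f.create_dataset("bvecs", data=self.scheme.frame_bvecs())
            f.attrs["R"] = self.mask.R
            f.attrs["n_center"] = self.mask.n_center
            f.attrs["seed"] = self.mask.seed
            f.attrs["decay_power"] = self.mask.decay_power
            f.attrs["bvalues"] = np.asarray(self.scheme.bvalues)
            f.attrs["directions"] = np.asarray(self.scheme.directions)

    @classmethod
    def load(cls, path: str | Path) -> "KSpaceFrameSet":
        with h5py.File(path, "r") as f:
            kdata = f["kdata"][()].astype(np.complex128)
            mask = SamplingMask(
                line_pattern=f["mask"][()].astype(bool),
                R=float(f.attrs["R"]),
                n_center=int(f.attrs["n_center"]),
                seed=int(f.attrs["seed"]),
                decay_power=float(f.attrs["decay_power"]),
            )
            scheme = BValueScheme(
                bvalues=tuple(float(b) for b in f.attrs["bvalues"]),
                directions=tuple(tuple(d) for d in f.attrs["directions"]),
            )
        return cls(kdata=kdata, mask=mask, scheme=scheme)


def undersample(
    kdata: np.ndarray, mask: SamplingMask, scheme: BValueScheme
) -> KSpaceFrameSet:
    """Zero every non-sampled phase-encode line; sampled lines copy verbatim."""
    if kdata.shape[-2] != mask.n_lines:
        raise ValueError("k-space height does not match the mask")
    out = np.array(kdata, dtype=np.complex128)
    out[..., ~mask.line_pattern, :] = 0
    return KSpaceFrameSet(kdata=out, mask=mask, scheme=scheme)


def zero_fill_recon(frames: KSpaceFrameSet) -> DWISeries:
    """Direct inverse transform of the zero-filled k-space (network input X_u)."""
    return DWISeries(data=kspace_to_image(frames.kdata), scheme=frames.scheme)


def data_consistency(
    x: np.ndarray, y: np.ndarray, mask: SamplingMask
) -> np.ndarray:
    """Hard data consistency: keep acquired k-space lines, re-transform.

    Returns the inverse transform of mask*y + (1-mask)*FT(x).  A projection:
    applying it twice equals applying it once.
    """
    if x.shape != y.shape:
        raise ValueError("image and k-space frame shapes must agree")
    k = image_to_kspace(x)
    k[..., mask.line_pattern, :] = y[..., mask.line_pattern, :]
    return kspace_to_image(k)


def series_to_kspace(series: DWISeries) -> np.ndarray:
    """Pseudo k-space of the magnitude images (fully sampled)."""
    return image_to_kspace(series.magnitude().astype(np.complex128))
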