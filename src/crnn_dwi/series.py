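"""Frame-indexed DWI image stacks bound to an acquisition scheme."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .scheme import BValueScheme

__all__ = ["DWISeries"]


@dataclass
class DWISeries:
    """A multi-frame DWI stack.

    ``data`` has shape (n_frames, n_slices, H, W) and is complex internally;
    acquisition-like exports take the magnitude. Frames follow the scheme's
    b-major layout (b = 0 first, then directions within each ascending b).
    """

    data: np.ndarray
    scheme: BValueScheme
    subject_id: str | None = None
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single slice
            self.data = self.data[:, None]
        if self.data.ndim != 4:
            raise ValueError("data must have shape (n_frames, n_slices, H, W)")
        if self.data.shape[0] != self.scheme.n_frames:
            raise ValueError(
                f"{self.data.shape[0]} frames but scheme defines {self.scheme.n_frames}"
            )

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def magnitude(self) -> np.ndarray:
        """Elementwise modulus of the complex data."""
        return np.abs(self.data)

    def with_data(self, data: np.ndarray) -> "DWISeries":
        return replace(self, data=data)

    # -- NIfTI export / import ---------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write <prefix>.nii.gz magnitude volume with FSL .bval/.bvec and a
        JSON provenance sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        # NIfTI convention: spatial axes first, frames last
        vol = np.transpose(self.magnitude(), (3, 2, 1, 0)).astype(np.float32)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), str(prefix) + ".nii.gz")
        self.scheme.save_fsl(str(prefix) + ".bval", str(prefix) + ".bvec")
        meta = {
            "subject_id": self.subject_id,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }
        Path(str(prefix) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "DWISeries":
        prefix = str(prefix)
        vol = np.asanyarray(nib.load(prefix + ".nii.gz").dataobj)
        data = np.transpose(vol, (3, 2, 1, 0)).astype(np.complex128)
        scheme = BValueScheme.from_fsl(prefix + ".bval", prefix + ".bvec")
        meta_path = Path(prefix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            data=data,
            scheme=scheme,
            subject_id=meta.get("subject_id"),
            noise_sigma=meta.get("noise_sigma", 0.0),
            seed=meta.get("seed"),
        )
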