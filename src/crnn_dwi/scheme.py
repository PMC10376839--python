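"""Diffusion acquisition schemes: b-values, directions and frame ordering.

A multi-b-value DWI series is a stack of 2D frames, one per
(b-value, direction) combination, with a single b = 0 frame acquired once.
The scheme fixes the mapping between frames and (b, direction) pairs; frame
order is b-major, ascending b, directions in listed order within each b.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["BValueScheme", "DEFAULT_BVALUES", "default_scheme"]

#: Default 14-point b-value ladder spanning 0-4000 s/mm^2.
DEFAULT_BVALUES: tuple[float, ...] = (
    0, 50, 100, 200, 400, 600, 800, 1000, 1500, 2000, 2500, 3000, 3500, 4000
)

#: Three orthogonal diffusion-encoding directions (x, y, z).
DEFAULT_DIRECTIONS: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
)


@dataclass(frozen=True)
class BValueScheme:
    """Ordered b-values and unit gradient directions defining the frame layout.

    Parameters
    ----------
    bvalues:
        Strictly ascending b-values in s/mm^2; the first must be 0.
    directions:
        Unit vectors applied to every nonzero b-value. The b = 0 image is
        acquired once (no direction).
    """

    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    directions: tuple[tuple[float, float, float], ...] = DEFAULT_DIRECTIONS

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        if b.size < 2 or b[0] != 0:
            raise ValueError("bvalues must start at 0 and contain at least one nonzero b")
        if np.any(np.diff(b) <= 0):
            raise ValueError("bvalues must be strictly ascending")
        if len(self.directions) < 1:
            raise ValueError("at least one diffusion direction is required")
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError("directions must be 3-vectors")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors (|norm - 1| <= 1e-6)")

    # -- layout -------------------------------------------------------------

    @property
    def n_bvalues(self) -> int:
        return len(self.bvalues)

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    @property
    def n_frames(self) -> int:
        """One b = 0 frame plus one frame per (nonzero b, direction)."""
        return 1 + (self.n_bvalues - 1) * self.n_directions

    def frame_index(self, b_index: int, dir_index: int | None = None) -> int:
        """Frame position of (b-value index, direction index); bijective.

        For ``b_index == 0`` the direction index is ignored (must be None or 0).
        """
        if b_index == 0:
            if dir_index not in (None, 0):
                raise IndexError("b = 0 is acquired once; no direction index")
            return 0
        if not 1 <= b_index < self.n_bvalues:
            raise IndexError(f"b_index {b_index} out of range")
        if dir_index is None or not 0 <= dir_index < self.n_directions:
            raise IndexError(f"dir_index {dir_index} out of range")
        return 1 + (b_index - 1) * self.n_directions + dir_index

    def frame_bvalue(self, frame: int) -> float:
        return self.bvalues[self.frame_b_index(frame)]

    def frame_b_index(self, frame: int) -> int:
        if frame == 0:
            return 0
        return 1 + (frame - 1) // self.n_directions

    def frame_dir_index(self, frame: int) -> int | None:
        if frame == 0:
            return None
        return (frame - 1) % self.n_directions

    def frames_for_direction(self, dir_index: int) -> list[int]:
        """Frames forming one b-ascending sequence for a single direction.

        The shared b = 0 frame leads every sequence.
        """
        return [0] + [self.frame_index(bi, dir_index) for bi in range(1, self.n_bvalues)]

    # -- FSL dialect IO -----------------------------------------------------

    def frame_bvals(self) -> np.ndarray:
        """Per-frame b-value row (FSL .bval layout)."""
        return np.array([self.frame_bvalue(f) for f in range(self.n_frames)], dtype=float)

    def frame_bvecs(self) -> np.ndarray:
        """3 x n_frames direction table (FSL .bvec layout); zeros for b = 0."""
        vecs = np.zeros((3, self.n_frames))
        for f in range(1, self.n_frames):
            vecs[:, f] = self.directions[self.frame_dir_index(f)]
        return vecs

    def save_fsl(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        np.savetxt(bval_path, self.frame_bvals()[None, :], fmt="%g")
        np.savetxt(bvec_path, self.frame_bvecs(), fmt="%.8f")

    @classmethod
    def from_fsl(cls, bval_path: str | Path, bvec_path: str | Path) -> "BValueScheme":
        """Rebuild a scheme from FSL sidecars written by :meth:`save_fsl`."""
        bvals = np.atleast_1d(np.loadtxt(bval_path)).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] != 3:
            raise ValueError(".bvec must have 3 rows")
        if bvals[0] != 0:
            raise ValueError("first frame must be b = 0")
        ub = sorted(set(bvals.tolist()))
        nz = bvals != 0
        n_dir = int(np.sum(bvals == ub[1])) if len(ub) > 1 else 1
        dirs = [tuple(bvecs[:, f]) for f in range(1, 1 + n_dir)]
        scheme = cls(bvalues=tuple(ub), directions=tuple(dirs))
        if not np.array_equal(scheme.frame_bvals(), bvals):
            raise ValueError("frame order does not follow the b-major layout")
        return scheme


def default_scheme() -> BValueScheme:
    """The 14-b-value, 3-direction acquisition scheme used throughout."""
    return BValueScheme()
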