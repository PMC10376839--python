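"""Synthetic multi-b-value DWI phantoms with exact CTRW ground truth.

The phantom family is a nested-ellipse digital object: an outer "skull"
ellipse enclosing a configurable number of interior elliptical regions, each
carrying its own CTRW parameter tuple (S0, Dm, alpha, beta) drawn from
tissue-plausible uniform ranges.  Signal decay follows the CTRW model
exactly, optional per-direction anisotropy scales Dm (geometric mean 1 per
region), and noise enters as complex Gaussian noise in k-space so the
magnitude statistics are Rician, as in real MRI.

Full-scale geometry mirroring a clinical multi-b-value protocol is
256 x 256 with 25 slices per subject; the package's tests and examples use
a 64 x 64 / 4-slice scale of the same construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kspace import image_to_kspace, kspace_to_image
from .mittag_leffler import mittag_leffler_neg
from .scheme import BValueScheme, default_scheme
from .series import DWISeries

__all__ = [
    "GroundTruthMaps",
    "make_phantom_maps",
    "make_subject_maps",
    "simulate_dwi",
    "make_dataset",
    "DatasetSplit",
]

# Uniform sampling ranges for region parameters.
S0_RANGE = (0.5, 1.0)
DM_RANGE = (0.4e-3, 2.5e-3)  # mm^2/s
ALPHA_RANGE = (0.6, 1.0)
BETA_RANGE = (0.6, 1.0)


@dataclass
class GroundTruthMaps:
    """Exact voxelwise CTRW parameters of a phantom.

    ``region_labels`` is 0 for background, 1 for the outer ellipse and
    2..n_regions+1 for interior regions.  ``aniso_scales[r]`` holds one
    positive scale per diffusion direction for region r, with geometric
    mean 1, multiplying Dm in that direction.
    """

    alpha_map: np.ndarray
    beta_map: np.ndarray
    dm_map: np.ndarray
    s0_map: np.ndarray
    region_labels: np.ndarray
    aniso_scales: dict[int, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    @property
    def fit_mask(self) -> np.ndarray:
        return self.region_labels > 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.alpha_map.shape

    def region_params(self, label: int) -> tuple[float, float, float, float]:
        """(S0, Dm, alpha, beta) of one region (uniform inside it)."""
        sel = self.region_labels == label
        if not np.any(sel):
            raise KeyError(f"no region labelled {label}")
        return (
            float(self.s0_map[sel].flat[0]),
            float(self.dm_map[sel].flat[0]),
            float(self.alpha_map[sel].flat[0]),
            float(self.beta_map[sel].flat[0]),
        )


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, ry: float, rx: float, theta: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * y + st * x) / ry
    v = (-st * y + ct * x) / rx
    return u * u + v * v <= 1.0


def make_phantom_maps(
    height: int,
    width: int,
    n_regions: int,
    seed: int,
    n_directions: int = 3,
    aniso_spread: float = 0.0,
) -> GroundTruthMaps:
    """Nested-ellipse phantom with n_regions interior regions.

    Deterministic per seed.  Each interior ellipse must fall entirely inside
    the outer ellipse; degenerate draws are retried on fresh substreams (at
    most 100 attempts).  ``aniso_spread`` is the half-width of the uniform
    log-scale anisotropy draw (0 gives isotropic diffusion, the default).
    """
    if height < 32 or width < 32:
        raise ValueError("phantom geometry must be at least 32 x 32")
    if n_regions < 1:
        raise ValueError("need at least one interior region")
    rng = np.random.default_rng(seed)
    labels = np.zeros((height, width), dtype=np.int32)
    outer = _ellipse_mask(
        height, width, height / 2, width / 2, 0.44 * height, 0.46 * width, 0.0
    )
    labels[outer] = 1
    for r in range(n_regions):
        placed = False
        for _ in range(100):
            cy = rng.uniform(0.25 * height, 0.75 * height)
            cx = rng.uniform(0.25 * width, 0.75 * width)
            ry = rng.uniform(0.06, 0.16) * height
            rx = rng.uniform(0.06, 0.16) * width
            theta = rng.uniform(0, np.pi)
            ell = _ellipse_mask(height, width, cy, cx, ry, rx, theta)
            if np.any(ell) and np.all(outer[ell]):
                labels[ell] = r + 2
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place interior region {r} inside the phantom")

    maps = {k: np.zeros((height, width)) for k in ("alpha", "beta", "dm", "s0")}
    aniso: dict[int, np.ndarray] = {}
    for label in range(1, n_regions + 2):
        sel = labels == label
        maps["s0"][sel] = rng.uniform(*S0_RANGE)
        maps["dm"][sel] = rng.uniform(*DM_RANGE)
        maps["alpha"][sel] = rng.uniform(*ALPHA_RANGE)
        maps["beta"][sel] = rng.uniform(*BETA_RANGE)
        if aniso_spread > 0:
            logs = rng.uniform(-aniso_spread, aniso_spread, size=n_directions)
            logs -= logs.mean()  # geometric mean exactly 1
            aniso[label] = np.exp(logs)
        else:
            aniso[label] = np.ones(n_directions)
    return GroundTruthMaps(
        alpha_map=maps["alpha"],
        beta_map=maps["beta"],
        dm_map=maps["dm"],
        s0_map=maps["s0"],
        region_labels=labels,
        aniso_scales=aniso,
        seed=seed,
    )


def make_subject_maps(
    n_slices: int,
    height: int,
    width: int,
    n_regions: int,
    seed: int,
    n_directions: int = 3,
    aniso_spread: float = 0.0,
) -> list[GroundTruthMaps]:
    """Independent 2D phantoms for each slice of one subject."""
    seeds = np.random.SeedSequence(seed).generate_state(n_slices) % (2**31)
    return [
        make_phantom_maps(
            height, width, n_regions, int(s),
            n_directions=n_directions, aniso_spread=aniso_spread,
        )
        for s in seeds
    ]


def _noiseless_frames(
    maps: GroundTruthMaps, scheme: BValueScheme
) -> np.ndarray:
    """Exact CTRW signal per frame for one 2D phantom slice."""
    h, w = maps.shape
    frames = np.zeros((scheme.n_frames, h, w))
    frames[0] = maps.s0_map
    labels = np.unique(maps.region_labels)
    for label in labels:
        if label == 0:
            continue
        s0, dm, a, be = maps.region_params(int(label))
        aniso = maps.aniso_scales.get(int(label), np.ones(scheme.n_directions))
        sel = maps.region_labels == label
        for bi in range(1, scheme.n_bvalues):
            b = scheme.bvalues[bi]
            for d in range(scheme.n_directions):
                x = (b * dm * aniso[d]) ** be
                val = s0 * float(mittag_leffler_neg(a, x)[0])
                frames[scheme.frame_index(bi, d)][sel] = val
    return frames


def simulate_dwi(
    maps: GroundTruthMaps | list[GroundTruthMaps],
    scheme: BValueScheme | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    subject_id: str | None = None,
) -> DWISeries:
    """Forward-simulate a DWI series from ground-truth maps.

    The noiseless frame for (b, direction d) is
    S0 * E_alpha(-(b * Dm * aniso_d)^beta) voxelwise; complex Gaussian noise
    of standard deviation ``noise_sigma`` per channel is added in k-space
    (the orthonormal transform makes image-domain noise the same sigma, and
    magnitudes Rician).  Deterministic per seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    scheme = scheme or default_scheme()
    slices = maps if isinstance(maps, list) else [maps]
    stack = np.stack([_noiseless_frames(m, scheme) for m in slices], axis=1)
    data = stack.astype(np.complex128)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        k = image_to_kspace(data)
        k += noise_sigma * (
            rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
        )
        data = kspace_to_image(k)
    return DWISeries(
        data=data,
        scheme=scheme,
        subject_id=subject_id,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass
class DatasetSplit:
    """Per-subject series and ground truth, split 7:2:1 by subject."""

    train: list[tuple[DWISeries, list[GroundTruthMaps]]]
    val: list[tuple[DWISeries, list[GroundTruthMaps]]]
    test: list[tuple[DWISeries, list[GroundTruthMaps]]]
    seed: int = 0

    @property
    def n_train_slices(self) -> int:
        return sum(s.n_slices for s, _ in self.train)

    def manifest(self) -> dict:
        def ids(group):
            return [s.subject_id for s, _ in group]

        return {
            "train": ids(self.train),
            "val": ids(self.val),
            "test": ids(self.test),
            "n_train_slices": self.n_train_slices,
            "seed": self.seed,
        }


def split_subjects(n_subjects: int) -> tuple[int, int, int]:
    """7:2:1 subject split (rounded, each part at least 1)."""
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a train/val/test split")
    n_train = max(1, round(0.7 * n_subjects))
    n_val = max(1, round(0.2 * n_subjects))
    n_test = n_subjects - n_train - n_val
    while n_test < 1:
        if n_train >= n_val and n_train > 1:
            n_train -= 1
        elif n_val > 1:
            n_val -= 1
        n_test = n_subjects - n_train - n_val
    return n_train, n_val, n_test


def make_dataset(
    n_subjects: int,
    slices_per_subject: int,
    height: int,
    width: int,
    scheme: BValueScheme | None = None,
    noise_sigma: float = 0.01,
    seed: int = 0,
    n_regions: int = 3,
    aniso_spread: float = 0.0,
    log: bool = True,
) -> DatasetSplit:
    """Simulate an n-subject cohort and split it 7:2:1 by subject.

    Every subject gets independent per-slice phantoms and an independent
    noise realization, all derived deterministically from ``seed``.
    """
    scheme = scheme or default_scheme()
    n_train, n_val, n_test = split_subjects(n_subjects)
    sub_seeds = np.random.SeedSequence(seed).generate_state(2 * n_subjects) % (2**31)
    subjects = []
    for i in range(n_subjects):
        maps = make_subject_maps(
            slices_per_subject, height, width, n_regions, int(sub_seeds[2 * i]),
            n_directions=scheme.n_directions, aniso_spread=aniso_spread,
        )
        series = simulate_dwi(
            maps, scheme, noise_sigma, int(sub_seeds[2 * i + 1]),
            subject_id=f"sub-{i:02d}",
        )
        subjects.append((series, maps))
    split = DatasetSplit(
        train=subjects[:n_train],
        val=subjects[n_train : n_train + n_val],
        test=subjects[n_train + n_val :],
        seed=seed,
    )
    if log:
        print(
            f"dataset: {n_train}/{n_val}/{n_test} subjects (train/val/test), "
            f"{split.n_train_slices} training slices"
        )
    return split


def save_dataset(split: DatasetSplit, out_dir: str | Path) -> None:
    """Write every subject as NIfTI + bval/bvec and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for group_name in ("train", "val", "test"):
        for series, _ in getattr(split, group_name):
            series.save(out / group_name / series.subject_id)
    (out / "manifest.json").write_text(json.dumps(split.manifest(), indent=2))
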