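"""Continuous-time random walk (CTRW) diffusion model and voxelwise fitting.

The CTRW model describes non-Gaussian diffusion signal decay over b-values as

    S(b) / S0 = E_alpha( -(b * Dm)^beta )

where E_alpha is the one-parameter Mittag-Leffler function, Dm (mm^2/s) is an
anomalous diffusion coefficient, and alpha, beta in (0, 1] capture temporal
and spatial diffusion heterogeneity (alpha = beta = 1 recovers the
mono-exponential ADC model).

Fitting proceeds in two steps per voxel: (i) Dm from a log-linear
mono-exponential regression over all usable b-values, then (ii) alpha and
beta jointly from damped (Levenberg-Marquardt-type) bounded nonlinear least
squares with Dm and S0 held fixed, capped at 80 iterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.optimize import least_squares

from .mittag_leffler import mittag_leffler_neg
from .scheme import BValueScheme
from .series import DWISeries

__all__ = [
    "CTRWParams",
    "CTRWMaps",
    "ctrw_signal",
    "trace_weighted",
    "fit_mono_exponential",
    "fit_ctrw_voxel",
    "fit_ctrw_volume",
]

# Physical clamp for the mono-exponential Dm estimate, mm^2/s.
DM_BOUNDS = (1e-6, 1e-2)
# Box bounds for (alpha, beta); open at 0 to keep E_alpha well defined.
AB_BOUNDS = (1e-3, 1.0)
AB_INIT = (0.9, 0.9)
MAX_ITER = 80
COST_TOL = 1e-10


@dataclass
class CTRWParams:
    """Per-voxel CTRW fit result; invariants: 0 < alpha, beta <= 1, Dm > 0."""

    S0: float
    Dm: float
    alpha: float
    beta: float
    converged: bool = True
    n_iter: int = 0


def ctrw_signal(
    scheme: BValueScheme | np.ndarray, params: CTRWParams
) -> np.ndarray:
    """Normalized decay S/S0 at each b-value of the scheme.

    Element i equals E_alpha(-(b_i * Dm)^beta); the b = 0 entry is exactly 1
    and the sequence is non-increasing in b.
    """
    bvalues = scheme.bvalues if isinstance(scheme, BValueScheme) else scheme
    b = np.asarray(bvalues, dtype=float)
    if not 0.0 < params.alpha <= 1.0 or not 0.0 < params.beta <= 1.0:
        raise ValueError("alpha and beta must lie in (0, 1]")
    if params.Dm <= 0:
        raise ValueError("Dm must be positive")
    x = (b * params.Dm) ** params.beta
    return mittag_leffler_neg(params.alpha, x)


def trace_weighted(series: DWISeries) -> DWISeries:
    """Geometric average over diffusion directions, one frame per b-value.

    Removes first-order direction dependence; the b = 0 frame passes through
    unchanged. Operates on magnitudes (zero voxels give zero geometric mean).
    """
    scheme = series.scheme
    mag = series.magnitude()
    out = np.empty((scheme.n_bvalues,) + mag.shape[1:])
    out[0] = mag[0]
    nd = scheme.n_directions
    for bi in range(1, scheme.n_bvalues):
        frames = [scheme.frame_index(bi, d) for d in range(nd)]
        out[bi] = np.prod(mag[frames], axis=0) ** (1.0 / nd)
    trace_scheme = BValueScheme(bvalues=scheme.bvalues, directions=((1.0, 0.0, 0.0),))
    # one frame per nonzero b in the reduced scheme requires a 1-direction layout
    return DWISeries(
        data=out.astype(np.complex128),
        scheme=trace_scheme,
        subject_id=series.subject_id,
        noise_sigma=series.noise_sigma,
        seed=series.seed,
    )


def fit_mono_exponential(
    bvalues: np.ndarray, signal: np.ndarray
) -> tuple[float, bool]:
    """Mono-exponential Dm: log-linear least squares through the origin.

    Regresses ln(S/S0) on -b over every b-value with positive signal
    (nonpositive entries are dropped); the slope is clamped to
    [1e-6, 1e-2] mm^2/s. Returns (Dm, ok); ok is False when fewer than two
    usable points remain.
    """
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signal, dtype=float)
    use = s > 0
    if use.sum() < 2 or not use[0] or b[0] != 0:
        return DM_BOUNDS[0], False
    y = np.log(s[use] / s[0])
    x = -b[use]
    denom = np.dot(x, x)
    if denom == 0:
        return DM_BOUNDS[0], False
    dm = float(np.dot(x, y) / denom)
    return float(np.clip(dm, *DM_BOUNDS)), True


def fit_ctrw_voxel(
    scheme: BValueScheme | np.ndarray, signal: np.ndarray
) -> CTRWParams:
    """Two-step CTRW fit of one voxel's multi-b-value signal.

    S0 is fixed to the measured b = 0 signal.  Step (i) estimates Dm by the
    mono-exponential regression; step (ii) determines (alpha, beta) by
    bounded damped least squares starting from (0.9, 0.9) with Dm initialized
    at — and refined from — the step-(i) estimate (a fixed biased
    mono-exponential Dm would make exact recovery of CTRW-generated signals
    impossible).  Terminates at relative cost change < 1e-8 or 80 iterations.
    Degenerate inputs return the initialization flagged unconverged.
    """
    bvalues = scheme.bvalues if isinstance(scheme, BValueScheme) else scheme
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signal, dtype=float)
    if s.shape != b.shape:
        raise ValueError("signal must have one entry per b-value")
    s0 = float(s[0])
    failed = CTRWParams(
        S0=max(s0, 0.0), Dm=DM_BOUNDS[0], alpha=AB_INIT[0], beta=AB_INIT[1],
        converged=False, n_iter=0,
    )
    if s0 <= 0:
        return failed
    dm, ok = fit_mono_exponential(b, s)
    if not ok:
        return failed

    use = s > 0
    bb, ss = b[use], s[use] / s0

    def residuals(p: np.ndarray) -> np.ndarray:
        a, be, d = p
        return mittag_leffler_neg(a, (bb * d) ** be) - ss

    try:
        res = least_squares(
            residuals,
            x0=np.array([*AB_INIT, dm]),
            bounds=(
                np.array([AB_BOUNDS[0], AB_BOUNDS[0], DM_BOUNDS[0]]),
                np.array([AB_BOUNDS[1], AB_BOUNDS[1], DM_BOUNDS[1]]),
            ),
            method="trf",
            ftol=COST_TOL,
            xtol=COST_TOL,
            gtol=COST_TOL,
            max_nfev=MAX_ITER,
        )
    except Exception:
        return failed
    if not np.all(np.isfinite(res.x)):
        return failed
    return CTRWParams(
        S0=s0,
        Dm=float(res.x[2]),
        alpha=float(res.x[0]),
        beta=float(res.x[1]),
        converged=bool(res.status > 0 and res.nfev < MAX_ITER),
        n_iter=int(min(res.nfev, MAX_ITER)),
    )


@dataclass
class CTRWMaps:
    """Voxelwise parameter images from :func:`fit_ctrw_volume`.

    Maps share the spatial shape of the fitted volume; voxels outside
    ``fit_mask`` are zero.
    """

    alpha_map: np.ndarray
    beta_map: np.ndarray
    dm_map: np.ndarray
    s0_map: np.ndarray
    fit_mask: np.ndarray
    n_converged: int = 0
    n_fitted: int = 0
    settings: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        """One NIfTI per parameter plus a JSON sidecar with fit settings."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, img in [
            ("alpha", self.alpha_map), ("beta", self.beta_map),
            ("dm", self.dm_map), ("s0", self.s0_map),
            ("fit_mask", self.fit_mask.astype(np.uint8)),
        ]:
            arr = np.transpose(np.atleast_3d(img), (2, 1, 0)).astype(np.float32)
            nib.save(nib.Nifti1Image(arr, np.eye(4)), out / f"{name}.nii.gz")
        sidecar = {
            "n_converged": self.n_converged,
            "n_fitted": self.n_fitted,
            "settings": self.settings,
        }
        (out / "fit.json").write_text(json.dumps(sidecar, indent=2))


def default_fit_mask(b0: np.ndarray) -> np.ndarray:
    """Foreground voxels: b = 0 signal above 5% of its 99th percentile."""
    thr = 0.05 * np.percentile(b0, 99)
    return b0 > thr


def fit_ctrw_volume(
    trace: DWISeries, fit_mask: np.ndarray | None = None
) -> CTRWMaps:
    """Apply :func:`fit_ctrw_voxel` to every voxel of a trace-weighted volume.

    ``trace`` must carry one frame per b-value (output of
    :func:`trace_weighted`). Deterministic given its inputs.
    """
    mag = trace.magnitude()  # (n_b, n_slices, H, W)
    b = np.asarray(trace.scheme.bvalues, dtype=float)
    if mag.shape[0] != b.size:
        raise ValueError("trace must have one frame per b-value")
    spatial = mag.shape[1:]
    if fit_mask is None:
        fit_mask = default_fit_mask(mag[0])
    fit_mask = np.asarray(fit_mask, dtype=bool)
    if fit_mask.ndim == len(spatial) - 1 and spatial[0] == 1:
        fit_mask = fit_mask[None]  # 2D mask on a single-slice volume
    if fit_mask.shape != spatial:
        raise ValueError("fit_mask shape must match the volume")

    maps = {k: np.zeros(spatial) for k in ("alpha", "beta", "dm", "s0")}
    n_conv = 0
    idx = np.argwhere(fit_mask)
    for vox in idx:
        sig = mag[(slice(None), *vox)]
        p = fit_ctrw_voxel(b, sig)
        maps["alpha"][tuple(vox)] = p.alpha
        maps["beta"][tuple(vox)] = p.beta
        maps["dm"][tuple(vox)] = p.Dm
        maps["s0"][tuple(vox)] = p.S0
        n_conv += int(p.converged)
    return CTRWMaps(
        alpha_map=maps["alpha"],
        beta_map=maps["beta"],
        dm_map=maps["dm"],
        s0_map=maps["s0"],
        fit_mask=fit_mask,
        n_converged=n_conv,
        n_fitted=len(idx),
        settings={
            "bounds_alpha_beta": AB_BOUNDS,
            "init_alpha_beta": AB_INIT,
            "dm_bounds": DM_BOUNDS,
            "max_iter": MAX_ITER,
            "cost_tol": COST_TOL,
        },
    )
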