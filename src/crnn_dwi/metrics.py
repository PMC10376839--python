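"""Image-quality metrics and paired statistical comparison of reconstructions.

SSIM uses the standard Gaussian-windowed form (11 x 11 window, sigma = 1.5,
K1 = 0.01, K2 = 0.03); PSNR is 10 log10(data_range^2 / MSE) in dB.  The data
range is the per-volume maximum of the ground-truth magnitude.  Diffusion
image metrics are averaged over frames within a slice, reported per slice;
parameter-map SSIM is computed with the background zeroed (inside the fit
mask only).  Methods are compared with paired t-tests at a Bonferroni-
corrected family-wise level of 0.05.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "ssim",
    "psnr",
    "MetricReport",
    "evaluate_methods",
    "compare_methods",
    "PairwiseTest",
]

PSNR_IDENTICAL = float("inf")  # sentinel for a zero-MSE pair


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float) -> float:
    """Mean local SSIM with an 11 x 11 Gaussian window (sigma 1.5)."""
    if reference.shape != test.shape:
        raise ValueError("ssim requires equal shapes")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(
        structural_similarity(
            reference.astype(float),
            test.astype(float),
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB; +inf sentinel for identical images."""
    if reference.shape != test.shape:
        raise ValueError("psnr requires equal shapes")
    mse = float(np.mean((reference.astype(float) - test.astype(float)) ** 2))
    if mse == 0:
        return PSNR_IDENTICAL
    return 10.0 * math.log10(data_range**2 / mse)


@dataclass
class MetricReport:
    """Per-slice, per-method image metrics and per-map SSIMs.

    ``image_metrics`` rows: (method, slice, ssim, psnr); ``map_metrics``
    rows: (method, slice, parameter, ssim).
    """

    image_metrics: pd.DataFrame
    map_metrics: pd.DataFrame
    data_range: float

    def summary(self) -> pd.DataFrame:
        """mean +/- SD per method and metric."""
        img = self.image_metrics.groupby("method")[["ssim", "psnr"]].agg(["mean", "std"])
        return img

    def map_summary(self) -> pd.DataFrame:
        return (
            self.map_metrics.groupby(["method", "parameter"])["ssim"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def mean_image_metric(self, method: str, metric: str) -> float:
        sel = self.image_metrics[self.image_metrics["method"] == method]
        return float(sel[metric].mean())

    def mean_map_ssim(self, method: str, parameter: str) -> float:
        sel = self.map_metrics[
            (self.map_metrics["method"] == method)
            & (self.map_metrics["parameter"] == parameter)
        ]
        return float(sel["ssim"].mean())

    def save(self, prefix: str | Path) -> None:
        """JSON summary plus a flat CSV (slice, method, metric, value)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        rows = []
        for _, r in self.image_metrics.iterrows():
            rows.append((r["slice"], r["method"], "ssim", r["ssim"]))
            rows.append((r["slice"], r["method"], "psnr", r["psnr"]))
        for _, r in self.map_metrics.iterrows():
            rows.append((r["slice"], r["method"], f"ssim_{r['parameter']}", r["ssim"]))
        flat = pd.DataFrame(rows, columns=["slice", "method", "metric", "value"])
        flat.to_csv(prefix.with_suffix(".csv"), index=False)
        summary = {
            "data_range": self.data_range,
            "image": {
                m: {
                    "ssim_mean": self.mean_image_metric(m, "ssim"),
                    "psnr_mean": self.mean_image_metric(m, "psnr"),
                }
                for m in self.image_metrics["method"].unique()
            },
            "maps": {
                f"{r['method']}/{r['parameter']}": {"ssim_mean": r["mean"]}
                for _, r in self.map_summary().iterrows()
            },
        }
        prefix.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def evaluate_methods(
    reconstructions: dict[str, np.ndarray],
    ground_truth: np.ndarray,
    parameter_maps: dict[str, dict[str, np.ndarray]] | None = None,
    gt_maps: dict[str, np.ndarray] | None = None,
    fit_mask: np.ndarray | None = None,
) -> MetricReport:
    """Score reconstructed magnitude volumes (and CTRW maps) against truth.

    ``reconstructions[method]`` and ``ground_truth`` are magnitude stacks of
    shape (n_frames, n_slices, H, W).  ``parameter_maps[method][param]`` and
    ``gt_maps[param]`` are (n_slices, H, W) images; map SSIM is computed with
    everything outside ``fit_mask`` zeroed.
    """
    data_range = float(ground_truth.max())
    img_rows = []
    n_slices = ground_truth.shape[1]
    for method, rec in reconstructions.items():
        if rec.shape != ground_truth.shape:
            import warnings

            warnings.warn(f"method {method!r} shape mismatch; omitted")
            continue
        for s in range(n_slices):
            vals_s = [
                ssim(ground_truth[f, s], rec[f, s], data_range)
                for f in range(ground_truth.shape[0])
            ]
            vals_p = [
                psnr(ground_truth[f, s], rec[f, s], data_range)
                for f in range(ground_truth.shape[0])
            ]
            img_rows.append((method, s, float(np.mean(vals_s)), float(np.mean(vals_p))))
    image_metrics = pd.DataFrame(img_rows, columns=["method", "slice", "ssim", "psnr"])

    map_rows = []
    if parameter_maps and gt_maps:
        for method, pmaps in parameter_maps.items():
            for param, img in pmaps.items():
                ref = gt_maps[param]
                ref = ref if ref.ndim == 3 else ref[None]
                img3 = img if img.ndim == 3 else img[None]
                for s in range(ref.shape[0]):
                    r, t = ref[s].copy(), img3[s].copy()
                    if fit_mask is not None:
                        m = fit_mask if fit_mask.ndim == 2 else fit_mask[s]
                        r[~m] = 0
                        t[~m] = 0
                    rng_val = float(r.max()) if r.max() > 0 else 1.0
                    map_rows.append((method, s, param, ssim(r, t, rng_val)))
    map_metrics = pd.DataFrame(map_rows, columns=["method", "slice", "parameter", "ssim"])
    return MetricReport(
        image_metrics=image_metrics, map_metrics=map_metrics, data_range=data_range
    )


@dataclass
class PairwiseTest:
    """One paired t-test between two methods on one metric group."""

    method_a: str
    method_b: str
    metric: str
    t_stat: float
    p_raw: float
    n: int
    degenerate: bool = False
    significant: bool = False


@dataclass
class ComparisonTable:
    tests: list[PairwiseTest]
    n_comparisons: int
    alpha_family: float = 0.05

    @property
    def bonferroni_threshold(self) -> float:
        """Adjusted per-test threshold: alpha / number of pairwise tests."""
        return self.alpha_family / self.n_comparisons

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                t.method_a, t.method_b, t.metric, t.t_stat, t.p_raw,
                self.bonferroni_threshold, t.significant, t.degenerate, t.n,
            )
            for t in self.tests
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "method_a", "method_b", "metric", "t", "p_raw",
                "threshold", "significant", "degenerate", "n",
            ],
        )


def compare_methods(report: MetricReport, alpha: float = 0.05) -> ComparisonTable:
    """Paired t-tests per method pair per metric, Bonferroni-corrected.

    Metric groups are image SSIM, image PSNR and per-parameter map SSIM,
    paired by slice.  Zero-variance difference vectors are flagged
    degenerate instead of producing NaN.
    """
    groups: dict[str, dict[str, np.ndarray]] = {}
    for metric in ("ssim", "psnr"):
        per_method = {}
        for m in report.image_metrics["method"].unique():
            sel = report.image_metrics[report.image_metrics["method"] == m]
            per_method[m] = sel.sort_values("slice")[metric].to_numpy()
        if len(per_method) >= 2:
            groups[f"image_{metric}"] = per_method
    for param in report.map_metrics["parameter"].unique() if len(report.map_metrics) else []:
        per_method = {}
        for m in report.map_metrics["method"].unique():
            sel = report.map_metrics[
                (report.map_metrics["method"] == m)
                & (report.map_metrics["parameter"] == param)
            ]
            per_method[m] = sel.sort_values("slice")["ssim"].to_numpy()
        if len(per_method) >= 2:
            groups[f"map_ssim_{param}"] = per_method

    tests: list[PairwiseTest] = []
    for metric, per_method in groups.items():
        methods = sorted(per_method)
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a, b = methods[i], methods[j]
                xa, xb = per_method[a], per_method[b]
                if xa.size != xb.size or xa.size < 2:
                    raise ValueError("paired test needs >= 2 paired observations")
                d = xa - xb
                if np.allclose(d.std(ddof=1), 0):
                    t_stat = 0.0 if np.allclose(d, 0) else math.copysign(math.inf, d.mean())
                    tests.append(
                        PairwiseTest(a, b, metric, t_stat, float("nan"), xa.size, degenerate=True)
                    )
                    continue
                res = stats.ttest_rel(xa, xb)
                tests.append(
                    PairwiseTest(a, b, metric, float(res.statistic), float(res.pvalue), xa.size)
                )
    table = ComparisonTable(tests=tests, n_comparisons=max(len(tests), 1), alpha_family=alpha)
    for t in table.tests:
        t.significant = (not t.degenerate) and t.p_raw < table.bonferroni_threshold
    return table
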