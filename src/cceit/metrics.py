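"""Pixel image-quality metrics and their dataset-level summaries.

All metrics are computed between a reference and a reconstructed
conductivity image expressed on a common byte-like display scale: the
conductivity range [0, sigma_max] S/m is mapped affinely onto [0, 255],
with sigma_max the highest conductivity in the tissue tables (the effusion
fluid, 1.4 S/m).  RMSE and PSNR are therefore comparable across methods,
and SSIM uses the standard stabilizers for L = 255.

SSIM is the global-statistics form (whole-FOV means, variances and
covariance, no sliding window).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .phantom import EPS0, OMEGA_DEFAULT, TISSUES

#: Display scale: conductivity range mapped to [0, 255].
SIGMA_MAX = TISSUES["effusion_fluid"].conductivity  # 1.4 S/m
DISPLAY_MAX = 255.0
PSNR_CAP_DB = 99.0

_C1 = (0.01 * DISPLAY_MAX) ** 2
_C2 = (0.03 * DISPLAY_MAX) ** 2


def conductivity_to_display(sigma: np.ndarray) -> np.ndarray:
    """Map conductivity (S/m) onto the fixed [0, 255] display scale."""
    return np.asarray(sigma) * (DISPLAY_MAX / SIGMA_MAX)


def complex_image_to_display(eps: np.ndarray, omega: float = OMEGA_DEFAULT) -> np.ndarray:
    """Display-scale conductivity from complex relative permittivity."""
    sigma = -np.imag(eps) * omega * EPS0
    return conductivity_to_display(sigma)


@dataclass(frozen=True)
class QualityReport:
    """Per-image quality metrics on the display scale."""

    rmse: float
    psnr_db: float
    ssim: float
    cc: float


def evaluate_pair(
    y: np.ndarray,
    y_hat: np.ndarray,
    c1: float = _C1,
    c2: float = _C2,
) -> QualityReport:
    """RMSE, PSNR, global SSIM and Pearson correlation of one image pair.

    ``y`` is the reference, ``y_hat`` the reconstruction, both flat vectors
    on the display scale.  PSNR uses the reference image maximum as the peak
    value and is capped at 99 dB for identical images.  Zero-variance inputs
    make the correlation undefined; it is returned as NaN with a warning.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    diff = y - y_hat
    mse = float(np.mean(diff**2))
    rmse = float(np.sqrt(mse))

    peak = float(np.max(np.abs(y)))
    if mse == 0 or peak == 0:
        psnr = PSNR_CAP_DB
    else:
        psnr = min(PSNR_CAP_DB, float(10.0 * np.log10(peak**2 / mse)))

    mu_y, mu_h = float(np.mean(y)), float(np.mean(y_hat))
    var_y, var_h = float(np.var(y)), float(np.var(y_hat))
    cov = float(np.mean((y - mu_y) * (y_hat - mu_h)))
    ssim = ((2 * mu_y * mu_h + c1) * (2 * cov + c2)) / (
        (mu_y**2 + mu_h**2 + c1) * (var_y + var_h + c2)
    )

    if var_y == 0 or var_h == 0:
        warnings.warn("zero-variance image: correlation undefined", stacklevel=2)
        cc = float("nan")
    else:
        cc = cov / np.sqrt(var_y * var_h)
    return QualityReport(rmse=rmse, psnr_db=psnr, ssim=float(ssim), cc=float(cc))


METRIC_NAMES = ("rmse", "psnr_db", "ssim", "cc")


@dataclass(frozen=True)
class MetricSummary:
    """Distributional summary of quality metrics over a dataset.

    ``stats[metric]`` holds mean/median/std (population convention);
    ``histograms[metric]`` holds (bin_edges, counts) with 64 fixed-width
    bins over the observed range.
    """

    stats: dict
    histograms: dict
    n: int


def summarize(reports: list[QualityReport], bins: int = 64) -> MetricSummary:
    """Mean, median, population std and histogram per metric."""
    if not reports:
        raise ValueError("cannot summarize an empty collection")
    stats, hists = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        finite = vals[np.isfinite(vals)]
        stats[name] = {
            "mean": float(np.mean(finite)) if finite.size else float("nan"),
            "median": float(np.median(finite)) if finite.size else float("nan"),
            "std": float(np.std(finite)) if finite.size else float("nan"),
        }
        if finite.size:
            counts, edges = np.histogram(finite, bins=bins)
        else:  # pragma: no cover
            counts, edges = np.zeros(bins, dtype=int), np.linspace(0, 1, bins + 1)
        hists[name] = (edges, counts)
    return MetricSummary(stats=stats, histograms=hists, n=len(reports))


def evaluate_batch(y: np.ndarray, y_hat: np.ndarray) -> list[QualityReport]:
    """Evaluate each row pair of two (n, N) display-scale arrays."""
    return [evaluate_pair(y[i], y_hat[i]) for i in range(y.shape[0])]
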