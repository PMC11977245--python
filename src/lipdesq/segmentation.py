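"""Flake segmentation by SD-outlier global thresholding.

Desquamated flakes appear brighter than the surrounding lip surface, but
occupy only a small area, so the grayscale histogram of a lip patch is
long-tailed and unimodal rather than bimodal. Histogram-shape thresholds
(Otsu, Triangle) then cut into the normal region; instead the threshold is
placed as an outlier bound on the intensity distribution::

    T = Mean + k * SD

with Mean and SD the population statistics of the cropped region's pixels
and ``k`` a dimensionless multiplier (default 2.5). Pixels strictly above
T are objects (flakes); the desquamation rate is the object-pixel
percentage of the region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu, threshold_triangle

from .landmarks import LandmarkSet, LipROI, crop, extract_target_region

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
GRAY_WEIGHTS: tuple[float, float, float] = (0.299, 0.587, 0.114)

#: Paper-pinned default multiplier for the SD-outlier threshold.
DEFAULT_K = 2.5

#: Calibration grid for k: 1.5 to 4.5 in steps of 0.1 (31 values).
DEFAULT_K_GRID: tuple[float, ...] = tuple(round(1.5 + 0.1 * i, 1) for i in range(31))


@dataclass(frozen=True)
class ThresholdSpec:
    """A global threshold and how it was obtained.

    For the SD-outlier method ``T = mean + k * sd`` exactly; for Otsu and
    Triangle the mean/sd/k fields are NaN (not applicable).
    """

    mean: float
    sd: float
    k: float
    T: float
    method: str = "sd_outlier"

    def __post_init__(self) -> None:
        if math.isfinite(self.sd) and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.method == "sd_outlier" and math.isfinite(self.k):
            if not math.isclose(self.T, self.mean + self.k * self.sd,
                                rel_tol=0.0, abs_tol=1e-9 * max(1.0, abs(self.T))):
                raise ValueError("inconsistent ThresholdSpec: T != mean + k*sd")


@dataclass(frozen=True)
class DesquamationResult:
    """Desquamation rate of one lip region plus the threshold that produced it."""

    rate: float                      # percent of region area
    n_object_pixels: int
    n_total_pixels: int
    threshold: ThresholdSpec | None = None
    roi: LipROI | None = None

    def to_row(self, subject_id: str | None = None) -> dict:
        t = self.threshold
        row = {
            "subject_id": subject_id,
            "k": t.k if t else float("nan"),
            "mean": t.mean if t else float("nan"),
            "sd": t.sd if t else float("nan"),
            "T": t.T if t else float("nan"),
            "n_object": self.n_object_pixels,
            "n_total": self.n_total_pixels,
            "rate_percent": self.rate,
        }
        return row


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion; output is real-valued in [0, 255].

    A single-channel input is passed through unchanged (as float) with a
    logged note, so grayscale fixtures flow through the same pipeline.
    """
    arr = np.asarray(rgb)
    if arr.ndim == 2:
        logger.info("to_grayscale: input already single-channel; passing through")
        return arr.astype(np.float64)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected H x W x 3 RGB input, got shape {arr.shape}")
    w = np.asarray(GRAY_WEIGHTS, dtype=np.float64)
    return arr[..., :3].astype(np.float64) @ w


def compute_threshold(gray: np.ndarray, k: float = DEFAULT_K) -> ThresholdSpec:
    """SD-outlier threshold of a grayscale region: ``T = mean + k * sd``.

    ``mean`` and ``sd`` are the population statistics (SD divides by N) of
    all pixels in the region. Statistics are intentionally computed on the
    cropped region, not a whole face.
    """
    arr = np.asarray(gray, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot threshold an empty image")
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    mean = float(arr.mean())
    sd = float(arr.std())  # population SD
    return ThresholdSpec(mean=mean, sd=sd, k=float(k), T=mean + k * sd)


def segment(gray: np.ndarray, spec: ThresholdSpec) -> np.ndarray:
    """Binary flake mask: object iff intensity strictly above ``spec.T``.

    Strict comparison pins the boundary so a zero-variance region yields an
    empty mask (rate 0), the only sensible degenerate outcome.
    """
    arr = np.asarray(gray, dtype=np.float64)
    return arr > spec.T


def desquamation_rate(
    mask: np.ndarray, threshold: ThresholdSpec | None = None,
    roi: LipROI | None = None,
) -> DesquamationResult:
    """Percent of object (white) pixels among all pixels of the mask."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        raise ValueError("cannot compute a rate on an empty mask")
    n_obj = int(m.sum())
    n_tot = int(m.size)
    return DesquamationResult(
        rate=100.0 * n_obj / n_tot,
        n_object_pixels=n_obj,
        n_total_pixels=n_tot,
        threshold=threshold,
        roi=roi,
    )


def quantify(image: np.ndarray, lm: LandmarkSet, k: float = DEFAULT_K) -> DesquamationResult:
    """Full measurement on one facial image.

    Composition: extract_target_region -> crop -> to_grayscale ->
    compute_threshold -> segment -> desquamation_rate.
    """
    roi = extract_target_region(lm)
    gray = to_grayscale(crop(image, roi))
    spec = compute_threshold(gray, k=k)
    mask = segment(gray, spec)
    return desquamation_rate(mask, threshold=spec, roi=roi)


def rates_over_grid(gray: np.ndarray, grid: Sequence[float] = DEFAULT_K_GRID) -> np.ndarray:
    """Desquamation rate (percent) at each k of the grid, for one region.

    Shares one pass over the sorted pixel values, so sweeping the full
    31-value grid costs little more than a single threshold.
    """
    arr = np.asarray(gray, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("cannot threshold an empty image")
    mean = arr.mean()
    sd = arr.std()
    ts = mean + np.asarray(grid, dtype=np.float64) * sd
    sorted_vals = np.sort(arr)
    # strictly-above count via right-bisection
    n_above = arr.size - np.searchsorted(sorted_vals, ts, side="right")
    return 100.0 * n_above / arr.size


def _histogram_threshold(gray: np.ndarray, method: str) -> ThresholdSpec:
    arr = np.asarray(gray, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot threshold an empty image")
    q = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if q.min() == q.max():
        # single-valued histogram: threshold equals that value, mask empty
        t = float(q.min())
    elif method == "otsu":
        t = float(threshold_otsu(q, nbins=256))
    else:
        t = float(threshold_triangle(q, nbins=256))
    nan = float("nan")
    return ThresholdSpec(mean=nan, sd=nan, k=nan, T=t, method=method)


def otsu_threshold(gray: np.ndarray) -> ThresholdSpec:
    """Otsu's between-class-variance threshold on the 256-bin histogram."""
    return _histogram_threshold(gray, "otsu")


def triangle_threshold(gray: np.ndarray) -> ThresholdSpec:
    """Triangle (peak-to-tail chord) threshold on the 256-bin histogram."""
    return _histogram_threshold(gray, "triangle")
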