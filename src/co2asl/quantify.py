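"""Brain demarcation, RMS-noise thresholding, and the four activation metrics.

The brain slice is demarcated by an intensity threshold on the baseline
perfusion image; the pixels inside it define the total slice area and the RMS
noise

    RMS = sqrt( sum_i (X_i - mean(X))^2 / n )

(population standard deviation over the n demarcated pixels).  The activation
threshold is 2 x RMS; a pixel strictly above it is activated.  Four scalar
summaries follow: the normalized activation intensity (sum of activated
pixel values of the baseline-normalized map), the activation area (activated
pixel count), the activation intensity per pixel, and the normalized
activation area (fraction of the slice activated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .activation import ActivationMap
from .perfusion import PerfusionMap, as_values


@dataclass
class BrainMask:
    """Demarcated brain slice: binary mask plus the threshold that made it."""

    mask: np.ndarray
    threshold: float
    method: str = "fraction-of-max"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.total_slice_area == 0:
            raise ValueError("brain mask is empty")

    @property
    def total_slice_area(self) -> int:
        return int(self.mask.sum())


@dataclass
class ActivationMetrics:
    """The four scalar activation summaries for one subject x condition."""

    normalized_activation_intensity: float
    activation_area: int
    activation_intensity_per_pixel: float
    normalized_activation_area: float
    rms_noise_used: float
    threshold_used: float
    total_slice_area: int
    per_pixel_convention: str = "activated"


def demarcate_brain(baseline_map: PerfusionMap | np.ndarray,
                    method: str = "fraction-of-max",
                    parameter: float = 0.2) -> BrainMask:
    """Intensity-threshold the baseline image to demarcate the brain slice.

    Methods: "fraction-of-max" (threshold = parameter x robust maximum, the
    99.5th percentile; default parameter 0.2), "absolute" (threshold =
    parameter), "otsu" (parameter ignored).  The resolved threshold is
    recorded on the returned mask.
    """
    base = as_values(baseline_map)
    if not np.isfinite(base).all():
        raise ValueError("baseline map must be finite")
    if method == "fraction-of-max":
        threshold = parameter * float(np.percentile(base, 99.5))
    elif method == "absolute":
        threshold = float(parameter)
    elif method == "otsu":
        threshold = float(threshold_otsu(base))
    else:
        raise ValueError(f"unknown demarcation method: {method!r}")
    mask = base > threshold
    if not mask.any():
        raise ValueError(f"no brain found: no pixel exceeds the "
                         f"{method} threshold {threshold:.4g}")
    return BrainMask(mask=mask, threshold=threshold, method=method)


def rms_noise(image: np.ndarray | ActivationMap, mask: BrainMask | np.ndarray
              ) -> float:
    """Population (divide-by-n) SD of the masked pixel intensities."""
    values = image.values if isinstance(image, ActivationMap) else np.asarray(image, float)
    m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask, bool)
    if isinstance(image, ActivationMap):
        m = m & image.valid
    x = values[m]
    if x.size == 0:
        raise ValueError("mask selects no pixels")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def activated_mask(activation: ActivationMap | np.ndarray,
                   mask: BrainMask | np.ndarray,
                   rms_image: np.ndarray | None = None,
                   threshold: float | None = None
                   ) -> tuple[np.ndarray, float, float]:
    """Activated pixels under the 2 x RMS-noise rule.

    Returns ``(activated, threshold, rms)``.  By default the RMS noise is
    computed on the activation map itself over the brain mask; pass
    ``rms_image`` to compute it on another image (e.g. the baseline map), or
    ``threshold`` to bypass the 2 x RMS rule entirely.  A pixel is activated
    iff it is inside the mask (and valid) and strictly exceeds the threshold.
    """
    values = (activation.values if isinstance(activation, ActivationMap)
              else np.asarray(activation, float))
    m = mask.mask if isinstance(mask, BrainMask) else np.asarray(mask, bool)
    if isinstance(activation, ActivationMap):
        m = m & activation.valid
    if threshold is None:
        rms = rms_noise(rms_image if rms_image is not None else activation,
                        mask)
        threshold = 2.0 * rms
    else:
        rms = float("nan")
    with np.errstate(invalid="ignore"):
        activated = m & (values > threshold)
    return activated, float(threshold), float(rms)


def compute_metrics(activation: ActivationMap | np.ndarray,
                    activated: np.ndarray,
                    mask: BrainMask,
                    threshold: float = float("nan"),
                    rms: float = float("nan"),
                    per_pixel: str = "activated") -> ActivationMetrics:
    """Summarize an activation map into the four scalar metrics.

    ``per_pixel`` chooses the denominator of the intensity-per-pixel metric:
    "activated" (intensity / activation area) or "slice" (intensity / total
    slice area).  With no activated pixels all four metrics are 0.
    """
    if per_pixel not in ("activated", "slice"):
        raise ValueError(f"unknown per_pixel convention: {per_pixel!r}")
    values = (activation.values if isinstance(activation, ActivationMap)
              else np.asarray(activation, float))
    activated = np.asarray(activated, dtype=bool)
    if values.shape != activated.shape or values.shape != mask.mask.shape:
        raise ValueError("activation, activated and mask dimensions differ")
    area = int(activated.sum())
    intensity = float(values[activated].sum()) if area else 0.0
    if area == 0:
        per_px = 0.0
    elif per_pixel == "activated":
        per_px = intensity / area
    else:
        per_px = intensity / mask.total_slice_area
    return ActivationMetrics(
        normalized_activation_intensity=intensity,
        activation_area=area,
        activation_intensity_per_pixel=per_px,
        normalized_activation_area=area / mask.total_slice_area,
        rms_noise_used=float(rms),
        threshold_used=float(threshold),
        total_slice_area=mask.total_slice_area,
        per_pixel_convention=per_pixel,
    )
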