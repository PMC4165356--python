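"""Baseline-normalized activation maps and pixel-wise z-score maps.

The activation map at a CO2 concentration is the per-pixel fractional change
of the perfusion image relative to the 0 %-CO2 baseline image:
(conc - baseline) / baseline, evaluated on brain pixels with a valid
(strictly positive) baseline.  A z-score map over the replicate session maps
gives a parallel, threshold-at-3 view of the same contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .perfusion import PerfusionMap, as_values

#: factor of the robust baseline maximum below which a baseline pixel is
#: treated as non-tissue (division guard)
EPSILON_FRACTION = 1e-6


@dataclass
class ActivationMap:
    """Fractional perfusion change relative to baseline (dimensionless).

    ``values`` is NaN on invalid pixels (outside the mask or with a
    near-zero baseline); ``valid`` marks where the map is defined.
    """

    values: np.ndarray
    valid: np.ndarray
    condition: str | None = None
    mask_applied: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask must share a shape")
        if not np.isfinite(self.values[self.valid]).all():
            raise ValueError("activation map must be finite on valid pixels")


@dataclass
class ZScoreMap:
    values: np.ndarray
    formula: str
    n_baseline: int = 0
    n_conc: int = 0
    threshold_used: float | None = None


def change_map(conc_map: PerfusionMap | np.ndarray,
               baseline_map: PerfusionMap | np.ndarray) -> np.ndarray:
    """Perfusion change induced by CO2: concentration minus baseline."""
    conc = as_values(conc_map)
    base = as_values(baseline_map)
    if conc.shape != base.shape:
        raise ValueError(f"dimension mismatch: {conc.shape} vs {base.shape}")
    return conc - base


def normalize_to_baseline(change: np.ndarray,
                          baseline_map: PerfusionMap | np.ndarray,
                          brain_mask: np.ndarray,
                          epsilon: float | None = None,
                          condition: str | None = None) -> ActivationMap:
    """Divide the change map by the baseline, pixel-by-pixel, on the mask.

    Pixels outside the mask, or whose baseline does not exceed ``epsilon``
    (default: 1e-6 of the robust — 99.5th percentile — baseline maximum),
    are marked invalid and excluded from all downstream sums; the result is
    never infinite.
    """
    change = np.asarray(change, dtype=np.float64)
    base = as_values(baseline_map)
    mask = np.asarray(brain_mask, dtype=bool)
    if not (change.shape == base.shape == mask.shape):
        raise ValueError("change, baseline and mask must share dimensions")
    if epsilon is None:
        robust_max = np.percentile(np.abs(base), 99.5)
        epsilon = EPSILON_FRACTION * robust_max
    valid = mask & (base > epsilon)
    if not valid.any():
        raise ValueError("no valid pixels: baseline is non-positive on the "
                         "entire mask")
    values = np.full(change.shape, np.nan)
    values[valid] = change[valid] / base[valid]
    return ActivationMap(values=values, valid=valid, condition=condition)


def zscore_map(baseline_session_maps: Sequence[PerfusionMap | np.ndarray],
               conc_session_maps: Sequence[PerfusionMap | np.ndarray],
               variant: str = "two-sample") -> ZScoreMap:
    """Pixel-wise z statistic between replicate session maps.

    ``variant="two-sample"`` (default):
        z = (mean_conc - mean_base) / sqrt(var_base/n_base + var_conc/n_conc)
    ``variant="baseline-sd"``:
        z = (mean_conc - mean_base) / sd_base

    Sample variances use ddof=1.  Pixels where both the numerator and the
    pooled spread are zero get z = 0.
    """
    if len(baseline_session_maps) < 2 or len(conc_session_maps) < 2:
        raise ValueError("need >= 2 replicate maps per condition "
                         "(variance undefined otherwise)")
    base = np.stack([as_values(m) for m in baseline_session_maps])
    conc = np.stack([as_values(m) for m in conc_session_maps])
    if base.shape[1:] != conc.shape[1:]:
        raise ValueError("replicate maps must share dimensions")
    num = conc.mean(axis=0) - base.mean(axis=0)
    if variant == "two-sample":
        denom = np.sqrt(base.var(axis=0, ddof=1) / base.shape[0]
                        + conc.var(axis=0, ddof=1) / conc.shape[0])
        formula = "(mean_conc - mean_base)/sqrt(var_base/n_base + var_conc/n_conc), ddof=1"
    elif variant == "baseline-sd":
        denom = base.std(axis=0, ddof=1)
        formula = "(mean_conc - mean_base)/sd_base, ddof=1"
    else:
        raise ValueError(f"unknown z-score variant: {variant!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / denom
    z[(num == 0) & (denom == 0)] = 0.0
    return ZScoreMap(values=z, formula=formula,
                     n_baseline=base.shape[0], n_conc=conc.shape[0])


def threshold_zmap(z: ZScoreMap | np.ndarray, cutoff: float = 3.0
                   ) -> np.ndarray:
    """Binary map of pixels with z strictly above the cutoff.

    One-sided: only perfusion increases count; a pixel at exactly the cutoff
    is not included.
    """
    values = z.values if isinstance(z, ZScoreMap) else np.asarray(z, float)
    if isinstance(z, ZScoreMap):
        z.threshold_used = cutoff
    with np.errstate(invalid="ignore"):
        return values > cutoff
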