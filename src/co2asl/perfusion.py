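"""Control-minus-labeled perfusion mapping.

The ASL perfusion signal is the difference between the averaged control
frames and the averaged labeled frames of a scan session; replicate session
maps at the same CO2 concentration are then averaged into the per-condition
perfusion image.  All values are in arbitrary units proportional to regional
cerebral blood flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_io import ScanSession


@dataclass
class PerfusionMap:
    """2-D perfusion image (a.u., proportional to regional CBF)."""

    values: np.ndarray
    condition: str | None = None
    n_sessions: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("PerfusionMap values must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("PerfusionMap must be finite everywhere")


def as_values(x: PerfusionMap | np.ndarray) -> np.ndarray:
    return x.values if isinstance(x, PerfusionMap) else np.asarray(x, float)


def session_perfusion(session: ScanSession) -> PerfusionMap:
    """mean(control frames) - mean(labeled frames), pixel-wise."""
    control = session.control_frames
    labeled = session.labeled_frames
    if control.shape[1:] != labeled.shape[1:]:
        raise ValueError("control and labeled frames have mismatched shapes")
    values = control.mean(axis=0) - labeled.mean(axis=0)
    return PerfusionMap(values=values,
                        condition=session.metadata.get("condition"))


def concentration_perfusion(session_maps: Sequence[PerfusionMap | np.ndarray]
                            ) -> PerfusionMap:
    """Pixel-wise mean of the replicate session maps for one concentration."""
    if len(session_maps) == 0:
        raise ValueError("need at least one session map to average")
    conditions = {m.condition for m in session_maps
                  if isinstance(m, PerfusionMap) and m.condition is not None}
    if len(conditions) > 1:
        raise ValueError(f"cannot average maps from mixed conditions: "
                         f"{sorted(conditions)}")
    stack = np.stack([as_values(m) for m in session_maps])
    if stack.ndim != 3:
        raise ValueError("all session maps must share identical dimensions")
    return PerfusionMap(values=stack.mean(axis=0),
                        condition=next(iter(conditions), None),
                        n_sessions=len(session_maps))
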