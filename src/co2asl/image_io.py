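"""Reading and writing frame stacks, maps, and metric tables.

Formats: multi-page TIFF for interleaved control/labeled frame stacks (one
page per 64x64 frame, uint16 on disk after an affine quantization), 32-bit
float single-page TIFF for derived maps, CSV for the tidy per-subject metrics
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class MalformedStackError(ValueError):
    """Frame stack violates the interleaved control/labeled layout."""


class CompletenessError(ValueError):
    """Repeated-measures table is missing a subject x condition cell."""


#: stable column order of the metrics CSV
METRIC_COLUMNS = [
    "subject", "group", "condition",
    "normalized_activation_intensity", "activation_area",
    "activation_intensity_per_pixel", "normalized_activation_area",
    "rms_noise", "threshold",
]
METRIC_NAMES = METRIC_COLUMNS[3:7]


@dataclass
class ScanSession:
    """One scan: interleaved control and labeled frames plus metadata.

    ``frames`` is an (n_frames, h, w) float array in acquisition order;
    ``labels`` tags each frame as "control" or "labeled".
    """

    frames: np.ndarray
    labels: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise MalformedStackError("frames must be a (n, h, w) stack")
        if len(self.labels) != self.frames.shape[0]:
            raise MalformedStackError("one label per frame required")
        bad = set(self.labels) - {"control", "labeled"}
        if bad:
            raise MalformedStackError(f"unknown frame labels: {sorted(bad)}")
        if self.n_control != self.n_labeled:
            raise MalformedStackError(
                f"unequal frame counts: {self.n_control} control vs "
                f"{self.n_labeled} labeled")

    @property
    def n_control(self) -> int:
        return sum(1 for lab in self.labels if lab == "control")

    @property
    def n_labeled(self) -> int:
        return sum(1 for lab in self.labels if lab == "labeled")

    @property
    def control_frames(self) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.labels) if lab == "control"]
        return self.frames[idx]

    @property
    def labeled_frames(self) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.labels) if lab == "labeled"]
        return self.frames[idx]


def read_session(path: str | Path, interleave: str = "control-first",
                 scale: float = 1.0, offset: float = 0.0) -> ScanSession:
    """Read an interleaved multi-page TIFF stack as a ScanSession.

    ``interleave`` ("control-first" or "labeled-first") resolves which
    acquisition the even pages are; the source format does not record it and
    getting it wrong flips the sign of every perfusion map, so a warning is
    emitted when the mean control-minus-labeled difference comes out negative.
    ``scale``/``offset`` invert the affine quantization applied on write.
    """
    if interleave not in ("control-first", "labeled-first"):
        raise ValueError(f"unknown interleave convention: {interleave!r}")
    frames = tifffile.imread(str(path))
    frames = np.atleast_3d(frames)
    if frames.ndim != 3:
        raise MalformedStackError(f"{path}: expected a stack of 2-D frames")
    n = frames.shape[0]
    if n % 2:
        raise MalformedStackError(f"{path}: odd page count ({n}); "
                                  "interleaved stacks must pair control and "
                                  "labeled frames")
    first, second = (("control", "labeled") if interleave == "control-first"
                     else ("labeled", "control"))
    labels = (first, second) * (n // 2)
    session = ScanSession(frames=frames.astype(np.float64) * scale + offset,
                          labels=labels, metadata={"path": str(path)})
    diff = session.control_frames.mean() - session.labeled_frames.mean()
    if diff < 0:
        warnings.warn(
            f"{path}: mean (control - labeled) difference is negative "
            f"({diff:.3g}); the interleave convention may be mis-set",
            stacklevel=2)
    return session


def write_session(session: ScanSession, path: str | Path,
                  scale: float = 1.0, offset: float = 0.0) -> None:
    """Write a session as a uint16 multi-page TIFF.

    Values are stored as ``round((v - offset)/scale)`` clipped to the uint16
    range; pass the same scale/offset to :func:`read_session` to recover
    intensities up to the quantization step.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    raw = np.round((session.frames - offset) / scale)
    stack = np.clip(raw, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def write_map(values: np.ndarray, path: str | Path,
              allow_nonfinite: bool = False) -> None:
    """Write a 2-D map as a single-page float32 TIFF (lossless round-trip)."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2:
        raise ValueError("write_map expects a 2-D map")
    if not allow_nonfinite and not np.isfinite(values).all():
        raise ValueError("map contains non-finite values; pass "
                         "allow_nonfinite=True to write anyway")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), values, photometric="minisblack")


def read_map(path: str | Path) -> np.ndarray:
    values = tifffile.imread(str(path))
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-page 2-D map")
    return np.asarray(values)


def check_complete(table: pd.DataFrame) -> None:
    """Raise CompletenessError unless every subject has every condition."""
    conditions = set(table["condition"].unique())
    for subject, sub in table.groupby("subject"):
        missing = conditions - set(sub["condition"])
        if missing:
            raise CompletenessError(
                f"subject {subject!r} is missing condition(s) "
                f"{sorted(missing)}; repeated-measures analysis requires a "
                "balanced table")
        if sub["group"].nunique() != 1:
            raise CompletenessError(
                f"subject {subject!r} appears in multiple groups")


def write_metrics_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy metrics table (one row per subject x condition) as CSV."""
    missing_cols = [c for c in METRIC_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"metrics table is missing columns: {missing_cols}")
    check_complete(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table[METRIC_COLUMNS].to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"condition": str, "subject": str})
    check_complete(table)
    return table
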