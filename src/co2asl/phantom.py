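"""Digital perfusion phantoms for the CO2-challenge ASL pipeline.

The phantom emulates a continuous arterial-spin-labeling (CASL) experiment in
which a rat breathes stepwise-increasing CO2 (0, 7, 10, 15, 20 %, then back to
0 %) while interleaved control/labeled image frames are acquired.  The signal
model is additive and chosen so that the standard control-minus-labeled
subtraction recovers the injected perfusion map exactly in the noiseless
limit:

    control frame = anatomy + perfusion_signal + noise
    labeled frame = anatomy + noise

with, inside an elliptical "brain" region,

    perfusion_signal = baseline * (1 + stress * (g_global(c) + g_roi(c)*ROI))

and zero outside.  ``g_global`` is the brain-wide fractional perfusion
increase at concentration ``c`` (vasodilation), ``g_roi`` the extra increase
inside a dorsal cortical band (neural activation), and ``stress`` in [0, 1]
attenuates both — the occlusion produced by prior chronic stress (1 =
unstressed, 0 = fully occluded).
"""

from __future__ import annotations

import hashlib
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any
from zlib import crc32

import numpy as np
import yaml

from .image_io import ScanSession, write_session

#: Condition labels in acquisition order; "post0" is the return to 0 % CO2
#: after the 20 % step.
DEFAULT_CONDITIONS: tuple[str, ...] = ("0", "7", "10", "15", "20", "post0")

# The study reports a flat dose response across the non-zero concentrations
# ("no dose-dependent differences"), a 15 % whole-slice increase and a 50 %
# total increase in the cortical ROI at 20 % CO2; the default gains mirror
# that: 0.15 global everywhere non-zero, plus 0.35 extra in the ROI.
_DEFAULT_GLOBAL_GAIN = {"0": 0.0, "7": 0.15, "10": 0.15, "15": 0.15,
                        "20": 0.15, "post0": 0.0}
_DEFAULT_ROI_GAIN = {"0": 0.0, "7": 0.35, "10": 0.35, "15": 0.35,
                     "20": 0.35, "post0": 0.0}

#: Affine quantization used when stacks are written to 16-bit TIFF:
#: stored = round((value - offset) / scale), recorded in the manifest.
QUANT_SCALE = 0.05
QUANT_OFFSET = 0.0


@dataclass(frozen=True)
class EllipseGeometry:
    """Axis-aligned ellipse in pixel coordinates (row = y, col = x)."""

    center_y: float = 31.5
    center_x: float = 31.5
    semi_y: float = 18.0
    semi_x: float = 24.0

    def radius(self, grid_size: int) -> np.ndarray:
        """Normalized elliptical radius for every pixel (1 on the boundary)."""
        yy, xx = np.mgrid[0:grid_size, 0:grid_size]
        return np.sqrt(((yy - self.center_y) / self.semi_y) ** 2
                       + ((xx - self.center_x) / self.semi_x) ** 2)


@dataclass(frozen=True)
class BandGeometry:
    """Dorsal band between two normalized elliptical radii of the brain.

    Stands in for the somatosensory/motor cortex: the shell of the brain
    ellipse with normalized radius in [r_inner, r_outer], restricted to rows
    dorsal to (above) the ellipse center.  ``r_outer < 1`` keeps the band
    strictly inside the brain.
    """

    r_inner: float = 0.65
    r_outer: float = 0.92


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth parameters for one synthetic subject.

    All intensities are in arbitrary units (a.u.), matching the scanner's
    uncalibrated output.  ``anatomy_level`` is static tissue signal present in
    both control and labeled frames; it cancels in the subtraction.
    """

    grid_size: int = 64
    brain_geometry: EllipseGeometry = field(default_factory=EllipseGeometry)
    roi_geometry: BandGeometry = field(default_factory=BandGeometry)
    baseline_perfusion: float = 100.0
    anatomy_level: float = 500.0
    global_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GLOBAL_GAIN))
    roi_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ROI_GAIN))
    stress_factor: float = 1.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = self.brain_geometry
        if not (g.semi_y > 0 and g.semi_x > 0):
            raise ValueError("brain semi-axes must be positive")
        if (g.center_y - g.semi_y <= 0 or g.center_y + g.semi_y >= self.grid_size - 1
                or g.center_x - g.semi_x <= 0
                or g.center_x + g.semi_x >= self.grid_size - 1):
            raise ValueError("brain ellipse must lie strictly inside the grid")
        b = self.roi_geometry
        if not (0.0 <= b.r_inner < b.r_outer < 1.0):
            raise ValueError("ROI band must satisfy 0 <= r_inner < r_outer < 1 "
                             "(strictly inside the brain)")
        if not 0.0 <= self.stress_factor <= 1.0:
            raise ValueError("stress_factor must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_perfusion <= 0:
            raise ValueError("baseline_perfusion must be > 0")
        if self.global_gain.get("0", 0.0) != 0.0 or self.roi_gain.get("0", 0.0) != 0.0:
            raise ValueError("gains must be 0 at the 0% baseline condition")

    # -- geometry -----------------------------------------------------------
    def brain_mask(self) -> np.ndarray:
        return self.brain_geometry.radius(self.grid_size) < 1.0

    def roi_mask(self) -> np.ndarray:
        r = self.brain_geometry.radius(self.grid_size)
        dorsal = np.arange(self.grid_size)[:, None] < self.brain_geometry.center_y
        band = (r >= self.roi_geometry.r_inner) & (r < self.roi_geometry.r_outer)
        return band & dorsal

    # -- signal model -------------------------------------------------------
    def gains(self, condition: str) -> tuple[float, float]:
        """(global, roi) fractional gains for a condition label."""
        if condition not in self.global_gain or condition not in self.roi_gain:
            raise ValueError(f"unknown condition label: {condition!r}")
        return self.global_gain[condition], self.roi_gain[condition]

    def perfusion_signal(self, condition: str) -> np.ndarray:
        """Noise-free perfusion map (a.u.) injected at a condition."""
        g_glob, g_roi = self.gains(condition)
        brain = self.brain_mask()
        frac = self.stress_factor * (g_glob + g_roi * self.roi_mask())
        return np.where(brain, self.baseline_perfusion * (1.0 + frac), 0.0)


def _session_rng(spec: PhantomSpec, condition: str, session_index: int
                 ) -> np.random.Generator:
    # crc32 of the label gives a platform-stable per-condition stream key
    key = (crc32(condition.encode("utf-8")), int(session_index))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(spec.seed), spawn_key=key))


def make_scan_session(spec: PhantomSpec, condition: str, session_index: int,
                      n_pairs: int = 8) -> ScanSession:
    """Simulate one scan session: ``n_pairs`` interleaved control/labeled pairs.

    Control frames carry the perfusion signal on top of the static anatomy;
    labeled frames carry anatomy only (the inflowing inverted spins suppress
    the perfusion signal).  Every frame receives independent Gaussian noise.
    Deterministic given ``(spec.seed, condition, session_index)``.
    """
    signal = spec.perfusion_signal(condition)
    rng = _session_rng(spec, condition, session_index)
    shape = (spec.grid_size, spec.grid_size)
    frames = np.empty((2 * n_pairs, *shape), dtype=np.float64)
    labels = []
    for i in range(n_pairs):
        noise_c = rng.normal(0.0, spec.noise_sd, shape) if spec.noise_sd else 0.0
        noise_l = rng.normal(0.0, spec.noise_sd, shape) if spec.noise_sd else 0.0
        frames[2 * i] = spec.anatomy_level + signal + noise_c
        frames[2 * i + 1] = spec.anatomy_level + noise_l
        labels += ["control", "labeled"]
    return ScanSession(frames=frames, labels=tuple(labels),
                       metadata={"condition": condition,
                                 "session_index": session_index})


@dataclass(frozen=True)
class ExperimentDesign:
    """Cohort layout: group x subject x concentration x session."""

    n_per_group: int = 6
    concentrations: tuple[str, ...] = DEFAULT_CONDITIONS
    sessions_per_concentration: int = 4
    pairs_per_session: int = 8
    groups: tuple[str, ...] = ("unstressed", "stressed")
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)
    #: per-group PhantomSpec field overrides; stressed subjects default to a
    #: strong occlusion of the CO2 response
    group_overrides: Mapping[str, Mapping[str, Any]] = field(
        default_factory=lambda: {"stressed": {"stress_factor": 0.2}})
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.concentrations[0] != "0":
            raise ValueError("condition list must begin with the 0% baseline")
        if self.n_per_group < 1 or self.sessions_per_concentration < 1:
            raise ValueError("n_per_group and sessions_per_concentration must be >= 1")

    def subject_spec(self, group: str, subject_index: int) -> PhantomSpec:
        """Resolved spec (including a derived seed) for one subject."""
        if group not in self.groups:
            raise ValueError(f"unknown group: {group!r}")
        overrides = dict(self.group_overrides.get(group, {}))
        ss = np.random.SeedSequence(
            entropy=int(self.master_seed),
            spawn_key=(self.groups.index(group), int(subject_index)))
        seed = int(ss.generate_state(1)[0] % (2 ** 31))
        return replace(self.base_spec, seed=seed, **overrides)

    def subjects(self) -> Iterator[tuple[str, str, PhantomSpec]]:
        for group in self.groups:
            for i in range(self.n_per_group):
                yield group, f"{group}_{i + 1:02d}", self.subject_spec(group, i)


def iter_cohort_sessions(design: ExperimentDesign
                         ) -> Iterator[tuple[str, str, str, int, ScanSession]]:
    """Yield (group, subject, condition, session_index, session) in order."""
    for group, subject, spec in design.subjects():
        for condition in design.concentrations:
            for s in range(design.sessions_per_concentration):
                session = make_scan_session(
                    spec, condition, s, n_pairs=design.pairs_per_session)
                session.metadata.update(group=group, subject=subject)
                yield group, subject, condition, s, session


def _spec_record(spec: PhantomSpec) -> dict:
    return {
        "grid_size": spec.grid_size,
        "brain_geometry": vars(spec.brain_geometry) | {},
        "roi_geometry": vars(spec.roi_geometry) | {},
        "baseline_perfusion": spec.baseline_perfusion,
        "anatomy_level": spec.anatomy_level,
        "global_gain": dict(spec.global_gain),
        "roi_gain": dict(spec.roi_gain),
        "stress_factor": spec.stress_factor,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }


def generate_cohort(design: ExperimentDesign, out_dir: str | Path) -> dict:
    """Write the full cohort to disk and return the ground-truth manifest.

    Layout: ``<group>/<subject>/<condition>/session_<k>.tif`` — one 16-page
    multi-page TIFF per session (uint16 after the affine quantization recorded
    in the manifest, interleave order control-first).  Two calls with the same
    ``master_seed`` produce byte-identical output.  The manifest (also written
    as ``manifest.yaml``) records every injected parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "design": {
            "n_per_group": design.n_per_group,
            "concentrations": list(design.concentrations),
            "sessions_per_concentration": design.sessions_per_concentration,
            "pairs_per_session": design.pairs_per_session,
            "groups": list(design.groups),
            "master_seed": design.master_seed,
        },
        "quantization": {"scale": QUANT_SCALE, "offset": QUANT_OFFSET},
        "interleave": "control-first",
        "subjects": {},
    }
    for group, subject, spec in design.subjects():
        rec = _spec_record(spec)
        rec["roi_total_gain"] = {
            c: spec.stress_factor * (spec.global_gain[c] + spec.roi_gain[c])
            for c in design.concentrations}
        manifest["subjects"][subject] = {"group": group, "spec": rec}
    for group, subject, condition, s, session in iter_cohort_sessions(design):
        path = out / group / subject / condition / f"session_{s + 1}.tif"
        path.parent.mkdir(parents=True, exist_ok=True)
        write_session(session, path, scale=QUANT_SCALE, offset=QUANT_OFFSET)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def cohort_checksum(out_dir: str | Path) -> str:
    """SHA-256 over all TIFF bytes in a cohort directory (sorted paths)."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).rglob("*.tif")):
        h.update(path.relative_to(out_dir).as_posix().encode())
        h.update(path.read_bytes())
    return h.hexdigest()


def design_from_yaml(path: str | Path) -> ExperimentDesign:
    """Build an ExperimentDesign from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    spec_cfg = cfg.pop("base_spec", {})
    if "brain_geometry" in spec_cfg:
        spec_cfg["brain_geometry"] = EllipseGeometry(**spec_cfg["brain_geometry"])
    if "roi_geometry" in spec_cfg:
        spec_cfg["roi_geometry"] = BandGeometry(**spec_cfg["roi_geometry"])
    base = PhantomSpec(**spec_cfg)
    if "concentrations" in cfg:
        cfg["concentrations"] = tuple(str(c) for c in cfg["concentrations"])
    if "groups" in cfg:
        cfg["groups"] = tuple(cfg["groups"])
    return ExperimentDesign(base_spec=base, **cfg)
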