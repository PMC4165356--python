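"""End-to-end orchestration: sessions -> perfusion -> activation -> metrics.

Ties the stage modules together for one subject, for a cohort on disk (the
``<group>/<subject>/<condition>/session_k.tif`` layout), and for fully
in-memory simulated cohorts used in Monte-Carlo studies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import phantom
from .activation import normalize_to_baseline, change_map
from .image_io import METRIC_COLUMNS, ScanSession, read_session, write_metrics_table
from .perfusion import PerfusionMap, concentration_perfusion, session_perfusion
from .quantify import activated_mask, compute_metrics, demarcate_brain


@dataclass
class AnalysisConfig:
    """All analysis choices in one place (serializable to YAML).

    interleave: page order of stacks on disk ("control-first"/"labeled-first")
    baseline_condition: label of the 0 %-CO2 condition
    demarcation_method/parameter: brain-slice intensity threshold rule
    rms_on: image the RMS noise is computed on ("activation" or "baseline")
    per_pixel: intensity-per-pixel denominator ("activated" or "slice")
    z_variant / z_cutoff: z-score formula and threshold
    """

    interleave: str = "control-first"
    baseline_condition: str = "0"
    demarcation_method: str = "fraction-of-max"
    demarcation_parameter: float = 0.2
    rms_on: str = "activation"
    per_pixel: str = "activated"
    z_variant: str = "two-sample"
    z_cutoff: float = 3.0
    epsilon: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def subject_condition_maps(sessions_by_condition: Mapping[str, Sequence[ScanSession]]
                           ) -> dict[str, PerfusionMap]:
    """Per-condition perfusion maps: subtract within sessions, then average."""
    return {cond: concentration_perfusion([session_perfusion(s) for s in sessions])
            for cond, sessions in sessions_by_condition.items()}


def analyze_subject(sessions_by_condition: Mapping[str, Sequence[ScanSession]],
                    config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Run the full per-subject pipeline; one metrics row per condition.

    The baseline (0 %) condition anchors the brain mask and the
    normalization; metrics are reported for every other condition.
    """
    config = config or AnalysisConfig()
    maps = subject_condition_maps(sessions_by_condition)
    if config.baseline_condition not in maps:
        raise ValueError(f"baseline condition {config.baseline_condition!r} "
                         "missing from the session set")
    baseline = maps[config.baseline_condition]
    brain = demarcate_brain(baseline, method=config.demarcation_method,
                            parameter=config.demarcation_parameter)
    rows = []
    for cond, conc in maps.items():
        if cond == config.baseline_condition:
            continue
        act = normalize_to_baseline(change_map(conc, baseline), baseline,
                                    brain.mask, epsilon=config.epsilon,
                                    condition=cond)
        rms_image = baseline.values if config.rms_on == "baseline" else None
        activated, threshold, rms = activated_mask(act, brain,
                                                   rms_image=rms_image)
        metrics = compute_metrics(act, activated, brain, threshold=threshold,
                                  rms=rms, per_pixel=config.per_pixel)
        rows.append({
            "condition": cond,
            "normalized_activation_intensity": metrics.normalized_activation_intensity,
            "activation_area": metrics.activation_area,
            "activation_intensity_per_pixel": metrics.activation_intensity_per_pixel,
            "normalized_activation_area": metrics.normalized_activation_area,
            "rms_noise": metrics.rms_noise_used,
            "threshold": metrics.threshold_used,
        })
    return pd.DataFrame(rows)


def analyze_cohort(root: str | Path, config: AnalysisConfig | None = None
                   ) -> pd.DataFrame:
    """Analyze a cohort directory into the tidy metrics table."""
    config = config or AnalysisConfig()
    root = Path(root)
    quant = {"scale": 1.0, "offset": 0.0}
    manifest_path = root / "manifest.yaml"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
        quant = manifest.get("quantization", quant)
    tables = []
    for group_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for subject_dir in sorted(p for p in group_dir.iterdir() if p.is_dir()):
            sessions = {
                cond_dir.name: [read_session(f, interleave=config.interleave,
                                             scale=quant["scale"],
                                             offset=quant["offset"])
                                for f in sorted(cond_dir.glob("*.tif"))]
                for cond_dir in sorted(p for p in subject_dir.iterdir()
                                       if p.is_dir())
            }
            table = analyze_subject(sessions, config)
            table.insert(0, "subject", subject_dir.name)
            table.insert(1, "group", group_dir.name)
            tables.append(table)
    if not tables:
        raise ValueError(f"no subject data found under {root}")
    return pd.concat(tables, ignore_index=True)[METRIC_COLUMNS]


def simulate_metrics_table(design: phantom.ExperimentDesign,
                           config: AnalysisConfig | None = None
                           ) -> pd.DataFrame:
    """Generate a cohort in memory and run the full analysis on it."""
    config = config or AnalysisConfig()
    tables = []
    for group, subject, spec in design.subjects():
        sessions = {
            cond: [phantom.make_scan_session(spec, cond, s,
                                             n_pairs=design.pairs_per_session)
                   for s in range(design.sessions_per_concentration)]
            for cond in design.concentrations
        }
        table = analyze_subject(sessions, config)
        table.insert(0, "subject", subject)
        table.insert(1, "group", group)
        tables.append(table)
    return pd.concat(tables, ignore_index=True)[METRIC_COLUMNS]
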