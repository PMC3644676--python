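"""Configuration objects for the continuous-tracking learning pipeline.

One structured config governs every stage (stimulus generation, cohort
simulation, first-level GLM, group map).  All randomness is controlled by a
single ``seed``; each stage derives an independent named stream from it via
:class:`numpy.random.SeedSequence` so stages are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

# Stand-in coefficient set for the repeated segment (the original stimulus
# coefficients are not public).  Chosen once so the rendered segment has a
# range of motion comfortably inside +/-20 deg and a non-degenerate slope at
# the segment junctions.
DEFAULT_REPEATED_A = (5.0, 3.0, -2.0, 1.5, 1.0, 0.5)
DEFAULT_REPEATED_B = (4.0, -3.0, 2.0, -1.0, 0.8, -0.5)


@dataclass
class TargetConfig:
    """Stimulus synthesis and difficulty-screening parameters.

    The target is a sinusoidal series of six harmonics traversing one full
    period per segment; segments are screened so random segments match the
    repeated segment's difficulty (range of motion within ``rom_tolerance``,
    mean absolute velocity above ``velocity_floor_frac`` of the repeated
    segment's, junction slope within ``slope_tolerance``).
    """

    duration_s: float = 10.0
    sample_rate: float = 50.0
    coefficient_range: float = 10.0
    rom_tolerance: float = 0.05
    velocity_floor_frac: float = 0.8
    slope_tolerance: float = 0.20
    amplitude_limit_deg: float = 20.0
    repeated_a: tuple = DEFAULT_REPEATED_A
    repeated_b: tuple = DEFAULT_REPEATED_B
    max_attempts: int = 2000


@dataclass
class ScheduleConfig:
    """Trial schedule: practice days of paired repeated/random segments."""

    n_practice_days: int = 5
    blocks_per_day: int = 5
    trials_per_block: int = 10


@dataclass
class CohortConfig:
    """Synthetic cohort with subject-specific lag-learning dynamics.

    Tracking lag decays exponentially with practice day at a condition
    specific rate; the repeated-sequence rate exceeds the random rate so a
    positive temporal-precision difference score emerges by the retention
    day.  Units: lags in ms (negative = response trails target), noise in
    degrees.
    """

    n_subjects: int = 10
    baseline_lag_range_ms: tuple = (-350.0, -250.0)
    rate_repeated_range: tuple = (0.25, 0.55)
    rate_random_range: tuple = (0.05, 0.15)
    motor_noise_sd_range_deg: tuple = (0.8, 2.0)
    segments_per_condition_scan: int = 15


@dataclass
class BoldConfig:
    """Block-design BOLD simulation on a small isotropic grid.

    Each 7-minute run alternates rest and single-condition stimulation
    (40/150/40/150/40 s) at TR 2 s, i.e. 210 volumes; two stimulation blocks
    per run (one repeated, one random, order counterbalanced across runs).
    Behaviour-coupled regions carry a Repeated-Random amplitude equal to
    ``coupling_gain`` times the subject's behavioural weight.
    """

    grid: tuple = (20, 20, 20)
    voxel_size_mm: float = 4.0
    tr_s: float = 2.0
    block_schedule_s: tuple = (40.0, 150.0, 40.0, 150.0, 40.0)
    n_runs: int = 4
    baseline: float = 100.0
    base_task_amplitude: float = 0.8
    coupling_gain: float = 12.0
    uniform_contrast_amplitude: float = 1.2
    noise_sd: float = 1.0
    drift_per_run: float = 0.5
    motion_leak: float = 0.0
    motion_amplitude_mm: float = 0.15


@dataclass
class GlmConfig:
    """First-level GLM: smoothing, HRF shape, statistic type."""

    fwhm_mm: float = 4.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 6.0
    statistic: str = "t"  # or "beta"
    t_cap: float = 1e6


@dataclass
class GroupConfig:
    """Behaviourally weighted group map and cluster thresholding."""

    p_threshold: float = 0.005
    p_threshold_components: float = 0.0005
    min_cluster_voxels: int = 200
    connectivity: int = 6  # 6, 18 or 26 neighbours
    center_weights: bool = False


@dataclass
class PipelineConfig:
    """Top-level configuration: one seed, all stage parameters."""

    seed: int = 0
    targets: TargetConfig = field(default_factory=TargetConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bold: BoldConfig = field(default_factory=BoldConfig)
    glm: GlmConfig = field(default_factory=GlmConfig)
    group: GroupConfig = field(default_factory=GroupConfig)

    # ---- named RNG streams -------------------------------------------------
    _STREAMS = ("segments", "schedule", "cohort", "behavior", "bold")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named purpose, derived from ``seed``."""
        if stream not in self._STREAMS:
            raise KeyError(f"unknown RNG stream {stream!r}; one of {self._STREAMS}")
        idx = self._STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(self._STREAMS))[idx])

    # ---- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        sections = {
            "targets": TargetConfig, "schedule": ScheduleConfig,
            "cohort": CohortConfig, "bold": BoldConfig,
            "glm": GlmConfig, "group": GroupConfig,
        }
        for key, typ in sections.items():
            if key in kw and isinstance(kw[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in kw[key].items()}
                kw[key] = typ(**sub)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "PipelineConfig":
        """Reduced problem size for quick end-to-end runs and tests."""
        cfg = cls(seed=seed)
        cfg.schedule = ScheduleConfig(n_practice_days=2, blocks_per_day=1, trials_per_block=4)
        cfg.cohort = CohortConfig(n_subjects=3, segments_per_condition_scan=3)
        cfg.bold = BoldConfig(grid=(10, 10, 10), n_runs=2)
        return cfg
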