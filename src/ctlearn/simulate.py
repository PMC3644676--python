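"""Synthetic cohort: tracking behaviour and block-design BOLD with known truth.

Each simulated subject has a baseline tracking lag that decays
exponentially with practice day at a condition-specific rate; the repeated
sequence rate exceeds the random rate, so the temporal-precision
difference score becomes positive by the retention day.  Joystick
responses are lagged copies of the target plus Gaussian motor noise.

BOLD runs follow the scanner protocol: 40/150/40/150/40 s rest-stimulation
blocks at TR 2 s (210 volumes per 7-min run), four runs per scan day, one
repeated and one random stimulation block per run with the order
counterbalanced across runs.  A ground-truth region map seeds voxel
amplitudes: behaviour-coupled regions carry a Repeated-Random amplitude
proportional to the subject's behavioural weight, uniform regions carry
the same fixed contrast for every subject, and null regions carry no task
signal.  The simulator convolves boxcars with the same canonical HRF the
GLM uses (a mismatch toggle exists via ``hrf_kwargs``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import BoldConfig, CohortConfig, TargetConfig
from .glm import condition_regressor
from .kinematics import TrackingRecord
from .targets import TargetSegment, make_repeated_segment, sample_random_segment

__all__ = ["SubjectProfile", "BoldRun", "GroundTruth", "make_cohort",
           "programmed_lag_ms", "programmed_weight", "simulate_response",
           "simulate_tracking_day", "default_truth", "simulate_subject_day",
           "simulate_bold", "n_volumes_per_run", "run_timing"]


@dataclass(frozen=True)
class SubjectProfile:
    """Latent behavioural parameters of one simulated subject."""

    subject_id: str
    baseline_lag_ms: float           # <= 0; response trails target
    lag_learning_rate_repeated: float  # per day, >= 0
    lag_learning_rate_random: float
    motor_noise_sd: float            # degrees
    coupling_gain: float             # BOLD amplitude per unit behavioural weight

    def __post_init__(self):
        if self.baseline_lag_ms > 0:
            raise ValueError("baseline_lag_ms must be <= 0")
        if min(self.lag_learning_rate_repeated, self.lag_learning_rate_random,
               self.motor_noise_sd) < 0:
            raise ValueError("rates and noise SD must be >= 0")


@dataclass
class BoldRun:
    """One simulated 4-D run with its timing and motion sidecars."""

    volumes: np.ndarray              # (x, y, z, t)
    tr_s: float
    timing: dict                     # condition -> (onsets_s, durations_s)
    motion: np.ndarray               # (t, 6)
    run_index: int
    day: int
    subject_id: str


@dataclass
class GroundTruth:
    """Disjoint active-region masks with per-region coupling rules."""

    grid: tuple
    coupled_mask: np.ndarray
    uniform_mask: np.ndarray
    null_mask: np.ndarray

    def __post_init__(self):
        overlap = (self.coupled_mask.astype(int) + self.uniform_mask.astype(int)
                   + self.null_mask.astype(int))
        if overlap.max() > 1:
            raise ValueError("ground-truth region masks must be disjoint")


def make_cohort(cfg: CohortConfig, rng: np.random.Generator,
                coupling_gain: float) -> list[SubjectProfile]:
    """Draw a heterogeneous cohort from the configured parameter ranges."""
    profiles = []
    for i in range(cfg.n_subjects):
        profiles.append(SubjectProfile(
            subject_id=f"sub{i + 1:02d}",
            baseline_lag_ms=float(rng.uniform(*cfg.baseline_lag_range_ms)),
            lag_learning_rate_repeated=float(rng.uniform(*cfg.rate_repeated_range)),
            lag_learning_rate_random=float(rng.uniform(*cfg.rate_random_range)),
            motor_noise_sd=float(rng.uniform(*cfg.motor_noise_sd_range_deg)),
            coupling_gain=coupling_gain,
        ))
    return profiles


def programmed_lag_ms(profile: SubjectProfile, day: int, kind: str) -> float:
    """Closed-form tracking lag (ms, <= 0) on a given day and condition."""
    rate = (profile.lag_learning_rate_repeated if kind == "repeated"
            else profile.lag_learning_rate_random)
    return profile.baseline_lag_ms * np.exp(-rate * (day - 1))


def programmed_weight(profile: SubjectProfile, day: int) -> float:
    """Ground-truth temporal-precision weight in seconds (positive = advantage)."""
    diff_ms = (programmed_lag_ms(profile, day, "repeated")
               - programmed_lag_ms(profile, day, "random"))
    return diff_ms / 1000.0


def simulate_response(target: TargetSegment, lag_ms: float, noise_sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Joystick response: target delayed by |lag| plus Gaussian motor noise."""
    t = np.arange(target.samples.size) / target.sample_rate
    delay_s = -lag_ms / 1000.0  # lag <= 0 means trailing
    shifted = np.interp(t - delay_s, t, target.samples,
                        left=target.samples[0], right=target.samples[-1])
    return shifted + rng.normal(0.0, noise_sd, shifted.size)


def simulate_tracking_day(profile: SubjectProfile, day: int,
                          n_segments_per_condition: int,
                          rng: np.random.Generator,
                          target_cfg: TargetConfig | None = None,
                          repeated: TargetSegment | None = None,
                          random_pool: list[TargetSegment] | None = None) -> list[TrackingRecord]:
    """Simulate one day's scored segments for a subject.

    The repeated condition always tracks the fixed repeated segment; the
    random condition tracks fresh screened segments (or segments drawn from
    ``random_pool``, letting a whole cohort share one stimulus set as in
    the task protocol).
    """
    target_cfg = target_cfg or TargetConfig()
    repeated = repeated if repeated is not None else make_repeated_segment(target_cfg)
    records = []
    for i in range(n_segments_per_condition):
        for kind in ("repeated", "random"):
            if kind == "repeated":
                seg = repeated
            elif random_pool is not None:
                seg = random_pool[i % len(random_pool)]
            else:
                seg = sample_random_segment(rng, repeated, target_cfg)
            lag = programmed_lag_ms(profile, day, kind)
            resp = simulate_response(seg, lag, profile.motor_noise_sd, rng)
            records.append(TrackingRecord(
                target=seg.samples, response=resp, sample_rate=seg.sample_rate,
                segment_kind=kind, subject_id=profile.subject_id, day=day,
                trial_index=i))
    return records


def default_truth(grid: tuple = (20, 20, 20)) -> GroundTruth:
    """Three disjoint cubic regions: behaviour-coupled, uniform, null.

    Sized so the coupled and null regions each exceed the 200-voxel cluster
    extent used at the group level; regions are separated by several voxels
    so spatial smoothing does not bleed signal between them.
    """
    nx, ny, nz = grid
    coupled = np.zeros(grid, bool)
    uniform = np.zeros(grid, bool)
    null = np.zeros(grid, bool)
    s = 7 if min(grid) >= 16 else max(1, (min(grid) - 2) // 2)
    lo = slice(1, 1 + s)
    hi = {n: slice(n - 1 - s, n - 1) for n in (nx, ny, nz)}
    coupled[lo, lo, lo] = True
    uniform[hi[nx], hi[ny], lo] = True
    null[hi[nx], lo, hi[nz]] = True
    return GroundTruth(grid=grid, coupled_mask=coupled, uniform_mask=uniform,
                       null_mask=null)


def n_volumes_per_run(cfg: BoldConfig) -> int:
    """Volumes in one run: total block schedule duration / TR."""
    return int(round(sum(cfg.block_schedule_s) / cfg.tr_s))


def run_timing(cfg: BoldConfig, run_index: int) -> dict:
    """Condition onsets/durations for one run, order counterbalanced across runs."""
    sched = cfg.block_schedule_s
    if len(sched) != 5:
        raise ValueError("block schedule must be rest/stim/rest/stim/rest")
    onset1 = sched[0]
    onset2 = sched[0] + sched[1] + sched[2]
    order = ("repeated", "random") if run_index % 2 == 0 else ("random", "repeated")
    return {order[0]: ([onset1], [sched[1]]),
            order[1]: ([onset2], [sched[3]])}


def _smooth_motion(n: int, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Six smooth low-amplitude motion-parameter series (random-walk, lowpassed)."""
    walk = np.cumsum(rng.normal(0, 1, (n, 6)), axis=0)
    walk = ndimage.gaussian_filter1d(walk, sigma=5.0, axis=0)
    walk -= walk.mean(axis=0)
    peak = np.abs(walk).max(axis=0)
    peak[peak == 0] = 1.0
    return walk / peak * amplitude


def simulate_subject_day(profile: SubjectProfile, weight: float,
                         truth: GroundTruth, cfg: BoldConfig, day: int,
                         rng: np.random.Generator,
                         hrf_kwargs: dict | None = None) -> list[BoldRun]:
    """Simulate all runs of one scan day for one subject.

    Voxel model: baseline + amplitude x (boxcar (x) HRF) + linear drift +
    optional motion leak + Gaussian noise.  In coupled regions the
    Repeated-Random amplitude equals ``coupling_gain * weight``; in uniform
    regions it is the same fixed value for every subject; null regions and
    unlabelled voxels carry no task amplitude.
    """
    nv = n_volumes_per_run(cfg)
    amp_rep = np.zeros(truth.grid)
    amp_ran = np.zeros(truth.grid)
    amp_rep[truth.coupled_mask] = cfg.base_task_amplitude + profile.coupling_gain * weight
    amp_ran[truth.coupled_mask] = cfg.base_task_amplitude
    amp_rep[truth.uniform_mask] = cfg.base_task_amplitude + cfg.uniform_contrast_amplitude
    amp_ran[truth.uniform_mask] = cfg.base_task_amplitude

    runs = []
    for r in range(cfg.n_runs):
        timing = run_timing(cfg, r)
        regs = {c: condition_regressor(*timing[c], nv, cfg.tr_s, hrf_kwargs)
                for c in timing}
        drift = cfg.drift_per_run * np.linspace(-1, 1, nv)
        motion = _smooth_motion(nv, rng, cfg.motion_amplitude_mm)
        shared = cfg.baseline + drift
        if cfg.motion_leak:
            shared = shared + cfg.motion_leak * motion.sum(axis=1)
        vols = rng.normal(0.0, cfg.noise_sd, (*truth.grid, nv))
        vols += shared
        vols += amp_rep[..., None] * regs["repeated"]
        vols += amp_ran[..., None] * regs["random"]
        runs.append(BoldRun(volumes=vols, tr_s=cfg.tr_s, timing=timing,
                            motion=motion, run_index=r, day=day,
                            subject_id=profile.subject_id))
    return runs


def simulate_bold(profiles: list[SubjectProfile], weights: dict,
                  truth: GroundTruth, cfg: BoldConfig, day: int,
                  rng: np.random.Generator, hrf_kwargs: dict | None = None):
    """Yield ``(profile, runs)`` per subject; one RNG stream drives the cohort."""
    for profile in profiles:
        yield profile, simulate_subject_day(
            profile, weights[profile.subject_id], truth, cfg, day, rng, hrf_kwargs)
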