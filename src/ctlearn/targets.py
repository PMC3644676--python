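"""Continuous-tracking target synthesis and difficulty screening.

A target segment is a sinusoidal series of six harmonics,

    f(x) = b0 + a1 sin(x) + b1 cos(x) + ... + a6 sin(6x) + b6 cos(6x),

rendered over one full period ``x in [0, 2*pi]`` spanning a 10-s segment
sampled at 50 Hz.  A fixed *repeated* segment is covertly embedded in every
trial; *random* segments are drawn with coefficients in [-10, 10] and
screened so their difficulty matches the repeated segment:

* range of motion (ROM) within 5% of the repeated segment's ROM,
* mean absolute velocity above a floor derived from the repeated segment,
* junction slope within 20% of the repeated segment's slope, so linked
  segments are kinematically seamless in either presentation order.

Segments are centred so min and max are equidistant from the midline and
their ends are adjusted to cross zero, where consecutive segments link.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import TargetConfig

__all__ = [
    "SegmentCoefficients", "TargetSegment", "Trial", "ScreenReport",
    "GenerationError", "render_segment", "center_midline", "zero_endpoints",
    "center_and_zero", "screen_random",
    "sample_random_segment", "make_repeated_segment", "build_schedule",
    "schedule_to_frame", "write_trajectories",
]


class GenerationError(RuntimeError):
    """Raised when no screen-compliant random segment is found."""

    def __init__(self, message: str, failure_counts: dict | None = None):
        super().__init__(message)
        self.failure_counts = dict(failure_counts or {})


@dataclass(frozen=True)
class SegmentCoefficients:
    """Coefficients of the sinusoidal series: offset b0, sine a1..a6, cosine b1..b6."""

    b0: float
    a: tuple[float, ...]
    b: tuple[float, ...]

    def __post_init__(self):
        if len(self.a) != 6 or len(self.b) != 6:
            raise ValueError("expected six sine and six cosine coefficients")
        vals = (self.b0, *self.a, *self.b)
        if not all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.b0, *self.a, *self.b], dtype=float)


@dataclass(frozen=True)
class TargetSegment:
    """One rendered target trajectory (angles in degrees at ``sample_rate`` Hz)."""

    kind: str  # "repeated" | "random"
    coefficients: SegmentCoefficients
    samples: np.ndarray
    duration_s: float = 10.0
    sample_rate: float = 50.0

    @property
    def rom(self) -> float:
        """Peak-to-peak range of motion, degrees."""
        return float(np.ptp(self.samples))

    @property
    def mean_abs_velocity(self) -> float:
        """Mean absolute sample-to-sample velocity, deg/s."""
        return float(np.mean(np.abs(np.diff(self.samples))) * self.sample_rate)

    def start_slope(self) -> float:
        """One-sided slope estimate at the segment start, deg/s."""
        s = self.samples
        return float((s[1] - s[0]) * self.sample_rate)

    def end_slope(self) -> float:
        """One-sided slope estimate at the segment end, deg/s."""
        s = self.samples
        return float((s[-1] - s[-2]) * self.sample_rate)


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of the random-segment difficulty screens."""

    rom: float
    mean_abs_velocity: float
    rom_ok: bool
    velocity_ok: bool
    slope_ok: bool

    @property
    def passed(self) -> bool:
        return self.rom_ok and self.velocity_ok and self.slope_ok


@dataclass(frozen=True)
class Trial:
    """One 20-s trial: a repeated and a random 10-s segment, in counterbalanced order."""

    repeated: TargetSegment
    random: TargetSegment
    order_flag: str  # "repeated-first" | "random-first"
    day: int = 1
    block: int = 1
    trial_index: int = 0

    @property
    def segments(self) -> tuple[TargetSegment, TargetSegment]:
        if self.order_flag == "repeated-first":
            return (self.repeated, self.random)
        return (self.random, self.repeated)


def render_segment(coeffs: SegmentCoefficients, duration_s: float = 10.0,
                   sample_rate: float = 50.0, kind: str = "random") -> TargetSegment:
    """Evaluate the sinusoidal series over one full period.

    ``x_i = 2*pi*i/(N-1)`` with ``N = duration_s * sample_rate`` samples, so
    the segment traverses exactly one period and ``f(0) == f(2*pi)``.
    """
    if duration_s <= 0 or sample_rate <= 0:
        raise ValueError("duration_s and sample_rate must be positive")
    n = int(round(duration_s * sample_rate))
    x = np.linspace(0.0, 2.0 * np.pi, n)
    k = np.arange(1, 7)[:, None]
    f = (coeffs.b0
         + np.asarray(coeffs.a) @ np.sin(k * x)
         + np.asarray(coeffs.b) @ np.cos(k * x))
    return TargetSegment(kind=kind, coefficients=coeffs, samples=f,
                         duration_s=duration_s, sample_rate=sample_rate)


def center_midline(seg: TargetSegment) -> TargetSegment:
    """Shift the offset so minimum and maximum are equidistant from zero."""
    s = seg.samples
    if np.ptp(s) == 0:
        raise ValueError("constant segment cannot be centered (zero range of motion)")
    return replace(seg, samples=s - (s.max() + s.min()) / 2.0)


def zero_endpoints(seg: TargetSegment) -> TargetSegment:
    """Subtract the linear ramp through the endpoints so both ends are 0.

    This is the linkage adjustment that lets consecutive segments cross the
    screen midline where they join.
    """
    s = seg.samples
    return replace(seg, samples=s - np.linspace(s[0], s[-1], s.size))


def center_and_zero(seg: TargetSegment) -> TargetSegment:
    """Centre the segment on the midline and force its ends to cross zero.

    Composition of :func:`center_midline` then :func:`zero_endpoints`.  For
    exact one-period sinusoidal series the endpoints are equal, so the ramp
    is a constant shift: ROM is preserved exactly and the operation is
    idempotent.  Midline symmetry is exact before the linkage shift and
    offset by the shared endpoint value after it.
    """
    return zero_endpoints(center_midline(seg))


def screen_random(seg: TargetSegment, repeated: TargetSegment,
                  rom_tolerance: float = 0.05,
                  velocity_floor_frac: float = 0.8,
                  slope_tolerance: float = 0.20) -> ScreenReport:
    """Audit a random segment against the repeated segment's difficulty.

    Flags:
      rom_ok      -- ROM within ``rom_tolerance`` (fraction) of the repeated ROM
      velocity_ok -- mean |velocity| >= ``velocity_floor_frac`` x repeated's
      slope_ok    -- junction slopes within ``slope_tolerance`` of the
                     repeated segment's, for both linking orders
                     (random end -> repeated start, repeated end -> random start)
    """
    if seg.samples.size != repeated.samples.size or seg.sample_rate != repeated.sample_rate:
        raise ValueError("segments must share duration and sample rate")
    rom, rom_rep = seg.rom, repeated.rom
    rom_ok = abs(rom - rom_rep) <= rom_tolerance * rom_rep
    mav = seg.mean_abs_velocity
    velocity_ok = mav >= velocity_floor_frac * repeated.mean_abs_velocity

    def _close(x, ref):
        return abs(x - ref) <= slope_tolerance * abs(ref)

    slope_ok = (_close(seg.end_slope(), repeated.start_slope())
                and _close(seg.start_slope(), repeated.end_slope()))
    return ScreenReport(rom=rom, mean_abs_velocity=mav, rom_ok=bool(rom_ok),
                        velocity_ok=bool(velocity_ok), slope_ok=bool(slope_ok))


def make_repeated_segment(cfg: TargetConfig | None = None) -> TargetSegment:
    """Render and centre the fixed repeated segment from the configured coefficients."""
    cfg = cfg or TargetConfig()
    coeffs = SegmentCoefficients(b0=0.0, a=tuple(cfg.repeated_a), b=tuple(cfg.repeated_b))
    seg = render_segment(coeffs, cfg.duration_s, cfg.sample_rate, kind="repeated")
    return center_and_zero(seg)


def _finalize_candidate(coeffs: np.ndarray, cfg: TargetConfig) -> TargetSegment:
    c = SegmentCoefficients(b0=0.0, a=tuple(coeffs[:6]), b=tuple(coeffs[6:]))
    seg = render_segment(c, cfg.duration_s, cfg.sample_rate, kind="random")
    return center_and_zero(seg)


def sample_random_segment(rng: np.random.Generator, repeated: TargetSegment,
                          cfg: TargetConfig | None = None,
                          max_attempts: int | None = None) -> TargetSegment:
    """Draw a screened random segment matched in difficulty to ``repeated``.

    Proposal: coefficients drawn uniformly in ``+/-coefficient_range``, then
    rescaled so the rendered ROM falls inside the ROM tolerance band and the
    first sine amplitude solved so the junction slope lands inside the slope
    band (the analytic junction slope of a one-period series is
    ``(2*pi/T) * sum(k * a_k)``).  Every candidate is then centred, checked
    against the +/-20 deg excursion limit and audited with
    :func:`screen_random`; only candidates passing all screens are returned.
    The joint screens are nearly measure-zero under blind uniform draws, so
    the proposal concentrates mass where the audit can pass without ever
    weakening the audit itself.
    """
    cfg = cfg or TargetConfig()
    max_attempts = max_attempts or cfg.max_attempts
    fails = {"range": 0, "coefficients": 0, "rom": 0, "velocity": 0, "slope": 0}
    rom_target = repeated.rom
    slope_target = repeated.start_slope()  # deg/s; == end slope analytically
    dx_dt = 2.0 * np.pi / cfg.duration_s
    k = np.arange(1, 7)

    for _ in range(max_attempts):
        coeffs = rng.uniform(-cfg.coefficient_range, cfg.coefficient_range, 12)
        rom_jit = 0.8 * min(cfg.rom_tolerance, 0.5)
        slope_jit = 0.75 * min(cfg.slope_tolerance, 0.5)
        rom_goal = rom_target * (1.0 + rng.uniform(-rom_jit, rom_jit))
        slope_goal = slope_target * (1.0 + rng.uniform(-slope_jit, slope_jit))
        ok = True
        for _ in range(4):  # alternate ROM rescale / junction-slope solve
            seg = _finalize_candidate(coeffs, cfg)
            if seg.rom == 0:
                ok = False
                break
            coeffs = coeffs * (rom_goal / seg.rom)
            coeffs[0] = slope_goal / dx_dt - k[1:] @ coeffs[1:6]
        if not ok:
            continue
        if np.abs(coeffs).max() > cfg.coefficient_range:
            fails["coefficients"] += 1
            continue
        seg = _finalize_candidate(coeffs, cfg)
        if np.abs(seg.samples).max() > cfg.amplitude_limit_deg:
            fails["range"] += 1
            continue
        report = screen_random(seg, repeated, cfg.rom_tolerance,
                               cfg.velocity_floor_frac, cfg.slope_tolerance)
        if report.passed:
            return seg
        for name, flag in (("rom", report.rom_ok), ("velocity", report.velocity_ok),
                           ("slope", report.slope_ok)):
            if not flag:
                fails[name] += 1

    raise GenerationError(
        f"no screen-compliant random segment in {max_attempts} attempts "
        f"(failures: {fails})", fails)


def build_schedule(n_trials: int, rng: np.random.Generator,
                   cfg: TargetConfig | None = None,
                   trials_per_block: int = 10,
                   n_days: int = 1,
                   repeated: TargetSegment | None = None) -> list[Trial]:
    """Build a counterbalanced trial schedule.

    ``n_trials`` per day, grouped in blocks of ``trials_per_block``; within
    each block exactly half the trials present the repeated segment first.
    The repeated segment is the identical object in every trial; each trial
    receives a freshly drawn screened random segment.
    """
    cfg = cfg or TargetConfig()
    if n_trials % trials_per_block:
        raise ValueError("n_trials must be a whole number of blocks")
    if trials_per_block % 2:
        raise ValueError("trials_per_block must be even for counterbalancing")
    repeated = repeated if repeated is not None else make_repeated_segment(cfg)
    trials: list[Trial] = []
    for day in range(1, n_days + 1):
        for block in range(1, n_trials // trials_per_block + 1):
            flags = ["repeated-first"] * (trials_per_block // 2) + \
                    ["random-first"] * (trials_per_block // 2)
            rng.shuffle(flags)
            for i, flag in enumerate(flags):
                rand_seg = sample_random_segment(rng, repeated, cfg)
                trials.append(Trial(repeated=repeated, random=rand_seg,
                                    order_flag=flag, day=day, block=block,
                                    trial_index=(block - 1) * trials_per_block + i))
    return trials


def schedule_to_frame(trials: list[Trial]) -> pd.DataFrame:
    """Long-format trajectory table: time_s, angle_deg, segment_kind, trial/segment index."""
    rows = []
    for t in trials:
        for seg_index, seg in enumerate(t.segments):
            n = seg.samples.size
            time = (np.arange(n) / seg.sample_rate
                    + seg_index * seg.duration_s)
            rows.append(pd.DataFrame({
                "time_s": time,
                "angle_deg": seg.samples,
                "segment_kind": seg.kind,
                "trial_index": t.trial_index,
                "segment_index": seg_index,
                "day": t.day,
                "block": t.block,
            }))
    return pd.concat(rows, ignore_index=True)


def write_trajectories(trials: list[Trial], path) -> None:
    """Write the schedule's trajectory table as TSV."""
    schedule_to_frame(trials).to_csv(path, sep="\t", index=False)
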