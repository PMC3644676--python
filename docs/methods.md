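# Methods

This note documents the models, numerical choices and known limitations of
the pipeline, in the spirit of a methods appendix: what each stage assumes,
which parameters matter and why their defaults are what they are, and what
the synthetic cohort does and does not establish about real data.

## Stimulus model

A target segment is the sinusoidal series
`f(x) = b0 + Σₖ₌₁⁶ aₖ sin(kx) + bₖ cos(kx)` evaluated over exactly one
period, `x ∈ [0, 2π]`, spanning a 10-s segment at 50 Hz (500 samples).
One period per segment makes `f(0) = f(2π)` and the analytic junction
slope equal at both ends — the property the segment-linking rules rely on.
A 20-s trial holds one repeated and one random segment, order
counterbalanced within blocks.

The shipped repeated-segment coefficients
(`a = (5, 3, −2, 1.5, 1, 0.5)`, `b = (4, −3, 2, −1, 0.8, −0.5)`) are a
synthetic stand-in: they were chosen once so the rendered segment has a
range of motion (≈22.7°) comfortably inside the ±20° excursion limit and a
non-degenerate junction slope (≈12°/s), and are exposed in config.  Any
analysis depending on the *specific* repeated trajectory should supply its
own coefficients.

**Centering and linkage.** Midline symmetry (min and max equidistant from
zero) and zero endpoint crossing are enforced by two successive
adjustments: an offset shift of `(max+min)/2`, then subtraction of the
linear ramp through the endpoints.  For exact one-period series the
endpoints are equal, so the ramp is a constant shift: range of motion is
preserved exactly and the combined operation is idempotent.  The two goals
are mutually exclusive in general; endpoint zeroing is treated as the hard
constraint (it is what allows seamless linking), and midline symmetry is
exact up to the shared endpoint value.

**Difficulty screens.** A random segment is accepted only if (i) its range
of motion is within 5% of the repeated segment's, (ii) its mean absolute
sample-to-sample velocity is at least `velocity_floor_frac` (default 0.8)
of the repeated segment's — the floor is a configurable fraction because
the original criterion was derived empirically from pilot rankings — and
(iii) its junction slopes are within 20% of the repeated segment's for
*both* linking orders, so a segment is reusable in either trial position.
Screens (i) and (iii) select a nearly measure-zero subset of uniform
coefficient draws (measured acceptance below 10⁻⁶), so the sampler uses a
guided proposal: coefficients are drawn uniformly in ±10, rescaled so the
rendered ROM lands inside the tolerance band, and the first sine amplitude
is solved for the junction slope (analytically `(2π/T)·Σ k·aₖ`).  Every
candidate is then centred, checked against the ±20° limit and audited with
the *unmodified* screens; only passing candidates are returned, so the
acceptance guarantee is unchanged — the proposal merely concentrates mass
where the audit can pass.  Candidates exceeding ±20° after centring are
rejected, not rescaled.

## Kinematic decomposition

For each segment, overall error is
`RMSE = sqrt(mean((response − target)²))` in degrees.  The temporal
component is estimated by evaluating the Pearson correlation at every
integer-sample shift within ±2 s (the window is configurable; ±2 s
comfortably covers human visuomotor lags of 100–500 ms), using only the
continuously overlapping samples at each shift with per-shift re-meaning —
no zero padding, so long shifts are not penalised by padding artefacts.
The shift with the largest correlation *magnitude* is the lag, reported in
ms with trailing responses negative; using the magnitude lets an inverted
but otherwise faithful response align at its true delay, which is then
flagged `anti_correlated`.  Ties break toward the smallest |shift|,
favouring the null of no lag.  R² at the best shift is the spatial
accuracy; RMSE recomputed over the lag-corrected overlap is the spatial
error.  Lags are reported at integer-sample (20 ms) resolution; no
sub-sample interpolation is attempted.  Degenerate inputs are flagged
rather than scored: zero-variance overlap at every shift
(`undefined_correlation`), peak |r| below 0.3 (`low_correlation`,
configurable), lag-corrected overlap under 1 s (`short_overlap`).

On generated task stimuli (harmonic content up to 6 cycles/segment) the
estimator recovers injected delays of 0–500 ms exactly in ≥95% of
segments with motor-noise SD up to 20% of signal SD; the rare misses are
±1 sample at the highest noise levels.  Smoother signals have flatter
autocorrelation peaks and correspondingly lower exact-recovery rates.

## Behavioural summary

Difference scores are `mean(repeated) − mean(random)` per subject, day and
measure.  For the error measures (RMSE, spatial error) the sign is
inverted when forming the statistical weight; the lag difference is used
as-is (lags are ≤0 with 0 = no lag, so a positive difference already means
better repeated timing).  A positive weight therefore always denotes a
sequence-specific advantage.  For group-map weighting the pipeline
expresses lag weights in seconds and error weights in degrees; both are
then O(0.1–1), which keeps the summed group statistic on a scale where the
standard-normal threshold is meaningful (see below).

Outlier removal drops values more than 2 SD from the group mean, with mean
and SD computed once on the full table (no re-iteration).  The two-way
fully-within-subject ANOVA uses the standard sums-of-squares decomposition
with each effect tested against its own effect-by-subject interaction, and
reports partial η²; it is cross-validated against an independent
implementation (pingouin) in the test suite.  A zero error mean square
(noiseless constructed data) yields an infinite F and is flagged rather
than masked.  Explicit recognition is scored against the criterion of ≥2/3
true sequences recognised and ≥4/7 foils rejected.

The bundled reference cohort (`ctlearn.datasets`) carries retention-day
weighted difference scores for ten middle-aged participants on an
already-normalised scale; the pipeline reproduces its sign structure
(3/8/1 positive weights across the three measures), not its magnitudes,
whose normalisation is not recoverable.

## First-level GLM

Volumes are smoothed with a 4-mm FWHM Gaussian
(`σ = FWHM / (2√(2 ln 2))` per axis) before fitting.  The design for the
concatenated runs holds, per condition, the run-wise boxcar convolved with
a canonical double-gamma HRF (difference of gamma densities with delay 6 s
and undershoot delay 16 s, ratio 1:6 — parameters configurable; the shape
correlates 0.95 with nilearn's canonical HRF), built on a 20× oversampled
grid so block edges are not quantised to whole volumes and convolution
never crosses run boundaries.  Six motion parameters plus per-run baseline
and linear drift complete the design (2 + 6 + 2·n_runs columns); the
per-run baseline/drift columns are required by concatenation.  Fitting is
voxelwise OLS; the residual sum of squares is computed via the normal
equations with perfect fits clamped to exactly zero so noiseless voxels
are reported as capped (flagged) t values rather than numerical noise.
The Repeated−Random contrast is a t image by default
(`t = c'β / sqrt(σ̂²·c'(X'X)⁻¹c)`), with a beta-difference mode available.
Head-motion realignment, slice-timing, prewhitening and anatomical
registration are out of scope; motion parameters are inputs.

## Weighted group analysis

The group image is `Σᵢ wᵢ·cᵢ(v)/√N`.  Thresholding converts the statistic
to a one-sided p under a standard-normal null (positive tail: the analysis
targets positive brain–behaviour correlations) and keeps suprathreshold
voxels only in connected components of at least 200 voxels
(6-face connectivity by default; 18/26 configurable).  This null is
conventional rather than exact: its calibration depends on the scale of
the weights, which is why the pipeline feeds weights in natural units of
O(0.1–1).  Cluster peaks are reported as 0-based grid indices plus
affine-transformed mm when an affine is present; no atlas space is
implied.

An optional mean-centering of the weights (default **off**, matching the
literal summed-image procedure) addresses a documented confound: a region
activated identically in every subject correlates with any all-positive
weight vector and will appear in the uncentered map; centering removes it
exactly (`Σ(wᵢ−w̄) = 0`) at the cost of also removing any genuine
common-amplitude component.  The simulator's uniform-activation region
exists precisely to exhibit this behaviour, and the test suite verifies
both the appearance (uncentered) and the disappearance (centered).

Day-1 maps index performance-related activation; voxels suprathreshold on
both day 1 and day 7 are subtracted from the day-7 set to leave
learning-specific activation.

## Synthetic cohort: what it emulates, and what it does not

Each simulated subject has a baseline lag drawn from −350 to −250 ms that
decays exponentially with practice day at condition-specific rates
(repeated 0.25–0.55/day, random 0.05–0.15/day), so every subject's
temporal-precision difference score is zero on day 1 and positive by
day 7 — the qualitative signature of sequence-specific learning with
realistic between-subject spread (day-7 lag weights ≈ 0.08–0.20 s).
Responses are lagged copies of the target plus Gaussian motor noise
(0.8–2.0° SD).  BOLD runs follow the scanner protocol exactly
(40/150/40/150/40 s blocks, TR 2 s, 210 volumes, 4 runs/day, block order
counterbalanced across runs) on a 20³ grid of 4-mm voxels with baseline
100, Gaussian noise SD 1, per-run linear drift, and smooth low-amplitude
motion series that can optionally leak into the signal.  Coupled regions
carry `Repeated−Random = coupling_gain × weight` with gain 12 (≈1–2.5%
signal change at typical weights — a strong but plausible block-design
motor response chosen so single-subject contrast t values reach the 7–15
range); the uniform region carries a fixed 1.2 contrast for every subject;
the null region carries no task signal.  The simulator convolves with the
same canonical HRF as the GLM by default — a deliberate choice to avoid
model mismatch in recovery tests — with a mismatch toggle via
`hrf_kwargs`.

The three truth regions are 7³ = 343-voxel cubes, comfortably above the
200-voxel extent threshold and separated by several voxels so smoothing
does not bleed signal between them.  Under these conditions the full loop
(simulate → GLM → weighted map → threshold) recovers 100% of coupled
voxels with 0% false positives in the null region across seeds.

What passing these tests does **not** show about real data: the simulator
has no anatomy, no physiological noise or temporal autocorrelation, no EPI
distortion, no genuine head motion, and its behavioural model is a pure
delay — real tracking error has shape errors the lag model cannot absorb.
The recovery rates are properties of the stated SNR regime, not of 3-T
data.

## Problem sizes and determinism

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` streams (segments, schedule, cohort,
behaviour, BOLD), so reruns are bit-identical; the pipeline manifest
records SHA-256 checksums of every output to make this checkable.  The
validation experiments use 200 seeded segments for lag recovery, 100
accepted segments for the screening re-audit, 20 simulated cohorts
(10 subjects, 20³ grid, 4 runs) for the retention-day recovery test and a
smaller number of two-day cohorts for the overlap logic; the acceptance
script uses 10 and 2 cohorts respectively.  These sizes were chosen to
give stable rates at desk scale.
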