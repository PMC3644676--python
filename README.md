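# ctlearn

Analysis pipeline for **implicit motor sequence learning with a continuous
tracking (CT) task**, from stimulus synthesis to behaviourally weighted
fMRI group maps — with a seeded cohort simulator so every stage can be
validated against known ground truth.

In the CT paradigm a participant tracks a vertically moving target with
wrist movements on a joystick. Each 20-s trial links two 10-s segments: a
fixed *repeated* trajectory, covertly embedded in every trial, and a
freshly generated *random* trajectory. Superior repeated-segment
performance at a delayed retention test indexes sequence-specific implicit
learning. The package implements:

- **Stimulus synthesis** (`ctlearn.targets`). Targets are sinusoidal
  series `f(x) = b0 + Σₖ aₖ sin(kx) + bₖ cos(kx)` (k = 1..6, one period per
  10-s segment, 50 Hz, coefficients in ±10, excursion within ±20°).
  Random segments are screened to match the repeated segment's
  difficulty: range of motion within 5%, mean absolute velocity above a
  floor, junction slope within 20% so linked segments are seamless.
  Trials are counterbalanced (equal chance of either segment first).
- **Kinematic decomposition** (`ctlearn.kinematics`). Overall tracking
  error is RMSE between target and response. A time-series analysis
  cross-correlates the two streams at every integer-sample shift over the
  overlapping sections only; the shift of peak correlation is the time
  lag (ms, negative = trailing, 0 = no lag), the squared correlation at
  that shift (R²) is spatial accuracy, and RMSE after shifting out the lag
  is the spatial error.
- **Behavioural summary** (`ctlearn.summary`). Per-subject difference
  scores `mean(repeated) − mean(random)` per measure and day, with the
  error-measure signs inverted for statistical weighting so positive
  weight = sequence-specific advantage; 2-SD outlier removal; day ×
  sequence repeated-measures ANOVA; explicit-recognition scoring (3 true +
  7 foils, criterion 2/3 hits and 4/7 correct rejections).
- **First-level GLM** (`ctlearn.glm`). 4-mm FWHM Gaussian smoothing;
  concatenated-run design with condition boxcars convolved with a
  canonical double-gamma HRF, six motion regressors, per-run baseline and
  drift; voxelwise OLS; Repeated−Random contrast t-image.
- **Weighted group map** (`ctlearn.groupmap`). The group statistic at each
  voxel is `Σᵢ wᵢ·cᵢ(v) / √N` — each subject's contrast image multiplied
  by their behavioural weight, summed, and scaled — thresholded one-sided
  under a standard-normal null with a cluster-extent rule (default
  p < 0.005 for overall error, p < 0.0005 for the temporal/spatial
  components, 200 contiguous voxels). Day-1/day-7 overlap separates
  performance-related from learning-specific activation.
- **Cohort simulator** (`ctlearn.simulate`). Ten subjects with
  exponentially decaying tracking lags (repeated decaying faster than
  random), motor noise, and block-design BOLD runs
  (40/150/40/150/40 s rest–stimulation at TR 2 s, 210 volumes per run,
  4 runs/day) in which behaviour-coupled regions carry a Repeated−Random
  amplitude proportional to each subject's behavioural weight.

## Worked example

```python
import numpy as np
from ctlearn.targets import make_repeated_segment, sample_random_segment, screen_random
from ctlearn.kinematics import TrackingRecord, score_segment
from ctlearn.simulate import simulate_response
from ctlearn.datasets import reference_weighted_scores
from ctlearn.summary import count_positive

rep = make_repeated_segment()
rand = sample_random_segment(np.random.default_rng(0), rep)
print(screen_random(rand, rep).passed)        # True
print(round(rep.rom, 1), round(rand.rom, 1))  # 22.7 22.9

# a subject tracking 160 ms behind the target with 1 deg motor noise
resp = simulate_response(rep, lag_ms=-160.0, noise_sd=1.0,
                         rng=np.random.default_rng(1))
s = score_segment(TrackingRecord(target=rep.samples, response=resp))
print(round(s.rmse, 2), s.lag_ms, round(s.r2, 3), round(s.spatial_rmse, 2))
# 1.5 -160.0 0.978 0.92

# bundled 10-subject reference cohort: positive weighted difference scores
table = reference_weighted_scores()
print([count_positive(table, m) for m in ("rmse", "lag", "spatial")])
# [3, 8, 1]
```

The RMSE of 1.5° decomposes into a −160 ms time lag (recovered exactly)
and a 0.92° residual spatial error — the motor noise left after the
temporal component is shifted out. In the reference cohort, 3 of 10
subjects show a sequence-specific advantage in overall error, 8 in
temporal precision, and 1 in spatial accuracy.

A full synthetic study (stimuli → behaviour → GLM → group maps, with a
checksummed manifest) runs from one config:

```bash
ctlearn run --seed 1 --out-dir out/
```

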