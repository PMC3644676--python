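"""First-level block-design GLM: smoothing, design matrix, OLS fit, contrast.

Runs from one session are concatenated and fit voxelwise by ordinary least
squares to a design holding, per condition, a boxcar convolved with a
canonical double-gamma haemodynamic response function, six motion
regressors of no interest, and per-run baseline and linear-drift columns.
The Repeated-Random contrast produces the per-subject statistical image
consumed by the weighted group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .config import GlmConfig

__all__ = ["DesignMatrix", "GLMFit", "ContrastImage", "double_gamma_hrf",
           "condition_regressor", "smooth", "build_design", "fit_glm",
           "contrast_repeated_minus_random"]

CONDITIONS = ("repeated", "random")


def double_gamma_hrf(dt: float, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 6.0, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, peak-normalised.

    Difference of two gamma densities with the standard delay
    parameterisation: shape ``peak_s`` for the positive lobe (mode at
    ``peak_s - 1`` seconds) and shape ``undershoot_s`` for the undershoot,
    scaled down by ``ratio``.
    """
    t = np.arange(0.0, duration_s, dt)
    h = stats.gamma.pdf(t, peak_s) - stats.gamma.pdf(t, undershoot_s) / ratio
    return h / h.max()


def condition_regressor(onsets_s, durations_s, n_volumes: int, tr_s: float,
                        hrf_kwargs: dict | None = None,
                        oversample: int = 20) -> np.ndarray:
    """Boxcar for the given stimulation blocks convolved with the HRF.

    Built on an oversampled grid then decimated to the TR so block edges
    are not quantised to whole volumes.
    """
    dt = tr_s / oversample
    n_fine = n_volumes * oversample
    box = np.zeros(n_fine)
    tfine = np.arange(n_fine) * dt
    for onset, dur in zip(np.atleast_1d(onsets_s), np.atleast_1d(durations_s)):
        box[(tfine >= onset) & (tfine < onset + dur)] = 1.0
    h = double_gamma_hrf(dt, **(hrf_kwargs or {}))
    reg = np.convolve(box, h)[:n_fine] * dt
    reg = reg[::oversample]
    return reg / reg.max() if reg.max() > 0 else reg


@dataclass
class DesignMatrix:
    """Concatenated-run design: task, motion and per-run baseline/drift columns."""

    matrix: np.ndarray           # (n_volumes_total, n_columns)
    column_names: list[str]
    tr_s: float
    n_runs: int

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, name: str) -> int:
        return self.column_names.index(name)


@dataclass
class GLMFit:
    """Voxelwise OLS solution over a spatial grid."""

    beta: np.ndarray             # (*grid, n_columns)
    resid_var: np.ndarray        # (*grid,)
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray


@dataclass
class ContrastImage:
    """Per-subject voxelwise Repeated-Random statistic."""

    data: np.ndarray
    statistic: str               # "t" | "beta"
    subject_id: str = ""
    day: int = 1
    capped_mask: np.ndarray | None = None
    affine: np.ndarray | None = None


def smooth(volumes: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian spatial smoothing of a 3-D or 4-D (x,y,z,t) image.

    sigma = fwhm / (2 sqrt(2 ln 2)) per spatial axis; the time axis is
    untouched.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return volumes.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    sigmas = [sigma_vox] * 3 + [0] * (volumes.ndim - 3)
    return ndimage.gaussian_filter(volumes.astype(float), sigmas)


def build_design(run_timings: list[dict], motion: list[np.ndarray], tr_s: float,
                 n_volumes_per_run: list[int],
                 hrf_kwargs: dict | None = None) -> DesignMatrix:
    """Assemble the concatenated-run design matrix.

    ``run_timings[r]`` maps condition name -> (onsets_s, durations_s) within
    run ``r``; ``motion[r]`` is the (n_volumes, 6) motion-parameter table.
    Columns: one HRF-convolved boxcar per condition (convolved within run,
    never across the run boundary), the six concatenated motion regressors,
    then per-run baseline and linear drift.
    """
    n_runs = len(run_timings)
    if len(motion) != n_runs or len(n_volumes_per_run) != n_runs:
        raise ValueError("run_timings, motion and n_volumes_per_run must align")
    for r, (m, nv) in enumerate(zip(motion, n_volumes_per_run)):
        if m.shape != (nv, 6):
            raise ValueError(f"run {r}: motion table shape {m.shape} != ({nv}, 6)")

    total = sum(n_volumes_per_run)
    task = {c: np.zeros(total) for c in CONDITIONS}
    offset = 0
    for r, timing in enumerate(run_timings):
        nv = n_volumes_per_run[r]
        for cond in CONDITIONS:
            onsets, durs = timing.get(cond, ([], []))
            if len(np.atleast_1d(onsets)):
                task[cond][offset:offset + nv] = condition_regressor(
                    onsets, durs, nv, tr_s, hrf_kwargs)
        offset += nv

    cols = [task[c] for c in CONDITIONS]
    names = list(CONDITIONS)
    mot = np.vstack(motion)
    for j in range(6):
        cols.append(mot[:, j])
        names.append(f"motion{j}")
    offset = 0
    for r, nv in enumerate(n_volumes_per_run):
        base = np.zeros(total)
        base[offset:offset + nv] = 1.0
        drift = np.zeros(total)
        drift[offset:offset + nv] = np.linspace(-1, 1, nv)
        cols += [base, drift]
        names += [f"baseline_run{r}", f"drift_run{r}"]
        offset += nv
    X = np.column_stack(cols)
    return DesignMatrix(matrix=X, column_names=names, tr_s=tr_s, n_runs=n_runs)


def _rank_deficient_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank (diagnostic only)."""
    bad = []
    rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        Xr = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(Xr) == rank:
            bad.append(names[j])
    return bad


def fit_glm(volumes: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Voxelwise ordinary least squares on concatenated volumes (x,y,z,t)."""
    X = design.matrix
    n, p = X.shape
    if volumes.shape[-1] != n:
        raise ValueError("time dimension does not match the design")
    if np.linalg.matrix_rank(X) < p:
        bad = _rank_deficient_columns(X, design.column_names)
        raise ValueError(f"rank-deficient design; implicated columns: {bad}")
    grid = volumes.shape[:-1]
    Y = np.ascontiguousarray(volumes.reshape(-1, n))  # (V, n)
    xtx_inv = np.linalg.inv(X.T @ X)
    ytx = Y @ X                                       # (V, p)
    beta = ytx @ xtx_inv
    df = n - p
    # residual sum of squares without materialising the residual:
    # ||y - Xb||^2 = y'y - b'(X'y); clamp tiny negative round-off (noiseless data)
    yty = np.einsum("vn,vn->v", Y, Y)
    rss = yty - np.einsum("vp,vp->v", beta, ytx)
    rss = np.where(rss < yty * 1e-10, 0.0, rss)  # perfect fits -> exactly zero
    resid_var = np.maximum(rss, 0.0) / df
    return GLMFit(beta=beta.reshape(*grid, p),
                  resid_var=resid_var.reshape(grid),
                  df=df, design=design, xtx_inv=xtx_inv)


def contrast_repeated_minus_random(fit: GLMFit, statistic: str | None = None,
                                   cfg: GlmConfig | None = None,
                                   subject_id: str = "", day: int = 1) -> ContrastImage:
    """Repeated-Random contrast image (t statistic by default).

    t = c'beta / sqrt(var * c'(X'X)^-1 c).  Voxels with zero residual
    variance (noiseless data) would yield infinite t; they are capped at
    ``cfg.t_cap`` and reported in ``capped_mask``.
    """
    cfg = cfg or GlmConfig()
    statistic = statistic or cfg.statistic
    d = fit.design
    c = np.zeros(d.n_columns)
    c[d.column_index("repeated")] = 1.0
    c[d.column_index("random")] = -1.0
    effect = fit.beta @ c
    if statistic == "beta":
        return ContrastImage(effect, "beta", subject_id, day)
    if statistic != "t":
        raise ValueError("statistic must be 't' or 'beta'")
    cvc = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(fit.resid_var * cvc)
    capped = ~np.isfinite(t)
    t = np.where(capped, np.sign(effect) * cfg.t_cap, t)
    t = np.clip(t, -cfg.t_cap, cfg.t_cap)
    return ContrastImage(t, "t", subject_id, day, capped_mask=capped)
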