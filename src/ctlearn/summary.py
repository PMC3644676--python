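"""Behavioural aggregation: difference scores, outliers, ANOVA, recognition.

Sequence-specific learning is indexed by the difference score
``mean(repeated) - mean(random)`` per subject, day and measure.  For the
error measures (overall RMSE and spatial error) the sign is inverted when
forming the statistical *weight*, so a positive weight always means a
sequence-specific advantage; for the lag measure (negative = trailing,
0 = no lag) the raw difference already has that orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MEASURES", "DifferenceScore", "RecognitionResult",
           "difference_scores", "count_positive", "remove_outliers",
           "rm_anova", "mauchly_test", "score_recognition", "normalize_blocks"]

#: measure name -> (score-table column, weight sign applied to the difference)
MEASURES = {
    "rmse": ("rmse", -1.0),
    "lag": ("lag_ms", +1.0),
    "spatial": ("spatial_rmse", -1.0),
}


@dataclass(frozen=True)
class DifferenceScore:
    subject_id: str
    measure: str
    mean_repeated: float
    mean_random: float

    @property
    def diff(self) -> float:
        return self.mean_repeated - self.mean_random

    @property
    def weight(self) -> float:
        return MEASURES[self.measure][1] * self.diff


@dataclass(frozen=True)
class RecognitionResult:
    """Explicit-recognition outcome: 3 true sequences and 7 foils, forced choice."""

    hits: int
    correct_rejections: int

    @property
    def percent_correct(self) -> float:
        return 100.0 * (self.hits + self.correct_rejections) / 10.0

    @property
    def explicit(self) -> bool:
        # criterion: at least 2 of 3 true sequences and 4 of 7 foils correct
        return self.hits >= 2 and self.correct_rejections >= 4


def difference_scores(scores: pd.DataFrame, day: int,
                      measures=("rmse", "lag", "spatial"),
                      lag_unit: str = "ms") -> pd.DataFrame:
    """Per-subject sequence-specific difference scores for one day.

    Means are taken over all of that day's segments per sequence kind.
    Subjects missing either kind are excluded (logged in the ``excluded``
    attribute of the returned frame).  ``lag_unit='s'`` reports the lag
    difference and weight in seconds, a scale comparable to the error
    measures in degrees.
    """
    day_scores = scores[scores["day"] == day]
    rows, excluded = [], []
    for subject, grp in day_scores.groupby("subject_id"):
        kinds = set(grp["segment_kind"])
        if not {"repeated", "random"} <= kinds:
            excluded.append(subject)
            continue
        for measure in measures:
            col, sign = MEASURES[measure]
            m_rep = grp.loc[grp["segment_kind"] == "repeated", col].mean()
            m_ran = grp.loc[grp["segment_kind"] == "random", col].mean()
            scale = 1e-3 if (measure == "lag" and lag_unit == "s") else 1.0
            diff = (m_rep - m_ran) * scale
            rows.append({"subject_id": subject, "day": day, "measure": measure,
                         "mean_repeated": m_rep * scale, "mean_random": m_ran * scale,
                         "diff": diff, "weight": sign * diff})
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def count_positive(diff_table: pd.DataFrame, measure: str) -> int:
    """Number of subjects with a strictly positive weight on ``measure``."""
    sel = diff_table[diff_table["measure"] == measure]
    return int((sel["weight"] > 0).sum())


def remove_outliers(values: pd.DataFrame, column: str = "value",
                    n_sd: float = 2.0) -> pd.DataFrame:
    """Drop rows more than ``n_sd`` standard deviations from the group mean.

    The mean and SD are computed once on the full table (no iteration).
    """
    if len(values) < 3:
        raise ValueError("need at least 3 rows to define outliers")
    v = values[column].to_numpy(dtype=float)
    mu, sd = v.mean(), v.std(ddof=1)
    keep = np.abs(v - mu) <= n_sd * sd
    return values.loc[keep].reset_index(drop=True)


def rm_anova(data: pd.DataFrame, dv: str = "value", subject: str = "subject_id",
             within=("day", "sequence")) -> pd.DataFrame:
    """Two-way fully within-subject (repeated-measures) ANOVA.

    Standard sums-of-squares decomposition with each effect tested against
    its own effect-by-subject interaction.  Requires a complete balanced
    design (one observation per subject x cell).  Returns a frame with
    F, df, p and partial eta squared per effect; a zero error mean square
    yields an infinite F flagged in the ``flag`` column.
    """
    fa, fb = within
    cell = data.pivot_table(index=subject, columns=[fa, fb], values=dv)
    if cell.isna().any().any():
        raise ValueError("incomplete design: missing subject x cell observations")
    arr = cell.to_numpy(dtype=float)
    s = arr.shape[0]
    a = data[fa].nunique()
    b = data[fb].nunique()
    y = arr.reshape(s, a, b)

    gm = y.mean()
    mean_s = y.mean(axis=(1, 2))
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_sa = y.mean(axis=2)
    mean_sb = y.mean(axis=1)
    mean_ab = y.mean(axis=0)

    ss_a = s * b * np.sum((mean_a - gm) ** 2)
    ss_b = s * a * np.sum((mean_b - gm) ** 2)
    ss_ab = s * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((mean_sa - mean_s[:, None] - mean_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((mean_sb - mean_s[:, None] - mean_b[None, :] + gm) ** 2)
    ss_tot = np.sum((y - gm) ** 2)
    ss_subj = a * b * np.sum((mean_s - gm) ** 2)
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_as - ss_bs - ss_subj

    effects = [
        (fa, ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        (fb, ss_b, b - 1, ss_bs, (b - 1) * (s - 1)),
        (f"{fa}*{fb}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (s - 1)),
    ]
    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in effects:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        flag = ""
        if ms_err == 0 or not np.isfinite(ms_err):
            f = 0.0 if ss_eff == 0 else np.inf
            p = 1.0 if ss_eff == 0 else 0.0
            flag = "degenerate_error_term" if ss_eff else ""
        else:
            f = ms_eff / ms_err
            p = float(stats.f.sf(f, df_eff, df_err))
        denom = ss_eff + ss_err
        eta_p2 = ss_eff / denom if denom > 0 else 0.0
        rows.append({"effect": name, "F": f, "df1": df_eff, "df2": df_err,
                     "p": p, "partial_eta_sq": eta_p2, "flag": flag})
    return pd.DataFrame(rows)


def mauchly_test(data: pd.DataFrame, dv: str = "value",
                 subject: str = "subject_id", within: str = "day"):
    """Mauchly's test of sphericity for one within-subject factor.

    Returns ``(W, chi2, df, p)``; small p flags a sphericity violation
    (the ANOVA itself applies no correction — the flag is advisory).
    Factors with two levels are trivially spherical (W = 1, p = 1).
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("incomplete design for sphericity test")
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    if k <= 2:
        return 1.0, 0.0, 0, 1.0
    # orthonormal contrasts of the factor levels
    c = np.linalg.qr(np.eye(k) - 1.0 / k, mode="complete")[0][:, :k - 1]
    a = c.T @ np.cov(y, rowvar=False) @ c
    d = k - 1
    w = float(np.linalg.det(a) / (np.trace(a) / d) ** d)
    df = d * (d + 1) // 2 - 1
    # Box's chi-square approximation with second-order correction
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d ** 2 + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f) ** 2))
    chi2 = -(n - 1) * f * np.log(w)
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w, float(chi2), df, p


def score_recognition(is_true_sequence, judged_recognized) -> RecognitionResult:
    """Score the 10-item explicit recognition test (3 true + 7 foils)."""
    truth = np.asarray(is_true_sequence, dtype=bool)
    judged = np.asarray(judged_recognized, dtype=bool)
    if truth.shape != judged.shape or truth.size != 10:
        raise ValueError("expected 10 paired truth/judgement items")
    if truth.sum() != 3:
        raise ValueError("expected exactly 3 true sequences and 7 foils")
    hits = int(np.sum(truth & judged))
    cr = int(np.sum(~truth & ~judged))
    return RecognitionResult(hits=hits, correct_rejections=cr)


def normalize_blocks(block_means: pd.DataFrame, value: str = "value",
                     subject: str = "subject_id") -> pd.DataFrame:
    """Normalise practice-day block means per subject for plotting.

    Each subject's values are divided by that subject's first available
    block mean, so learning curves are comparable across subjects.  Used
    for display only; difference scores always use raw values.
    """
    def _norm(g):
        ref = g[value].iloc[0]
        g = g.copy()
        g[value] = g[value] / ref if ref != 0 else np.nan
        return g
    cols = block_means.columns
    return (block_means.sort_values([subject, "day", "block"])
            .groupby(subject, group_keys=False)[cols].apply(_norm)
            .reset_index(drop=True))
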