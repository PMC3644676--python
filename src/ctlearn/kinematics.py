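"""Tracking-performance decomposition: overall error, time lag, spatial accuracy.

Overall tracking error is the RMSE between target and response angles.  A
time-series analysis then separates the temporal and spatial components:
the response is cross-correlated with the target at every integer-sample
shift inside a search window, using only the continuously overlapping
sections at each shift (no padding), and the shift of highest correlation
is the time lag.  Lags are reported in milliseconds with the convention
that a response trailing the target has a negative lag and 0 means no lag.
The squared correlation at the best shift (R^2) is the spatial accuracy,
and the RMSE recomputed after shifting out the lag is the spatial error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrackingRecord", "SegmentScores", "rmse", "estimate_lag",
           "spatial_error", "score_segment", "score_records",
           "records_from_tables", "write_scores"]


@dataclass(frozen=True)
class TrackingRecord:
    """Paired target/response angle streams for one segment of one trial."""

    target: np.ndarray
    response: np.ndarray
    sample_rate: float = 50.0
    segment_kind: str = "random"
    subject_id: str = ""
    day: int = 1
    trial_index: int = 0

    def __post_init__(self):
        t = np.asarray(self.target, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("target and response must be equal-length 1-D streams")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "target", t)
        object.__setattr__(self, "response", r)


@dataclass(frozen=True)
class SegmentScores:
    """(RMSE, lag, R^2, lag-corrected spatial error) for one segment.

    ``flags`` collects quality issues: ``low_correlation`` (peak |r| below
    the reliability floor), ``anti_correlated`` (best correlation negative),
    ``undefined_correlation`` (zero-variance overlap at every shift),
    ``short_overlap`` (less than 1 s of overlap for the spatial error).
    """

    rmse: float
    lag_ms: float
    r2: float
    spatial_rmse: float
    flags: tuple[str, ...] = ()


def rmse(record: TrackingRecord) -> float:
    """Root-mean-square deviation between response and target, degrees."""
    if record.target.size == 0:
        raise ValueError("empty record")
    return float(np.sqrt(np.mean((record.response - record.target) ** 2)))


def _overlap(target: np.ndarray, response: np.ndarray, delay: int):
    """Overlapping sections when the response is delayed by ``delay`` samples."""
    n = target.size
    if delay >= 0:
        return target[:n - delay] if delay else target, response[delay:]
    return target[-delay:], response[:n + delay]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float((xc @ yc) / denom)


def estimate_lag(record: TrackingRecord, max_lag_s: float = 2.0,
                 min_abs_r: float = 0.3):
    """Cross-correlation time lag and spatial accuracy.

    For every integer-sample delay in ``[-max_lag, +max_lag]`` the Pearson
    correlation is computed over only the overlapping sections (re-meaned
    per shift).  The delay maximising the correlation magnitude is the lag
    (an inverted but otherwise faithful response aligns at its true delay
    and is flagged ``anti_correlated``); ties are broken toward the
    smallest |delay| (favouring the null of no lag).

    Returns ``(lag_ms, r2, flags)`` where ``lag_ms = -delay * 1000/rate``
    (negative when the response trails the target).
    """
    n = record.target.size
    max_lag = int(round(max_lag_s * record.sample_rate))
    if max_lag >= n / 2:
        raise ValueError("lag window must be shorter than half the stream")
    # ordered so that ties resolve to the smallest |delay|
    delays = np.argsort(np.abs(np.arange(-max_lag, max_lag + 1))) - max_lag
    best_r, best_delay = 0.0, 0
    any_defined = False
    for d in delays:
        x, y = _overlap(record.target, record.response, int(d))
        r = _pearson(x, y)
        if np.isnan(r):
            continue
        any_defined = True
        if abs(r) > abs(best_r):
            best_r, best_delay = r, int(d)
    flags = []
    if not any_defined:
        return 0.0, np.nan, ("undefined_correlation",)
    if best_r < 0:
        flags.append("anti_correlated")
    if abs(best_r) < min_abs_r:
        flags.append("low_correlation")
    lag_ms = -best_delay * 1000.0 / record.sample_rate
    return lag_ms, float(best_r ** 2), tuple(flags)


def spatial_error(record: TrackingRecord, lag_samples: int):
    """RMSE after shifting out the estimated lag, over the overlap only.

    ``lag_samples`` is the delay of the response in samples (positive =
    trailing).  Returns ``(error_deg, flags)``; overlap shorter than 1 s is
    flagged.
    """
    x, y = _overlap(record.target, record.response, int(lag_samples))
    flags = []
    if x.size < record.sample_rate:
        flags.append("short_overlap")
    if x.size == 0:
        return np.nan, ("short_overlap",)
    return float(np.sqrt(np.mean((y - x) ** 2))), tuple(flags)


def score_segment(record: TrackingRecord, max_lag_s: float = 2.0,
                  min_abs_r: float = 0.3) -> SegmentScores:
    """Bundle overall RMSE, time lag, R^2 and lag-corrected spatial error."""
    overall = rmse(record)
    lag_ms, r2, flags = estimate_lag(record, max_lag_s, min_abs_r)
    if np.isnan(r2):
        return SegmentScores(overall, np.nan, np.nan, np.nan, flags)
    delay = int(round(-lag_ms * record.sample_rate / 1000.0))
    spat, sflags = spatial_error(record, delay)
    return SegmentScores(overall, lag_ms, r2, spat, flags + sflags)


def score_records(records, max_lag_s: float = 2.0,
                  min_abs_r: float = 0.3) -> pd.DataFrame:
    """Score an iterable of records into a tidy per-segment table."""
    rows = []
    for rec in records:
        s = score_segment(rec, max_lag_s, min_abs_r)
        rows.append({
            "subject_id": rec.subject_id, "day": rec.day,
            "trial_index": rec.trial_index, "segment_kind": rec.segment_kind,
            "rmse": s.rmse, "lag_ms": s.lag_ms, "r2": s.r2,
            "spatial_rmse": s.spatial_rmse, "flags": ";".join(s.flags),
        })
    return pd.DataFrame(rows)


def records_from_tables(target_table: pd.DataFrame,
                        response_table: pd.DataFrame,
                        sample_rate: float = 50.0,
                        subject_id: str = "") -> list[TrackingRecord]:
    """Pair target and response trajectory tables into per-segment records.

    Both tables use the trajectory schema (``time_s, angle_deg,
    segment_kind, trial_index, segment_index`` plus optional ``day``) and
    are matched on (day, trial, segment); rows are ordered by time within
    each segment.
    """
    keys = [k for k in ("day", "trial_index", "segment_index")
            if k in target_table.columns]
    records = []
    resp_groups = dict(tuple(response_table.groupby(keys)))
    for key, tgt in target_table.groupby(keys):
        if key not in resp_groups:
            raise ValueError(f"no response rows for segment {dict(zip(keys, key))}")
        resp = resp_groups[key]
        if len(resp) != len(tgt):
            raise ValueError(f"length mismatch for segment {dict(zip(keys, key))}")
        tgt = tgt.sort_values("time_s")
        resp = resp.sort_values("time_s")
        meta = dict(zip(keys, key))
        records.append(TrackingRecord(
            target=tgt["angle_deg"].to_numpy(),
            response=resp["angle_deg"].to_numpy(),
            sample_rate=sample_rate,
            segment_kind=str(tgt["segment_kind"].iloc[0]),
            subject_id=subject_id or str(resp.get("subject_id", pd.Series([""])).iloc[0]),
            day=int(meta.get("day", 1)),
            trial_index=int(meta.get("trial_index", 0))))
    return records


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)
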