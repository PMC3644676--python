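"""Bundled example data.

``reference_weighted_scores`` is a published-style worked example: retention
day weighted difference scores for a cohort of ten middle-aged adults who
practised the continuous-tracking task for five days.  The values are
already statistically weighted (error-measure signs inverted), so a
positive value means a sequence-specific advantage on that measure.  Sign
counts on this cohort are 3 (overall movement error), 8 (temporal
precision) and 1 (spatial accuracy).
"""

from __future__ import annotations

import pandas as pd

_REFERENCE_COHORT = [
    # participant, age, sex, overall movement error, temporal precision, spatial accuracy
    (1, 54, "F", 0.702, -0.328, -0.534),
    (2, 64, "F", 0.084, 0.116, 0.201),
    (3, 72, "F", 0.123, -0.033, -0.141),
    (4, 67, "F", -0.574, 0.130, -0.342),
    (5, 60, "F", -0.009, 0.358, -0.422),
    (6, 51, "M", -0.061, 0.361, -0.206),
    (7, 63, "M", -0.220, 0.201, -0.268),
    (8, 68, "M", -1.38, 0.036, -0.899),
    (9, 80, "F", -0.347, 0.538, -0.676),
    (10, 69, "M", -0.584, 0.296, -0.655),
]

_MEASURE_COLS = {"rmse": 3, "lag": 4, "spatial": 5}


def reference_weighted_scores(long: bool = True) -> pd.DataFrame:
    """Retention-day weighted difference scores for the 10-subject reference cohort.

    With ``long=True`` (default) returns one row per subject x measure with
    columns ``subject_id, measure, weight`` — the shape consumed by
    :func:`ctlearn.summary.count_positive`.  Otherwise returns the wide
    participant table (age, sex, three weighted scores).
    """
    wide = pd.DataFrame(_REFERENCE_COHORT, columns=[
        "subject_id", "age", "sex", "rmse_weight", "lag_weight", "spatial_weight"])
    if not long:
        return wide
    rows = []
    for rec in _REFERENCE_COHORT:
        for measure, col in _MEASURE_COLS.items():
            rows.append({"subject_id": rec[0], "measure": measure, "weight": rec[col]})
    return pd.DataFrame(rows)
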