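"""Study outcomes from longitudinal visit data.

Two outcomes are computed per subject: 4-year progression to AD dementia
(binary; any dementia diagnosis recorded at a visit within the horizon) and
the 4-year MMSE slope (continuous; ordinary-least-squares slope of MMSE on
time in years, fitted per subject on all visits within the horizon,
baseline included).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic_cohort import SubjectRecord, Visit

__all__ = ["label_progression", "compute_mmse_slope", "outcome_table"]

DEFAULT_HORIZON_YEARS = 4.0


def _as_visit_arrays(visits: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.array([v.time_years for v in visits], dtype=float)
    y = np.array([v.mmse for v in visits], dtype=float)
    f = np.array([v.ad_dementia_flag for v in visits], dtype=bool)
    if t.size == 0:
        raise DataError("empty visit list")
    if np.any(t < 0):
        raise DataError("visit times must be non-negative")
    return t, y, f


def label_progression(visits: Sequence[Visit], horizon_years: float = DEFAULT_HORIZON_YEARS) -> bool:
    """True iff an AD-dementia diagnosis is recorded at any visit with
    time <= horizon (closed interval)."""
    t, _, flags = _as_visit_arrays(visits)
    return bool(np.any(flags & (t <= horizon_years)))


def compute_mmse_slope(visits: Sequence[Visit], horizon_years: float = DEFAULT_HORIZON_YEARS) -> float:
    """OLS slope (points/year) of MMSE on time, restricted to visits within
    the horizon.  Requires >= 2 visits at distinct times inside [0, horizon].
    """
    t, y, _ = _as_visit_arrays(visits)
    keep = t <= horizon_years
    t, y = t[keep], y[keep]
    if t.size < 2 or np.ptp(t) == 0:
        raise DataError(
            "MMSE slope requires >= 2 visits at distinct times within the horizon"
        )
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def outcome_table(
    cohort: Iterable[SubjectRecord], horizon_years: float = DEFAULT_HORIZON_YEARS
) -> pd.DataFrame:
    """Per-subject outcome table.

    Columns: ``progressed_4y`` (bool), ``mmse_slope`` (NaN when fewer than two
    usable visits — such subjects stay in the binary analysis but drop out of
    the continuous one), ``n_visits_used``.
    """
    rows = []
    for r in cohort:
        t = np.array([v.time_years for v in r.visits], dtype=float)
        n_used = int(np.sum(t <= horizon_years))
        try:
            slope = compute_mmse_slope(r.visits, horizon_years)
        except DataError:
            slope = np.nan
        rows.append({
            "subject_id": r.subject_id,
            "progressed_4y": label_progression(r.visits, horizon_years),
            "mmse_slope": slope,
            "n_visits_used": n_used,
        })
    if not rows:
        raise DataError("empty cohort")
    return pd.DataFrame(rows).set_index("subject_id")
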