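"""Binary moderate-to-severe xerostomia endpoint from follow-up reports.

Follow-up CTCAE grades between 6 and 24 months after radiotherapy (window
bounds inclusive) are pooled per patient: the final score is the arithmetic
mean of in-window grades rounded half-up to the nearest integer, and the
endpoint is positive when that pooled grade is >= 2.  Patients without any
in-window report are excluded with a logged warning rather than an error.

Half-up rounding is implemented in exact integer arithmetic — a mean of
exactly k + 0.5 always pools to k + 1, never to even.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MONTHS = (6.0, 24.0)
POSITIVE_GRADE = 2


class EndpointInputError(ValueError):
    pass


@dataclass(frozen=True)
class EndpointLabel:
    patient_id: str
    pooled_grade: int
    label: int
    n_reports_used: int


def pool_grades(grades: list[int]) -> int:
    """Arithmetic mean of integer grades, rounded half-up. Exact."""
    if not grades:
        raise EndpointInputError("need at least one grade to pool")
    for g in grades:
        if int(g) != g or not 0 <= g <= 4:
            raise EndpointInputError(f"grade {g!r} not an integer in 0..4")
    s, k = sum(int(g) for g in grades), len(grades)
    # floor(mean + 1/2) = floor((2s + k) / (2k)) in integers
    return (2 * s + k) // (2 * k)


def pool_reports(
    reports: pd.DataFrame,
    window_months: tuple[float, float] = DEFAULT_WINDOW_MONTHS,
) -> pd.DataFrame:
    """Per-patient pooled grade and binary G2+ label.

    ``reports`` needs columns ``patient_id, months_after_rt, grade``.
    Returns a frame with ``patient_id, pooled_grade, label, n_reports_used``.
    """
    required = {"patient_id", "months_after_rt", "grade"}
    missing = required - set(reports.columns)
    if missing:
        raise EndpointInputError(f"reports table missing columns: {sorted(missing)}")
    lo, hi = window_months
    if not lo < hi:
        raise EndpointInputError("window_months must be an increasing pair")
    rows = []
    for pid, sub in reports.groupby("patient_id", sort=True):
        inside = sub[(sub["months_after_rt"] >= lo) & (sub["months_after_rt"] <= hi)]
        if inside.empty:
            logger.warning(
                "patient %s: no follow-up report in [%g, %g] months; excluded",
                pid, lo, hi,
            )
            continue
        pooled = pool_grades([int(g) for g in inside["grade"]])
        rows.append(
            EndpointLabel(
                patient_id=str(pid),
                pooled_grade=pooled,
                label=int(pooled >= POSITIVE_GRADE),
                n_reports_used=len(inside),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["patient_id", "pooled_grade", "label", "n_reports_used"])
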