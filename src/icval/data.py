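"""Domain types and I/O for intermittently assessed event-history data.

A subject in a validation sample is seen at a baseline assessment at time 0
(event-free by construction) and then at irregular follow-up visits, at each
of which the binary disease status Z(a) = I(T <= a) is recorded.  Follow-up
ends at C = min(R, B), where B is the planned administrative end of follow-up
and R an (optional) random loss-to-follow-up time.  The event time T is never
observed directly: it is known only to lie in the censoring interval
(a-, a+] bracketed by the last event-free visit and the first post-event
visit (a+ = +inf for right-censored subjects).

At a landmark time t0 the quantity to be validated is the event-free status
Y = I(T > t0).  Y is determined by the visit history -- ``delta = 1`` -- in
exactly two situations:

* a post-event visit occurred by t0 (a+ <= t0), so Y = 0;
* an event-free visit occurred at or after t0 (a- >= t0), so Y = 1.

Otherwise the censoring interval spans t0 (or the subject was lost before t0
while still event-free) and Y is unknown (``delta = 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VisitRecord",
    "SubjectRecord",
    "ClassificationStatus",
    "SchemaError",
    "ConsistencyError",
    "censoring_interval",
    "classify_at_landmark",
    "read_sample",
    "write_sample",
]


class SchemaError(ValueError):
    """A file or record does not conform to the expected layout."""


class ConsistencyError(ValueError):
    """A record violates an invariant of the observation scheme."""


@dataclass(frozen=True)
class VisitRecord:
    """A single assessment: ``time`` since origin and observed status Z(time)."""

    time: float
    status: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ConsistencyError(f"visit time {self.time} < 0")
        if self.status not in (0, 1):
            raise SchemaError(f"visit status must be 0/1, got {self.status}")


@dataclass
class SubjectRecord:
    """One subject: covariates, visit history, and end of follow-up.

    Parameters
    ----------
    id : str
        Subject identifier.
    x : ndarray
        Covariate vector of length p.
    visits : list of VisitRecord
        Strictly increasing in time, first visit at (0, 0), statuses
        monotone nondecreasing (state 1 is absorbing).
    C : float
        End of follow-up, min(R, B); every visit time is <= C.
    delta_dropout : int
        1 if follow-up ended by random loss to follow-up (R < B), 0 if by
        the administrative end B.
    """

    id: str
    x: np.ndarray
    visits: list[VisitRecord]
    C: float
    delta_dropout: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not self.visits:
            raise SchemaError(f"subject {self.id}: no visits")
        if self.visits[0].time != 0 or self.visits[0].status != 0:
            raise SchemaError(
                f"subject {self.id}: first visit must be the baseline (0, 0)"
            )
        if self.C <= 0:
            raise ConsistencyError(f"subject {self.id}: C={self.C} must be > 0")
        if self.delta_dropout not in (0, 1):
            raise SchemaError(f"subject {self.id}: delta_dropout must be 0/1")
        times = [v.time for v in self.visits]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConsistencyError(
                f"subject {self.id}: visit times not strictly increasing"
            )
        if times[-1] > self.C:
            raise ConsistencyError(
                f"subject {self.id}: visit at {times[-1]} after end of follow-up C={self.C}"
            )
        statuses = [v.status for v in self.visits]
        if any(b < a for a, b in zip(statuses, statuses[1:])):
            raise ConsistencyError(
                f"subject {self.id}: status sequence not monotone nondecreasing"
            )

    @property
    def n_post_baseline(self) -> int:
        return len(self.visits) - 1


@dataclass(frozen=True)
class ClassificationStatus:
    """The (delta, Y) classification at a landmark plus the censoring interval.

    ``y`` is None when ``delta == 0``.
    """

    delta: int
    y: int | None
    a_minus: float
    a_plus: float  # +inf when right-censored

    def __post_init__(self) -> None:
        if not self.a_minus < self.a_plus:
            raise ConsistencyError(
                f"degenerate censoring interval [{self.a_minus}, {self.a_plus}]"
            )


def censoring_interval(subject: SubjectRecord) -> tuple[float, float]:
    """Endpoints (a-, a+) of the censoring interval containing T.

    a- is the last event-free visit time, a+ the first post-event visit time
    or +inf if the subject was never seen post-event.  The event lies in
    (a-, a+].
    """
    a_minus = max(v.time for v in subject.visits if v.status == 0)
    post = [v.time for v in subject.visits if v.status == 1]
    a_plus = min(post) if post else math.inf
    return a_minus, a_plus


def classify_at_landmark(subject: SubjectRecord, t0: float) -> ClassificationStatus:
    """Determine whether Y = I(T > t0) is known from the visit history.

    Boundary conventions (chosen once): an event-free visit exactly at t0
    gives Y = 1 (a- >= t0); a post-event visit exactly at t0 gives Y = 0
    (a+ <= t0).  These match Y = I(T > t0) with events in (a-, a+].
    """
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    a_minus, a_plus = censoring_interval(subject)
    if a_plus <= t0:
        return ClassificationStatus(1, 0, a_minus, a_plus)
    if a_minus >= t0:
        return ClassificationStatus(1, 1, a_minus, a_plus)
    return ClassificationStatus(0, None, a_minus, a_plus)


def _covariate_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    cols.sort(key=lambda c: int(c[1:]))
    if cols != [f"x{i + 1}" for i in range(len(cols))]:
        raise SchemaError(f"covariate columns must be x1..xp, found {cols}")
    return cols


def read_sample(subjects_path, visits_path) -> list[SubjectRecord]:
    """Read a sample from ``subjects.csv`` (id, x1..xp, C, delta_dropout)
    and ``visits.csv`` (id, time, status) in long visit format.

    All record invariants are enforced; violations raise SchemaError or
    ConsistencyError.
    """
    subj = pd.read_csv(subjects_path, dtype={"id": str}, float_precision="round_trip")
    vis = pd.read_csv(visits_path, dtype={"id": str}, float_precision="round_trip")
    for col in ("id", "C", "delta_dropout"):
        if col not in subj.columns:
            raise SchemaError(f"subjects file missing column {col!r}")
    for col in ("id", "time", "status"):
        if col not in vis.columns:
            raise SchemaError(f"visits file missing column {col!r}")
    xcols = _covariate_columns(subj)
    visits_by_id: dict[str, list[VisitRecord]] = {}
    for sid, grp in vis.groupby("id", sort=False):
        grp = grp.sort_values("time")
        visits_by_id[sid] = [
            VisitRecord(float(t), int(s)) for t, s in zip(grp["time"], grp["status"])
        ]
    sample = []
    for row in subj.itertuples(index=False):
        sid = row.id
        if sid not in visits_by_id:
            raise SchemaError(f"subject {sid}: no visits in visits file")
        sample.append(
            SubjectRecord(
                id=sid,
                x=np.array([getattr(row, c) for c in xcols], dtype=float),
                visits=visits_by_id[sid],
                C=float(row.C),
                delta_dropout=int(row.delta_dropout),
            )
        )
    return sample


def write_sample(sample: list[SubjectRecord], subjects_path, visits_path) -> None:
    """Inverse of :func:`read_sample`; round-trips valid samples exactly."""
    p = len(sample[0].x) if sample else 0
    subj_rows = []
    vis_rows = []
    for s in sample:
        row = {"id": s.id}
        row.update({f"x{j + 1}": s.x[j] for j in range(p)})
        row.update({"C": s.C, "delta_dropout": s.delta_dropout})
        subj_rows.append(row)
        for v in s.visits:
            vis_rows.append({"id": s.id, "time": v.time, "status": v.status})
    pd.DataFrame(subj_rows).to_csv(subjects_path, index=False, float_format="%.17g")
    pd.DataFrame(vis_rows).to_csv(visits_path, index=False, float_format="%.17g")
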