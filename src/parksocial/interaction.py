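"""Social-interaction measurements.

Two observational outcomes are computed per spatial study unit:

* the **crowds-congregate index** ``R``, a normalized behavior-mapping
  statistic combining congregate-group sizes ``B_i``, congregate times
  ``T_i`` (minutes, capped by the 60-minute observation window), the average
  crowd total ``A`` and the unit area ``S`` (m^2)::

      R = sum_i (B_i / A) * ln(T_i)  /  (N * log10(S)),
      A = (A_start + A_end) / 2

  where the sum runs over all ``N`` people present in the unit;

* the **engagement-with-the-park score**, the mean of three 1-7
  questionnaire items (participation intensity, preference for the space,
  visit frequency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .domain import SpatialUnit

__all__ = [
    "CongregateSession",
    "EngagementResponse",
    "DegenerateSessionError",
    "average_crowd_size",
    "congregate_index",
    "engagement_score",
    "summarize_by_space_type",
    "sessions_to_frames",
    "sessions_from_frames",
]

MAX_CONGREGATE_MINUTES = 60.0


class DegenerateSessionError(ValueError):
    """Session primitives make the index undefined (empty crowd, tiny area)."""


@dataclass(frozen=True)
class CongregateSession:
    """Raw behavior-mapping primitives for one observation session.

    ``persons`` holds one ``(B, T)`` pair per person present: the size of
    the congregate group that person belongs to and that person's congregate
    time in minutes.  Solitary people are included with ``B = 1``.
    """

    unit_id: int
    area_m2: float
    a_start: int
    a_end: int
    persons: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "persons", tuple((float(b), float(t)) for b, t in self.persons))
        if self.area_m2 <= 1.0:
            raise DegenerateSessionError(
                f"unit {self.unit_id}: area {self.area_m2} m^2 must exceed 1 m^2 "
                "(log10 normalizer degenerates)"
            )
        if self.a_start < 0 or self.a_end < 0:
            raise ValueError("start/end crowd totals must be nonnegative")
        if not self.persons:
            raise ValueError("session needs at least one person present")
        n = self.n_present
        for b, t in self.persons:
            if not 1.0 <= t <= MAX_CONGREGATE_MINUTES:
                raise ValueError(
                    f"congregate time {t} min outside [1, {MAX_CONGREGATE_MINUTES:.0f}]; "
                    "cap observations at the 60-min window upstream"
                )
            if not 1.0 <= b <= n:
                raise ValueError(f"group size {b} outside [1, N={n}]")

    @property
    def n_present(self) -> int:
        return len(self.persons)


@dataclass(frozen=True)
class EngagementResponse:
    """Three 1-7 questionnaire items behind the engagement score."""

    unit_id: int
    item_participation: int
    item_preference: int
    item_frequency: int

    def __post_init__(self) -> None:
        for item in (self.item_participation, self.item_preference, self.item_frequency):
            if not 1 <= item <= 7:
                raise ValueError(f"questionnaire item {item} outside the 1-7 scale")


def average_crowd_size(a_start: int, a_end: int) -> float:
    """Average crowd total ``A = (A_start + A_end) / 2``.

    Each person is assumed to appear in the space only once, so the simple
    mean of the start and end totals is the session-level crowd size.
    """
    if a_start < 0 or a_end < 0:
        raise ValueError("crowd totals must be nonnegative")
    if a_start + a_end == 0:
        raise DegenerateSessionError("empty session: both crowd totals are zero")
    return (a_start + a_end) / 2.0


def congregate_index(session: CongregateSession) -> float:
    """Normalized crowds-congregate index ``R`` for one session.

    Vectorized over the per-person ``(B, T)`` pairs; natural log on times,
    base-10 log on area.  ``R >= 0`` because times are >= 1 minute and the
    area exceeds 1 m^2.
    """
    a = average_crowd_size(session.a_start, session.a_end)
    arr = np.asarray(session.persons, dtype=float)
    b, t = arr[:, 0], arr[:, 1]
    numerator = float(np.sum(b / a * np.log(t)))
    denominator = session.n_present * math.log10(session.area_m2)
    return numerator / denominator


def engagement_score(resp: EngagementResponse) -> float:
    """Mean of the three questionnaire items; lies in [1, 7]."""
    return (resp.item_participation + resp.item_preference + resp.item_frequency) / 3.0


def summarize_by_space_type(
    sessions: Sequence[CongregateSession],
    responses: Sequence[EngagementResponse],
    units: Sequence[SpatialUnit],
) -> pd.DataFrame:
    """Per-space-type mean/sd of the congregate index and engagement score.

    Returns a frame indexed by space type with columns
    ``congregate_mean/sd/n`` and ``engagement_mean/sd/n``, sorted descending
    by mean congregate index (the space-type ranking).  Standard deviations
    are population (ddof=0), so a single observation reports sd 0.  Space
    types with no data are omitted with a warning column left NaN-free.
    """
    type_of = {u.unit_id: u.space_type for u in units}

    def _resolve(uid: int) -> str:
        try:
            return type_of[uid]
        except KeyError:
            raise ValueError(f"unit_id {uid} not in the unit inventory") from None

    r_rows = [(_resolve(s.unit_id), congregate_index(s)) for s in sessions]
    e_rows = [(_resolve(r.unit_id), engagement_score(r)) for r in responses]
    r_df = pd.DataFrame(r_rows, columns=["space_type", "value"])
    e_df = pd.DataFrame(e_rows, columns=["space_type", "value"])

    out = {}
    for stype in sorted(set(r_df["space_type"]) | set(e_df["space_type"])):
        rv = r_df.loc[r_df["space_type"] == stype, "value"].to_numpy()
        ev = e_df.loc[e_df["space_type"] == stype, "value"].to_numpy()
        out[stype] = {
            "congregate_mean": float(np.mean(rv)) if rv.size else np.nan,
            "congregate_sd": float(np.std(rv)) if rv.size else np.nan,
            "congregate_n": int(rv.size),
            "engagement_mean": float(np.mean(ev)) if ev.size else np.nan,
            "engagement_sd": float(np.std(ev)) if ev.size else np.nan,
            "engagement_n": int(ev.size),
        }
    frame = pd.DataFrame.from_dict(out, orient="index")
    frame.index.name = "space_type"
    return frame.sort_values("congregate_mean", ascending=False)


# ---------------------------------------------------------------------------
# CSV interchange: one session header row per session plus long-format person
# rows keyed by session_id.


def sessions_to_frames(
    sessions: Sequence[CongregateSession],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    head = pd.DataFrame(
        [
            {
                "session_id": i,
                "unit_id": s.unit_id,
                "S_m2": s.area_m2,
                "A_start": s.a_start,
                "A_end": s.a_end,
            }
            for i, s in enumerate(sessions)
        ]
    )
    persons = pd.DataFrame(
        [
            {"session_id": i, "B": b, "T_min": t}
            for i, s in enumerate(sessions)
            for b, t in s.persons
        ]
    )
    return head, persons


def sessions_from_frames(head: pd.DataFrame, persons: pd.DataFrame) -> list[CongregateSession]:
    grouped = dict(tuple(persons.groupby("session_id")))
    out = []
    for _, row in head.iterrows():
        pers = grouped.get(row["session_id"])
        if pers is None:
            raise ValueError(f"session {row['session_id']} has no person rows")
        out.append(
            CongregateSession(
                unit_id=int(row["unit_id"]),
                area_m2=float(row["S_m2"]),
                a_start=int(row["A_start"]),
                a_end=int(row["A_end"]),
                persons=tuple(zip(pers["B"].tolist(), pers["T_min"].tolist())),
            )
        )
    return out
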