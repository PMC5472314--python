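"""Within-day session schedules.

The study design consists of six walking sessions (S1..S6) performed within a
single day, separated by rest intervals of 10, 30 and 90 minutes.  A
:class:`SessionSchedule` records the start time of each session in minutes
from the first one; all pairwise gaps between sessions (the "durations")
follow from those start times.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["SessionSchedule", "default_schedule"]


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered session labels with start times in minutes from the first session."""

    session_ids: tuple[str, ...]
    start_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.session_ids) != len(self.start_times):
            raise ValueError("session_ids and start_times must have equal length")
        if len(self.session_ids) != len(set(self.session_ids)):
            raise ValueError("session ids must be unique")
        diffs = np.diff(self.start_times)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("start_times must be strictly increasing")

    @property
    def n_sessions(self) -> int:
        return len(self.session_ids)

    def start_of(self, session_id: str) -> float:
        try:
            return self.start_times[self.session_ids.index(session_id)]
        except ValueError as exc:
            raise KeyError(f"unknown session {session_id!r}") from exc

    def duration(self, a: str, b: str) -> float:
        """Elapsed time in minutes between the starts of sessions ``a`` and ``b``."""
        return abs(self.start_of(a) - self.start_of(b))

    def pairwise_durations(self) -> dict[tuple[str, str], float]:
        """Durations for all unordered session pairs, keyed in schedule order."""
        return {
            (a, b): self.duration(a, b)
            for a, b in combinations(self.session_ids, 2)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"session": self.session_ids, "start_min": self.start_times}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SessionSchedule":
        return cls(
            tuple(str(s) for s in frame["session"]),
            tuple(float(t) for t in frame["start_min"]),
        )

    @classmethod
    def from_csv(cls, path) -> "SessionSchedule":
        return cls.from_frame(pd.read_csv(path))


def default_schedule() -> SessionSchedule:
    """The study's six-session schedule.

    Rest intervals after sessions 1, 3 and 5 are 10 minutes; between sessions
    2-3 and 4-5 they are 30 and 90 minutes.  Start times (0, 10, 40, 50, 140,
    150) min are the unique schedule consistent with every pairwise gap of the
    design (e.g. S1-S2 = 10 min, S2-S3 = 30 min, S4-S5 = 90 min, S1-S6 = 150
    min).
    """
    return SessionSchedule(
        session_ids=("S1", "S2", "S3", "S4", "S5", "S6"),
        start_times=(0.0, 10.0, 40.0, 50.0, 140.0, 150.0),
    )
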