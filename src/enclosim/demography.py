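"""Demography schedules: the fixed scaffold every simulated room must follow.

A schedule lists, per monitoring point, how many new adults of each sex enter
and which earlier cohorts are removed.  Cohorts are labelled by the monitoring
point at which they entered; the first step is the founding step.  Within a
step the order of events is: offspring of the standing population enter, then
scheduled cohorts are removed, then the census is taken.  The population size
and sex composition after every step are therefore functions of the schedule
alone, never of the fitness model.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataFormatError, ScheduleError


@dataclasses.dataclass(frozen=True)
class ScheduleStep:
    step: int
    n_new_females: int
    n_new_males: int
    cohorts_removed: frozenset[int] = frozenset()
    include_in_stats: bool = True

    def __post_init__(self) -> None:
        if self.n_new_females < 0 or self.n_new_males < 0:
            raise ScheduleError(f"step {self.step}: negative entry counts")

    @property
    def n_new(self) -> int:
        return self.n_new_females + self.n_new_males


@dataclasses.dataclass(frozen=True)
class DemographySchedule:
    """Ordered per-room schedule.

    For a full experiment ``steps[0]`` is the founding step and ``standing``
    is empty.  A schedule restarted mid-experiment instead lists the cohorts
    already alive at the restart in ``standing`` (as ``(label, n_females,
    n_males)``), and every step is a breeding step.
    """

    room_id: str
    steps: tuple[ScheduleStep, ...]
    standing: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.steps:
            raise ScheduleError(f"room {self.room_id}: empty schedule")
        labels = [s.step for s in self.steps]
        if labels != sorted(labels) or len(set(labels)) != len(labels):
            raise ScheduleError(f"room {self.room_id}: step labels not increasing")
        self.implied_sizes()  # validates removals

    @property
    def init_sizes(self) -> tuple[int, int]:
        """(females, males) the caller must supply as the initial population."""
        if self.standing:
            return (
                sum(f for _, f, _ in self.standing),
                sum(m for _, _, m in self.standing),
            )
        first = self.steps[0]
        return first.n_new_females, first.n_new_males

    def implied_sizes(self) -> list[tuple[int, int]]:
        """Alive (females, males) after each step, from the schedule alone."""
        alive: dict[int, tuple[int, int]] = {
            lab: (f, m) for lab, f, m in self.standing
        }
        out = []
        breed_steps = self.steps if self.standing else self.steps[1:]
        if not self.standing:
            first = self.steps[0]
            alive[first.step] = (first.n_new_females, first.n_new_males)
            for label in sorted(first.cohorts_removed):
                self._pop_cohort(alive, label, first.step)
            out.append(self._totals(alive))
        for st in breed_steps:
            alive[st.step] = (st.n_new_females, st.n_new_males)
            for label in sorted(st.cohorts_removed):
                self._pop_cohort(alive, label, st.step)
            out.append(self._totals(alive))
        return out

    def _pop_cohort(self, alive: dict, label: int, step: int) -> None:
        if label not in alive:
            raise ScheduleError(
                f"room {self.room_id} step {step}: cohort {label} "
                "removed but never created (or removed twice)"
            )
        del alive[label]

    @staticmethod
    def _totals(alive: dict) -> tuple[int, int]:
        return (
            sum(f for f, _ in alive.values()),
            sum(m for _, m in alive.values()),
        )

    def included_steps(self) -> list[int]:
        return [s.step for s in self.steps if s.include_in_stats]

    def truncated_at(self, start_step: int) -> "DemographySchedule":
        """Restart the schedule at ``start_step`` with the standing population.

        The returned schedule's ``standing`` holds the cohorts alive just
        after ``start_step`` (labels preserved, so later scheduled removals of
        pre-start cohorts still apply); its steps are the ones after
        ``start_step``.
        """
        labels = [s.step for s in self.steps]
        if start_step not in labels:
            raise ScheduleError(f"room {self.room_id}: no step {start_step}")
        idx = labels.index(start_step)
        if idx == len(self.steps) - 1:
            raise ScheduleError(
                f"room {self.room_id}: nothing left after step {start_step}"
            )
        alive: dict[int, tuple[int, int]] = {
            lab: (f, m) for lab, f, m in self.standing
        }
        for st in self.steps[: idx + 1]:
            alive[st.step] = (st.n_new_females, st.n_new_males)
            for label in st.cohorts_removed:
                self._pop_cohort(alive, label, st.step)
        standing = tuple((lab, f, m) for lab, (f, m) in sorted(alive.items()))
        return DemographySchedule(self.room_id, self.steps[idx + 1 :], standing)


SCHEDULE_COLUMNS = (
    "room",
    "step",
    "n_new_females",
    "n_new_males",
    "cohorts_removed",
    "include_in_stats",
)


def read_schedules(path: str | Path) -> list[DemographySchedule]:
    """Read per-room schedules from delimited text (CSV/TSV by extension)."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s) {missing}")
    out = []
    for room, grp in df.groupby("room", sort=True):
        steps = []
        for _, row in grp.iterrows():
            raw = row["cohorts_removed"]
            removed = (
                frozenset(int(x) for x in str(raw).split(";") if x != "")
                if not pd.isna(raw)
                else frozenset()
            )
            steps.append(
                ScheduleStep(
                    step=int(row["step"]),
                    n_new_females=int(row["n_new_females"]),
                    n_new_males=int(row["n_new_males"]),
                    cohorts_removed=removed,
                    include_in_stats=str(row["include_in_stats"]).lower()
                    in {"1", "true", "yes"},
                )
            )
        steps.sort(key=lambda s: s.step)
        out.append(DemographySchedule(str(room), tuple(steps)))
    return out


def write_schedules(schedules: Iterable[DemographySchedule], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = []
    for sched in schedules:
        for st in sched.steps:
            rows.append(
                dict(
                    room=sched.room_id,
                    step=st.step,
                    n_new_females=st.n_new_females,
                    n_new_males=st.n_new_males,
                    cohorts_removed=";".join(map(str, sorted(st.cohorts_removed))),
                    include_in_stats=st.include_in_stats,
                )
            )
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, sep=sep, index=False)
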