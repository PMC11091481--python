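"""Synthetic enclosure experiments: demography schedules and pseudo-observed data.

The generator emulates the structure of the real experiment: three replicate
rooms, each founded with 10 WT/WT and 10 ko/ko adults at an equal sex ratio,
monitored at nine points while growing to several hundred adults, founders
removed at monitoring point 4 and later cohorts removed on a staggered
schedule.  Exact per-point adult counts are parameters of the design (the
default ramp is small through point 3 and steep afterwards); pseudo-observed
genotype-count tables are produced by running the individual-based simulator
under a known true fitness model, with the truth written to a sidecar so
downstream validation never has to guess it.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import spawn_rng
from .counts import GenotypeCounts, write_counts
from .demography import DemographySchedule, ScheduleStep, write_schedules
from .errors import ExtinctionError, ScheduleError
from .simulate import FitnessModel, Trajectory, simulate_room

#: default alive-adult targets per monitoring point (rooms 1-2, then room 3,
#: which ran at roughly half the scale of the others)
_DEFAULT_TARGETS_LARGE = (20, 36, 60, 90, 140, 200, 260, 330, 400)
_DEFAULT_TARGETS_SMALL = (20, 32, 52, 76, 110, 150, 190, 240, 290)

#: staggered removal of older cohorts: monitoring point -> entry points removed
_DEFAULT_REMOVALS = {7: (2,), 8: (3,), 9: (4,)}


def _default_growth(n_rooms: int, n_timepoints: int) -> tuple[tuple[int, ...], ...]:
    rows = []
    for r in range(n_rooms):
        base = _DEFAULT_TARGETS_SMALL if r == 2 else _DEFAULT_TARGETS_LARGE
        if n_timepoints > len(base):
            raise ScheduleError("default growth ramp covers at most 9 points")
        rows.append(tuple(base[:n_timepoints]))
    return tuple(rows)


@dataclasses.dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of a synthetic enclosure experiment."""

    n_rooms: int = 3
    founders_per_genotype: int = 10
    n_timepoints: int = 9
    growth_targets: tuple[tuple[int, ...], ...] | None = None
    founder_removal_point: int = 4
    cohort_removal_map: dict[int, tuple[int, ...]] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_REMOVALS)
    )
    true_model: FitnessModel = dataclasses.field(
        default_factory=lambda: FitnessModel.males_only(0.5, 0.5)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders_per_genotype % 2:
            raise ScheduleError("founders_per_genotype must be even (equal sex split)")
        if self.growth_targets is None:
            object.__setattr__(
                self,
                "growth_targets",
                _default_growth(self.n_rooms, self.n_timepoints),
            )
        if len(self.growth_targets) != self.n_rooms:
            raise ScheduleError("one growth-target row per room required")
        for row in self.growth_targets:
            if len(row) != self.n_timepoints:
                raise ScheduleError("growth targets must cover every time point")
            if any(t <= 0 for t in row):
                raise ScheduleError("growth targets must be positive")

    @property
    def room_ids(self) -> list[str]:
        return [f"room{i + 1}" for i in range(self.n_rooms)]

    def founder_init(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """Per-sex founding genotype triples: half WT/WT, half ko/ko."""
        half = self.founders_per_genotype // 2
        return (half, 0, half), (half, 0, half)


def make_schedule(design: SyntheticDesign) -> list[DemographySchedule]:
    """Schedules whose implied alive-adult counts hit the growth targets exactly.

    Entries are split equally between the sexes; the number of new adults at
    each point is solved from target[t] = target[t-1] + births - removals.
    """
    removal_at: dict[int, set[int]] = {}
    for point, entries in design.cohort_removal_map.items():
        removal_at.setdefault(point, set()).update(entries)
    removal_at.setdefault(design.founder_removal_point, set()).add(1)

    out = []
    for room, targets in zip(design.room_ids, design.growth_targets):
        if targets[0] != 2 * design.founders_per_genotype:
            raise ScheduleError(
                f"{room}: first growth target must equal the founder count "
                f"({2 * design.founders_per_genotype})"
            )
        cohort_size: dict[int, int] = {1: targets[0]}
        steps = [ScheduleStep(1, targets[0] // 2, targets[0] // 2)]
        for t in range(2, design.n_timepoints + 1):
            removed = removal_at.get(t, set())
            for lab in removed:
                if lab not in cohort_size:
                    raise ScheduleError(f"{room}: point {t} removes unknown cohort {lab}")
            n_removed = sum(cohort_size[lab] for lab in removed)
            births = targets[t - 1] - targets[t - 2] + n_removed
            if births < 0:
                raise ScheduleError(
                    f"{room}: target at point {t} requires {births} births"
                )
            cohort_size[t] = births
            for lab in removed:
                del cohort_size[lab]
            steps.append(
                ScheduleStep(
                    t,
                    births // 2 + births % 2,
                    births // 2,
                    frozenset(removed),
                )
            )
        sched = DemographySchedule(room, tuple(steps))
        implied = [f + m for f, m in sched.implied_sizes()]
        assert implied == list(targets), "schedule bookkeeping failed"
        out.append(sched)
    return out


def make_pseudo_observed(
    design: SyntheticDesign,
    rng: np.random.Generator | None = None,
    max_retries: int = 20,
) -> tuple[list[GenotypeCounts], dict]:
    """Simulate one pseudo-observed experiment under the design's true model.

    Returns the monitoring records (per room/point, with sex split) plus a
    truth sidecar recording the generating parameters.  Rooms that go extinct
    are re-simulated from a fresh sub-stream, up to ``max_retries`` times.
    """
    schedules = make_schedule(design)
    init = design.founder_init()
    records: list[GenotypeCounts] = []
    base_seed = design.seed if rng is None else int(rng.integers(2**31))
    for ridx, sched in enumerate(schedules):
        traj: Trajectory | None = None
        for attempt in range(max_retries):
            sub = spawn_rng(base_seed, ridx, attempt)
            try:
                traj = simulate_room(sched, design.true_model, init, sub)
                break
            except ExtinctionError:
                continue
        if traj is None:
            raise ExtinctionError(
                f"{sched.room_id}: extinct in all {max_retries} attempts"
            )
        records.extend(traj.to_records())
    m = design.true_model
    truth = dict(
        variant=m.variant,
        s_male=m.s_male,
        h_male=m.h_male,
        s_female=m.s_female,
        h_female=m.h_female,
        g=m.g,
        lam=m.lam,
        seed=base_seed,
    )
    return records, truth


def emit(design: SyntheticDesign, out_dir: str | Path) -> dict[str, Path]:
    """Write counts.csv, schedule.csv and truth.json for a design."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = make_pseudo_observed(design)
    paths = {
        "counts": out_dir / "counts.csv",
        "schedule": out_dir / "schedule.csv",
        "truth": out_dir / "truth.json",
    }
    write_counts(records, paths["counts"])
    write_schedules(make_schedule(design), paths["schedule"])
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
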