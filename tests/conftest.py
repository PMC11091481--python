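"""Shared fixtures: small synthetic experiments reused across the test modules."""
import numpy as np
import pytest

from enclosim import (
    FitnessModel,
    SyntheticDesign,
    make_pseudo_observed,
    make_schedule,
    observation_vector,
)
from enclosim.abc import PriorSpec, build_reference_table, variant
from enclosim.suite import excluded_timepoint_policy

#: printed cumulative genotype counts (WT/WT, HET, ko/ko) per room
ROOM_COUNTS = {
    "room1": (338, 576, 267),
    "room2": (329, 584, 292),
    "room3": (216, 264, 98),
}


def toy_design(seed: int = 0, s: float = 0.5, h: float = 0.5) -> SyntheticDesign:
    """A two-room, five-point design small enough for tight test loops."""
    model = (
        FitnessModel.males_only(s, h) if s or h else FitnessModel.neutral()
    )
    return SyntheticDesign(
        n_rooms=2,
        n_timepoints=5,
        growth_targets=((20, 28, 40, 50, 64), (20, 26, 36, 48, 58)),
        cohort_removal_map={},
        true_model=model,
        seed=seed,
    )


@pytest.fixture(scope="session")
def toy():
    """Toy experiment bundle: records, truth, schedules, fitting setup."""
    design = toy_design(seed=3)
    records, truth = make_pseudo_observed(design)
    schedules = make_schedule(design)
    inits, trunc, start = excluded_timepoint_policy(records, schedules)
    obs = observation_vector(records, "A", start)
    return dict(
        design=design,
        records=records,
        truth=truth,
        schedules=schedules,
        inits=inits,
        trunc=trunc,
        start=start,
        obs=obs,
    )


@pytest.fixture(scope="session")
def toy_table(toy):
    """Small males-only reference table on the toy demography (mode A)."""
    return build_reference_table(
        1500,
        PriorSpec(),
        variant("males_only"),
        toy["trunc"],
        toy["inits"],
        "A",
        seed=42,
        start_time=toy["start"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
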