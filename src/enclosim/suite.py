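"""Orchestration of the full model grid: estimates, model choice, goodness of fit.

Seven fitness-model variants are fitted against either allele-frequency (A)
or genotype-frequency (G) summary statistics.  Because founders enter as pure
homozygotes, the first two monitoring points are excluded: the third point's
observed frequencies become the simulation's initial condition and the
statistics cover the fourth point onward.  Each grid row reports the adjusted
posterior mean and 95% interval per parameter, the posterior probability of
the selection model against the neutral model, and goodness-of-fit p-values
for both.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import largest_remainder, spawn_rng
from .abc import (
    ModelVariant,
    PriorSpec,
    ReferenceTable,
    abc_fit,
    build_reference_table,
    goodness_of_fit,
    model_posterior,
    variant,
)
from .counts import GenotypeCounts, observation_vector
from .demography import DemographySchedule
from .errors import ScheduleError
from .simulate import InitSpec, Triple

#: variants that sample g or lam and therefore double the simulation budget
_EXTRA_PARAM_VARIANTS = {
    "males_only_g",
    "males_only_lambda",
    "males_only_lambda3",
    "males_only_lambda_g",
}
_LAMBDA_VARIANTS = {"males_only_lambda", "males_only_lambda3", "males_only_lambda_g"}

#: monitoring point whose observed frequencies seed the simulations (1-based)
DEFAULT_START_POINT = 3


@dataclasses.dataclass(frozen=True)
class ModelRunSpec:
    """One row of the experiment grid."""

    variant_name: str
    mode: Literal["A", "G"]
    n_sims: int | None = None
    tolerance: float = 0.1
    n_gof: int = 200

    def __post_init__(self) -> None:
        variant(self.variant_name)  # validates the name
        if self.mode not in {"A", "G"}:
            raise ValueError("mode must be 'A' or 'G'")
        if self.variant_name in _LAMBDA_VARIANTS and self.mode != "G":
            raise ValueError(
                f"{self.variant_name} is defined on genotype frequencies only"
            )
        if self.n_sims is None:
            object.__setattr__(
                self,
                "n_sims",
                200_000 if self.variant_name in _EXTRA_PARAM_VARIANTS else 100_000,
            )

    @property
    def model_variant(self) -> ModelVariant:
        return variant(self.variant_name)


def default_grid(n_sims: int | None = None) -> list[ModelRunSpec]:
    """The full experiment grid (seven variants x applicable statistic modes)."""
    rows = []
    for name in ("sex_averaged", "sex_specific", "males_only", "males_only_g"):
        for mode in ("A", "G"):
            rows.append(ModelRunSpec(name, mode, n_sims))
    for name in ("males_only_lambda", "males_only_lambda3", "males_only_lambda_g"):
        rows.append(ModelRunSpec(name, "G", n_sims))
    return rows


def excluded_timepoint_policy(
    records: Sequence[GenotypeCounts],
    schedules: Sequence[DemographySchedule],
    start_point: int = DEFAULT_START_POINT,
) -> tuple[dict[str, InitSpec], list[DemographySchedule], int]:
    """Derive initial conditions and the statistic grid from observed records.

    The observed frequencies at ``start_point`` are converted into initial
    genotype counts (deterministic largest-remainder rounding against the
    schedule-implied per-sex totals, cohort structure preserved), and the
    returned statistics start time is ``start_point + 1``.
    """
    by_room: dict[str, dict[int, GenotypeCounts]] = {}
    for rec in records:
        by_room.setdefault(rec.room_id, {})[rec.time_point] = rec
    inits: dict[str, InitSpec] = {}
    trunc: list[DemographySchedule] = []
    for sched in schedules:
        points = by_room.get(sched.room_id, {})
        if len(points) < start_point + 1:
            raise ScheduleError(
                f"room {sched.room_id}: need at least {start_point + 1} "
                f"monitoring points, have {len(points)}"
            )
        if start_point not in points:
            raise ScheduleError(
                f"room {sched.room_id}: no observed record at point {start_point}"
            )
        obs = points[start_point]
        tsched = sched.truncated_at(start_point)
        n_f, n_m = tsched.init_sizes
        if obs.sex_split is not None:
            trip_f, trip_m = obs.sex_split
        else:
            trip_f = trip_m = obs.triple
        if sum(trip_f) == 0:
            trip_f = obs.triple
        if sum(trip_m) == 0:
            trip_m = obs.triple
        init_f: Triple = tuple(
            int(x) for x in largest_remainder(np.array(trip_f, float), n_f)
        )
        init_m: Triple = tuple(
            int(x) for x in largest_remainder(np.array(trip_m, float), n_m)
        )
        inits[sched.room_id] = (init_f, init_m)
        trunc.append(tsched)
    return inits, trunc, start_point + 1


@dataclasses.dataclass
class SuiteRow:
    spec: ModelRunSpec
    posterior_mean: pd.Series | None = None
    interval95: pd.DataFrame | None = None
    model_posteriors: dict[str, float] | None = None
    gof_p: dict[str, float] | None = None
    error: str | None = None


@dataclasses.dataclass
class SuiteReport:
    rows: list[SuiteRow]

    def to_frame(self) -> pd.DataFrame:
        """Flat tabular report in the frozen grid column order."""
        recs = []
        for row in self.rows:
            rec: dict = dict(
                model=row.spec.variant_name,
                mode=row.spec.mode,
                n_sims=row.spec.n_sims,
                tolerance=row.spec.tolerance,
            )
            if row.error is not None:
                rec["error"] = row.error
            else:
                for p in row.posterior_mean.index:
                    lo, hi = row.interval95.loc[p]
                    rec[f"{p}_mean"] = row.posterior_mean[p]
                    rec[f"{p}_lo"] = lo
                    rec[f"{p}_hi"] = hi
                rec["p_neutral"] = row.model_posteriors["neutral"]
                rec["p_selection"] = row.model_posteriors["selection"]
                rec["gof_neutral"] = row.gof_p["neutral"]
                rec["gof_selection"] = row.gof_p["selection"]
            recs.append(rec)
        return pd.DataFrame(recs)


def fit_one(
    spec: ModelRunSpec,
    obs_records: Sequence[GenotypeCounts],
    schedules: Sequence[DemographySchedule],
    seed: int,
    prior: PriorSpec | None = None,
    start_point: int = DEFAULT_START_POINT,
    with_diagnostics: bool = True,
) -> SuiteRow:
    """Fit one grid row: reference table, ABC fit, model choice, goodness of fit.

    The neutral reference table used for model choice integrates the same
    nuisance parameters (g, lam) over their priors as the selection variant.
    """
    prior = prior or PriorSpec()
    inits, trunc, start_time = excluded_timepoint_policy(
        obs_records, schedules, start_point
    )
    obs = observation_vector(obs_records, spec.mode, start_time)
    mv = spec.model_variant
    table = build_reference_table(
        spec.n_sims, prior, mv, trunc, inits, spec.mode,
        seed=seed, start_time=start_time,
    )
    res = abc_fit(obs, table, spec.tolerance)
    # nuisance parameters (integrated over their priors) are not reported
    est = list(mv.estimated)
    row = SuiteRow(
        spec=spec,
        posterior_mean=res.posterior_mean[est],
        interval95=res.interval95.loc[est],
    )
    if not with_diagnostics:
        return row
    neutral_mv = ModelVariant(
        "neutral", "neutral", (), integrated=mv.integrated, fixed={}
    )
    neutral_table = build_reference_table(
        spec.n_sims, prior, neutral_mv, trunc, inits, spec.mode,
        seed=seed + 1, start_time=start_time,
    )
    tables = {"neutral": neutral_table, "selection": table}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mc = model_posterior(obs, tables, spec.tolerance)
    gof_rng = spawn_rng(seed, 2)
    gof = {
        name: goodness_of_fit(obs, tab, spec.n_gof, spec.tolerance, gof_rng)
        for name, tab in tables.items()
    }
    row.model_posteriors = mc.posterior_probs
    row.gof_p = gof
    return row


def run_suite(
    specs: Sequence[ModelRunSpec],
    obs_records: Sequence[GenotypeCounts],
    schedules: Sequence[DemographySchedule],
    seed: int,
    prior: PriorSpec | None = None,
    start_point: int = DEFAULT_START_POINT,
) -> SuiteReport:
    """Run every grid row with per-row seeds derived from the root seed.

    A row that fails is reported in place (its ``error`` field set) without
    aborting the rest of the suite.
    """
    rows = []
    for i, spec in enumerate(specs):
        row_seed = int(
            np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % 2**31
        )
        try:
            rows.append(
                fit_one(spec, obs_records, schedules, row_seed, prior, start_point)
            )
        except Exception as exc:  # deliberate: row-level containment
            rows.append(SuiteRow(spec=spec, error=f"{type(exc).__name__}: {exc}"))
    return SuiteReport(rows)
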