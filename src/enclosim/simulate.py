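"""Individual-based forward simulation of enclosure populations.

One enclosure (room) holds freely breeding diploid individuals carrying a
biallelic locus (WT vs. knockout allele).  Reproduction follows a fixed
demography schedule: at each monitoring step the scheduled number of new
adults of each sex is created by sampling one mother and one father per
offspring with probability proportional to fitness, Mendelian segregation
decides the offspring genotype, and scheduled cohorts are then removed.
Population size and sex composition are therefore schedule-determined;
selection only shifts genotype composition.

Fitness parameterisation (per sex): ko/ko = 1, heterozygote = 1 + h*s,
WT/WT = 1 + s.  Optional extensions: non-genetic fitness noise with standard
deviation ``g`` (a Normal draw around the genotype value, floored at 0) and a
non-random-mating penalty ``lam`` that down-weights mate pairs sharing
alleles: identical allele sets x(1-lam), one shared allele x(1-lam/2),
no shared allele x1.

Genotypes are coded internally by WT-allele count: 0 = ko/ko, 1 = HET,
2 = WT/WT.  Count triples at the API boundary use the (WT/WT, HET, ko/ko)
order of the monitoring tables.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from ._util import largest_remainder
from .counts import GenotypeCounts, Triple
from .demography import DemographySchedule
from .errors import DegenerateWeightsError, ExtinctionError, ScheduleError

FEMALE, MALE = 0, 1

VARIANTS = ("neutral", "males_only", "sex_averaged", "sex_specific")


@dataclasses.dataclass(frozen=True)
class FitnessModel:
    """Selection/dominance parameters per sex plus the optional g and lam knobs."""

    s_male: float = 0.0
    h_male: float = 0.0
    s_female: float = 0.0
    h_female: float = 0.0
    g: float = 0.0
    lam: float = 0.0
    variant: str = "males_only"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for s in (self.s_male, self.s_female):
            if s <= -1.0:
                raise ValueError(f"selection coefficient {s} must be > -1")
        if not 0.0 <= self.g:
            raise ValueError("g must be >= 0")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.variant == "males_only" and self.s_female != 0.0:
            raise ValueError("males_only requires s_female = 0")
        if self.variant == "sex_averaged" and (
            self.s_female != self.s_male or self.h_female != self.h_male
        ):
            raise ValueError("sex_averaged requires shared (s, h) across sexes")
        if self.variant == "neutral" and (self.s_male != 0 or self.s_female != 0):
            raise ValueError("neutral requires s = 0 in both sexes")

    @classmethod
    def neutral(cls) -> "FitnessModel":
        return cls(variant="neutral")

    @classmethod
    def males_only(cls, s: float, h: float, g: float = 0.0, lam: float = 0.0) -> "FitnessModel":
        return cls(s_male=s, h_male=h, g=g, lam=lam, variant="males_only")

    @classmethod
    def sex_averaged(cls, s: float, h: float, g: float = 0.0, lam: float = 0.0) -> "FitnessModel":
        return cls(s, h, s, h, g=g, lam=lam, variant="sex_averaged")

    @classmethod
    def sex_specific(
        cls, s_male: float, h_male: float, s_female: float, h_female: float,
        g: float = 0.0, lam: float = 0.0,
    ) -> "FitnessModel":
        return cls(s_male, h_male, s_female, h_female, g=g, lam=lam, variant="sex_specific")

    def base_fitness(self, genotypes: np.ndarray, male: bool) -> np.ndarray:
        """Deterministic genotype fitness for one sex (genotype = WT-allele count)."""
        s, h = (self.s_male, self.h_male) if male else (self.s_female, self.h_female)
        table = np.array([1.0, 1.0 + h * s, 1.0 + s])
        return table[np.asarray(genotypes, dtype=np.intp)]


@dataclasses.dataclass(frozen=True)
class Individual:
    sex: int  # FEMALE or MALE
    genotype: int  # WT-allele count, 0..2
    cohort: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in (0, 1, 2):
            raise ValueError(f"invalid genotype {self.genotype}")
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"invalid sex {self.sex}")


def individual_fitness(
    ind: Individual, model: FitnessModel, rng: np.random.Generator | None = None
) -> float:
    """Fitness of one individual; stochastic only when ``model.g > 0``."""
    base = float(model.base_fitness(np.array([ind.genotype]), ind.sex == MALE)[0])
    if model.g == 0.0:
        return base
    if rng is None:
        raise ValueError("rng required when g > 0")
    return max(0.0, float(rng.normal(base, model.g)))


def mating_modifier(gen_a: int, gen_b: int, lam: float) -> float:
    """Pair weight multiplier under non-random mating.

    Allele sets: ko/ko = {ko}, HET = {WT, ko}, WT/WT = {WT}.  Identical sets
    give 1 - lam, exactly one shared allele 1 - lam/2, disjoint sets 1.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    if gen_a == gen_b:
        return 1.0 - lam
    if {gen_a, gen_b} == {0, 2}:
        return 1.0
    return 1.0 - lam / 2.0


def _modifier_row(gen_mother: int, male_genotypes: np.ndarray, lam: float) -> np.ndarray:
    table = np.array(
        [[mating_modifier(a, b, lam) for b in (0, 1, 2)] for a in (0, 1, 2)]
    )
    return table[gen_mother][male_genotypes]


def _weighted_choice(rng: np.random.Generator, weights: np.ndarray, size: int) -> np.ndarray:
    cw = np.cumsum(weights)
    total = cw[-1]
    if not total > 0.0 or not np.isfinite(total):
        raise DegenerateWeightsError("all candidate parent weights are zero")
    idx = np.searchsorted(cw, rng.random(size) * total, side="right")
    n = len(weights)
    if idx.size and idx.max() >= n:  # float round-up at the boundary
        idx[idx >= n] = n - 1
    return idx


def sample_parent_pair(
    females: Sequence[Individual],
    males: Sequence[Individual],
    model: FitnessModel,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Draw one (mother, father) pair.

    The mother is sampled proportional to female fitness; the father
    proportional to male fitness times the mating modifier against the chosen
    mother's genotype (sequential sampling).  Draws are independent across
    offspring, i.e. with replacement.
    """
    if not females or not males:
        raise ExtinctionError("cannot sample parents from an empty sex")
    w_f = np.array([individual_fitness(f, model, rng) for f in females])
    w_m = np.array([individual_fitness(m, model, rng) for m in males])
    mi = int(_weighted_choice(rng, w_f, 1)[0])
    mother = females[mi]
    if model.lam > 0.0:
        w_m = w_m * np.array(
            [mating_modifier(mother.genotype, m.genotype, model.lam) for m in males]
        )
    father = males[int(_weighted_choice(rng, w_m, 1)[0])]
    return mother, father


def mendelian_offspring(
    mother_gen: int, father_gen: int, rng: np.random.Generator
) -> int:
    """Offspring genotype from independent gamete draws (WT-allele counts)."""
    return int(rng.random() < mother_gen / 2.0) + int(rng.random() < father_gen / 2.0)


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Alive-adult genotype counts by sex at each included monitoring step."""

    room_id: str
    steps: tuple[int, ...]
    counts_female: np.ndarray  # (n_steps, 3) in (WT/WT, HET, ko/ko) order
    counts_male: np.ndarray

    def to_records(self) -> list[GenotypeCounts]:
        recs = []
        for i, t in enumerate(self.steps):
            f = tuple(int(x) for x in self.counts_female[i])
            m = tuple(int(x) for x in self.counts_male[i])
            total = tuple(a + b for a, b in zip(f, m))
            recs.append(
                GenotypeCounts(self.room_id, t, *total, sex_split=(f, m))
            )
        return recs


import functools


@functools.lru_cache(maxsize=4096)
def _triple_to_geno_array(triple: Triple) -> np.ndarray:
    """Expand a (WT/WT, HET, ko/ko) triple into per-individual genotype codes."""
    wt, het, ko = triple
    return np.repeat(np.array([2, 1, 0], dtype=np.int8), [wt, het, ko])


def _geno_counts_to_triple(genotypes: np.ndarray) -> np.ndarray:
    c = np.bincount(genotypes, minlength=3)
    return c[::-1]  # genotype code 2,1,0 -> (WT/WT, HET, ko/ko)


@functools.lru_cache(maxsize=4096)
def _split_init_across_cohorts(
    triple: Triple, cohort_sizes: tuple[int, ...]
) -> tuple[Triple, ...]:
    """Partition a genotype-count triple across cohorts of fixed sizes.

    Each cohort receives approximately the pooled genotype frequencies
    (sequential largest-remainder), so cohort removal does not systematically
    remove one genotype.  Deterministic.
    """
    remaining = np.array(triple, dtype=int)
    out = []
    for size in cohort_sizes:
        if size == 0:
            out.append(np.zeros(3, dtype=int))
            continue
        if remaining.sum() == 0:
            raise ScheduleError("init cohorts demand more individuals than supplied")
        alloc = largest_remainder(remaining, size)
        alloc = np.minimum(alloc, remaining)
        # repair any shortfall deterministically
        short = size - int(alloc.sum())
        while short > 0:
            for k in range(3):
                if short == 0:
                    break
                take = min(short, int(remaining[k] - alloc[k]))
                alloc[k] += take
                short -= take
        remaining -= alloc
        out.append(alloc)
    if remaining.sum() != 0:
        raise ScheduleError("init totals exceed the cohort sizes")
    return tuple(tuple(int(x) for x in a) for a in out)


class _SexPool:
    """Mutable per-sex population state (vectorized over individuals)."""

    __slots__ = ("genotype", "cohort", "weight")

    def __init__(self) -> None:
        self.genotype = np.empty(0, dtype=np.int8)
        self.cohort = np.empty(0, dtype=np.int32)
        self.weight = np.empty(0, dtype=np.float64)

    def add(self, genotype: np.ndarray, cohort: int, weight: np.ndarray) -> None:
        self.genotype = np.concatenate([self.genotype, genotype.astype(np.int8)])
        self.cohort = np.concatenate(
            [self.cohort, np.full(len(genotype), cohort, dtype=np.int32)]
        )
        self.weight = np.concatenate([self.weight, weight])

    def remove_cohorts(self, labels: frozenset[int]) -> None:
        if not labels:
            return
        keep = np.ones(len(self.cohort), dtype=bool)
        for label in labels:  # removal sets are tiny; per-label masks beat isin
            keep &= self.cohort != label
        self.genotype = self.genotype[keep]
        self.cohort = self.cohort[keep]
        self.weight = self.weight[keep]


def _entry_weights(
    genotypes: np.ndarray, male: bool, model: FitnessModel, rng: np.random.Generator
) -> np.ndarray:
    base = model.base_fitness(genotypes, male)
    if model.g == 0.0:
        return base
    return np.maximum(0.0, rng.normal(base, model.g))


def simulate_room(
    schedule: DemographySchedule,
    model: FitnessModel,
    init: tuple[Triple, Triple],
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one room along its schedule.

    ``init`` gives the initial genotype triples (female, male); their totals
    must equal the schedule's initial per-sex population.  When the schedule
    carries ``standing`` cohorts (a mid-experiment restart), the initial
    individuals are partitioned across those cohorts so that later scheduled
    removals of pre-start cohorts still apply.
    """
    init_f, init_m = init
    want_f, want_m = schedule.init_sizes
    if sum(init_f) != want_f or sum(init_m) != want_m:
        raise ScheduleError(
            f"room {schedule.room_id}: init totals ({sum(init_f)}F/{sum(init_m)}M) "
            f"do not match the schedule ({want_f}F/{want_m}M)"
        )

    pools = (_SexPool(), _SexPool())
    if schedule.standing:
        init_cohorts = schedule.standing
        breed_steps = schedule.steps
    else:
        first = schedule.steps[0]
        init_cohorts = ((first.step, first.n_new_females, first.n_new_males),)
        breed_steps = schedule.steps[1:]
    sizes_f = tuple(c[1] for c in init_cohorts)
    sizes_m = tuple(c[2] for c in init_cohorts)
    init_f = tuple(int(x) for x in init_f)
    init_m = tuple(int(x) for x in init_m)
    for (label, _, _), tf, tm in zip(
        init_cohorts,
        _split_init_across_cohorts(init_f, sizes_f),
        _split_init_across_cohorts(init_m, sizes_m),
    ):
        gf = _triple_to_geno_array(tf)
        gm = _triple_to_geno_array(tm)
        pools[FEMALE].add(gf, label, _entry_weights(gf, False, model, rng))
        pools[MALE].add(gm, label, _entry_weights(gm, True, model, rng))

    steps_out: list[int] = []
    counts_f: list[np.ndarray] = []
    counts_m: list[np.ndarray] = []

    def census(step: int) -> None:
        steps_out.append(step)
        counts_f.append(_geno_counts_to_triple(pools[FEMALE].genotype))
        counts_m.append(_geno_counts_to_triple(pools[MALE].genotype))

    if not schedule.standing:
        first = schedule.steps[0]
        pools[FEMALE].remove_cohorts(first.cohorts_removed)
        pools[MALE].remove_cohorts(first.cohorts_removed)
        if first.include_in_stats:
            census(first.step)

    lam = model.lam
    for st in breed_steps:
        n_new = st.n_new
        if n_new > 0:
            if len(pools[FEMALE].genotype) == 0 or len(pools[MALE].genotype) == 0:
                raise ExtinctionError(
                    f"room {schedule.room_id} step {st.step}: a sex died out"
                )
            w_f, w_m = pools[FEMALE].weight, pools[MALE].weight
            g_f, g_m = pools[FEMALE].genotype, pools[MALE].genotype
            mothers = _weighted_choice(rng, w_f, n_new)
            mg = g_f[mothers]
            if lam == 0.0:
                fathers = _weighted_choice(rng, w_m, n_new)
            else:
                fathers = np.empty(n_new, dtype=np.intp)
                for gen in (0, 1, 2):
                    sel = mg == gen
                    k = int(sel.sum())
                    if k:
                        fathers[sel] = _weighted_choice(
                            rng, w_m * _modifier_row(gen, g_m, lam), k
                        )
            fg = g_m[fathers]
            child = (
                (rng.random(n_new) < mg / 2.0).astype(np.int8)
                + (rng.random(n_new) < fg / 2.0).astype(np.int8)
            )
            new_f, new_m = child[: st.n_new_females], child[st.n_new_females :]
            pools[FEMALE].add(new_f, st.step, _entry_weights(new_f, False, model, rng))
            pools[MALE].add(new_m, st.step, _entry_weights(new_m, True, model, rng))
        pools[FEMALE].remove_cohorts(st.cohorts_removed)
        pools[MALE].remove_cohorts(st.cohorts_removed)
        if st.include_in_stats:
            census(st.step)

    return Trajectory(
        schedule.room_id,
        tuple(steps_out),
        np.array(counts_f, dtype=int),
        np.array(counts_m, dtype=int),
    )


InitSpec = tuple[Triple, Triple]


def trajectory_statistics(
    trajectories: Sequence[Trajectory],
    mode: Literal["A", "G"],
    start_time: int = 0,
) -> np.ndarray:
    """Summary-statistic vector from simulated trajectories.

    Same frozen ordering contract as :func:`enclosim.counts.observation_vector`:
    rooms ascending, time points ascending, genotype frequencies in
    (WT/WT, HET, ko/ko) order; sexes pooled.
    """
    out: list[float] = []
    for traj in sorted(trajectories, key=lambda t: t.room_id):
        totals = traj.counts_female + traj.counts_male
        for i, t in enumerate(traj.steps):
            if t < start_time:
                continue
            triple = totals[i]
            n = int(triple.sum())
            if mode == "A":
                out.append((2 * triple[0] + triple[1]) / (2 * n))
            else:
                out.extend(triple / n)
    return np.asarray(out, dtype=float)


def simulate_experiment(
    schedules: Sequence[DemographySchedule],
    model: FitnessModel,
    inits: Mapping[str, InitSpec],
    mode: Literal["A", "G"],
    rng: np.random.Generator,
    start_time: int = 0,
) -> np.ndarray:
    """Simulate all rooms once and return the pooled summary-statistic vector."""
    trajs = []
    for sched in sorted(schedules, key=lambda s: s.room_id):
        trajs.append(simulate_room(sched, model, inits[sched.room_id], rng))
    return trajectory_statistics(trajs, mode, start_time)
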