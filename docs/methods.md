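# Methods

## The demographic scaffold

A `DemographySchedule` lists, per room and monitoring point, how many new
adults of each sex enter and which earlier cohorts (labelled by their entry
point) leave. Within a step, events are ordered: offspring of the standing
population enter → scheduled cohorts are removed → the census is taken.
Consequences:

* Population size and sex composition after every step are functions of the
  schedule alone — identical across fitness models and random seeds. This is
  deliberate: in the enclosure protocol, census sizes and removals are
  imposed by the experimenters, so the data carry selection signal only
  through genotype composition.
* One monitoring interval is one reproduction event. The scheduled number of
  new adults at a point is exactly the number of offspring created that
  step. Mice breed continuously, so this "one litter cycle per census" view
  compresses within-interval turnover; it is the simplest mapping consistent
  with per-point adult counts.
* Offspring sexes are assigned to match the scheduled per-sex counts exactly
  (not Bernoulli), because the schedule encodes the observed sex ratio.

A schedule restarted mid-experiment (see *Start-point policy*) carries its
`standing` cohorts explicitly, so removals of pre-start cohorts scheduled
for later points still apply.

## Fitness and mating

Per sex, genotype fitness is 1 (ko/ko), 1 + h·s (heterozygote), 1 + s
(WT/WT). Model variants: `males_only` (females all 1), `sex_averaged`
(shared s, h), `sex_specific` (independent per sex), `neutral` (s = 0).

Parents are drawn independently per offspring, with replacement — a
prolific male can sire many offspring in one interval. The mother is
sampled ∝ female fitness; the father ∝ male fitness, multiplied under
non-random mating by (1−λ) when the pair's allele sets are identical,
(1−λ/2) when exactly one allele is shared, 1 otherwise. Sampling is
sequential (mother first) rather than joint over pairs: it costs O(F + M)
per genotype class instead of O(F·M), and for this modifier the two readings
coincide in the father's conditional distribution given the mother.

Non-genetic fitness noise (`g` > 0) draws each individual's fitness once at
entry from Normal(genotype value, g), floored at 0. Flooring (rather than
resampling) keeps the random-draw count deterministic so that trajectories
are bit-reproducible for a given seed; the probability mass at 0 is
negligible for the g ≤ 0.5 prior range. With g = 0 the noisy model reduces
exactly to the base model.

Offspring genotypes follow Mendelian segregation: each parent transmits a
WT allele with probability (own WT-allele count)/2, independently.

## Start-point policy

Founders enter as pure homozygotes, so the first censuses are far from any
mating equilibrium. The first two monitoring points are therefore excluded:
the third point's observed frequencies become the simulation's initial
condition and the summary statistics cover point 4 onward.

Initial genotype counts are deterministic largest-remainder roundings of the
observed start-point frequencies against the schedule-implied per-sex
totals (per-sex frequencies when the records carry a sex split, pooled
otherwise). The standing population at the start point consists of several
cohorts with different future removal dates; observed data do not resolve
genotype-by-cohort, so each cohort receives (approximately) the pooled
frequencies, again by largest remainder. This prevents a cohort removal from
systematically stripping one genotype, which would otherwise inject spurious
frequency jumps.

## Summary statistics

Mode `A`: the WT allele frequency at every room × included time point.
Mode `G`: the three genotype frequencies (WT/WT, HET, ko/ko — the third
component is redundant but kept for interpretability; distances change only
by a constant factor). Ordering is frozen: rooms ascending, time points
ascending, genotypes in the order above. Sexes are pooled.

## Priors

* `s` ~ Gamma(shape 3, rate 3) − 1: support (−1, ∞), mean 0, slight right
  skew. (The rate — not scale — reading is the one consistent with a zero
  mean; it is fixed throughout.)
* `h`, `λ` ~ Uniform(0, 1); `g` ~ Uniform(0, 0.5).
* Model variants with an extra nuisance parameter (g, λ in the
  two-parameter mating model) sample it from its prior but do not report
  it — it is integrated out. The "three-parameter" mating variant instead
  reports λ alongside s and h. Both readings of the grid row are available
  (`males_only_lambda` vs `males_only_lambda3`).
* For confusion matrices, the selection table can fix `s` at its posterior
  point estimate while `h` stays on its prior (`variant("males_only",
  s=s_hat)`), mirroring the point-estimate-vs-neutral comparison design.

## ABC: rejection and regression adjustment

Statistics are scaled by their full-reference-table median absolute
deviation (zero-MAD columns dropped with a warning); distance is Euclidean.
The closest ceil(tolerance·N) rows are accepted (default tolerance 0.1;
distance ties break by row index) with Epanechnikov kernel weights
1 − (d/d_max)².

Adjustment is local-linear: per parameter, a weighted ridge regression of
the parameter on the obs-centred scaled statistics gives the conditional
mean at the observation; residuals are rescaled by the conditional-SD ratio
σ̂(obs)/σ̂(xᵢ) — from a second weighted ridge regression of log squared
residuals on the same design — and re-attached. The ridge penalty is chosen
by generalised cross-validation over the fixed grid 10⁻⁴…1 (the local
design is often near-collinear; GCV avoids hand-tuning). Parameters are
regressed on transformed scales so adjusted draws respect their supports:
log(1+s) for selection coefficients, logit for h and λ, logit(g/0.5) for g.
Posterior summaries are the weighted mean and weighted equal-tailed
2.5/97.5 percentiles (not HPD) of the adjusted draws. If the accepted set is
smaller than p + 2 the adjustment falls back to the rejection sample with a
warning.

## Model choice, cross-validation, goodness of fit

* **Model posterior**: tables pooled, one rejection step on the pooled
  cloud, then a (multinomial) logistic regression of the model label on the
  standardised accepted statistics, evaluated at the observation. A model
  absent from the accepted set gets probability 0 with a warning.
* **Cross-validation**: each fold holds one table row out, treats its
  statistics as the pseudo-observation and its parameters as truth.
  Prediction error per parameter is Σ(θ̂ − θ)² / (n · Var(θ)) — ≈ 1 for a
  parameter the statistics carry no information about, → 0 for a perfectly
  informative statistic.
* **Confusion matrix**: per generating model, pseudo-observations are table
  rows (each excluded from its own reference set); the row records the
  fraction assigned to each candidate by highest posterior probability.
* **Goodness of fit**: the statistic is the mean scaled distance of the
  observation to its accepted set; the null distribution re-computes it for
  table rows treated as pseudo-observations. p is the null fraction at least
  as large as observed. The procedure is the standard distance-based
  posterior-predictive check; nothing sharper is attempted.

## The synthetic experiment generator

`SyntheticDesign` emulates the structure of the study: 3 rooms founded with
10 WT/WT + 10 ko/ko adults at equal sex ratio, 9 monitoring points, founders
removed at point 4, later cohorts removed on a staggered schedule (entry
point 2 at 7, 3 at 8, 4 at 9), growth to several hundred adults per room.
The default per-point adult counts (20, 36, 60, 90, 140, 200, 260, 330, 400
for rooms 1–2; a ramp to 290 for room 3, which ran at roughly half scale)
are a parameterised stand-in: small through point 3, steep afterwards. The
default true model is males-only selection with s = 0.5, h = 0.5 — the
middle of the range such enclosure competitions are powered to detect and
the magnitude around which this package's diagnostics are exercised.

What the generator does **not** emulate: the real experiment's exact
per-point counts and sex ratios (published only as supplementary data files,
not reproduced here), deaths between censuses beyond scheduled
removals, litter structure and multiple paternity, and any spatial
organisation of the rooms. Passing tests therefore demonstrate that the
inference machinery recovers known truths under the *structural* conditions
of the experiment, not that it reproduces the study's real-data numbers.

## Numerical and reproducibility choices

* One root seed per run; per-replicate sub-streams derive deterministically
  from (seed, replicate index, retry index) via `SeedSequence`, so reference
  tables are bit-reproducible and independent of execution order.
* Replicates whose simulation loses a whole sex are re-drawn from a fresh
  sub-stream (≤ 20 retries); the build aborts if >1% of replicates fail
  persistently.
* Largest-remainder rounding breaks ties by ascending index; acceptance-set
  ties break by row index.
* Human-readable reports round to 2–3 decimals; machine outputs keep full
  precision; every CLI output carries a JSON metadata sidecar (inputs, seed,
  version).

## Problem sizes

The test suite and the acceptance script run the pipeline at 10,000
simulations per reference table with tolerance 0.1 (the tolerance-comparison
property checks 0.01/0.1/0.2 agree), 200 cross-validation folds, and
10 + 10 parameter-recovery repetitions at true s ∈ {0, 0.5}; the full-scale
grid defaults (100,000 simulations, 200,000 with an extra nuisance
parameter) remain the package defaults for real analyses. At 10,000
simulations the Monte-Carlo spread of the posterior mean of s across
pseudo-experiments is roughly ±0.15.

## Known limitations

* The dominance coefficient h is essentially unidentifiable from these
  designs (cross-validation error ≈ 0.9–1.0); its posterior mainly returns
  the prior.
* The generation mapping (one reproduction event per monitoring interval)
  ignores within-interval generational overlap; selection estimates are
  therefore per monitoring interval, not per mouse generation.
* The non-random-mating model reweights pair formation only; it cannot
  express territory- or dominance-driven mating structure, and the sequential
  mother-then-father sampling is one of two defensible readings of
  pair-weight models.
* Goodness-of-fit p-values use a generic distance statistic; they flag
  gross misfit but have limited power against subtle model violations.
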