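# enclosim

Estimating the fitness effect of a knockout allele from replicated
semi-natural enclosure populations.

## The problem

A gene-knockout mouse line competes against its parental wildtype strain in
closed rooms where animals breed freely over several overlapping
generations. At each monitoring point every adult is caught, genotyped
(WT/WT, WT/ko, ko/ko) and counted, and scheduled cohorts of older animals
are removed. The question: does carrying the intact gene confer a fitness
advantage, and how large is the selection coefficient?

Allele-frequency trajectories from such experiments are short, noisy and
demographically constrained — population size, sex ratio and removals are
imposed by the protocol, not by the genotypes. `enclosim` answers the
question the way a population geneticist would: simulate the experiment
forward under the *exact* observed demography with a parameterised fitness
model, and infer the parameters by approximate Bayesian computation (ABC).

## The model

Each individual carries one biallelic locus. Relative fitness per sex
follows Wright's parameterisation:

    w(ko/ko) = 1,    w(WT/ko) = 1 + h·s,    w(WT/WT) = 1 + s

with selection coefficient `s > −1` and dominance `h ∈ [0,1]`. Variants of
the model restrict the effect to males (`s = h = 0` in females), share it
across sexes, or give each sex its own `(s, h)`. Two optional extensions add
non-genetic fitness noise (a Normal draw with SD `g` around the genotype
value) and non-random mating (pair weight ×(1−λ) for identical allele sets,
×(1−λ/2) for one shared allele, ×1 otherwise).

Reproduction follows a demography schedule: at each monitoring step, exactly
the scheduled number of new adults of each sex is created by drawing one
mother and one father per offspring with probability proportional to
fitness, Mendelian segregation decides the genotype, then scheduled cohorts
are removed. Population size and sex composition are therefore
schedule-determined; selection moves only genotype composition.

Inference is classical rejection ABC with regression adjustment: draw
`(s, h, …)` from the priors (`s` ~ Gamma(shape 3, rate 3) − 1, mean 0;
`h`, `λ` ~ U(0,1); `g` ~ U(0, 0.5)), simulate the whole multi-room
experiment, keep the 10% of simulations whose summary statistics (allele or
genotype frequencies at every room/time point) are closest to the
observation, then sharpen the accepted sample with a weighted ridge
regression with heteroscedasticity correction. Model choice (selection vs.
neutral), leave-one-out cross-validation, confusion matrices and a
distance-based goodness-of-fit test complete the toolkit.

## Worked example

Cumulative genotype statistics per room from the published counts
(`python analysis/01_table_statistics.py`):

```
 room    n  n_wt_hom  n_het  n_ko_hom chi2 f_wt f_ko
room1 1181       338    576       267 0.52 0.53 0.47
room2 1205       329    584       292 1.07 0.52 0.48
room3  578       216    264        98 1.26 0.60 0.40
```

Every room ends with a WT allele frequency above the founding 0.5, and the
Hardy–Weinberg chi-squares (1 df) are all non-significant — offspring
genotype proportions are compatible with random mating per census.

A full inference run on a synthetic three-room experiment generated at a
known truth (males-only selection, s = 0.5, h = 0.5; scripts
`analysis/02…05`) gives, at 10,000 simulations and tolerance 0.1:

```
mode parameter  mean    lo    hi
   A         s 0.437 0.043 1.046
   A         h 0.485 0.033 0.971
   G         s 0.508 0.161 1.013
   G         h 0.557 0.045 0.967
```

The `s` posterior concentrates on positive values and its 95% interval
covers the truth in both statistic modes, while the `h` posterior stays
close to its flat prior. The diagnostics agree: cross-validation prediction
error ≈ 0.12 for `s` (identifiable) versus ≈ 0.94 for `h` (not), the
selection model is favoured over the neutral one, and the neutral/selection
confusion matrix classifies ~86% of pseudo-datasets correctly.

There is also a CLI for the individual steps:

```bash
enclosim synth --seed 7 --out data/
enclosim table1 data/counts.csv
enclosim fit --obs data/counts.csv --schedule data/schedule.csv \
    --model males_only --mode A --n-sims 10000 --seed 1 --out posterior.csv
```

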