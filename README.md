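# svhdecay

Forgetting-curve analysis for vestibular roll-tilt perception: does the
short-term memory of an angular displacement, sensed by the semicircular
canals, decay exponentially or as a power law?

In a swing-out gondola centrifuge, spinning a seated subject up to 2.5 G
rolls the gondola 66° outward while the gravitoinertial resultant stays
aligned with the body axis — the canals register a roll tilt that the
otolith organs deny. The resulting tilt sensation is measured as the
subjective visual horizontal (SVH): the subject repeatedly sets a
luminous line in darkness to what feels horizontal, and the deviation
(degrees, right tilt positive) fades over ~6 minutes. This package fits
and compares the two classical retention-curve candidates on such series,

    SVH(t) = A·e^(−b·t) + C        (exponential; time constant T = 1/b)
    SVH(t) = A·t^(−b) + C          (power)

by unweighted least squares over the observation interval [4, 360] s,
and quantifies the *averaging artifact*: pooling individually exponential
decays with heterogeneous rates produces group data that a power function
fits nearly as well.

It is intended for vestibular psychophysicists and for anyone studying
the functional form of forgetting curves who needs a careful
individual-vs-group model-comparison pipeline.

## What it provides

- `decay_models` — evaluation of the exponential, power, and
  single-trace-fragility (`λ(1+βt)^(−ψ)e^(−πt)`) families, observation
  interval endpoint values F(4)/F(360), time constants.
- `fitting` — global three-parameter fits by variable projection: for
  fixed b both families are linear in (A, C), so the fit is a
  deterministic log-spaced multistart over b with the linear subproblem
  solved exactly; run-averaging into per-individual summaries.
- `group_analysis` — group mean/median/SD tables, the per-run
  exponential-vs-power RMS contest with a paired t-test across subjects,
  three pooling schemes (15 bin means, 5 bin means, all raw points), and
  a six-criterion discriminability report.
- `synthetic_data` — a seeded generator of study-conformant cohorts
  (27 subjects, 1–2 runs each, 3–5 settings/min over 360 s, cohort-level
  parameter dispersion and setting noise matching the published group
  statistics), sum-of-exponentials multi-trace series, and centrifuge
  stimulus kinematics (G level, gondola swing-out, ramp time).
- `io` / `cli` — delimited settings files, YAML run configs, table
  rendering with Mean/Median/SD footers, and a `svhdecay` command with
  `simulate`, `fit`, `group`, `pool`, `report` subcommands.
- `study` — the published per-run reference tables used by the
  reproduction checks (the original raw series were never deposited).

## Worked example

```python
from svhdecay import (CohortConfig, Family, aggregation_experiment,
                      group_summary, model_contest, study)

# Reproduce the published group statistics from the per-run tables
gs = group_summary(study.individual_summaries(Family.EXPONENTIAL))
contest = model_contest(study.run_results(Family.EXPONENTIAL),
                        study.run_results(Family.POWER))
print(f"group mean fit: SVH(t) = {gs['mean','A']:.1f}·exp(-{gs['mean','b']:.4f}·t) + {gs['mean','C']:.1f}")
print(f"mean individual time constant: {gs['mean','T']:.0f} s")
print(f"power RMS excess: {contest.percent_excess:.0f}%  "
      f"(power wins {contest.n_runs_power_wins}/{contest.n_runs_total} runs, "
      f"paired t p = {contest.p_value:.1e})")

# The averaging artifact on a synthetic cohort with study-level dispersion
rep = aggregation_experiment(CohortConfig(seed=1))
print(f"synthetic cohort ({rep.n_runs} runs): exponential wins "
      f"{rep.n_exponential_wins}/{rep.n_runs} per-run fits")
print(f"power/exponential RMS ratio: {rep.mean_individual_gap_ratio:.3f} per individual, "
      f"{rep.binned[15].rms_gap_ratio:.3f} on 15 bin means, "
      f"{rep.all_points_gap_ratio:.3f} on all {len(rep.all_points.points)} points")
```

prints

```
group mean fit: SVH(t) = 27.8·exp(-0.0181·t) + 0.5
mean individual time constant: 85 s
power RMS excess: 31%  (power wins 4/44 runs, paired t p = 2.4e-05)
synthetic cohort (44 runs): exponential wins 38/44 per-run fits
power/exponential RMS ratio: 1.165 per individual, 3.044 on 15 bin means, 1.006 on all 977 points
```

Reading the numbers: at the individual level the exponential fit beats
the power fit in the vast majority of runs (its RMS error is ~31%
smaller on the published data), and the mean individual tilt sensation
decays with an ~85 s time constant toward an asymptote near zero. But
the more aggressively runs are pooled, the more the power function
catches up — on all raw points at once the two families are essentially
tied (ratio ≈ 1.0), even though every generated run decays exponentially
by construction. Group-level curve fits can therefore misrepresent the
functional form that holds in every individual.

The same pipeline runs from the shell:

```sh
svhdecay simulate --seed 1 --out cohort.csv --truth truth.csv
svhdecay report cohort.csv --out-dir results/ --bins 15,5
```

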