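# beemaze

A virtual instrument for aversive conditioning of walking honey bees in
an automated Y-maze.  The package models the apparatus (three 140 mm
arms at 120°, each with a 26-photocell position array, floor/ceiling
shock grids, calibrated monochromatic LEDs at 375/465/520 nm and an
odor port for limonene or linalool), builds classical differential
conditioning schedules, simulates walking bees as agents with
phototaxis, shock responses and a minimal synthetic learning rule, and
analyzes the resulting event logs with the occupancy-based learning
scores and nonparametric statistics used in this kind of place-aversion
assay.  It lets conditioning experiments be designed, power-checked and
analyzed end to end without hardware or animals; the analysis pipeline
equally accepts externally produced logs in the package's TSV dialect.

## The assay and its read-out

During training, a conditioned stimulus (CS+: a color, an odor, or a
color+odor compound) fills the whole maze for 10 s paired with a train
of mild electric shocks — 2 Hz pulses of 200 ms for 10 s, i.e. 20
pulses — while a second stimulus (CS−) is presented without shocks;
exposures alternate in a balanced pseudo-random order with 30 s
inter-trial intervals.  Unpaired controls receive the same stimuli and
the same trains, but the shocks fall in the middle of the intervals, so
no contingency exists.  A bee only receives a delivered pulse when it
bridges adjacent grid wires (modeled as per-pulse Bernoulli contact
with probability 0.344, so a full train yields ≈7 received shocks of
≈1.38 µA).

Memory is then tested by position-contingent stimulus control: in a
*spontaneous* choice the bee's current arm goes dark and the two test
stimuli light the other arms; in a *forced* choice the CS+ fills the
bee's arm plus one other and the CS− the third, measuring escape.  The
learning score for a test is the percentage of the 20 s spent in each
stimulus environment; all environments present are reported, so the
percentages stack to 100.  Bees slower than 6 mm/s during the test
phase are excluded as unhealthy.  Statistics follow the standard
battery: Wilcoxon signed-rank for within-bee CS+ vs CS− comparisons,
Mann–Whitney U for trained vs control, Benjamini–Hochberg FDR within
each group's test battery, ANOVA + Tukey HSD for speed analyses, and
1.5×IQR outlier flags.

## Worked example

Simulate the standard blue/green experiment — a trained pool (Nt = 4
trials per CS, 20 bees per mirrored training cell) against an unpaired
control pool — and run the full analysis:

```python
from beemaze import ArmState, LightStimulus, TestConfigSpec
from beemaze.beesim import symmetric_groups
from beemaze.pipeline import run_experiment

blue = ArmState(light=LightStimulus.blue())
green = ArmState(light=LightStimulus.green())
choice = TestConfigSpec("spontaneous", (("CS+", blue), ("CS-", green)))

trained = symmetric_groups("bg", blue, green, 20, nt=4, tests=(choice,))
control = symmetric_groups("ctrl", blue, green, 20, nt=4, paired=False,
                           tests=(choice,))
result = run_experiment(trained + control, master_seed=7,
                        control_pool="ctrl")
print(result.occupancy_summary().round(2).to_string(index=False))
print(result.stats[["pool", "test", "comparison", "environment",
                    "z", "p", "p_fdr"]].round(4).to_string(index=False))
```

which prints

```
pool       test role  mean  sem  count
  bg test:stm:1  CS+  1.41 1.00     40
  bg test:stm:1  CS- 32.30 4.93     40
  bg test:stm:1 dark 66.29 5.00     40
ctrl test:stm:1  CS+ 25.88 4.73     40
ctrl test:stm:1  CS- 23.99 4.57     40
ctrl test:stm:1 dark 50.14 5.10     40

pool       test         comparison environment       z      p  p_fdr
  bg test:stm:1         CS+ vs CS-             -4.4211 0.0000 0.0000
  bg test:stm:1 trained vs control         CS+ -5.1572 0.0000 0.0000
  bg test:stm:1 trained vs control         CS-  1.2085 0.2269 0.2269
  bg test:stm:1 trained vs control        dark  2.1896 0.0286 0.0381
```

Trained bees spend almost no time in the shocked color (1.4% vs 25.9%
in controls, Mann–Whitney z = −5.16), while their time in the CS− does
not differ from controls — learned avoidance of the CS+, with no
evidence of safety learning of the CS−.  The signed-rank z of −4.42
is the within-bee CS+ vs CS− comparison.

The same experiment can be driven from a shell via the `beemaze` CLI
(`simulate`, `analyze`, `report`, `validate`) with a YAML config; see
`beemaze --help` and the docstring of `beemaze.config`.

## Layout

- `beemaze.apparatus` — geometry, stimulus types, environment labels.
- `beemaze.protocol` — shock trains, training sequences, test
  configurations, session schedules, design enumeration.
- `beemaze.beesim` — the agent-based bee and cohort simulator.
- `beemaze.analysis` / `beemaze.stats` — tracks, occupancy scores,
  exclusion, symmetric pooling, and the statistical battery.
- `beemaze.eventlog` / `beemaze.config` / `beemaze.cli` — versioned TSV
  log dialect, YAML configuration with the `yapis-2019` preset, and
  the command-line interface.

See `docs/methods.md` for the behavioral model, its parameters and its
limitations.
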