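# Methods

## Scope

`beemaze` is a virtual instrument: a faithful model of an automated
Y-maze conditioning apparatus and its protocols, a deliberately simple
agent model of the walking bee, and the complete analysis pipeline for
the event logs either the simulator or compatible hardware produces.
The apparatus, protocol and analysis layers aim at fidelity; the bee
model aims only at reproducing the coarse empirical regularities of
walking bees in such a maze, well enough that the analysis pipeline
can be exercised, calibrated and power-checked end to end.

## Apparatus model

Three arms (140 × 20 × 5.5 mm inner dimensions, 120° apart) meet at a
central junction, modeled as a zero-length node connecting photocell 1
of each arm; dwell time is always attributed to the arm of the
occupied cell, so occupancy accounting has exactly the three arms'
environments and no fourth "center" category.  Each arm carries 26
photocells (configurable), pitch = 140/25 = 5.6 mm, cell 1 central and
cell 26 distal.  The central vacuum sits above cell 9.  Stimuli per
arm are: one LED color (375, 465 or 520 nm) at an intensity fraction,
one odorant (limonene or linalool) delivered as an instantaneous
square pulse (plume latency and dispersion are not modeled — the
physical delivery is sharply defined in space and time), and a shock
grid.  Environment labels are canonical strings ("dark", "blue",
"green+linalool", "limonene", …) derived only from which components
are present, not their intensity; the dim blue background (intensity
0.025) used in odor tests is therefore the same *environment* as full
blue, which matches how occupancy is scored.

## Protocol engine

Sessions are 60 s dark adaptation, 2·Nt trials (10 s CS, 30 s ITI),
240 s rest, then 20 s tests with 30 s rests.  The standard Nt=4
session with one test totals 670 s.  The US train is 2 Hz × 10 s =
20 pulses of 200 ms (10 V metadata).  Unpaired controls get one train
per ITI, 10–20 s after CS offset — never overlapping any CS.

The literal pseudo-random CS orders used at the bench are not public;
the default here tiles the pattern `ABBABAAB` (A = CS+) truncated to
2·Nt, which is balanced on every even prefix, starts with the CS+,
and never repeats one CS more than twice in a row; sequence 2 is its
exact role mirror, and half of each cohort runs each.  Orders are
user-overridable by constructing `TrialSpec` lists directly.

Tests assign stimuli relative to the bee's arm at test onset.  Side
placement of the two alternatives uses arm-index order and flips with
a per-bee test counter (the starting side is fixed, the flip
deterministic — the bench rule states alternation but not the first
side).  A 24 h battery is modeled as a gap phase (no movement
simulated; memory decays by the retention factor) followed by a fresh
60 s adaptation — whether re-inserted bees got a second adaptation is
not documented; this choice is ours.

## Bee model

The bee is a 1-D walker on the photocell lattice.

| parameter | default | meaning |
|---|---|---|
| `baseline_speed` | 30 mm/s (summer 32, winter 28) | cohort mean walking speed |
| `speed_sd` | 8 mm/s | between-bee speed spread |
| `shock_speed_multiplier` | 1.5 | startle acceleration while a pulse is active |
| `contact_probability` | 0.344 | per-pulse chance of closing the grid circuit |
| `current_mean`, `current_sd` | 1.38, 0.67 µA | truncated-normal received current |
| `learning_rate` | 0.1 | aversive strength per received shock per component |
| `decay` | 0.7 /day | retention factor before a delayed battery |
| `choice_noise` | 1.0 | softmax temperature at the junction |
| `dwell_end_prob` | 0.55 | per-step stay probability at arm ends |
| `vacuum_turn_prob` | 0.25 | turn-around on entering the vacuum cell |
| `turn_prob` | 0.01 | spontaneous mid-arm reversal per step |
| `dt` | 0.1 s | simulation step (resolves 200 ms pulses at 2 Hz) |

Movement: speed accumulates fractionally in pitch units; the bee dwells
stochastically at the distal cell and at cell 1 (producing the
occupancy maxima at arm ends that real bees show), turns around under
the vacuum with elevated probability, and reverses spontaneously at a
low rate.  At cell 1 heading inward it makes a junction choice among
all three arms (return included) with weights
`exp((attraction − aversion)/choice_noise)`.

Phototaxis: attraction is `weight[λ] × intensity`, with per-wavelength
weights defaulting to the reciprocal calibrated intensities
(0.64/0.44/0.24 for 520/465/375 nm), so all three lights at their
calibrated defaults have attraction exactly 1 and naive bees are
indifferent between any two of them — the calibration the real
instrument achieves behaviorally.  Dark arms have attraction 0.

Learning: each received shock adds `learning_rate ×
learnability[component]` to the aversive strength of every CS
component active at that moment.  Compound (color+odor) stimuli train
both components independently; shocks with no CS active (unpaired
controls) train nothing, so the absence of safety learning is built in
— CS− strength is identically zero, and trained and control bees are
exchangeable with respect to the CS−.  The optional `learnability`
multiplier (e.g. `{"uv": 0.3}`) represents the empirical resistance of
UV to aversive conditioning as a parameter, not a mechanism.  This
rule is synthetic: the real learning mechanism is unknown, and this is
the minimal rule consistent with graded acquisition over trials,
independent component learning, no CS− learning, and weaker day-old
memory after minimal training.  Rare defecation short-circuits (upper
current outliers in winter data) are not simulated.

## What the simulator does and does not establish

Passing pipeline tests on simulated cohorts shows that the analysis
correctly recovers the patterns the generator encodes (graded CS+
avoidance, no CS− shift, nominal false-positive rate under the null).
It says nothing about real bees: within-trial dynamics, sensory
acuity, inter-individual learning differences, circadian and seasonal
effects beyond a mean-speed shift, and any neural mechanism are all
outside the model.  Occupancy magnitudes (e.g. how much time trained
bees spend in the dark arm) depend on the dwell/choice parameters and
should not be read quantitatively.

## Analysis conventions

- Speed: adjacent-cell transitions × pitch / window duration; passing
  through the zero-length junction adds no distance.  "Slower than
  6 mm/s" excludes with a strict `<` on the short-term-memory test
  phase by default (per-phase computation is available).
- Occupancy: piecewise-constant arm dwell between position events;
  every environment available in the test is reported (including 0%),
  so stacks total 100.
- Signed-rank test: midrank ties, zero differences dropped by default
  (Pratt handling available), tie-corrected normal approximation
  reported as a signed z; all-zero differences give z = 0, p = 1 by
  convention.  Exact mode enumerates the 2^n sign assignments with the
  symmetric two-sided definition P(|W − μ| ≥ |w_obs − μ|).
- Mann–Whitney: midranks, tie-corrected σ, signed z, no continuity
  correction; exact mode enumerates all C(n, n1) labelings.
- FDR: Benjamini–Hochberg step-up (statsmodels), by default within
  each pool's test battery; a global family is available.
- ANOVA: additive fixed-effects model (no interactions), as used for
  speed ~ season + phase; Tukey HSD on a chosen factor's level means.
- Outliers: 1.5×IQR fences with linear-interpolation quartiles (the
  quantile rule is not dictated by the assay; this one is documented).
  Values exactly on a fence are kept.

## Numerical and determinism choices

Timestamps are integer milliseconds throughout the log dialect, so
log round-trips are bit-exact.  All randomness flows from numpy
`SeedSequence` spawning: a cohort is a pure function of (design,
parameters, master seed), and per-bee substreams make cohorts
insensitive to bee order.  dt must be a whole number of milliseconds.
Phases are expanded to an exactly gap-free timeline and validated
(durations sum to the session total; paired pulses inside CS+ windows;
unpaired pulses disjoint from all CS windows).

## Problem sizes in the test suite

The quantitative contract tests use desk-scale sizes chosen to give
stable statistics: 2000 trains for the contact-fraction recovery
(3-standard-error acceptance), 200 replicate cohorts of n = 40 with
single-trial null sessions for the type-I calibration (with the
learning rate at zero, training length cannot affect test behavior,
so the shortest legitimate session is used), one 4 × 40-bee sweep for
the avoidance-vs-Nt monotonicity (with a pre-declared 0.5 percentage
point allowance for near-ties between adjacent levels), and 100
random designs for schedule time accounting.
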