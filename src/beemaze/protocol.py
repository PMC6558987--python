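"""Session schedules: training sequences, shock trains, memory tests.

A session is: 60 s adaptation in the dark, then 2*Nt training trials
(10 s CS exposure, 30 s inter-trial interval each, alternating the two
conditioned stimuli in a balanced pseudo-random order), 240 s rest in
the dark, then a battery of 20 s choice tests separated by 30 s rest.
In paired (trained) groups the shock train is co-extensive with each
CS+ exposure; in the unpaired control the same trains are moved into
the middle of each inter-trial interval (10-20 s after CS offset), so
no CS-shock contingency exists.  An optional long-term-memory battery
runs after a configurable delay (24 h by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .apparatus import ARMS, DARK, ArmState

__all__ = [
    "UsTrainSpec",
    "TrialSpec",
    "TestConfigSpec",
    "SessionSchedule",
    "DesignRow",
    "Phase",
    "build_us_train",
    "build_training_sequence",
    "assign_test_configuration",
    "schedule_session",
    "enumerate_design",
    "CS_PLUS",
    "CS_MINUS",
]

CS_PLUS = "CS+"
CS_MINUS = "CS-"

# Default pseudo-random CS order, tiled and truncated to 2*Nt trials.
# It is balanced over every even-length prefix, never repeats one CS
# more than twice in a row, and starts with the CS+.  Sequence 2 is the
# role mirror of sequence 1.
_ROLE_PATTERN = "ABBABAAB"


@dataclass(frozen=True)
class UsTrainSpec:
    """A train of mild electric shocks (the punishment).

    Defaults give the standard train: 2 Hz pulses of 200 ms at 10 V for
    10 s, i.e. 20 pulses.  Voltage is metadata only; received current
    is a property of the bee-grid contact, modeled in the simulator.
    """

    rate: float = 2.0
    pulse_duration: float = 0.2
    pulse_voltage: float = 10.0
    train_duration: float = 10.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("pulse rate must be positive")
        if self.pulse_duration > 1.0 / self.rate:
            raise ValueError("pulses longer than the inter-pulse interval")
        if self.train_duration < 0:
            raise ValueError("train_duration must be non-negative")

    @property
    def n_pulses(self) -> int:
        return round(self.rate * self.train_duration)


def build_us_train(
    spec: UsTrainSpec, start: float = 0.0
) -> tuple[tuple[float, float], ...]:
    """Expand a shock-train spec into (onset, duration) pulse pairs.

    Pulses are equally spaced at 1/rate starting at ``start``; the
    whole train fits inside ``[start, start + train_duration]``.
    """
    period = 1.0 / spec.rate
    return tuple(
        (start + k * period, spec.pulse_duration) for k in range(spec.n_pulses)
    )


@dataclass(frozen=True)
class TrialSpec:
    """One training trial: a CS exposure followed by an ITI.

    ``shocked`` marks paired shock delivery during the CS; in unpaired
    mode ``unpaired_shock`` schedules the train inside the ITI instead,
    ``control_shock_offset`` seconds after CS offset.
    """

    cs_id: str
    stimulus: ArmState | None = None
    duration: float = 10.0
    iti: float = 30.0
    shocked: bool = False
    unpaired_shock: bool = False
    control_shock_offset: float = 10.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        if self.iti < 0:
            raise ValueError("inter-trial interval must be non-negative")
        if self.shocked and self.unpaired_shock:
            raise ValueError("a trial cannot be both paired and unpaired")


@dataclass(frozen=True)
class TestConfigSpec:
    """A position-contingent memory test.

    ``stimuli`` are the two (role, arm-state) alternatives, roles being
    free labels such as ``"CS+"``, ``"CS-"``, ``"new"`` or ``"none"``.
    In spontaneous mode the bee's arm at test onset gets ``background``
    (dark, or a dim blue light for odor tests) and the two alternatives
    go into the other arms, sides alternating between successive tests.
    In forced mode the first stimulus (the CS+) fills the bee's arm and
    one other, the second fills the remaining arm, measuring escape.
    """

    __test__ = False  # name starts with "Test" but this is not a test class

    mode: str
    stimuli: tuple[tuple[str, ArmState], tuple[str, ArmState]]
    background: ArmState = DARK
    duration: float = 20.0
    rest: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("spontaneous", "forced"):
            raise ValueError("mode must be 'spontaneous' or 'forced'")
        if self.duration <= 0:
            raise ValueError("test duration must be positive")
        (role_a, _), (role_b, _) = self.stimuli
        if role_a == role_b:
            raise ValueError("the two test roles must be distinct")


def assign_test_configuration(
    spec: TestConfigSpec, bee_arm: int, side_state: int = 0
) -> dict[int, ArmState]:
    """Map each arm to its stimulus for one test, given the bee's arm.

    The left/right placement of the two stimuli relative to the bee
    alternates with ``side_state`` (the per-bee count of tests run so
    far); arms are ordered by index as the side convention.  The
    returned dict always covers exactly arms 1-3.
    """
    if bee_arm not in ARMS:
        raise ValueError(f"invalid arm id {bee_arm}")
    others = sorted(a for a in ARMS if a != bee_arm)
    (_, stim_a), (_, stim_b) = spec.stimuli
    if spec.mode == "spontaneous":
        first, second = (stim_a, stim_b) if side_state % 2 == 0 else (stim_b, stim_a)
        return {bee_arm: spec.background, others[0]: first, others[1]: second}
    # forced: CS+ (first stimulus) in the bee's arm and one other
    partner = others[side_state % 2]
    third = others[1 - side_state % 2]
    return {bee_arm: stim_a, partner: stim_a, third: stim_b}


@dataclass(frozen=True)
class Phase:
    """One contiguous segment of the expanded session timeline."""

    name: str
    kind: str  # adaptation | cs | iti | rest | test | test_rest | gap
    t0: float
    t1: float
    cs: ArmState | None = None
    pulses: tuple[tuple[float, float], ...] = ()
    test: TestConfigSpec | None = None

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass
class SessionSchedule:
    """A fully specified session for one bee."""

    trials: list[TrialSpec]
    tests: list[TestConfigSpec] = field(default_factory=list)
    adaptation: float = 60.0
    post_training_rest: float = 240.0
    us: UsTrainSpec = field(default_factory=UsTrainSpec)
    ltm_delay: float | None = None
    ltm_tests: list[TestConfigSpec] = field(default_factory=list)
    ltm_adaptation: float = 60.0

    def total_duration(self) -> float:
        """Length of the main session (excluding any LTM battery)."""
        return (
            self.adaptation
            + sum(t.duration + t.iti for t in self.trials)
            + self.post_training_rest
            + sum(t.duration + t.rest for t in self.tests)
        )

    def expand(self) -> list[Phase]:
        """Expand to an ordered, gap-free list of timeline phases."""
        phases: list[Phase] = []
        t = 0.0
        phases.append(Phase("adaptation", "adaptation", t, t + self.adaptation))
        t += self.adaptation
        for i, trial in enumerate(self.trials, start=1):
            pulses = build_us_train(self.us, t) if trial.shocked else ()
            phases.append(
                Phase(
                    f"cs:{i}:{trial.cs_id}",
                    "cs",
                    t,
                    t + trial.duration,
                    cs=trial.stimulus,
                    pulses=pulses,
                )
            )
            t += trial.duration
            iti_pulses = (
                build_us_train(self.us, t + trial.control_shock_offset)
                if trial.unpaired_shock
                else ()
            )
            phases.append(Phase(f"iti:{i}", "iti", t, t + trial.iti, pulses=iti_pulses))
            t += trial.iti
        phases.append(Phase("rest", "rest", t, t + self.post_training_rest))
        t += self.post_training_rest
        t = self._expand_tests(phases, self.tests, "stm", t)
        if self.ltm_tests:
            if not self.ltm_delay:
                raise ValueError("LTM battery requires a positive ltm_delay")
            phases.append(Phase("gap", "gap", t, t + self.ltm_delay))
            t += self.ltm_delay
            phases.append(
                Phase("ltm:adaptation", "adaptation", t, t + self.ltm_adaptation)
            )
            t += self.ltm_adaptation
            t = self._expand_tests(phases, self.ltm_tests, "ltm", t)
        return phases

    @staticmethod
    def _expand_tests(
        phases: list[Phase],
        tests: list[TestConfigSpec],
        battery: str,
        t: float,
    ) -> float:
        for j, test in enumerate(tests, start=1):
            phases.append(
                Phase(f"test:{battery}:{j}", "test", t, t + test.duration, test=test)
            )
            t += test.duration
            phases.append(
                Phase(f"testrest:{battery}:{j}", "test_rest", t, t + test.rest)
            )
            t += test.rest
        return t

    def validate(self) -> None:
        """Check time accounting and CS/US window disjointness rules."""
        phases = self.expand()
        for a, b in itertools.pairwise(phases):
            if abs(a.t1 - b.t0) > 1e-9:
                raise AssertionError("timeline has a gap or overlap")
        main = [p for p in phases if p.kind not in ("gap",) and not p.name.startswith("ltm")]
        main_end = max(p.t1 for p in main if not p.name.startswith("test:ltm")
                       and not p.name.startswith("testrest:ltm"))
        if abs(main_end - self.total_duration()) > 1e-9:
            raise AssertionError("phase durations do not sum to the session total")
        cs_windows = [(p.t0, p.t1) for p in phases if p.kind == "cs"]
        for p in phases:
            for onset, dur in p.pulses:
                if p.kind == "cs":
                    if not (p.t0 - 1e-9 <= onset and onset + dur <= p.t1 + 1e-9):
                        raise AssertionError("paired pulse escapes its CS window")
                else:
                    for w0, w1 in cs_windows:
                        if onset < w1 and onset + dur > w0:
                            raise AssertionError("unpaired pulse overlaps a CS")


def build_training_sequence(
    nt: int,
    sequence_id: int = 1,
    paired: bool = True,
    cs_plus: ArmState | None = None,
    cs_minus: ArmState | None = None,
    duration: float = 10.0,
    iti: float = 30.0,
) -> list[TrialSpec]:
    """Build the ordered trial list for one training sequence.

    ``nt`` trials of each CS are interleaved in a balanced pseudo-random
    order with at most two consecutive exposures of the same CS;
    sequence 2 is the exact role mirror of sequence 1 (half of a cohort
    runs each).  In paired mode the shock train rides on every CS+
    exposure; in unpaired mode one train is placed inside every ITI.
    """
    if nt < 1:
        raise ValueError("need at least one training trial per CS")
    if sequence_id not in (1, 2):
        raise ValueError("sequence_id must be 1 or 2")
    pattern = (_ROLE_PATTERN * ((2 * nt) // len(_ROLE_PATTERN) + 1))[: 2 * nt]
    if sequence_id == 2:
        pattern = pattern.translate(str.maketrans("AB", "BA"))
    trials = []
    for role in pattern:
        is_plus = role == "A"
        trials.append(
            TrialSpec(
                cs_id=CS_PLUS if is_plus else CS_MINUS,
                stimulus=cs_plus if is_plus else cs_minus,
                duration=duration,
                iti=iti,
                shocked=paired and is_plus,
                unpaired_shock=not paired,
            )
        )
    return trials


def schedule_session(
    nt: int,
    tests: list[TestConfigSpec],
    sequence_id: int = 1,
    paired: bool = True,
    cs_plus: ArmState | None = None,
    cs_minus: ArmState | None = None,
    ltm_tests: list[TestConfigSpec] | None = None,
    ltm_delay: float = 86400.0,
    us: UsTrainSpec | None = None,
) -> SessionSchedule:
    """Compose a full session schedule from its design cell.

    For the standard Nt=4 design with one test the total comes to
    60 + 8*40 + 240 + 50 = 670 s.
    """
    trials = build_training_sequence(
        nt, sequence_id=sequence_id, paired=paired, cs_plus=cs_plus, cs_minus=cs_minus
    )
    schedule = SessionSchedule(
        trials=trials,
        tests=list(tests),
        us=us or UsTrainSpec(),
        ltm_delay=ltm_delay if ltm_tests else None,
        ltm_tests=list(ltm_tests or []),
    )
    schedule.validate()
    return schedule


@dataclass(frozen=True)
class DesignRow:
    """One block of an experimental design: crossed factors x bees."""

    factors: dict[str, tuple]
    bees_per_cell: int

    def __post_init__(self) -> None:
        if self.bees_per_cell <= 0:
            raise ValueError("bees_per_cell must be positive")
        for name, levels in self.factors.items():
            if len(levels) == 0:
                raise ValueError(f"factor {name!r} has no levels")


def enumerate_design(rows: list[DesignRow]) -> tuple[pd.DataFrame, int]:
    """Expand design rows into a cell table and the grand bee total.

    Each output row is one factor-level combination with its bee count;
    the total is the sum over all cells of all design rows.
    """
    records = []
    for block_idx, row in enumerate(rows):
        names = list(row.factors)
        for combo in itertools.product(*(row.factors[n] for n in names)):
            rec = {"block": block_idx}
            rec.update(dict(zip(names, combo)))
            rec["bees"] = row.bees_per_cell
            records.append(rec)
    table = pd.DataFrame(records)
    total = int(table["bees"].sum()) if len(table) else 0
    return table, total
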