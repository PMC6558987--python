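"""Agent-based simulator of a walking bee driven through a session.

The bee is a one-dimensional random walker on the photocell lattice of
the three arms.  It walks at an individual baseline speed (cohort mean
30 mm/s), dwells preferentially at the distal end of each arm and at
the central junction, tends to turn around under the vacuum port, and
accelerates while a shock pulse is active.  At the junction it picks
the next arm with softmax weights combining innate phototaxis (lights
calibrated to be equi-attractive at their default intensities) and the
learned aversive strength of the stimulus components present in each
arm.

Shocks are delivered as scheduled pulse trains, but a pulse is only
*received* when the bee happens to bridge adjacent grid wires, which is
modeled as an independent Bernoulli event per pulse (default contact
probability 0.344, so a full 20-pulse train yields about 7 received
shocks); each received shock carries a current drawn from a truncated
normal (mean 1.38 uA, sd 0.67 uA).

Learning is a deliberately minimal, clearly synthetic rule: each
received shock adds ``learning_rate`` to the aversive strength of every
CS component active at that time (color and odor independently for
bimodal compounds); unpaired shocks, arriving in the dark, train
nothing; a per-day retention factor scales strengths before a 24 h
test battery.  The rule is chosen as the simplest one consistent with
graded acquisition over trials, independent learning of compound
components, absence of safety learning, and weaker day-old memory
after minimal training — it makes no claim of neural realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .apparatus import (
    ARMS,
    CALIBRATED_INTENSITY,
    DARK,
    DEFAULT_GEOMETRY,
    ArmGeometry,
    ArmState,
    components_of,
    environment_of,
)
from .eventlog import EventRecord
from .protocol import SessionSchedule, TestConfigSpec, assign_test_configuration

__all__ = [
    "BeeParams",
    "SEASON_PRESETS",
    "LearningState",
    "BeeState",
    "step",
    "choose_arm",
    "contact_process",
    "expected_received_per_train",
    "update_learning",
    "simulate_bee",
    "simulate_cohort",
    "GroupSpec",
    "symmetric_groups",
]

#: Season presets shift the cohort walking-speed distribution: summer
#: foragers walk a little faster than winter bees reared indoors.
#: Means bracket the pooled 30 mm/s average.
SEASON_PRESETS = {
    "default": {"baseline_speed": 30.0, "speed_sd": 8.0},
    "summer": {"baseline_speed": 32.0, "speed_sd": 7.0},
    "winter": {"baseline_speed": 28.0, "speed_sd": 9.0},
}


def _default_phototaxis() -> dict[int, float]:
    # weight per unit intensity, normalized so each wavelength at its
    # calibrated intensity contributes attraction exactly 1.0
    return {wl: 1.0 / frac for wl, frac in CALIBRATED_INTENSITY.items()}


@dataclass
class BeeParams:
    """Tunable simulator parameters (one object per bee or cohort).

    Attributes
    ----------
    baseline_speed, speed_sd
        Mean and between-bee sd of individual walking speed (mm/s).
    shock_speed_multiplier
        Speed factor while a shock pulse is active (startle response).
    phototaxis_weight
        Attraction per unit light intensity by wavelength; defaults are
        the reciprocal calibrated intensities, so all three lights are
        equi-attractive at their defaults.
    contact_probability
        Per-pulse probability that the bee closes the grid circuit and
        actually receives a delivered shock.
    current_mean, current_sd
        Truncated-normal parameters of the received current (uA).
    learning_rate
        Aversive-strength increment per received shock, per active CS
        component.
    learnability
        Optional per-component multiplier on the learning rate (e.g.
        below 1 for ``"uv"`` to model UV resistance to aversive
        conditioning).
    decay
        Per-day retention factor applied before a delayed test battery.
    choice_noise
        Softmax temperature of the junction arm choice.
    dwell_end_prob, vacuum_turn_prob, turn_prob
        Per-step probabilities of dwelling at an arm end, turning under
        the vacuum cell, and spontaneously reversing mid-arm.
    dt
        Simulation step (s); 0.1 s resolves the 200 ms shock pulses.
    """

    baseline_speed: float = 30.0
    speed_sd: float = 8.0
    shock_speed_multiplier: float = 1.5
    phototaxis_weight: dict[int, float] = field(default_factory=_default_phototaxis)
    contact_probability: float = 0.344
    current_mean: float = 1.38
    current_sd: float = 0.67
    learning_rate: float = 0.1
    learnability: dict[str, float] = field(default_factory=dict)
    decay: float = 0.7
    choice_noise: float = 1.0
    dwell_end_prob: float = 0.55
    vacuum_turn_prob: float = 0.25
    turn_prob: float = 0.01
    dt: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_probability <= 1.0:
            raise ValueError("contact_probability must lie in [0, 1]")
        if self.baseline_speed <= 0:
            raise ValueError("baseline_speed must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.current_sd < 0:
            raise ValueError("current_sd must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def with_season(self, season: str) -> "BeeParams":
        """Copy of the parameters with a season speed preset applied."""
        preset = SEASON_PRESETS[season]
        return replace(self, **preset)


@dataclass
class LearningState:
    """Per-stimulus-component aversive strengths of one bee."""

    association: dict[str, float] = field(default_factory=dict)

    def strength(self, component: str) -> float:
        return self.association.get(component, 0.0)

    def aversion(self, arm_state: ArmState) -> float:
        """Total learned aversion of all components present in an arm."""
        return sum(self.association.get(c, 0.0) for c in components_of(arm_state))

    def decayed(self, factor: float) -> "LearningState":
        return LearningState({k: factor * v for k, v in self.association.items()})


@dataclass
class BeeState:
    """Kinematic state of the walker."""

    arm: int
    cell: int
    heading: int  # +1 outward (toward the distal end), -1 inward
    frac: float = 0.0  # fractional progress toward the next cell
    time: float = 0.0


def update_learning(
    learning: LearningState,
    components: tuple[str, ...],
    n_received: int,
    params: BeeParams,
) -> LearningState:
    """Apply the learning rule after one shock train.

    Every CS component active during the train gains
    ``learning_rate * learnability[c] * n_received``.  With no active
    CS (unpaired shocks in the dark) nothing is learned.
    """
    if n_received < 0:
        raise ValueError("n_received must be non-negative")
    assoc = dict(learning.association)
    for comp in components:
        gain = params.learning_rate * params.learnability.get(comp, 1.0) * n_received
        if gain or comp in assoc:
            assoc[comp] = assoc.get(comp, 0.0) + gain
    return LearningState(assoc)


def contact_process(
    pulses,
    params: BeeParams,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Stochastic shock receipt: (onset, current uA) per received pulse.

    Each delivered pulse is independently received with
    ``contact_probability``; received pulses carry a current drawn from
    a normal truncated at zero.
    """
    out = []
    p = params.contact_probability
    for onset, _dur in pulses:
        if rng.random() < p:
            current = -1.0
            while current < 0.0:
                current = rng.normal(params.current_mean, params.current_sd)
            out.append((onset, float(current)))
    return out


def expected_received_per_train(n_pulses: int, contact_probability: float) -> float:
    """Expected number of received shocks in one delivered train."""
    return n_pulses * contact_probability


def _attraction(arm_state: ArmState, params: BeeParams) -> float:
    if arm_state.light is None:
        return 0.0
    w = params.phototaxis_weight.get(arm_state.light.wavelength, 0.0)
    return w * arm_state.light.intensity_fraction


def arm_weight(arm_state: ArmState, params: BeeParams, learning: LearningState) -> float:
    """Unnormalized softmax weight of one arm at the junction."""
    drive = _attraction(arm_state, params) - learning.aversion(arm_state)
    return math.exp(drive / params.choice_noise)


def choose_arm(
    current_arm: int,
    arm_states: dict[int, ArmState],
    params: BeeParams,
    learning: LearningState,
    rng: np.random.Generator,
) -> int:
    """Sample the next arm at the central junction.

    All three arms (the two alternatives plus a return into the current
    arm) compete with weights ``exp((attraction - aversion)/noise)``.
    With no learned aversion and calibrated lights, lit arms are
    equally likely.
    """
    arms = sorted(arm_states)
    weights = [arm_weight(arm_states[a], params, learning) for a in arms]
    total = sum(weights)
    u = rng.random() * total
    acc = 0.0
    for a, w in zip(arms, weights):
        acc += w
        if u < acc:
            return a
    return arms[-1]


def step(
    state: BeeState,
    arm_states: dict[int, ArmState],
    params: BeeParams,
    learning: LearningState,
    rng: np.random.Generator,
    dt: float | None = None,
    speed: float | None = None,
    shock_active: bool = False,
    geometry: ArmGeometry = DEFAULT_GEOMETRY,
) -> BeeState:
    """Advance the walker by one time step (pure-kinematics reference).

    Speed accumulates fractionally in units of the photocell pitch, so
    the cell index changes by at most a few cells per step at realistic
    speeds, the bee may dwell at the arm ends, turns around under the
    vacuum with elevated probability, and is accelerated while a shock
    pulse is active.  :func:`simulate_bee` inlines this logic for
    throughput; this function is the readable single-step form of the
    same dynamics.
    """
    dt = params.dt if dt is None else dt
    v = params.baseline_speed if speed is None else speed
    if shock_active:
        v *= params.shock_speed_multiplier
    n = geometry.n_photocells
    s = BeeState(state.arm, state.cell, state.heading, state.frac, state.time + dt)
    if params.turn_prob and 1 < s.cell < n and rng.random() < params.turn_prob:
        s.heading = -s.heading
    s.frac += v * dt / geometry.pitch
    while s.frac >= 1.0:
        s.frac -= 1.0
        if s.heading > 0:
            if s.cell < n:
                s.cell += 1
                if s.cell == geometry.vacuum_cell and rng.random() < params.vacuum_turn_prob:
                    s.heading = -1
            elif rng.random() < params.dwell_end_prob:
                s.frac = 0.0
                break
            else:
                s.heading = -1
        else:
            if s.cell > 1:
                s.cell -= 1
                if s.cell == geometry.vacuum_cell and rng.random() < params.vacuum_turn_prob:
                    s.heading = 1
            elif rng.random() < params.dwell_end_prob:
                s.frac = 0.0
                break
            else:
                new_arm = choose_arm(s.arm, arm_states, params, learning, rng)
                s.arm = new_arm
                s.heading = 1
    return s


class _UniformStream:
    """Buffered uniform(0,1) draws from a Generator (fast scalar access)."""

    __slots__ = ("rng", "buf", "i", "n")

    def __init__(self, rng: np.random.Generator, n: int = 16384):
        self.rng = rng
        self.n = n
        self.buf = rng.random(n)
        self.i = 0

    def __call__(self) -> float:
        i = self.i
        if i >= self.n:
            self.buf = self.rng.random(self.n)
            i = 0
        self.i = i + 1
        return self.buf[i]


def _stimulus_records(t_ms: int, arm: str, state: ArmState, on: bool) -> list[EventRecord]:
    recs = []
    if state.light is not None:
        val = f"{state.light.wavelength}:{state.light.intensity_fraction:g}" if on else "off"
        recs.append(EventRecord(t_ms, "light", arm, val))
    if state.odor is not None:
        val = f"{state.odor.odorant}:on" if on else f"{state.odor.odorant}:off"
        recs.append(EventRecord(t_ms, "odor", arm, val))
    return recs


def simulate_bee(
    schedule: SessionSchedule,
    params: BeeParams,
    geometry: ArmGeometry = DEFAULT_GEOMETRY,
    seed: int | np.random.SeedSequence = 0,
    start_arm: int | None = None,
) -> list[EventRecord]:
    """Run one bee through a session and return its event log.

    The log is a pure function of (schedule, params, geometry, seed):
    the same inputs produce byte-identical logs.  During training
    phases stimuli fill the whole maze; at each test onset the per-arm
    assignment is derived from the bee's current arm and the test's
    side-alternation state.
    """
    rng = np.random.default_rng(seed)
    uni = _UniformStream(rng)
    dt = params.dt
    dt_ms = int(round(dt * 1000))
    if abs(dt_ms - dt * 1000) > 1e-9:
        raise ValueError("dt must be a whole number of milliseconds")
    pitch = geometry.pitch
    n_cells = geometry.n_photocells
    vac = geometry.vacuum_cell
    mult = params.shock_speed_multiplier
    turn_p = params.turn_prob
    dwell_p = params.dwell_end_prob
    vac_p = params.vacuum_turn_prob

    speed = max(1.0, float(rng.normal(params.baseline_speed, params.speed_sd)))
    step_gain = speed * dt / pitch
    shock_gain = step_gain * mult

    learning = LearningState()
    records: list[EventRecord] = []
    add = records.append

    arm = int(start_arm) if start_arm is not None else int(rng.integers(1, 4))
    cell = (n_cells + 1) // 2
    heading = -1
    frac = 0.0
    side_state = 0

    arm_str = {a: str(a) for a in ARMS}
    cell_str = {c: str(c) for c in range(1, n_cells + 1)}

    add(EventRecord(0, "door", arm_str[arm], "insert"))
    add(EventRecord(0, "arm_entry", arm_str[arm], "enter"))
    add(EventRecord(0, "position", arm_str[arm], cell_str[cell]))

    arm_ids = sorted(ARMS)

    for phase in schedule.expand():
        t0_ms = int(round(phase.t0 * 1000))
        t1_ms = int(round(phase.t1 * 1000))
        add(EventRecord(t0_ms, "phase", "all", phase.name))

        if phase.kind == "gap":
            # bee is held outside the apparatus; memory decays, no walk
            learning = learning.decayed(params.decay)
            continue

        # per-arm stimulus state for this phase
        stim_records_off: list[EventRecord] = []
        if phase.kind == "cs" and phase.cs is not None:
            arm_states = {a: phase.cs for a in ARMS}
            for r in _stimulus_records(t0_ms, "all", phase.cs, on=True):
                add(r)
            stim_records_off = _stimulus_records(t1_ms, "all", phase.cs, on=False)
        elif phase.kind == "test":
            assignment = assign_test_configuration(phase.test, arm, side_state)
            side_state += 1
            arm_states = assignment
            for a in arm_ids:
                st = assignment[a]
                for r in _stimulus_records(t0_ms, arm_str[a], st, on=True):
                    add(r)
                stim_records_off.extend(
                    _stimulus_records(t1_ms, arm_str[a], st, on=False)
                )
        else:
            arm_states = {a: DARK for a in ARMS}

        # junction choice weights for this phase (learning is constant
        # within a phase: updates happen at phase end)
        weights = [
            arm_weight(arm_states[a], params, learning) for a in arm_ids
        ]
        w_total = weights[0] + weights[1] + weights[2]

        # shock bookkeeping
        pulses = phase.pulses
        n_pulses = len(pulses)
        pulse_idx = 0
        n_received = 0
        active_until = -1
        if n_pulses:
            pulse_on_ms = [int(round(p[0] * 1000)) for p in pulses]
            pulse_dur_ms = int(round(pulses[0][1] * 1000))
            hit = [uni() < params.contact_probability for _ in range(n_pulses)]

        n_steps = round((t1_ms - t0_ms) / dt_ms)
        t_ms = t0_ms
        for _ in range(n_steps):
            if pulse_idx < n_pulses and pulse_on_ms[pulse_idx] <= t_ms:
                onset = pulse_on_ms[pulse_idx]
                add(EventRecord(onset, "shock_delivered", "all", "pulse"))
                if hit[pulse_idx]:
                    current = -1.0
                    while current < 0.0:
                        current = rng.normal(params.current_mean, params.current_sd)
                    add(EventRecord(onset, "shock_received", arm_str[arm], "contact"))
                    add(EventRecord(onset, "current", arm_str[arm], f"{current:.4f}"))
                    n_received += 1
                active_until = onset + pulse_dur_ms
                pulse_idx += 1
            frac += shock_gain if t_ms < active_until else step_gain
            if turn_p and 1 < cell < n_cells and uni() < turn_p:
                heading = -heading
            while frac >= 1.0:
                frac -= 1.0
                if heading > 0:
                    if cell < n_cells:
                        cell += 1
                        add(EventRecord(t_ms, "position", arm_str[arm], cell_str[cell]))
                        if cell == vac and uni() < vac_p:
                            heading = -1
                    elif uni() < dwell_p:
                        frac = 0.0
                        break
                    else:
                        heading = -1
                else:
                    if cell > 1:
                        cell -= 1
                        add(EventRecord(t_ms, "position", arm_str[arm], cell_str[cell]))
                        if cell == vac and uni() < vac_p:
                            heading = 1
                    elif uni() < dwell_p:
                        frac = 0.0
                        break
                    else:
                        u = uni() * w_total
                        if u < weights[0]:
                            new_arm = 1
                        elif u < weights[0] + weights[1]:
                            new_arm = 2
                        else:
                            new_arm = 3
                        if new_arm != arm:
                            arm = new_arm
                            add(EventRecord(t_ms, "arm_entry", arm_str[arm], "enter"))
                            add(EventRecord(t_ms, "position", arm_str[arm], cell_str[1]))
                        heading = 1
            t_ms += dt_ms

        # learning update at the end of a shocked phase
        if n_pulses and phase.cs is not None:
            learning = update_learning(
                learning, components_of(phase.cs), n_received, params
            )
            weights = None  # phase is over anyway
        for r in stim_records_off:
            add(r)

    end_ms = int(round(schedule.expand()[-1].t1 * 1000))
    add(EventRecord(end_ms, "door", arm_str[arm], "remove"))
    return records


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: a design cell ready for simulation."""

    name: str
    cs_plus: ArmState
    cs_minus: ArmState
    n_bees: int
    nt: int = 4
    paired: bool = True
    tests: tuple[TestConfigSpec, ...] = ()
    ltm_tests: tuple[TestConfigSpec, ...] = ()
    ltm_delay: float = 86400.0
    season: str = "default"
    pool: str | None = None  # symmetric-pooling label

    @property
    def cs_plus_env(self) -> str:
        return environment_of(self.cs_plus)

    @property
    def cs_minus_env(self) -> str:
        return environment_of(self.cs_minus)


def _mirror_tests(
    tests: tuple[TestConfigSpec, ...], stim_a: ArmState, stim_b: ArmState
) -> tuple[TestConfigSpec, ...]:
    """Swap the two training stimuli inside each test configuration."""
    swap = {stim_a: stim_b, stim_b: stim_a}

    def flip(test: TestConfigSpec) -> TestConfigSpec:
        stimuli = tuple(
            (role, swap.get(stim, stim)) for role, stim in test.stimuli
        )
        return replace(test, stimuli=stimuli)

    return tuple(flip(t) for t in tests)


def symmetric_groups(
    name: str,
    stim_a: ArmState,
    stim_b: ArmState,
    n_bees_per_cell: int,
    **kwargs,
) -> list[GroupSpec]:
    """Build the two mirrored training cells of a symmetric design.

    Half the bees are trained with ``stim_a`` as CS+ and ``stim_b`` as
    CS-, the other half with the roles reversed (the test
    configurations are mirrored accordingly), so innate preferences
    cancel when the cells are pooled by role.
    """
    mirror_kwargs = dict(kwargs)
    for key in ("tests", "ltm_tests"):
        if key in mirror_kwargs and mirror_kwargs[key]:
            mirror_kwargs[key] = _mirror_tests(
                tuple(mirror_kwargs[key]), stim_a, stim_b
            )
    return [
        GroupSpec(
            name=f"{name}-T1",
            cs_plus=stim_a,
            cs_minus=stim_b,
            n_bees=n_bees_per_cell,
            pool=name,
            **kwargs,
        ),
        GroupSpec(
            name=f"{name}-T2",
            cs_plus=stim_b,
            cs_minus=stim_a,
            n_bees=n_bees_per_cell,
            pool=name,
            **mirror_kwargs,
        ),
    ]


def _group_schedule(group: GroupSpec, sequence_id: int) -> SessionSchedule:
    from .protocol import schedule_session

    return schedule_session(
        group.nt,
        list(group.tests),
        sequence_id=sequence_id,
        paired=group.paired,
        cs_plus=group.cs_plus,
        cs_minus=group.cs_minus,
        ltm_tests=list(group.ltm_tests) or None,
        ltm_delay=group.ltm_delay,
    )


def simulate_cohort(
    groups: list[GroupSpec],
    params: BeeParams | None = None,
    master_seed: int | np.random.SeedSequence = 0,
) -> tuple[dict[str, list[EventRecord]], "pd.DataFrame"]:
    """Simulate every bee of every group; returns (logs, manifest).

    Per-bee RNG substreams are spawned from the master seed, so the
    whole cohort is a pure function of (groups, params, master_seed).
    Within each group, bees alternate between the two pseudo-random
    training sequences so that half run each.
    """
    import pandas as pd

    params = params or BeeParams()
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    logs: dict[str, list[EventRecord]] = {}
    rows = []
    total = sum(g.n_bees for g in groups)
    children = ss.spawn(total) if total else []
    k = 0
    for group in groups:
        gparams = (
            params.with_season(group.season) if group.season != "default" else params
        )
        for b in range(group.n_bees):
            bee_id = f"{group.name}-b{b + 1:03d}"
            sequence_id = 1 + (b % 2)
            schedule = _group_schedule(group, sequence_id)
            child = children[k]
            logs[bee_id] = simulate_bee(schedule, gparams, seed=child)
            rows.append(
                {
                    "bee": bee_id,
                    "group": group.name,
                    "pool": group.pool or group.name,
                    "cs_plus_env": group.cs_plus_env,
                    "cs_minus_env": group.cs_minus_env,
                    "nt": group.nt,
                    "paired": group.paired,
                    "season": group.season,
                    "sequence": sequence_id,
                    "seed_entropy": str(child.entropy),
                    "spawn_key": str(child.spawn_key),
                }
            )
            k += 1
    manifest = pd.DataFrame(rows)
    return logs, manifest
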