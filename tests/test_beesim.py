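import numpy as np
import pytest

from beemaze.apparatus import DARK, DEFAULT_GEOMETRY, position_to_mm
from beemaze.beesim import (
    BeeParams,
    BeeState,
    GroupSpec,
    LearningState,
    choose_arm,
    contact_process,
    simulate_bee,
    simulate_cohort,
    step,
    symmetric_groups,
    update_learning,
)
from beemaze.protocol import build_us_train, UsTrainSpec
from conftest import BLUE, GREEN, LIMONENE


def _dark_arms():
    return {1: DARK, 2: DARK, 3: DARK}


class TestStep:
    def test_total_dwell_freezes_the_bee(self):
        """With dwell probability 1 at an arm end the bee never leaves."""
        params = BeeParams(dwell_end_prob=1.0, turn_prob=0.0, vacuum_turn_prob=0.0)
        rng = np.random.default_rng(0)
        s = BeeState(arm=1, cell=26, heading=1, time=0.0)
        for _ in range(200):
            s = step(s, _dark_arms(), params, LearningState(), rng, speed=30.0)
        assert (s.arm, s.cell) == (1, 26)

    def test_distance_accumulation_matches_speed(self):
        """1000 undisturbed steps at 30 mm/s cover ~3000 mm of path."""
        params = BeeParams(
            dwell_end_prob=0.0, turn_prob=0.0, vacuum_turn_prob=0.0, choice_noise=1.0
        )
        rng = np.random.default_rng(1)
        s = BeeState(arm=1, cell=13, heading=1, time=0.0)
        dist = 0.0
        prev = position_to_mm(s.cell)
        prev_arm = s.arm
        for _ in range(1000):
            s = step(s, _dark_arms(), params, LearningState(), rng, speed=30.0)
            pos = position_to_mm(s.cell)
            if s.arm == prev_arm:
                dist += abs(pos - prev)
            prev, prev_arm = pos, s.arm
        # junction pass-throughs lose at most one pitch each
        assert dist == pytest.approx(3000.0, rel=0.05)

    def test_occupancy_peaks_at_junction_and_distal_end(self):
        """Long dark runs dwell most at cell 1 and the distal cell."""
        params = BeeParams()
        rng = np.random.default_rng(2)
        s = BeeState(arm=1, cell=13, heading=1, time=0.0)
        counts = np.zeros(DEFAULT_GEOMETRY.n_photocells + 1)
        for _ in range(60000):
            s = step(s, _dark_arms(), params, LearningState(), rng, speed=30.0)
            counts[s.cell] += 1
        interior = counts[2:-1]
        assert counts[1] > interior.max()
        assert counts[-1] > interior.max()


class TestChooseArm:
    def test_naive_bee_has_no_light_preference(self):
        """Calibrated lights are equi-attractive: ~50/50 between them."""
        arms = {1: DARK, 2: BLUE, 3: GREEN}
        params = BeeParams()
        rng = np.random.default_rng(3)
        picks = [
            choose_arm(1, arms, params, LearningState(), rng) for _ in range(4000)
        ]
        lit = [p for p in picks if p != 1]
        frac_blue = sum(1 for p in lit if p == 2) / len(lit)
        assert frac_blue == pytest.approx(0.5, abs=0.03)

    def test_strong_aversion_drives_choice_to_floor(self):
        arms = {1: DARK, 2: BLUE, 3: GREEN}
        params = BeeParams()
        learning = LearningState({"blue": 50.0})
        rng = np.random.default_rng(4)
        picks = [choose_arm(1, arms, params, learning, rng) for _ in range(2000)]
        assert picks.count(2) == 0  # weight exp(1-50) is numerically nil

    def test_cs_minus_attraction_unchanged_by_training(self):
        """No safety learning: the CS- weight is identical pre/post."""
        from beemaze.beesim import arm_weight

        naive = LearningState()
        trained = LearningState({"blue": 2.8})  # CS+ was blue
        assert arm_weight(GREEN, BeeParams(), trained) == arm_weight(
            GREEN, BeeParams(), naive
        )


class TestContactProcess:
    def test_degenerate_probabilities(self):
        pulses = build_us_train(UsTrainSpec())
        rng = np.random.default_rng(5)
        assert contact_process(pulses, BeeParams(contact_probability=0.0), rng) == []
        hits = contact_process(pulses, BeeParams(contact_probability=1.0), rng)
        assert len(hits) == 20

    def test_received_fraction_and_currents(self):
        pulses = build_us_train(UsTrainSpec())
        params = BeeParams()
        rng = np.random.default_rng(6)
        received = [contact_process(pulses, params, rng) for _ in range(500)]
        frac = sum(len(r) for r in received) / (500 * 20)
        assert frac == pytest.approx(0.344, abs=0.03)
        currents = [c for r in received for _, c in r]
        assert min(currents) >= 0.0
        assert np.mean(currents) == pytest.approx(params.current_mean, abs=0.1)


class TestUpdateLearning:
    def test_no_learning_without_rate_or_contingency(self):
        params = BeeParams(learning_rate=0.0)
        out = update_learning(LearningState(), ("blue",), 7, params)
        assert out.association == {}
        # unpaired shock: no CS component active
        out = update_learning(LearningState(), (), 7, BeeParams())
        assert out.association == {}

    def test_bimodal_components_gain_independently(self):
        params = BeeParams(learning_rate=0.1)
        out = update_learning(LearningState(), ("blue", "limonene"), 7, params)
        assert out.association["blue"] == pytest.approx(0.7)
        assert out.association["limonene"] == pytest.approx(0.7)

    def test_learnability_multiplier_scales_one_component(self):
        params = BeeParams(learning_rate=0.1, learnability={"uv": 0.25})
        out = update_learning(LearningState(), ("uv",), 4, params)
        assert out.association["uv"] == pytest.approx(0.1)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            update_learning(LearningState(), ("blue",), -1, BeeParams())


class TestSimulateBee:
    def test_same_seed_gives_identical_logs(self, nt4_schedule):
        a = simulate_bee(nt4_schedule, BeeParams(), seed=7)
        b = simulate_bee(nt4_schedule, BeeParams(), seed=7)
        assert a == b
        c = simulate_bee(nt4_schedule, BeeParams(), seed=8)
        assert c != a

    def test_us_trains_inside_cs_plus_windows(self, nt4_schedule, nt4_log):
        cs_plus_windows = [
            (p.t0, p.t1)
            for p in nt4_schedule.expand()
            if p.kind == "cs" and p.name.endswith("CS+")
        ]
        delivered = [r.t for r in nt4_log if r.channel == "shock_delivered"]
        assert len(delivered) == 4 * 20
        for t in delivered:
            assert any(w0 <= t <= w1 for w0, w1 in cs_plus_windows)
        received = [r.t for r in nt4_log if r.channel == "shock_received"]
        assert set(received) <= set(delivered)

    def test_log_covers_every_data_collection_channel(self, nt4_log):
        channels = {r.channel for r in nt4_log}
        assert {
            "position",
            "arm_entry",
            "shock_delivered",
            "shock_received",
            "current",
            "odor",
            "light",
            "phase",
            "door",
        } >= channels
        assert {"position", "arm_entry", "shock_delivered", "light", "phase"} <= channels

    def test_spontaneous_test_starts_in_dark_arm(self, nt4_schedule, nt4_log):
        """At test onset the bee's arm is the one left dark."""
        test_phase = next(p for p in nt4_schedule.expand() if p.kind == "test")
        t0_ms = int(test_phase.t0 * 1000)
        bee_arm = None
        lit_arms = set()
        for r in nt4_log:
            if r.channel == "position" and r.t_ms <= t0_ms:
                bee_arm = r.arm
            if r.channel == "light" and r.t_ms == t0_ms and r.value != "off":
                lit_arms.add(r.arm)
        assert bee_arm is not None
        assert bee_arm not in lit_arms
        assert len(lit_arms) == 2


class TestSimulateCohort:
    def test_symmetric_cells_mirror_roles(self):
        groups = symmetric_groups("odors", LIMONENE, GREEN, 3, nt=1)
        logs, manifest = simulate_cohort(groups, master_seed=1)
        assert len(logs) == 6
        t1 = manifest[manifest["group"] == "odors-T1"].iloc[0]
        t2 = manifest[manifest["group"] == "odors-T2"].iloc[0]
        assert t1["cs_plus_env"] == t2["cs_minus_env"]
        assert t1["cs_minus_env"] == t2["cs_plus_env"]

    def test_determinism_and_empty_design(self):
        groups = [
            GroupSpec(name="g", cs_plus=BLUE, cs_minus=GREEN, n_bees=2, nt=1)
        ]
        logs1, m1 = simulate_cohort(groups, master_seed=11)
        logs2, m2 = simulate_cohort(groups, master_seed=11)
        assert logs1 == logs2
        assert m1.equals(m2)
        logs0, m0 = simulate_cohort([], master_seed=11)
        assert logs0 == {} and len(m0) == 0
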