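"""End-to-end convenience: simulate a design, analyze, and report.

Ties the simulator and the analysis pipeline together the way a full
experiment runs: simulate every bee of every group, score occupancy,
apply the speed exclusion (optionally drawing replacement bees, as
excluded animals are replaced by fresh ones at the bench), pool
symmetric cells, and run the statistical battery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import analyze_cohort, cohort_stats
from .beesim import BeeParams, GroupSpec, simulate_cohort
from .eventlog import EventRecord

__all__ = ["run_experiment", "ExperimentResult"]


class ExperimentResult:
    """Bundle of everything one simulated experiment produced."""

    def __init__(self, logs, manifest, results, stats):
        self.logs: dict[str, list[EventRecord]] = logs
        self.manifest: pd.DataFrame = manifest
        self.results: pd.DataFrame = results
        self.stats: pd.DataFrame = stats

    def occupancy_summary(self) -> pd.DataFrame:
        """Mean occupancy percent by pool, test and role."""
        kept = self.results[~self.results["excluded"]]
        return (
            kept.groupby(["pool", "test", "role"])["percent"]
            .agg(["mean", "sem", "count"])
            .reset_index()
        )


def run_experiment(
    groups: list[GroupSpec],
    params: BeeParams | None = None,
    master_seed: int | np.random.SeedSequence = 0,
    control_pool: str | None = None,
    replace_excluded: bool = False,
    max_redraws: int = 3,
) -> ExperimentResult:
    """Simulate a cohort and run the full analysis pipeline.

    With ``replace_excluded`` set, bees failing the 6 mm/s test-phase
    speed criterion are replaced by newly simulated bees (up to
    ``max_redraws`` rounds) before analysis, mirroring bench practice;
    otherwise they are only flagged and dropped from statistics.
    """
    params = params or BeeParams()
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    logs, manifest = simulate_cohort(groups, params, master_seed=ss)
    results = analyze_cohort(logs, manifest)
    redraw = 0
    while replace_excluded and results["excluded"].any() and redraw < max_redraws:
        redraw += 1
        bad = results.loc[results["excluded"], "bee"].unique()
        group_of = manifest.set_index("bee")["group"].to_dict()
        seq_of = manifest.set_index("bee")["sequence"].to_dict()
        replacement_children = ss.spawn(len(bad))
        from .beesim import _group_schedule, simulate_bee

        by_name = {g.name: g for g in groups}
        for bee, child in zip(bad, replacement_children):
            group = by_name[group_of[bee]]
            gparams = (
                params.with_season(group.season)
                if group.season != "default"
                else params
            )
            schedule = _group_schedule(group, seq_of[bee])
            logs[bee] = simulate_bee(schedule, gparams, seed=child)
            manifest.loc[manifest["bee"] == bee, "seed_entropy"] = str(child.entropy)
            manifest.loc[manifest["bee"] == bee, "spawn_key"] = str(child.spawn_key)
        results = analyze_cohort(logs, manifest)
    stats = cohort_stats(results, control_pool=control_pool)
    return ExperimentResult(logs, manifest, results, stats)
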