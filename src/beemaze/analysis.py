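"""Occupancy learning scores and the cohort statistics pipeline.

The behavioral read-out of learning is place preference: for each 20 s
test, the percentage of time the bee spends in each stimulus
environment (all environments present during that test are reported,
so the percentages always stack to 100).  Bees slower than 6 mm/s
during the test phase are flagged unhealthy and excluded.  Symmetric
training cells (half the bees trained to each stimulus of a pair) are
pooled by relabeling environments with their CS+/CS- roles, and the
statistical battery compares CS+ against CS- occupancy within bees
(signed rank) and trained against unpaired-control bees per
environment (rank sum), with per-group FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apparatus import ArmGeometry, DEFAULT_GEOMETRY
from .eventlog import EventRecord
from .stats import fdr_adjust, mann_whitney_u, wilcoxon_signed_rank

__all__ = [
    "Track",
    "TestWindow",
    "SPEED_EXCLUSION_MMPS",
    "extract_tests",
    "compute_speed",
    "occupancy",
    "analyze_log",
    "analyze_cohort",
    "exclusion_filter",
    "pool_symmetric_groups",
    "attach_roles",
    "cohort_stats",
]

#: Test-phase walking-speed threshold below which a bee is excluded.
SPEED_EXCLUSION_MMPS = 6.0


@dataclass(frozen=True)
class Track:
    """Position time series of one bee: (t, arm, cell) samples."""

    t: np.ndarray
    arm: np.ndarray
    cell: np.ndarray

    @classmethod
    def from_records(cls, records: list[EventRecord]) -> "Track":
        ts, arms, cells = [], [], []
        for rec in records:
            if rec.channel == "position":
                ts.append(rec.t_ms / 1000.0)
                arms.append(int(rec.arm))
                cells.append(int(rec.value))
        t = np.asarray(ts)
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("track timestamps must be non-decreasing")
        return cls(t, np.asarray(arms, dtype=int), np.asarray(cells, dtype=int))


@dataclass(frozen=True)
class TestWindow:
    """One test phase with its reconstructed arm environments."""

    name: str  # e.g. "test:stm:1"
    t0: float
    t1: float
    arm_env: dict[int, str]  # arm id -> environment label


def _parse_light(value: str):
    if value == "off":
        return None
    wl, _, frac = value.partition(":")
    return int(wl), float(frac)


def extract_tests(records: list[EventRecord]) -> list[TestWindow]:
    """Find test windows and their per-arm environments in a log.

    Light/odor on-off events are replayed to know each arm's stimulus
    state at each test onset; ``arm="all"`` events apply to all arms.
    """
    # pass 1: test phase boundaries (a window closes at the next
    # phase marker, or at the end of the log)
    bounds: list[tuple[str, float, float]] = []
    open_test: tuple[str, float] | None = None
    t_end = records[-1].t_ms / 1000.0 if records else 0.0
    for rec in records:
        if rec.channel != "phase":
            continue
        t = rec.t_ms / 1000.0
        if open_test is not None:
            bounds.append((open_test[0], open_test[1], t))
            open_test = None
        if rec.value.startswith("test:"):
            open_test = (rec.value, t)
    if open_test is not None:
        bounds.append((open_test[0], open_test[1], t_end))

    # pass 2: replay stimulus events to snapshot each arm's environment
    # at every window start (stimuli switch on at the same timestamp as
    # the phase marker, so events at exactly t0 are included)
    from .apparatus import WAVELENGTH_COLOR

    light: dict[int, tuple | None] = {1: None, 2: None, 3: None}
    odor: dict[int, str | None] = {1: None, 2: None, 3: None}
    events = [r for r in records if r.channel in ("light", "odor")]
    idx = 0
    out: list[TestWindow] = []
    for name, t0, t1 in bounds:
        while idx < len(events) and events[idx].t_ms / 1000.0 <= t0:
            rec = events[idx]
            targets = (1, 2, 3) if rec.arm == "all" else (int(rec.arm),)
            if rec.channel == "light":
                state = _parse_light(rec.value)
                for a in targets:
                    light[a] = state
            else:
                odorant, _, flag = rec.value.partition(":")
                for a in targets:
                    odor[a] = odorant if flag == "on" else None
            idx += 1
        env = {}
        for a in (1, 2, 3):
            parts = []
            if light[a] is not None:
                parts.append(WAVELENGTH_COLOR[light[a][0]])
            if odor[a] is not None:
                parts.append(odor[a])
            env[a] = "+".join(parts) if parts else "dark"
        out.append(TestWindow(name, t0, t1, env))
    return out


def compute_speed(
    track: Track,
    window: tuple[float, float],
    geometry: ArmGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Mean walking speed over a window, in mm/s.

    Path length is the number of adjacent-photocell transitions times
    the cell pitch (arm changes through the zero-length junction add
    no distance), divided by the window duration.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty or inverted window")
    sel = (track.t >= t0) & (track.t <= t1)
    cells = track.cell[sel]
    arms = track.arm[sel]
    if cells.size < 2:
        return 0.0
    same_arm = arms[1:] == arms[:-1]
    dist = float(np.abs(np.diff(cells))[same_arm].sum()) * geometry.pitch
    return dist / (t1 - t0)


def occupancy(
    track: Track,
    window: tuple[float, float],
    arm_env: dict[int, str],
) -> dict[str, float]:
    """Percent of window time spent in each environment.

    Every environment available during the test is reported, including
    those never visited, so the values always sum to 100.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty or inverted window")
    if set(arm_env) != {1, 2, 3}:
        raise ValueError("arm_env must cover arms 1..3")
    duration = t1 - t0
    if track.t.size == 0 or track.t[0] > t1:
        raise ValueError("window outside track span")
    result = {env: 0.0 for env in arm_env.values()}
    # piecewise-constant arm occupancy between position samples
    idx = np.searchsorted(track.t, t0, side="right") - 1
    if idx < 0:
        idx = 0
    t_prev = t0
    arm_prev = int(track.arm[idx])
    j = idx + 1
    while j < track.t.size and track.t[j] < t1:
        tj = float(track.t[j])
        if tj > t_prev:
            result[arm_env[arm_prev]] += tj - t_prev
            t_prev = tj
        arm_prev = int(track.arm[j])
        j += 1
    result[arm_env[arm_prev]] += t1 - t_prev
    return {env: 100.0 * dt / duration for env, dt in result.items()}


def analyze_log(
    records: list[EventRecord],
    geometry: ArmGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Per-test occupancy and speed for one bee's log (long format).

    Columns: test, environment, percent, mean_speed, t0, t1.
    """
    track = Track.from_records(records)
    rows = []
    for w in extract_tests(records):
        occ = occupancy(track, (w.t0, w.t1), w.arm_env)
        speed = compute_speed(track, (w.t0, w.t1), geometry)
        for env, pct in occ.items():
            rows.append(
                {
                    "test": w.name,
                    "environment": env,
                    "percent": pct,
                    "mean_speed": speed,
                    "t0": w.t0,
                    "t1": w.t1,
                }
            )
    return pd.DataFrame(rows)


def exclusion_filter(
    results: pd.DataFrame,
    threshold: float = SPEED_EXCLUSION_MMPS,
    phase_prefix: str = "test:stm",
) -> pd.DataFrame:
    """Flag unhealthy/exhausted bees by test-phase walking speed.

    A bee is excluded when its mean speed over the short-term-memory
    test phase (all ``test:stm`` windows by default) is strictly below
    the threshold; a bee exactly at threshold is kept.  Adds/overwrites
    a boolean ``excluded`` column, per bee.
    """
    out = results.copy()
    stm = out[out["test"].str.startswith(phase_prefix)]
    speed_by_bee = stm.groupby("bee")["mean_speed"].mean()
    excluded = speed_by_bee < threshold
    out["excluded"] = out["bee"].map(excluded).fillna(False).astype(bool)
    return out


def _role_of(env: str, plus_parts: set[str], minus_parts: set[str]) -> str:
    if env == "dark":
        return "dark"
    parts = set(env.split("+"))
    if parts & plus_parts:
        return "CS+"
    if parts & minus_parts:
        return "CS-"
    return "other"


def attach_roles(results: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Add a ``role`` column mapping environments to CS+/CS-/dark/other.

    An environment counts as CS+ (CS-) when it contains any component
    of the group's CS+ (CS-) stimulus, so single components of bimodal
    compounds and odor-over-background-light environments resolve to
    the right role.
    """
    meta = manifest.set_index("bee")
    plus = {
        b: set(str(e).split("+")) for b, e in meta["cs_plus_env"].items()
    }
    minus = {
        b: set(str(e).split("+")) for b, e in meta["cs_minus_env"].items()
    }
    out = results.copy()
    out["role"] = [
        _role_of(env, plus[bee], minus[bee])
        for bee, env in zip(out["bee"], out["environment"])
    ]
    return out


def pool_symmetric_groups(
    results: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Pool mirrored training cells by CS role.

    The two cells of each ``pool`` must be exact role mirrors (the
    CS+ of one is the CS- of the other); environments are relabeled by
    role and the cells' bees concatenate under the pool label.
    """
    meta = manifest.drop_duplicates("group").set_index("group")
    for pool_name, block in meta.groupby("pool"):
        if len(block) == 2:
            a, b = block.iloc[0], block.iloc[1]
            if not (
                a["cs_plus_env"] == b["cs_minus_env"]
                and a["cs_minus_env"] == b["cs_plus_env"]
            ):
                raise ValueError(
                    f"groups of pool {pool_name!r} are not role mirrors"
                )
    out = attach_roles(results, manifest)
    pool_of = manifest.set_index("bee")["pool"]
    out["pool"] = out["bee"].map(pool_of)
    return out


def analyze_cohort(
    logs: dict[str, list[EventRecord]],
    manifest: pd.DataFrame,
    geometry: ArmGeometry = DEFAULT_GEOMETRY,
    exclude: bool = True,
) -> pd.DataFrame:
    """Occupancy results for a whole cohort, role-labeled and pooled."""
    frames = []
    for bee, records in logs.items():
        df = analyze_log(records, geometry)
        df.insert(0, "bee", bee)
        frames.append(df)
    results = pd.concat(frames, ignore_index=True)
    results = results.merge(
        manifest[["bee", "group", "pool", "paired", "nt"]], on="bee"
    )
    if exclude:
        results = exclusion_filter(results)
    else:
        results["excluded"] = False
    return pool_symmetric_groups(results, manifest)


def _paired_pivot(block: pd.DataFrame) -> pd.DataFrame:
    return (
        block.groupby(["bee", "role"])["percent"]
        .sum()
        .unstack(fill_value=0.0)
    )


def cohort_stats(
    pooled: pd.DataFrame,
    control_pool: str | None = None,
    fdr_family: str = "pool",
) -> pd.DataFrame:
    """The statistical battery over pooled cohort results.

    For every (pool, test): a Wilcoxon signed-rank test of CS+ against
    CS- occupancy within bees (when both roles are present), and — if
    ``control_pool`` names an unpaired-control pool — Mann-Whitney U
    tests of trained against control occupancy per environment role.
    Excluded bees are dropped first.  FDR correction is applied within
    each pool's battery by default (``fdr_family="pool"``), or across
    everything with ``fdr_family="global"``.
    """
    data = pooled[~pooled["excluded"]]
    rows = []
    control = (
        data[data["pool"] == control_pool] if control_pool is not None else None
    )
    for (pool_name, test), block in data.groupby(["pool", "test"]):
        if pool_name == control_pool:
            continue
        wide = _paired_pivot(block)
        if "CS+" in wide.columns and "CS-" in wide.columns:
            res = wilcoxon_signed_rank(wide["CS+"], wide["CS-"])
            rows.append(
                {
                    "pool": pool_name,
                    "test": test,
                    "comparison": "CS+ vs CS-",
                    "environment": "",
                    "n1": len(wide),
                    "n2": len(wide),
                    "statistic": res.statistic,
                    "z": res.z,
                    "p": res.p,
                }
            )
        if control is not None:
            ctrl_block = control[control["test"] == test]
            if len(ctrl_block):
                ctrl_wide = _paired_pivot(ctrl_block)
                for role in wide.columns:
                    if role not in ctrl_wide.columns:
                        continue
                    res = mann_whitney_u(wide[role], ctrl_wide[role])
                    rows.append(
                        {
                            "pool": pool_name,
                            "test": test,
                            "comparison": "trained vs control",
                            "environment": role,
                            "n1": len(wide),
                            "n2": len(ctrl_wide),
                            "statistic": res.statistic,
                            "z": res.z,
                            "p": res.p,
                        }
                    )
    report = pd.DataFrame(rows)
    if len(report):
        families = (
            report["pool"] if fdr_family == "pool" else np.zeros(len(report))
        )
        report["p_fdr"] = fdr_adjust(report["p"].to_numpy(), families)
    return report
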