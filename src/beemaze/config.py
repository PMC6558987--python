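"""Declarative session configuration (YAML) with named presets.

A config file describes geometry overrides, simulator parameters and
the experimental groups; the ``yapis-2019`` preset carries the
standard apparatus defaults (three 140 mm arms, 26 photocells, vacuum
above cell 9, calibrated light intensities).  Unknown keys are
rejected so typos fail loudly.

Example::

    preset: yapis-2019
    master_seed: 7
    params:
      learning_rate: 0.1
    groups:
      - name: odors-nt4
        cs_plus: {odor: limonene}
        cs_minus: {odor: linalool}
        symmetric: true
        bees: 20
        nt: 4
        season: winter
        tests:
          - {mode: spontaneous, pair: [cs_plus, cs_minus], background: dim_blue}
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .apparatus import ArmGeometry, ArmState, LightStimulus, OdorStimulus
from .beesim import BeeParams, GroupSpec, symmetric_groups
from .protocol import TestConfigSpec

__all__ = ["SessionConfig", "load_config", "parse_stimulus", "PRESETS"]

#: Named presets; "yapis-2019" is the standard apparatus calibration.
PRESETS = {
    "yapis-2019": {
        "geometry": {},  # ArmGeometry defaults are the preset values
        "params": {},  # BeeParams defaults are the preset values
    }
}

_COLOR_WAVELENGTH = {"uv": 375, "blue": 465, "green": 520}


def parse_stimulus(spec) -> ArmState:
    """Build an ArmState from a config mapping or shorthand string.

    Accepts ``{color: blue}``, ``{odor: limonene}``, a bimodal
    ``{color: green, odor: linalool, intensity: 0.44}``, or the
    shorthands ``"blue"``, ``"limonene"``, ``"dim_blue"``, ``"dark"``.
    """
    if isinstance(spec, str):
        if spec == "dark":
            return ArmState()
        if spec == "dim_blue":
            return ArmState(light=LightStimulus.dim_blue())
        if spec in _COLOR_WAVELENGTH:
            return ArmState(light=LightStimulus(_COLOR_WAVELENGTH[spec]))
        return ArmState(odor=OdorStimulus(spec))
    unknown = set(spec) - {"color", "odor", "intensity"}
    if unknown:
        raise ValueError(f"unknown stimulus keys: {sorted(unknown)}")
    light = None
    if "color" in spec:
        wl = _COLOR_WAVELENGTH.get(spec["color"])
        if wl is None:
            raise ValueError(f"unknown color {spec['color']!r}")
        light = LightStimulus(wl, spec.get("intensity"))
    odor = OdorStimulus(spec["odor"]) if "odor" in spec else None
    if light is None and odor is None:
        raise ValueError("stimulus needs a color and/or an odor")
    return ArmState(light=light, odor=odor)


def _parse_test(spec, cs_plus: ArmState, cs_minus: ArmState) -> TestConfigSpec:
    unknown = set(spec) - {"mode", "pair", "background", "duration", "rest"}
    if unknown:
        raise ValueError(f"unknown test keys: {sorted(unknown)}")
    roles = {"cs_plus": ("CS+", cs_plus), "cs_minus": ("CS-", cs_minus)}

    def resolve(ref):
        if isinstance(ref, str) and ref in roles:
            return roles[ref]
        if isinstance(ref, str) and ref == "none":
            return ("none", ArmState())
        return ("new", parse_stimulus(ref))

    pair = spec.get("pair", ["cs_plus", "cs_minus"])
    if len(pair) != 2:
        raise ValueError("test pair must list exactly two stimuli")
    background = parse_stimulus(spec.get("background", "dark"))
    return TestConfigSpec(
        mode=spec.get("mode", "spontaneous"),
        stimuli=(resolve(pair[0]), resolve(pair[1])),
        background=background,
        duration=float(spec.get("duration", 20.0)),
        rest=float(spec.get("rest", 30.0)),
    )


_GROUP_KEYS = {
    "name",
    "cs_plus",
    "cs_minus",
    "bees",
    "nt",
    "paired",
    "symmetric",
    "season",
    "tests",
    "ltm_tests",
    "ltm_delay",
}


@dataclass
class SessionConfig:
    """Validated configuration for one simulated experiment."""

    groups: list[GroupSpec]
    params: BeeParams
    geometry: ArmGeometry
    master_seed: int = 0
    control_pool: str | None = None
    replace_excluded: bool = False

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance."""
        text = repr(
            (
                [dataclasses.asdict(g) if dataclasses.is_dataclass(g) else g
                 for g in self.groups],
                dataclasses.asdict(self.params),
                dataclasses.asdict(self.geometry),
                self.master_seed,
            )
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> SessionConfig:
    """Load and validate a YAML session configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {
        "preset",
        "master_seed",
        "params",
        "geometry",
        "groups",
        "control_pool",
        "replace_excluded",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    preset_name = raw.get("preset", "yapis-2019")
    if preset_name not in PRESETS:
        raise ValueError(f"unknown preset {preset_name!r}")
    preset = PRESETS[preset_name]
    geom_kwargs = dict(preset["geometry"])
    geom_kwargs.update(raw.get("geometry") or {})
    geometry = ArmGeometry(**geom_kwargs)
    param_kwargs = dict(preset["params"])
    param_kwargs.update(raw.get("params") or {})
    params = BeeParams(**param_kwargs)
    groups: list[GroupSpec] = []
    for gspec in raw.get("groups") or []:
        unknown = set(gspec) - _GROUP_KEYS
        if unknown:
            raise ValueError(
                f"unknown group keys in {gspec.get('name', '?')!r}: {sorted(unknown)}"
            )
        cs_plus = parse_stimulus(gspec["cs_plus"])
        cs_minus = parse_stimulus(gspec["cs_minus"])
        tests = tuple(
            _parse_test(t, cs_plus, cs_minus) for t in gspec.get("tests") or []
        )
        ltm_tests = tuple(
            _parse_test(t, cs_plus, cs_minus) for t in gspec.get("ltm_tests") or []
        )
        common = dict(
            nt=int(gspec.get("nt", 4)),
            paired=bool(gspec.get("paired", True)),
            tests=tests,
            ltm_tests=ltm_tests,
            ltm_delay=float(gspec.get("ltm_delay", 86400.0)),
            season=gspec.get("season", "default"),
        )
        if gspec.get("symmetric", False):
            groups.extend(
                symmetric_groups(
                    gspec["name"], cs_plus, cs_minus, int(gspec["bees"]), **common
                )
            )
        else:
            groups.append(
                GroupSpec(
                    name=gspec["name"],
                    cs_plus=cs_plus,
                    cs_minus=cs_minus,
                    n_bees=int(gspec["bees"]),
                    **common,
                )
            )
    return SessionConfig(
        groups=groups,
        params=params,
        geometry=geometry,
        master_seed=int(raw.get("master_seed", 0)),
        control_pool=raw.get("control_pool"),
        replace_excluded=bool(raw.get("replace_excluded", False)),
    )
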