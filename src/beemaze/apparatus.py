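"""Static model of the three-arm Y-maze and the stimulus state of each arm.

The maze consists of three identical arms (140 x 20 x 5.5 mm) joined at
120 degrees.  Each arm carries an array of infrared photocells (26 by
default) that report the position of a walking bee, an electric grid on
floor and ceiling for shock delivery, monochromatic LEDs below the floor
(375 / 465 / 520 nm), and an odor port at the distal end (limonene or
linalool injected into a constant airflow that is evacuated centrally by
a vacuum above photocell 9).

Light intensities are calibrated so that naive bees find the three
wavelengths equally attractive; the calibrated fractions of maximum
intensity are 0.64 (green, 520 nm), 0.44 (blue, 465 nm) and 0.24
(UV, 375 nm).  A dim blue background used to motivate arm entry during
odor tests runs at 0.025.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ARMS",
    "WAVELENGTH_COLOR",
    "CALIBRATED_INTENSITY",
    "DIM_BLUE_INTENSITY",
    "ODORANTS",
    "ArmGeometry",
    "DEFAULT_GEOMETRY",
    "LightStimulus",
    "OdorStimulus",
    "ArmState",
    "DARK",
    "ApparatusState",
    "environment_of",
    "components_of",
    "position_to_mm",
]

#: Arm identifiers of the three-arm maze.
ARMS = (1, 2, 3)

#: Human color-space name for each supported LED wavelength (nm).
WAVELENGTH_COLOR = {375: "uv", 465: "blue", 520: "green"}

#: Calibrated intensity fraction at which each wavelength is equally
#: attractive to naive bees in a two-choice test.
CALIBRATED_INTENSITY = {520: 0.64, 465: 0.44, 375: 0.24}

#: Background blue intensity used to motivate arm entry in odor tests.
DIM_BLUE_INTENSITY = 0.025

#: Odorants deliverable through the airflow system.
ODORANTS = ("limonene", "linalool")


@dataclass(frozen=True)
class ArmGeometry:
    """Geometry of the maze arms and of the photocell array.

    Parameters
    ----------
    n_arms
        Number of arms; the maze is a Y, so this is fixed at 3.
    arm_length, arm_width, arm_height
        Inner dimensions of one arm in mm.
    n_photocells
        Number of infrared photocells per arm.  Cell 1 is the most
        central one (at the junction end), cell ``n_photocells`` the
        most distal.
    angle_between_arms
        Angle between adjacent arms in degrees (metadata only; the
        position model is one-dimensional along each arm).
    vacuum_cell
        Photocell index above which the central vacuum sits; walking
        bees often turn around there.
    """

    n_arms: int = 3
    arm_length: float = 140.0
    arm_width: float = 20.0
    arm_height: float = 5.5
    n_photocells: int = 26
    angle_between_arms: float = 120.0
    vacuum_cell: int = 9

    def __post_init__(self) -> None:
        if self.n_arms != 3:
            raise ValueError("the maze is a Y: n_arms must be 3")
        if self.n_photocells < 2:
            raise ValueError("need at least 2 photocells per arm")
        if not 1 <= self.vacuum_cell <= self.n_photocells:
            raise ValueError("vacuum_cell outside the photocell array")
        if self.arm_length <= 0:
            raise ValueError("arm_length must be positive")

    @property
    def pitch(self) -> float:
        """Distance between adjacent photocells in mm."""
        return self.arm_length / (self.n_photocells - 1)


DEFAULT_GEOMETRY = ArmGeometry()


@dataclass(frozen=True)
class LightStimulus:
    """A monochromatic LED stimulus in one arm (or the whole maze)."""

    wavelength: int
    intensity_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength not in WAVELENGTH_COLOR:
            raise ValueError(
                f"unsupported wavelength {self.wavelength}; "
                f"supported: {sorted(WAVELENGTH_COLOR)}"
            )
        if self.intensity_fraction is None:
            # default to the calibrated equi-attractive intensity
            object.__setattr__(
                self, "intensity_fraction", CALIBRATED_INTENSITY[self.wavelength]
            )
        if not 0.0 <= self.intensity_fraction <= 1.0:
            raise ValueError("intensity_fraction must lie in [0, 1]")

    @property
    def color(self) -> str:
        return WAVELENGTH_COLOR[self.wavelength]

    @classmethod
    def green(cls) -> "LightStimulus":
        return cls(520)

    @classmethod
    def blue(cls) -> "LightStimulus":
        return cls(465)

    @classmethod
    def uv(cls) -> "LightStimulus":
        return cls(375)

    @classmethod
    def dim_blue(cls) -> "LightStimulus":
        """Dim blue background used during odor tests."""
        return cls(465, DIM_BLUE_INTENSITY)


@dataclass(frozen=True)
class OdorStimulus:
    """An odorant delivered as a square pulse into an arm's airflow."""

    odorant: str

    def __post_init__(self) -> None:
        if self.odorant not in ODORANTS:
            raise ValueError(
                f"unknown odorant {self.odorant!r}; known: {ODORANTS}"
            )


@dataclass(frozen=True)
class ArmState:
    """Instantaneous stimulus configuration of one arm."""

    light: LightStimulus | None = None
    odor: OdorStimulus | None = None
    grid_active: bool = False


#: The dark, odorless, unshocked arm state.
DARK = ArmState()


@dataclass(frozen=True)
class ApparatusState:
    """Stimulus state of all three arms at one time point."""

    arms: dict[int, ArmState]
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if set(self.arms) != set(ARMS):
            raise ValueError("apparatus state needs exactly arms 1, 2, 3")
        if self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")


def components_of(arm_state: ArmState) -> tuple[str, ...]:
    """Stimulus components present in an arm, as canonical labels.

    A lit arm contributes its color name, an odorized arm its odorant
    name; a bimodal arm contributes both (light first).  A dark,
    odorless arm contributes nothing.
    """
    parts: list[str] = []
    if arm_state.light is not None:
        parts.append(arm_state.light.color)
    if arm_state.odor is not None:
        parts.append(arm_state.odor.odorant)
    return tuple(parts)


def environment_of(arm_state: ArmState) -> str:
    """Canonical environment label of an arm state.

    Returns ``"dark"``, a color name, an odorant name, or
    ``"<color>+<odorant>"`` for bimodal arms.  Labels are stable across
    sessions so occupancy tables from different runs line up.
    """
    parts = components_of(arm_state)
    return "+".join(parts) if parts else "dark"


def position_to_mm(cell_index: int, geometry: ArmGeometry = DEFAULT_GEOMETRY) -> float:
    """Distance of a photocell from the central end of its arm, in mm.

    Cell 1 (most central) maps to 0 mm and cell ``n_photocells`` to
    ``arm_length``; the mapping is linear with constant pitch.
    """
    if not 1 <= cell_index <= geometry.n_photocells:
        raise ValueError(
            f"cell_index {cell_index} outside 1..{geometry.n_photocells}"
        )
    return (cell_index - 1) * geometry.pitch
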