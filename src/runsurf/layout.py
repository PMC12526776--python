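"""Body-worn sensor layout and the named sensor combinations.

The study design places 12 triaxial inertial sensors on the body (head,
shoulders, upper arms, hands, pelvis, lower legs, feet), each reporting
3-axis acceleration (m/s^2) and 3-axis angular velocity (rad/s).  Channel
names follow ``<sensor>_<signal>_<axis>`` with axes x, y, z in that order.

Four named subsets of the layout are evaluated as classifier inputs:
``full_body`` (12 sensors), ``lower_body`` (5), ``pelvis`` (1) and
``feet`` (2), crossed with the signal type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
AXES = ("x", "y", "z")
SIGNAL_TYPES = ("acceleration", "angular_velocity")

#: Canonical sensor order (head to feet, left before right).
SENSORS = (
    "head",
    "left_shoulder",
    "right_shoulder",
    "left_upper_arm",
    "right_upper_arm",
    "left_hand",
    "right_hand",
    "pelvis",
    "left_lower_leg",
    "right_lower_leg",
    "left_foot",
    "right_foot",
)

#: How strongly surface effects act on a sensor's channels: 1 at the feet,
#: decreasing up the body chain (the feet are closest to the ground).
PROXIMITY_WEIGHT = {
    "head": 0.08,
    "left_shoulder": 0.10,
    "right_shoulder": 0.10,
    "left_upper_arm": 0.12,
    "right_upper_arm": 0.12,
    "left_hand": 0.15,
    "right_hand": 0.15,
    "pelvis": 0.30,
    "left_lower_leg": 0.60,
    "right_lower_leg": 0.60,
    "left_foot": 1.00,
    "right_foot": 1.00,
}

_COMBINATION_SENSORS = {
    "full_body": SENSORS,
    "lower_body": (
        "pelvis",
        "left_lower_leg",
        "right_lower_leg",
        "left_foot",
        "right_foot",
    ),
    "pelvis": ("pelvis",),
    "feet": ("left_foot", "right_foot"),
}

COMBINATION_NAMES = tuple(_COMBINATION_SENSORS)

#: Extra kinematic channels (degrees); the right knee drives segmentation.
KNEE_CHANNELS = ("right_knee_flexion", "left_knee_flexion")


def channel_name(sensor: str, signal_type: str, axis: str) -> str:
    return f"{sensor}_{signal_type}_{axis}"


@dataclass(frozen=True)
class SensorLayout:
    """The ordered 12-sensor body map."""

    sensors: tuple[str, ...] = SENSORS

    def channel_names(self, signal_type: str) -> list[str]:
        """All channels of one signal type, in layout order x axis order."""
        if signal_type not in SIGNAL_TYPES:
            raise ValueError(f"unknown signal type {signal_type!r}")
        return [
            channel_name(s, signal_type, a) for s in self.sensors for a in AXES
        ]

    def all_channel_names(self) -> list[str]:
        """Every synthesized channel: both signal types plus knee angles."""
        names: list[str] = []
        for sig in SIGNAL_TYPES:
            names.extend(self.channel_names(sig))
        names.extend(KNEE_CHANNELS)
        return names


@dataclass(frozen=True)
class SensorCombination:
    """A named sensor subset crossed with a signal type."""

    name: str
    signal_type: str
    sensors: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.name not in _COMBINATION_SENSORS:
            raise ValueError(
                f"unknown combination {self.name!r}; "
                f"expected one of {COMBINATION_NAMES}"
            )
        if self.signal_type not in SIGNAL_TYPES:
            raise ValueError(f"unknown signal type {self.signal_type!r}")
        if not self.sensors:
            object.__setattr__(
                self, "sensors", tuple(_COMBINATION_SENSORS[self.name])
            )

    @property
    def channel_names(self) -> list[str]:
        """Channels of this combination, canonical order (3 per sensor)."""
        ordered = [s for s in SENSORS if s in self.sensors]
        return [
            channel_name(s, self.signal_type, a) for s in ordered for a in AXES
        ]
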