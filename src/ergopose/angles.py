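"""Postural parameter angles from keypoint pairs.

Each postural parameter is the orientation of one body segment — the
line through two keypoints — measured against an image axis:

* ``shoulder_alignment``: left_shoulder to right_shoulder against the
  image horizontal, folded into [0, 90] (a symmetric deviation: it does
  not matter which shoulder droops).
* ``neck_lateral_bend``: neck to nose against the image vertical,
  folded into [0, 90].
* ``right_arm_abduction`` / ``left_arm_abduction``: shoulder to
  same-side elbow against vertical-down, range [0, 180] (a hanging arm
  is 0, a raised arm past horizontal exceeds 90).

The two-argument arctangent is implemented as an explicit piecewise
function of the coordinate differences; the angle of an undefined
zero-length segment raises, and a measurement with an absent endpoint
is carried downstream as invalid rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .skeleton import Keypoint, SkeletonFrame

__all__ = [
    "UndefinedAngleError",
    "ParameterDefinition",
    "AngleMeasurement",
    "PARAMETERS",
    "PARAMETER_NAMES",
    "atan2",
    "segment_deviation",
    "measure_frame",
]


class UndefinedAngleError(ValueError):
    """atan2(0, 0): the orientation of a zero-length segment is undefined."""


def atan2(y: float, x: float) -> float:
    """Two-argument arctangent, defined piecewise on the signs of x and y.

    Returns the angle of the vector (x, y) in radians, in (-pi, pi].
    Raises :class:`UndefinedAngleError` at the origin.
    """
    if x > 0:
        return math.atan(y / x)
    if x < 0 and y >= 0:
        return math.atan(y / x) + math.pi
    if x < 0 and y < 0:
        return math.atan(y / x) - math.pi
    if x == 0 and y > 0:
        return math.pi / 2
    if x == 0 and y < 0:
        return -math.pi / 2
    raise UndefinedAngleError("atan2(0, 0) is undefined")


@dataclass(frozen=True)
class ParameterDefinition:
    """Binding of a parameter name to its keypoint pair and reference axis."""

    name: str
    point_a: str
    point_b: str
    reference_axis: str  # "horizontal" or "vertical"
    fold_max: float  # 90 for symmetric deviations, 180 for full abduction range

    def __post_init__(self) -> None:
        if self.reference_axis not in ("horizontal", "vertical"):
            raise ValueError(f"unknown reference axis {self.reference_axis!r}")
        if self.fold_max not in (90.0, 180.0):
            raise ValueError("fold_max must be 90 or 180 degrees")


#: The four parameters measurable from a frontal webcam view.
PARAMETERS: tuple[ParameterDefinition, ...] = (
    ParameterDefinition("shoulder_alignment", "left_shoulder", "right_shoulder", "horizontal", 90.0),
    ParameterDefinition("right_arm_abduction", "right_shoulder", "right_elbow", "vertical", 180.0),
    ParameterDefinition("left_arm_abduction", "left_shoulder", "left_elbow", "vertical", 180.0),
    ParameterDefinition("neck_lateral_bend", "neck", "nose", "vertical", 90.0),
)

PARAMETER_NAMES: tuple[str, ...] = tuple(p.name for p in PARAMETERS)


@dataclass(frozen=True)
class AngleMeasurement:
    """One parameter's angle for one frame; invalid when a keypoint is missing."""

    parameter: str
    angle: float  # degrees in [0, fold_max]; NaN when invalid
    valid: bool
    frame_index: int = -1


def _fold(theta: float, fold_max: float) -> float:
    """Fold an absolute angle in [0, 180] into [0, fold_max]."""
    if theta > fold_max:
        theta = 180.0 - theta
    # guard against -0.0 and tiny negatives from floating-point folding
    return abs(theta)


def segment_deviation(a: Keypoint, b: Keypoint, axis: str, fold_max: float) -> float:
    """Angle in degrees between segment a->b and an image axis.

    With dx = b.x - a.x and dy = b.y - a.y (y downward): the horizontal
    axis gives |atan2(dy, dx)| and the vertical(-down) axis gives
    |atan2(dx, dy)|, both in degrees and folded into [0, fold_max].
    With fold_max = 90 the result is symmetric about both axis
    directions, so vertical-up and vertical-down references coincide.

    Raises :class:`UndefinedAngleError` for coincident points and
    ``ValueError`` when either keypoint is absent.
    """
    if not (a.present and b.present):
        raise ValueError("segment_deviation requires both keypoints present")
    dx = b.x - a.x
    dy = b.y - a.y
    if axis == "horizontal":
        theta = abs(math.degrees(atan2(dy, dx)))
    elif axis == "vertical":
        theta = abs(math.degrees(atan2(dx, dy)))
    else:
        raise ValueError(f"unknown reference axis {axis!r}")
    return _fold(theta, fold_max)


def measure_frame(
    frame: SkeletonFrame,
    defs: Sequence[ParameterDefinition] = PARAMETERS,
    *,
    min_confidence: float = 0.0,
) -> list[AngleMeasurement]:
    """Measure every parameter on one frame.

    Absent endpoints (or endpoints below ``min_confidence``, when that
    gate is enabled) yield an invalid measurement instead of an error;
    so do coincident endpoints.
    """
    out: list[AngleMeasurement] = []
    for d in defs:
        a = frame.get(d.point_a)
        b = frame.get(d.point_b)
        usable = a.present and b.present
        if usable and min_confidence > 0.0:
            for kp in (a, b):
                if kp.confidence is not None and kp.confidence < min_confidence:
                    usable = False
        if not usable:
            out.append(AngleMeasurement(d.name, math.nan, False, frame.frame_index))
            continue
        try:
            angle = segment_deviation(a, b, d.reference_axis, d.fold_max)
        except UndefinedAngleError:
            out.append(AngleMeasurement(d.name, math.nan, False, frame.frame_index))
            continue
        out.append(AngleMeasurement(d.name, angle, True, frame.frame_index))
    return out
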