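"""Ergonomic range-of-motion zone classification.

Each postural parameter has four zones, 0 (healthiest) to 3 (most
strain), bounded by three degree thresholds taken from the ergonomics
range-of-motion literature.  A zone table row stores the three
inclusive upper bounds (u0, u1, u2); zone 3 is unbounded above.  The
printed bands are integer (e.g. neck lateral bend 0-5 / 6-12 / 13-24 /
25+); for real-valued angles the intervals are read left-open /
right-closed on the printed upper bounds, i.e. zone 0 = [0, u0],
zone 1 = (u0, u1], zone 2 = (u1, u2], zone 3 = (u2, inf) — gap-free and
consistent with every printed integer band.

Zones 0-1 collapse to the "safe" class and 2-3 to "dangerous"; a
dangerous posture misclassified as safe is the clinically consequential
("critical") error direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .angles import AngleMeasurement

__all__ = [
    "SAFE",
    "DANGEROUS",
    "RangeTable",
    "ZoneAssignment",
    "DEFAULT_RANGE_ROWS",
    "classify_angle",
    "collapse_to_binary",
    "classify_frame",
]

SAFE = "safe"
DANGEROUS = "dangerous"

#: Zone upper bounds (u0, u1, u2) in degrees for the nine standard
#: parameters.  Only four are measurable from a frontal camera; the
#: rest are carried for users supplying angles from other instruments.
DEFAULT_RANGE_ROWS: dict[str, tuple[float, float, float]] = {
    "back_lateral_bend": (5, 10, 20),
    "back_flexion": (10, 25, 45),
    "back_extension": (5, 10, 20),
    "shoulder_alignment": (5, 10, 20),
    "arms_adduction": (5, 12, 24),
    "arms_abduction": (13, 34, 67),
    "neck_lateral_bend": (5, 12, 24),
    "neck_flexion": (9, 22, 45),
    "neck_extension": (6, 15, 30),
}

#: Measured parameter name -> range-table row.  Both arm parameters use
#: the arms-abduction row: the movement measured (upper arm away from
#: vertical, i.e. from the body midline) is abduction.
PARAMETER_ROW: dict[str, str] = {
    "shoulder_alignment": "shoulder_alignment",
    "right_arm_abduction": "arms_abduction",
    "left_arm_abduction": "arms_abduction",
    "neck_lateral_bend": "neck_lateral_bend",
}


def _row_for(table_rows: Mapping[str, tuple[float, float, float]], parameter: str):
    row_name = PARAMETER_ROW.get(parameter, parameter)
    if row_name not in table_rows:
        raise KeyError(f"parameter {parameter!r} not in range table")
    return table_rows[row_name]


@dataclass(frozen=True)
class RangeTable:
    """Zone boundary table; defaults are the standard ergonomic bands."""

    rows: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGE_ROWS)
    )

    def __post_init__(self) -> None:
        for name, (u0, u1, u2) in self.rows.items():
            if not 0 < u0 < u1 < u2:
                raise ValueError(f"range row {name!r} must satisfy 0 < u0 < u1 < u2")

    def bounds(self, parameter: str) -> tuple[float, float, float]:
        return _row_for(self.rows, parameter)

    @classmethod
    def from_file(cls, path: str | Path) -> "RangeTable":
        """Load overrides from a YAML/flat key-value file: name: [u0, u1, u2]."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        rows = dict(DEFAULT_RANGE_ROWS)
        for name, bounds in data.items():
            vals = tuple(float(v) for v in bounds)
            if len(vals) != 3:
                raise ValueError(f"range row {name!r} needs exactly three upper bounds")
            rows[str(name)] = vals  # type: ignore[assignment]
        return cls(rows=rows)


@dataclass(frozen=True)
class ZoneAssignment:
    """Zone and safe/dangerous class for one parameter on one frame."""

    parameter: str
    angle: float
    zone: int | None
    binary: str | None
    valid: bool
    frame_index: int = -1


def classify_angle(table: RangeTable, parameter: str, angle: float) -> int:
    """Map a nonnegative angle to its zone 0-3 for the given parameter."""
    if angle < 0 or not math.isfinite(angle):
        raise ValueError(f"angle must be finite and nonnegative, got {angle}")
    u0, u1, u2 = table.bounds(parameter)
    if angle <= u0:
        return 0
    if angle <= u1:
        return 1
    if angle <= u2:
        return 2
    return 3


def collapse_to_binary(zone: int) -> str:
    """Zones 0-1 are safe; zones 2-3 are dangerous."""
    if zone not in (0, 1, 2, 3):
        raise ValueError(f"zone must be in 0..3, got {zone}")
    return SAFE if zone <= 1 else DANGEROUS


def classify_frame(
    measurements: list[AngleMeasurement], table: RangeTable | None = None
) -> list[ZoneAssignment]:
    """Classify each measurement; invalid measurements pass through as invalid."""
    table = table or RangeTable()
    out = []
    for m in measurements:
        if not m.valid:
            out.append(ZoneAssignment(m.parameter, math.nan, None, None, False, m.frame_index))
            continue
        zone = classify_angle(table, m.parameter, m.angle)
        out.append(
            ZoneAssignment(m.parameter, m.angle, zone, collapse_to_binary(zone), True, m.frame_index)
        )
    return out
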