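"""Sustained-posture alerts and session summaries.

Per-frame zone assignments are noisy: a single mis-estimated frame
should never nag the worker.  The temporal policy therefore has three
time constants, all configurable:

* ``window`` — trailing majority-vote smoothing of the zone series
  (ties break toward the higher, i.e. worse, zone; invalid frames do
  not vote, and a window with no valid frame is invalid);
* ``dwell`` — how long the smoothed zone must stay at or above
  ``trigger_zone`` before an alert opens;
* ``cooldown`` — a new violation episode starting within this long of
  the previous alert's close is treated as a continuation of it.

The session report accumulates exact time in each zone per parameter,
where each frame covers the interval up to the next frame (the last
frame covers one nominal frame period).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .zones import ZoneAssignment

__all__ = [
    "AlertPolicy",
    "Alert",
    "SessionReport",
    "RECOMMENDATION_TEXT",
    "smooth_zones",
    "monitor",
]

#: Static per-parameter recommendation messages.
RECOMMENDATION_TEXT: dict[str, str] = {
    "shoulder_alignment": "Level your shoulders: one shoulder has been hanging lower than the other.",
    "right_arm_abduction": "Lower your right arm: keep the elbow close to your side.",
    "left_arm_abduction": "Lower your left arm: keep the elbow close to your side.",
    "neck_lateral_bend": "Straighten your neck: your head has been tilted sideways.",
}


@dataclass(frozen=True)
class AlertPolicy:
    """Temporal policy for raising recommendations."""

    window: float = 2.0  # s of majority smoothing
    trigger_zone: int = 2  # minimum zone counted as a violation
    dwell: float = 10.0  # s a violation must persist before alerting
    cooldown: float = 60.0  # s within which a new episode merges into the last alert

    def __post_init__(self) -> None:
        if min(self.window, self.dwell, self.cooldown) <= 0:
            raise ValueError("window, dwell and cooldown must be positive")
        if self.trigger_zone not in (1, 2, 3):
            raise ValueError("trigger_zone must be in 1..3")


@dataclass
class Alert:
    """One sustained-violation episode for one parameter."""

    parameter: str
    start: float
    end: float
    peak_zone: int
    message: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "parameter": self.parameter,
                "start": round(self.start, 6),
                "end": round(self.end, 6),
                "peak_zone": self.peak_zone,
                "message": self.message,
            }
        )


@dataclass
class SessionReport:
    """Aggregated session statistics per parameter."""

    time_in_zone: dict[str, list[float]]  # parameter -> seconds in zones 0..3
    valid_fraction: dict[str, float]  # fraction of frames with a valid assignment
    alerts: list[Alert] = field(default_factory=list)
    duration: float = 0.0

    def total_valid_time(self, parameter: str) -> float:
        return sum(self.time_in_zone[parameter])

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "time_in_zone": self.time_in_zone,
            "valid_fraction": self.valid_fraction,
            "alerts": [json.loads(a.to_json()) for a in self.alerts],
        }

    def summary_text(self) -> str:
        lines = [f"Session duration: {self.duration:.1f} s", ""]
        for param, tz in self.time_in_zone.items():
            lines.append(
                f"{param}: valid {self.valid_fraction[param] * 100:.0f}% of frames; "
                + ", ".join(f"zone {z}: {t:.1f} s" for z, t in enumerate(tz))
            )
        lines.append("")
        lines.append(f"Alerts: {len(self.alerts)}")
        for a in self.alerts:
            lines.append(
                f"  [{a.start:.1f}-{a.end:.1f} s] {a.parameter} (peak zone {a.peak_zone}): {a.message}"
            )
        return "\n".join(lines)


def _series_by_parameter(
    assignments: Sequence[tuple[float, ZoneAssignment]],
) -> dict[str, list[tuple[float, int | None]]]:
    series: dict[str, list[tuple[float, int | None]]] = {}
    for t, za in assignments:
        series.setdefault(za.parameter, []).append((t, za.zone if za.valid else None))
    return series


def smooth_zones(
    assignments: Sequence[tuple[float, ZoneAssignment]], window: float
) -> dict[str, list[tuple[float, int | None]]]:
    """Trailing majority-vote smoothing per parameter.

    ``assignments`` is a time-ordered list of (timestamp, assignment)
    pairs.  The smoothed zone at time t is the majority zone over valid
    samples in (t - window, t]; ties break toward the higher zone, and
    a window with no valid sample is None.
    """
    out: dict[str, list[tuple[float, int | None]]] = {}
    for param, points in _series_by_parameter(assignments).items():
        smoothed: list[tuple[float, int | None]] = []
        lo = 0
        for i, (t, _) in enumerate(points):
            while points[lo][0] <= t - window:
                lo += 1
            counts = [0, 0, 0, 0]
            for _, z in points[lo : i + 1]:
                if z is not None:
                    counts[z] += 1
            if sum(counts) == 0:
                smoothed.append((t, None))
            else:
                best = max(range(4), key=lambda z: (counts[z], z))
                smoothed.append((t, best))
        out[param] = smoothed
    return out


def _frame_durations(times: list[float], frame_period: float) -> list[float]:
    durs = [b - a for a, b in zip(times, times[1:])]
    durs.append(frame_period)
    return durs


def monitor(
    assignments: Sequence[tuple[float, ZoneAssignment]],
    policy: AlertPolicy | None = None,
    frame_rate: float = 30.0,
) -> tuple[list[Alert], SessionReport]:
    """Run the alert policy over a session and aggregate the report.

    An alert opens once a parameter's smoothed zone has been at or
    above ``policy.trigger_zone`` continuously for ``policy.dwell``
    seconds (the alert's start is the moment the dwell elapses); it
    closes when the smoothed zone drops below the trigger.  An episode
    whose alert would open within ``policy.cooldown`` of the previous
    alert's close extends that alert instead of raising a new one.
    """
    policy = policy or AlertPolicy()
    frame_period = 1.0 / frame_rate if frame_rate > 0 else 0.0
    smoothed = smooth_zones(assignments, policy.window)
    raw = _series_by_parameter(assignments)

    time_in_zone: dict[str, list[float]] = {}
    valid_fraction: dict[str, float] = {}
    alerts: list[Alert] = []
    duration = 0.0

    for param, points in raw.items():
        times = [t for t, _ in points]
        durs = _frame_durations(times, frame_period)
        duration = max(duration, (times[-1] + durs[-1]) - times[0]) if times else duration

        tz = [0.0, 0.0, 0.0, 0.0]
        n_valid = 0
        for (_, z), d in zip(points, durs):
            if z is not None:
                tz[z] += d
                n_valid += 1
        time_in_zone[param] = tz
        valid_fraction[param] = n_valid / len(points) if points else 0.0

        # alert state machine over the smoothed series
        param_alerts: list[Alert] = []
        violation_start: float | None = None
        open_alert: Alert | None = None
        peak = 0
        sm = smoothed[param]
        sm_durs = _frame_durations([t for t, _ in sm], frame_period)
        for (t, z), d in zip(sm, sm_durs):
            violating = z is not None and z >= policy.trigger_zone
            if violating:
                if violation_start is None:
                    violation_start = t
                    peak = z
                peak = max(peak, z)
                t_end = t + d
                if open_alert is None and t_end - violation_start >= policy.dwell:
                    open_time = violation_start + policy.dwell
                    if param_alerts and open_time - param_alerts[-1].end <= policy.cooldown:
                        open_alert = param_alerts[-1]
                        open_alert.peak_zone = max(open_alert.peak_zone, peak)
                    else:
                        open_alert = Alert(
                            parameter=param,
                            start=open_time,
                            end=open_time,
                            peak_zone=peak,
                            message=RECOMMENDATION_TEXT.get(param, f"Correct your {param}."),
                        )
                        param_alerts.append(open_alert)
                if open_alert is not None:
                    open_alert.end = t_end
                    open_alert.peak_zone = max(open_alert.peak_zone, peak)
            else:
                violation_start = None
                open_alert = None
                peak = 0
        alerts.extend(param_alerts)

    alerts.sort(key=lambda a: (a.start, a.parameter))
    report = SessionReport(
        time_in_zone=time_in_zone,
        valid_fraction=valid_fraction,
        alerts=alerts,
        duration=duration,
    )
    return alerts, report
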