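"""Skeleton data model and stream I/O.

A person in one video frame is represented by 18 named 2D keypoints
(the 17 COCO body landmarks plus a neck point), in image coordinates:
origin at the top-left corner, x growing rightward, y growing downward,
units of pixels.  Keypoints a pose estimator failed to localise are kept
as explicit slots with ``present=False`` rather than dropped, so that
downstream validity propagation is deterministic.

Two interchange formats are supported, both plain text:

* JSON-Lines — one object per frame:
  ``{"frame": int, "t": float, "kp": {"<label>": [x, y, conf] | null}}``
* CSV — columns ``frame, t`` then ``<label>_x, <label>_y, <label>_c``
  triplets for all 18 labels in topology order; empty cells mean absent.

This schema doubles as the adapter contract for any external 2D pose
estimator feeding the tool.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

__all__ = [
    "SchemaError",
    "StreamParseError",
    "KeypointTopology",
    "Keypoint",
    "SkeletonFrame",
    "KeypointStream",
    "default_topology",
    "read_stream",
    "write_stream",
]


class SchemaError(ValueError):
    """A record refers to a keypoint label not in the topology."""


class StreamParseError(ValueError):
    """A stream file is malformed; the message names the offending line."""


COCO_NECK_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "neck",
)

COCO_NECK_BONES: tuple[tuple[str, str], ...] = (
    ("nose", "left_eye"),
    ("nose", "right_eye"),
    ("left_eye", "left_ear"),
    ("right_eye", "right_ear"),
    ("nose", "neck"),
    ("neck", "left_shoulder"),
    ("neck", "right_shoulder"),
    ("left_shoulder", "left_elbow"),
    ("right_shoulder", "right_elbow"),
    ("left_elbow", "left_wrist"),
    ("right_elbow", "right_wrist"),
    ("left_shoulder", "left_hip"),
    ("right_shoulder", "right_hip"),
    ("left_hip", "right_hip"),
    ("left_hip", "left_knee"),
    ("right_hip", "right_knee"),
    ("left_knee", "left_ankle"),
    ("right_knee", "right_ankle"),
)


@dataclass(frozen=True)
class KeypointTopology:
    """Ordered keypoint label set plus bone connectivity.

    Exactly 18 unique names; bones only reference listed names and are
    used for overlays and validation, never for angle computation.
    """

    names: tuple[str, ...]
    bones: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.names) != 18:
            raise ValueError(f"topology must have exactly 18 names, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("topology names must be unique")
        name_set = set(self.names)
        for a, b in self.bones:
            if a not in name_set or b not in name_set:
                raise ValueError(f"bone endpoint ({a!r}, {b!r}) not in topology names")

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class Keypoint:
    """One 2D landmark; absent landmarks carry present=False."""

    name: str
    x: float = math.nan
    y: float = math.nan
    confidence: float | None = None
    present: bool = True

    def __post_init__(self) -> None:
        if self.present and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"present keypoint {self.name!r} has non-finite coordinates")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @classmethod
    def absent(cls, name: str) -> "Keypoint":
        return cls(name=name, present=False)


@dataclass(frozen=True)
class SkeletonFrame:
    """One timestamped skeleton: exactly one keypoint per topology name."""

    frame_index: int
    timestamp: float
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be nonnegative")
        if self.timestamp < 0:
            raise ValueError("timestamp must be nonnegative")

    def get(self, name: str) -> Keypoint:
        for kp in self.keypoints:
            if kp.name == name:
                return kp
        raise KeyError(name)


@dataclass
class KeypointStream:
    """An ordered keypoint time series from one source."""

    topology: KeypointTopology
    frames: list[SkeletonFrame] = field(default_factory=list)
    source: str = ""
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev = -1
        for fr in self.frames:
            if fr.frame_index <= prev:
                raise ValueError("frame_index must be strictly increasing")
            prev = fr.frame_index
            names = tuple(kp.name for kp in fr.keypoints)
            if names != self.topology.names:
                raise ValueError(
                    f"frame {fr.frame_index} keypoints do not match topology order"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def default_topology() -> KeypointTopology:
    """The 18-point skeleton: 17 COCO keypoints plus a neck landmark."""
    return KeypointTopology(names=COCO_NECK_NAMES, bones=COCO_NECK_BONES)


# ---------------------------------------------------------------------------
# Frame construction helpers


def frame_from_mapping(
    topology: KeypointTopology,
    frame_index: int,
    timestamp: float,
    kp_map: dict[str, tuple[float, float, float | None] | None],
    *,
    context: str = "",
) -> SkeletonFrame:
    """Build a frame from a label -> (x, y, conf)|None mapping.

    Labels missing from the mapping or mapped to None become absent
    keypoints; unknown labels raise :class:`SchemaError`.
    """
    known = set(topology.names)
    for label in kp_map:
        if label not in known:
            raise SchemaError(f"unknown keypoint label {label!r}{context}")
    kps = []
    for name in topology.names:
        entry = kp_map.get(name)
        if entry is None:
            kps.append(Keypoint.absent(name))
        else:
            x, y, conf = entry
            kps.append(Keypoint(name=name, x=float(x), y=float(y), confidence=conf))
    return SkeletonFrame(frame_index=frame_index, timestamp=timestamp, keypoints=tuple(kps))


# ---------------------------------------------------------------------------
# JSON-Lines format


def _read_jsonl(path: Path, topology: KeypointTopology) -> tuple[list[SkeletonFrame], dict]:
    frames: list[SkeletonFrame] = []
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamParseError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
            if "meta" in obj and "frame" not in obj:
                meta = obj["meta"]
                continue
            try:
                idx = int(obj["frame"])
                t = float(obj["t"])
                kp_map = obj["kp"]
            except (KeyError, TypeError, ValueError) as exc:
                raise StreamParseError(f"{path}:{lineno}: malformed frame record") from exc
            parsed: dict[str, tuple[float, float, float | None] | None] = {}
            for label, entry in kp_map.items():
                if entry is None:
                    parsed[label] = None
                else:
                    if not isinstance(entry, (list, tuple)) or len(entry) not in (2, 3):
                        raise StreamParseError(
                            f"{path}:{lineno}: keypoint {label!r} must be [x, y, conf] or null"
                        )
                    conf = float(entry[2]) if len(entry) == 3 and entry[2] is not None else None
                    parsed[label] = (float(entry[0]), float(entry[1]), conf)
            frames.append(
                frame_from_mapping(topology, idx, t, parsed, context=f" at {path}:{lineno}")
            )
    return frames, meta


def _write_jsonl(stream: KeypointStream, path: Path) -> None:
    with open(path, "w") as fh:
        meta = {"meta": {"source": stream.source, "frame_rate": stream.frame_rate}}
        fh.write(json.dumps(meta) + "\n")
        for fr in stream.frames:
            kp_obj: dict[str, list | None] = {}
            for kp in fr.keypoints:
                if not kp.present:
                    kp_obj[kp.name] = None
                elif kp.confidence is None:
                    kp_obj[kp.name] = [kp.x, kp.y]
                else:
                    kp_obj[kp.name] = [kp.x, kp.y, kp.confidence]
            fh.write(json.dumps({"frame": fr.frame_index, "t": fr.timestamp, "kp": kp_obj}) + "\n")


# ---------------------------------------------------------------------------
# CSV format


def _csv_columns(topology: KeypointTopology) -> list[str]:
    cols = ["frame", "t"]
    for name in topology.names:
        cols += [f"{name}_x", f"{name}_y", f"{name}_c"]
    return cols


def _read_csv(path: Path, topology: KeypointTopology) -> tuple[list[SkeletonFrame], dict]:
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for part in first.lstrip("#").strip().split("\t"):
            if "=" in part:
                key, val = part.split("=", 1)
                meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(path, float_precision="round_trip", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise StreamParseError(f"{path}: empty CSV stream file") from exc
    expected = _csv_columns(topology)
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise SchemaError(f"{path}: unknown columns {extra}")
    missing = [c for c in expected if c not in df.columns and not c.endswith("_c")]
    if missing:
        raise StreamParseError(f"{path}: missing required columns {missing}")
    frames = []
    for i, row in df.iterrows():
        kp_map: dict[str, tuple[float, float, float | None] | None] = {}
        for name in topology.names:
            x, y = row.get(f"{name}_x"), row.get(f"{name}_y")
            if pd.isna(x) or pd.isna(y):
                kp_map[name] = None
            else:
                c = row.get(f"{name}_c")
                kp_map[name] = (float(x), float(y), None if pd.isna(c) else float(c))
        try:
            idx, t = int(row["frame"]), float(row["t"])
        except (TypeError, ValueError) as exc:
            raise StreamParseError(f"{path}: row {i + 2}: malformed frame/t value") from exc
        frames.append(frame_from_mapping(topology, idx, t, kp_map, context=f" at {path} row {i + 2}"))
    return frames, meta


def _meta_header(stream: KeypointStream) -> str:
    return f"# source={stream.source}\tframe_rate={stream.frame_rate}\n"


def _write_csv(stream: KeypointStream, path: Path) -> None:
    cols = _csv_columns(stream.topology)
    rows = []
    for fr in stream.frames:
        row: dict[str, float | int | None] = {"frame": fr.frame_index, "t": fr.timestamp}
        for kp in fr.keypoints:
            if kp.present:
                row[f"{kp.name}_x"] = kp.x
                row[f"{kp.name}_y"] = kp.y
                row[f"{kp.name}_c"] = kp.confidence
            else:
                row[f"{kp.name}_x"] = row[f"{kp.name}_y"] = row[f"{kp.name}_c"] = None
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(_meta_header(stream))
        pd.DataFrame(rows, columns=cols).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Public I/O


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unknown stream format {fmt!r}")
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_stream(
    path: str | Path,
    format: str | None = None,
    topology: KeypointTopology | None = None,
) -> KeypointStream:
    """Read a keypoint stream from a JSON-Lines or CSV file.

    Absent keypoints are preserved as ``present=False`` slots.  The
    format is inferred from the extension when not given.
    """
    path = Path(path)
    topology = topology or default_topology()
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        frames, meta = _read_jsonl(path, topology)
    else:
        frames, meta = _read_csv(path, topology)
    return KeypointStream(
        topology=topology,
        frames=frames,
        source=str(meta.get("source", path.name)),
        frame_rate=float(meta.get("frame_rate", 30.0)),
    )


def write_stream(stream: KeypointStream, path: str | Path, format: str | None = None) -> Path:
    """Write a stream; ``read_stream(write_stream(s))`` reproduces the frames exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        _write_jsonl(stream, path)
    else:
        _write_csv(stream, path)
    return path
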