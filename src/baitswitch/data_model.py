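"""Domain types and I/O for multi-animal tracking recordings.

A recording couples three tables that automated tracking/classification
pipelines produce for a group-housed session:

* a dense per-frame *pose table* (one row per mouse per frame) holding the
  tracked body ellipse (center, orientation, semi-axes) and nose position,
  in arena-centimeter coordinates at a fixed frame rate;
* a *behavior-event table* of labeled bouts (chase, flee, walk,
  investigate, fight) with actor/recipient identities and inclusive frame
  spans;
* an :class:`ArenaSpec` describing the enclosure.

Conventions used throughout the package:

* frames are 0-based; event spans are inclusive ``[start_frame, end_frame]``
  so a bout's duration in seconds is ``(end - start + 1) / fps``;
* the arena origin is the lower-left corner of a rectangular arena, +x east
  and +y north;
* ellipse orientation ``theta_rad`` is stored in ``(-pi, pi]`` and is axial
  (undirected); the nose position is authoritative for heading direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArenaSpec",
    "MouseInfo",
    "BehaviorEvent",
    "Recording",
    "ValidationError",
    "POSE_COLUMNS",
    "EVENT_COLUMNS",
    "BEHAVIORS",
    "AGGRESSIVE_BEHAVIORS",
    "read_recording",
    "write_recording",
    "events_to_dataframe",
    "dataframe_to_events",
    "instantaneous_speed",
    "event_roles",
]

POSE_COLUMNS = [
    "frame",
    "mouse_id",
    "x_cm",
    "y_cm",
    "theta_rad",
    "a_cm",
    "b_cm",
    "nose_x_cm",
    "nose_y_cm",
]
EVENT_COLUMNS = ["behavior", "actor_id", "recipient_id", "start_frame", "end_frame"]

BEHAVIORS = frozenset({"chase", "flee", "walk", "investigate", "fight"})
#: behaviors that define the aggressor/aggressed roles of a male-male bout
AGGRESSIVE_BEHAVIORS = frozenset({"chase", "flee"})

# wall tolerance: mesh walls flex and tracked centers may sit marginally outside
ARENA_TOLERANCE_CM = 1.5


class ValidationError(ValueError):
    """A table or object violates a recording invariant."""


@dataclass
class ArenaSpec:
    """Geometry and frame rate of the recording enclosure."""

    shape: str = "rectangle"
    width_cm: float = 76.2
    height_cm: float = 76.2
    diameter_cm: float | None = None
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "circle"):
            raise ValidationError(f"unknown arena shape {self.shape!r}")
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        if self.shape == "rectangle":
            if self.width_cm <= 0 or self.height_cm <= 0:
                raise ValidationError("arena dimensions must be > 0")
        else:
            if not self.diameter_cm or self.diameter_cm <= 0:
                raise ValidationError("circular arena needs diameter_cm > 0")

    @property
    def bounds(self) -> tuple[float, float]:
        """(max_x, max_y) of the bounding box, origin at (0, 0)."""
        if self.shape == "rectangle":
            return (self.width_cm, self.height_cm)
        return (self.diameter_cm, self.diameter_cm)

    def contains(self, x, y, tol: float = ARENA_TOLERANCE_CM):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "rectangle":
            return (
                (x >= -tol)
                & (x <= self.width_cm + tol)
                & (y >= -tol)
                & (y <= self.height_cm + tol)
            )
        r = self.diameter_cm / 2.0
        return (x - r) ** 2 + (y - r) ** 2 <= (r + tol) ** 2


@dataclass(frozen=True)
class MouseInfo:
    mouse_id: str
    sex: str  # "M" or "F"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class BehaviorEvent:
    """A labeled behavior bout with an inclusive frame span.

    Role conventions for aggressive behaviors: in a *chase* the actor is the
    aggressor (chaser) and the recipient the aggressed (chased); in a *flee*
    the actor is the aggressed (fleeing) mouse and the recipient the
    aggressor it flees from.  Walks have no recipient; fights involve both
    males with no role asymmetry.
    """

    behavior: str
    actor_id: str
    recipient_id: str | None
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValidationError(f"unknown behavior {self.behavior!r}")
        if self.start_frame > self.end_frame:
            raise ValidationError(
                f"start_frame {self.start_frame} > end_frame {self.end_frame}"
            )
        if self.start_frame < 0:
            raise ValidationError("start_frame must be >= 0")
        if self.recipient_id is not None and self.actor_id == self.recipient_id:
            raise ValidationError("actor and recipient must differ")
        if self.behavior != "walk" and self.recipient_id is None:
            raise ValidationError(f"{self.behavior} requires a recipient")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, fps: float) -> float:
        return self.n_frames / fps

    def start_time(self, fps: float) -> float:
        return self.start_frame / fps

    def end_time(self, fps: float) -> float:
        """Time of the bout's trailing edge (exclusive frame boundary)."""
        return (self.end_frame + 1) / fps


def event_roles(event: BehaviorEvent) -> tuple[str, str]:
    """Return ``(aggressor_id, aggressed_id)`` for a chase or flee bout."""
    if event.behavior == "chase":
        return event.actor_id, event.recipient_id
    if event.behavior == "flee":
        return event.recipient_id, event.actor_id
    raise ValueError(f"{event.behavior} has no aggressor/aggressed roles")


@dataclass
class Recording:
    arena: ArenaSpec
    mice: list[MouseInfo]
    poses: pd.DataFrame
    events: list[BehaviorEvent]
    metadata: dict = field(default_factory=dict)

    # -- identity helpers -------------------------------------------------
    @property
    def mouse_ids(self) -> list[str]:
        return [m.mouse_id for m in self.mice]

    @property
    def males(self) -> list[str]:
        return [m.mouse_id for m in self.mice if m.sex == "M"]

    @property
    def females(self) -> list[str]:
        return [m.mouse_id for m in self.mice if m.sex == "F"]

    def sex_of(self, mouse_id: str) -> str:
        for m in self.mice:
            if m.mouse_id == mouse_id:
                return m.sex
        raise KeyError(mouse_id)

    @property
    def fps(self) -> float:
        return self.arena.fps

    @property
    def n_frames(self) -> int:
        return int(self.poses["frame"].max()) + 1 if len(self.poses) else 0

    def poses_of(self, mouse_id: str) -> pd.DataFrame:
        sub = self.poses[self.poses["mouse_id"] == mouse_id]
        return sub.sort_values("frame").reset_index(drop=True)

    # -- validation -------------------------------------------------------
    def validate(self, strict: bool = False) -> "Recording":
        """Enforce all recording invariants; return self for chaining.

        ``strict`` additionally rejects events whose actor/recipient sexes
        contradict the behavior (e.g. a chase with a female actor).
        """
        ids = self.mouse_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("mouse ids must be unique")
        missing = set(self.poses["mouse_id"].unique()) - set(ids)
        if missing:
            raise ValidationError(f"pose table references unknown mice: {sorted(missing)}")

        p = self.poses
        if list(p.columns) != POSE_COLUMNS:
            raise ValidationError(f"pose table columns must be {POSE_COLUMNS}")
        if (p["frame"] < 0).any():
            raise ValidationError("negative frame numbers in pose table")
        n_frames = self.n_frames
        # density: every mouse present at every frame, exactly once
        counts = p.groupby("mouse_id")["frame"].agg(["count", "nunique"])
        for mid in ids:
            if mid not in counts.index:
                raise ValidationError(f"mouse {mid} absent from pose table")
            c = counts.loc[mid]
            if c["count"] != n_frames or c["nunique"] != n_frames:
                got = set(p.loc[p["mouse_id"] == mid, "frame"])
                gaps = sorted(set(range(n_frames)) - got)[:10]
                raise ValidationError(
                    f"pose table not dense for mouse {mid}: first missing frames {gaps}"
                )
        if not (p["a_cm"] >= p["b_cm"]).all() or not (p["b_cm"] > 0).all():
            raise ValidationError("ellipse axes must satisfy a_cm >= b_cm > 0")
        inside = self.arena.contains(p["x_cm"].to_numpy(), p["y_cm"].to_numpy())
        if not inside.all():
            n_bad = int((~inside).sum())
            raise ValidationError(f"{n_bad} pose centers outside arena bounds")
        nose_d = np.hypot(
            p["nose_x_cm"].to_numpy() - p["x_cm"].to_numpy(),
            p["nose_y_cm"].to_numpy() - p["y_cm"].to_numpy(),
        )
        if (nose_d > 1.5 * p["a_cm"].to_numpy() + 1e-9).any():
            raise ValidationError("nose farther than 1.5 * a_cm from ellipse center")

        for ev in self.events:
            if ev.end_frame >= max(n_frames, 1):
                raise ValidationError(
                    f"event {ev.behavior}[{ev.start_frame},{ev.end_frame}] beyond "
                    f"recording length {n_frames}"
                )
            for mid in (ev.actor_id, ev.recipient_id):
                if mid is not None and mid not in ids:
                    raise ValidationError(f"event references unknown mouse {mid!r}")
            if strict and ev.behavior in ("chase", "flee", "fight", "investigate"):
                sexes = {self.sex_of(ev.actor_id), self.sex_of(ev.recipient_id)}
                if sexes != {"M"}:
                    raise ValidationError(
                        f"{ev.behavior} between {ev.actor_id}/{ev.recipient_id} "
                        "must involve two males"
                    )
        return self


# -- serialization ---------------------------------------------------------

def events_to_dataframe(events: Iterable[BehaviorEvent]) -> pd.DataFrame:
    rows = [
        {
            "behavior": e.behavior,
            "actor_id": e.actor_id,
            "recipient_id": "" if e.recipient_id is None else e.recipient_id,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def dataframe_to_events(df: pd.DataFrame) -> list[BehaviorEvent]:
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        recipient = row.recipient_id
        if recipient is None or (isinstance(recipient, float) and math.isnan(recipient)):
            recipient = None
        elif isinstance(recipient, str) and recipient == "":
            recipient = None
        try:
            events.append(
                BehaviorEvent(
                    behavior=str(row.behavior),
                    actor_id=str(row.actor_id),
                    recipient_id=None if recipient is None else str(recipient),
                    start_frame=int(row.start_frame),
                    end_frame=int(row.end_frame),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"event row {i}: {exc}") from exc
    return events


def read_recording(
    pose_path,
    event_path,
    arena: ArenaSpec,
    mice: Sequence[MouseInfo] | None = None,
    strict: bool = False,
) -> Recording:
    """Read pose and event CSVs into a validated :class:`Recording`.

    If ``mice`` is omitted, identities are inferred from the pose table and
    sexes from the id prefix (``M*`` male, ``F*`` female).
    """
    try:
        poses = pd.read_csv(pose_path, dtype={"mouse_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"malformed pose file {pose_path}: {exc}") from exc
    if list(poses.columns) != POSE_COLUMNS:
        raise ValidationError(
            f"{pose_path}: expected columns {POSE_COLUMNS}, got {list(poses.columns)}"
        )
    try:
        edf = pd.read_csv(event_path, dtype={"actor_id": str, "recipient_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"malformed event file {event_path}: {exc}") from exc
    if list(edf.columns) != EVENT_COLUMNS:
        raise ValidationError(
            f"{event_path}: expected columns {EVENT_COLUMNS}, got {list(edf.columns)}"
        )
    events = dataframe_to_events(edf)
    if mice is None:
        ids = sorted(poses["mouse_id"].unique())
        mice = [MouseInfo(i, "F" if str(i).upper().startswith("F") else "M") for i in ids]
    poses = poses.sort_values(["frame", "mouse_id"]).reset_index(drop=True)
    rec = Recording(arena=arena, mice=list(mice), poses=poses, events=events)
    return rec.validate(strict=strict)


def write_recording(rec: Recording, pose_path, event_path) -> None:
    """Write pose and event tables as CSV readable by :func:`read_recording`.

    Numeric fields keep >= 6 significant digits so a round trip is lossless
    at that precision.
    """
    rec.poses.to_csv(pose_path, index=False, float_format="%.8g")
    events_to_dataframe(rec.events).to_csv(event_path, index=False)


# -- kinematics ------------------------------------------------------------

def instantaneous_speed(x, y=None, fps: float = 30.0) -> np.ndarray:
    """Per-frame speed (cm/s) from consecutive center displacements.

    Accepts either a single-mouse pose table (with ``x_cm``/``y_cm``
    columns, sorted by frame) or two coordinate arrays.  The first frame
    has no predecessor and copies the second frame's speed.
    """
    if y is None:
        df = x
        x = df["x_cm"].to_numpy(dtype=float)
        y = df["y_cm"].to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("instantaneous speed needs at least 2 frames")
    step = np.hypot(np.diff(x), np.diff(y)) * fps
    return np.concatenate([[step[0]], step])
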