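"""Domain types shared across the dyadscope pipeline.

Coordinates are meters, angles degrees, times float seconds.  Each sensor
has its own free-running clock; the world clock is sensor A's clock after
temporal alignment, and the world frame puts the table center at the
origin with +y up.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterator

import numpy as np

__all__ = [
    "JointId",
    "TrackingState",
    "Provenance",
    "SkeletonFrame",
    "RigidTransform",
    "SyncResult",
    "SensorRecording",
    "SessionManifest",
    "PhaseSegment",
    "DyadSeries",
    "RoleSeries",
    "FeatureSeries",
    "ContactEvent",
    "Utterance",
    "AudioActivity",
    "ROLES",
]

ROLES = ("parent", "child")


class JointId(IntEnum):
    """The 10 upper-body points tracked per person."""

    head = 0
    shoulder_center = 1
    shoulder_left = 2
    shoulder_right = 3
    elbow_left = 4
    elbow_right = 5
    wrist_left = 6
    wrist_right = 7
    hand_left = 8
    hand_right = 9


N_JOINTS = len(JointId)


class TrackingState(str, Enum):
    tracked = "tracked"
    inferred = "inferred"
    missing = "missing"


class Provenance(IntEnum):
    """Which sensor a fused sample came from."""

    none = 0
    A = 1
    B = 2
    fused = 3


@dataclass
class SkeletonFrame:
    """One timestamped set of joint positions for one tracked person.

    ``joints`` is a (10, 3) array indexed by :class:`JointId`; positions of
    missing joints are NaN and their state is ``missing``.
    """

    timestamp: float
    person_slot: int
    joints: np.ndarray
    states: list[TrackingState]

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        if self.joints.shape != (N_JOINTS, 3):
            raise ValueError(f"joints must be (10, 3), got {self.joints.shape}")
        if len(self.states) != N_JOINTS:
            raise ValueError("need one tracking state per joint")
        # sensor timestamps are non-negative on disk (enforced at parse
        # time); in-memory frames may go slightly negative after clock
        # alignment, so only finiteness is required here
        if not np.isfinite(self.timestamp):
            raise ValueError(f"timestamp must be finite, got {self.timestamp}")
        for j in JointId:
            if self.states[j] != TrackingState.missing and not np.all(
                np.isfinite(self.joints[j])
            ):
                raise ValueError(f"non-finite position for non-missing joint {j.name}")

    def position(self, joint: JointId) -> np.ndarray | None:
        """Position of ``joint`` or None when missing."""
        if self.states[joint] == TrackingState.missing:
            return None
        return self.joints[joint]

    def valid_mask(self) -> np.ndarray:
        return np.array(
            [s != TrackingState.missing for s in self.states], dtype=bool
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform p -> R @ p + t (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid transforms")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or a stack (..., 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class SyncResult:
    """Clock alignment from the shared clap: offset = clap_B - clap_A."""

    clap_time_a: float
    clap_time_b: float
    offset: float
    detection_window: float = 0.010

    def __post_init__(self) -> None:
        if self.offset != self.clap_time_b - self.clap_time_a:
            raise ValueError("offset must equal clap_time_b - clap_time_a")


@dataclass
class SensorRecording:
    """Everything one sensor saved for a session, on its own clock."""

    sensor_id: str  # "A" | "B"
    skeleton_stream: list[SkeletonFrame]
    audio: np.ndarray  # int16 mono PCM
    audio_rate: int
    source_angle_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    source_angle_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    calibration_points: np.ndarray | None = None  # (N, 3) in sensor frame
    calibration_grid: tuple[int, int, float] | None = None  # rows, cols, spacing m
    image_timestamps: np.ndarray = field(default_factory=lambda: np.empty(0))
    audio_origin: float = 0.0  # sensor time of audio sample 0

    def __post_init__(self) -> None:
        if self.sensor_id not in ("A", "B"):
            raise ValueError("sensor_id must be 'A' or 'B'")
        if self.audio_rate <= 0:
            raise ValueError("audio sample rate must be > 0")
        self.audio = np.asarray(self.audio, dtype=np.int16)
        self.source_angle_times = np.asarray(self.source_angle_times, dtype=float)
        self.source_angle_deg = np.asarray(self.source_angle_deg, dtype=float)
        self.image_timestamps = np.asarray(self.image_timestamps, dtype=float)
        ts = [f.timestamp for f in self.skeleton_stream]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("skeleton timestamps must be non-decreasing")
        if self.calibration_points is not None:
            self.calibration_points = np.asarray(self.calibration_points, dtype=float)
            if len(self.calibration_points) < 6:
                raise ValueError("need at least 6 calibration points")


@dataclass
class SessionManifest:
    """Session plan: protocol phases, seat layout, participant metadata."""

    phase_plan: list[tuple[str, float]]
    seat_layout: dict[str, np.ndarray]  # role -> seat position, world frame
    table_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    participants: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.phase_plan):
            raise ValueError("phase durations must be > 0")
        self.seat_layout = {
            k: np.asarray(v, dtype=float) for k, v in self.seat_layout.items()
        }
        if set(self.seat_layout) != set(ROLES):
            raise ValueError("seat_layout must contain exactly parent and child")
        self.table_center = np.asarray(self.table_center, dtype=float)


@dataclass(frozen=True)
class PhaseSegment:
    """Half-open protocol segment [start, end) on the world clock."""

    phase_name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class RoleSeries:
    """Per-joint position series for one participant on the common clock."""

    positions: np.ndarray  # (T, 10, 3), NaN where gap
    gap: np.ndarray  # (T, 10) bool, True where undefined
    provenance: np.ndarray  # (T, 10) uint8 Provenance codes

    def joint(self, joint: JointId) -> tuple[np.ndarray, np.ndarray]:
        """(positions (T,3), gap (T,)) for one joint."""
        return self.positions[:, joint, :], self.gap[:, joint]


@dataclass
class DyadSeries:
    """Both participants' joint tracks aligned on one uniform clock."""

    clock: np.ndarray  # (T,) seconds, uniform
    rate: float  # Hz
    roles: dict[str, RoleSeries]

    def __post_init__(self) -> None:
        T = len(self.clock)
        for role, rs in self.roles.items():
            if rs.positions.shape[0] != T or rs.gap.shape[0] != T:
                raise ValueError(f"series length mismatch for role {role}")

    @property
    def n_ticks(self) -> int:
        return len(self.clock)


@dataclass
class FeatureSeries:
    """A named scalar time series with an explicit gap mask."""

    name: str
    times: np.ndarray
    values: np.ndarray
    gap: np.ndarray
    scope: str = "dyad"  # parent | child | dyad
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.gap = np.asarray(self.gap, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.gap)):
            raise ValueError("times, values, gap must share one length")

    def defined(self) -> np.ndarray:
        return self.values[~self.gap]


@dataclass(frozen=True)
class ContactEvent:
    start: float
    end: float
    min_distance: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("contact end must exceed start")


@dataclass(frozen=True)
class Utterance:
    speaker: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("utterance end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class AudioActivity:
    """Framewise voice activity with source azimuth and attribution."""

    times: np.ndarray  # frame start times, seconds
    probability: np.ndarray  # (F,) in [0, 1]
    active: np.ndarray  # (F,) bool
    azimuth: np.ndarray  # (F,) degrees, NaN when no source angle sample
    attribution: np.ndarray  # (F,) object: parent|child|unattributed|silence

    def __iter__(self) -> Iterator[tuple[float, float, bool, float, str]]:
        return iter(
            zip(self.times, self.probability, self.active, self.azimuth, self.attribution)
        )
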