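"""Spatial calibration and temporal synchronization of the two sensors.

Spatial: least-squares rigid (SVD/Kabsch) registration of chessboard
corner correspondences, with determinant correction so reflections are
never returned.  The world frame is sensor A's frame re-expressed so the
chessboard (table) center is the origin, +y up, +z along the chessboard
column direction.

Temporal: both audio tracks contain the same shared clap; the offset
between the two sensor clocks is the difference of the detected clap
times.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfiguration, InvalidPoint, NoClapFound
from .types import RigidTransform, SensorRecording, SkeletonFrame, SyncResult  # noqa: F401

__all__ = [
    "estimate_rigid_transform",
    "apply_transform",
    "detect_clap",
    "align_clocks",
    "chessboard_template",
    "world_transform_from_chessboard",
    "CalibrationResult",
    "calibrate_bundle",
]


def estimate_rigid_transform(
    points_src: np.ndarray, points_dst: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid transform mapping src points onto dst.

    Minimizes sum ||R @ src + t - dst||^2 over rotations (det +1) and
    translations; returns the transform and the residual RMS in meters.
    """
    src = np.asarray(points_src, dtype=float)
    dst = np.asarray(points_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(dst))):
        raise InvalidPoint("calibration points contain NaN/inf")
    n = len(src)
    if n < 3:
        raise DegenerateConfiguration(f"need >= 3 correspondences, got {n}")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    cs, cd = src - mu_s, dst - mu_d
    sv = np.linalg.svd(cs, compute_uv=False)
    if sv[1] <= max(1e-10, 1e-9 * sv[0]):
        raise DegenerateConfiguration("source points are collinear")
    H = cs.T @ cd
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    residual = src @ R.T + t - dst
    rmse = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return RigidTransform(R, t), rmse


def apply_transform(T: RigidTransform, frame: SkeletonFrame) -> SkeletonFrame:
    """Map every non-missing joint of a frame into the destination basis."""
    joints = frame.joints.copy()
    valid = frame.valid_mask()
    joints[valid] = T.apply(joints[valid])
    return SkeletonFrame(frame.timestamp, frame.person_slot, joints,
                         list(frame.states))


def detect_clap(
    audio: np.ndarray,
    rate: int,
    window: float = 0.010,
    baseline_span: float = 0.5,
    ratio: float = 20.0,
    abs_floor: float = 0.05,
) -> float:
    """Start time of the first loud window (the shared synchronization clap).

    RMS is computed over contiguous ``window``-second windows; the first
    window whose RMS exceeds ``max(ratio * median RMS of the first
    baseline_span seconds, abs_floor)`` (full-scale units) marks the clap.
    """
    x = np.asarray(audio, dtype=float)
    if x.size == 0:
        raise NoClapFound("empty audio")
    if np.issubdtype(np.asarray(audio).dtype, np.integer):
        x = x / 32768.0
    w = max(1, int(round(window * rate)))
    n_win = len(x) // w
    if n_win == 0:
        raise NoClapFound("audio shorter than one analysis window")
    rms = np.sqrt(np.mean(x[: n_win * w].reshape(n_win, w) ** 2, axis=1))
    n_base = max(1, min(n_win, int(round(baseline_span / window))))
    threshold = max(ratio * float(np.median(rms[:n_base])), abs_floor)
    hits = np.nonzero(rms >= threshold)[0]
    if hits.size == 0:
        raise NoClapFound(f"no window RMS reached threshold {threshold:.4g}")
    return float(hits[0]) * w / rate


def align_clocks(sync: "SyncResult", rec_b: SensorRecording) -> SensorRecording:
    """Re-express sensor B's recording on sensor A's clock.

    All of B's timestamps shift by -offset so the two claps coincide.
    Inter-sample intervals are preserved exactly.
    """
    off = sync.offset
    if not np.isfinite(off):
        raise ValueError("sync offset must be finite")
    frames = [
        SkeletonFrame(f.timestamp - off, f.person_slot, f.joints.copy(),
                      list(f.states))
        for f in rec_b.skeleton_stream
    ]
    return SensorRecording(
        sensor_id=rec_b.sensor_id,
        skeleton_stream=frames,
        audio=rec_b.audio,
        audio_rate=rec_b.audio_rate,
        source_angle_times=rec_b.source_angle_times - off,
        source_angle_deg=rec_b.source_angle_deg.copy(),
        calibration_points=rec_b.calibration_points,
        calibration_grid=rec_b.calibration_grid,
        image_timestamps=rec_b.image_timestamps - off,
        audio_origin=rec_b.audio_origin - off,
    )


def chessboard_template(rows: int, cols: int, spacing: float) -> np.ndarray:
    """Ideal world-frame corner grid: centered at the origin, lying in the
    table plane (y = 0), columns running along +z, row-major ordering."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = (c.ravel() - (cols - 1) / 2.0) * spacing
    z = (r.ravel() - (rows - 1) / 2.0) * spacing
    return np.column_stack([x, np.zeros(rows * cols), z])


def world_transform_from_chessboard(
    points_sensor: np.ndarray, grid: tuple[int, int, float]
) -> tuple[RigidTransform, float]:
    """Sensor-frame -> world-frame transform from ordered chessboard corners.

    The world frame convention (table center origin, +z chessboard column
    direction) is realized by registering the measured corners onto the
    ideal grid template.
    """
    rows, cols, spacing = grid
    template = chessboard_template(rows, cols, spacing)
    if len(points_sensor) != len(template):
        raise DegenerateConfiguration(
            f"expected {len(template)} corners for a {rows}x{cols} grid, "
            f"got {len(points_sensor)}"
        )
    return estimate_rigid_transform(points_sensor, template)


@dataclass
class CalibrationResult:
    """Everything downstream stages need to reach the world frame/clock."""

    transform_b_to_a: RigidTransform
    world_from_a: RigidTransform  # sensor A frame -> world frame
    world_from_b: RigidTransform  # sensor B frame -> world frame
    rmse_pair: float  # B->A registration residual, m
    rmse_world: float  # chessboard-template residual, m
    sync: "SyncResult"

    def sensor_pose(self, sensor_id: str) -> RigidTransform:
        """World -> sensor transform (for azimuth computations)."""
        T = self.world_from_a if sensor_id == "A" else self.world_from_b
        return T.inverse()


def calibrate_bundle(recordings: dict[str, SensorRecording]) -> CalibrationResult:
    """Full spatial + temporal calibration from a recording pair."""
    rec_a, rec_b = recordings["A"], recordings["B"]
    if rec_a.calibration_points is None or rec_b.calibration_points is None:
        raise DegenerateConfiguration("both sensors need calibration points")
    T_ba, rmse_pair = estimate_rigid_transform(
        rec_b.calibration_points, rec_a.calibration_points
    )
    if rec_a.calibration_grid is None:
        raise DegenerateConfiguration("sensor A calibration lacks grid layout")
    T_wa, rmse_world = world_transform_from_chessboard(
        rec_a.calibration_points, rec_a.calibration_grid
    )
    clap_a = detect_clap(rec_a.audio, rec_a.audio_rate) + rec_a.audio_origin
    clap_b = detect_clap(rec_b.audio, rec_b.audio_rate) + rec_b.audio_origin
    sync = SyncResult(clap_time_a=clap_a, clap_time_b=clap_b,
                      offset=clap_b - clap_a, detection_window=0.010)
    return CalibrationResult(
        transform_b_to_a=T_ba,
        world_from_a=T_wa,
        world_from_b=T_wa.compose(T_ba),
        rmse_pair=rmse_pair,
        rmse_world=rmse_world,
        sync=sync,
    )
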