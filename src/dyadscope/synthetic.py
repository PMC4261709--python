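"""Synthetic two-sensor dyad recordings with full ground truth.

Emulates the acquisition setup end to end: two sensors with an unknown
proper rigid transform between them and a clock offset, a shared clap in
both audio tracks, seated torsos at 90 degrees around a table with
mean-reverting positional jitter, attention-driven torso rotations,
scripted hand-contact events and scripted speech bursts whose source
azimuth is written into each sensor's source-angle stream.

Sensor A's clock is the world clock (offset 0); sensor B's clock runs
ahead by a random offset.  All randomness comes from one seeded
generator, so equal seeds give byte-identical bundles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import ProfileError
from .types import (
    JointId,
    N_JOINTS,
    RigidTransform,
    ROLES,
    SensorRecording,
    SessionManifest,
    SkeletonFrame,
    TrackingState,
    Utterance,
)
from .recording_io import write_bundle

__all__ = [
    "ParticipantSpec",
    "DyadProfile",
    "GroundTruth",
    "default_geometry",
    "profile_control",
    "profile_pathological",
    "generate_recording",
]

# seated anthropometry (m)
_SHOULDER_HALF = {"parent": 0.17, "child": 0.12}
_SHOULDER_HEIGHT = {"parent": 0.35, "child": 0.25}  # above table plane
_HEAD_RISE = {"parent": 0.22, "child": 0.17}

_CHESSBOARD = (4, 3, 0.1)  # rows, cols, spacing


@dataclass(frozen=True)
class ParticipantSpec:
    """Behavioral parameters for one seated participant."""

    table_distance_mean: float  # 3D shoulder-center-to-table distance, m
    jitter_sd: float = 0.03  # OU torso jitter sd, m
    jitter_tau: float = 2.0  # OU reversion time, s
    hand_jitter_sd: float = 0.03
    attention_probs: dict[str, float] = field(
        default_factory=lambda: {"table": 0.5, "partner": 0.3, "away": 0.2}
    )
    attention_dwell: float = 5.0  # mean dwell per target, s


@dataclass(frozen=True)
class DyadProfile:
    """A behavioral contrast the generator can realize."""

    name: str
    parent: ParticipantSpec
    child: ParticipantSpec
    movement_leadership: float  # expected child share of movement
    contact_count: int
    speech_plan: str  # "alternating" | "child_dominant"
    speech_burst: float = 0.8  # s
    speech_gap: float = 1.2  # s between alternating bursts
    parent_interjections: int = 2  # child_dominant: parent bursts (4 turns)

    def __post_init__(self) -> None:
        if not 0.0 <= self.movement_leadership <= 1.0:
            raise ProfileError("movement_leadership must lie in [0, 1]")
        if self.contact_count < 0:
            raise ProfileError("contact_count must be >= 0")
        for role, spec in (("parent", self.parent), ("child", self.child)):
            if spec.table_distance_mean <= _SHOULDER_HEIGHT[role]:
                raise ProfileError(
                    f"{role} table distance {spec.table_distance_mean} m not "
                    f"reachable at shoulder height {_SHOULDER_HEIGHT[role]} m"
                )


def default_geometry() -> SessionManifest:
    """Seats 90 degrees apart around the table, three-phase protocol.

    Parent at (0.6, 0, 0.6), child at (0.6, 0, -0.6): the two seat
    directions seen from the table center are orthogonal, a torso facing
    the table center shows a 45 degree shoulder orientation against z,
    and one facing the partner's seat shows 90 degrees.
    """
    return SessionManifest(
        phase_plan=[("free_play", 240.0), ("directed_game", 120.0),
                    ("parent_occupied", 120.0)],
        seat_layout={
            "parent": np.array([0.6, 0.0, 0.6]),
            "child": np.array([0.6, 0.0, -0.6]),
        },
        table_center=np.zeros(3),
        participants={
            "parent": {"role": "parent"},
            "child": {"role": "child"},
        },
    )


def profile_control() -> DyadProfile:
    """Engaged dyad: parent near the table, balanced movement, frequent
    alternating speech, 25 scripted hand contacts."""
    return DyadProfile(
        name="control",
        parent=ParticipantSpec(
            table_distance_mean=0.50,
            jitter_sd=0.03, hand_jitter_sd=0.03,
            attention_probs={"table": 0.45, "partner": 0.4, "away": 0.15},
            attention_dwell=5.0,
        ),
        child=ParticipantSpec(
            table_distance_mean=0.40,
            jitter_sd=0.03, hand_jitter_sd=0.03,
            attention_probs={"table": 0.5, "partner": 0.35, "away": 0.15},
            attention_dwell=4.0,
        ),
        movement_leadership=0.5,
        contact_count=25,
        speech_plan="alternating",
    )


def profile_pathological() -> DyadProfile:
    """Withdrawn parent: far from the table and near-static, child leads
    movement (share ~0.9), sparse parent speech (4 turns), 20 contacts."""
    return DyadProfile(
        name="pathological",
        parent=ParticipantSpec(
            table_distance_mean=0.80,
            jitter_sd=0.005, hand_jitter_sd=0.005,
            attention_probs={"table": 0.75, "partner": 0.05, "away": 0.2},
            attention_dwell=25.0,
        ),
        child=ParticipantSpec(
            table_distance_mean=0.40,
            jitter_sd=0.045, hand_jitter_sd=0.045,
            attention_probs={"table": 0.8, "partner": 0.08, "away": 0.12},
            attention_dwell=6.0,
        ),
        movement_leadership=0.9,
        contact_count=20,
        speech_plan="child_dominant",
    )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    seed: int
    profile: str
    clock: np.ndarray  # world clock ticks
    tracks: dict[str, np.ndarray]  # role -> (T, 10, 3) world frame, noiseless
    transform_b_to_a: RigidTransform
    world_from_a: RigidTransform
    world_from_b: RigidTransform
    clock_offset: float  # sensor B clock minus world clock
    clap_time: float  # world clock
    contact_events: list[tuple[float, float]]
    utterances: list[Utterance]
    phase_plan: list[tuple[str, float]]
    child_gap: tuple[float, float]  # scripted off-camera window

    def as_yaml_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "profile": self.profile,
            "rotation_b_to_a": [float(v) for v in
                                self.transform_b_to_a.rotation.ravel()],
            "translation_b_to_a": [float(v) for v in
                                   self.transform_b_to_a.translation],
            "clock_offset": float(self.clock_offset),
            "clap_time": float(self.clap_time),
            "contact_events": [[float(s), float(e)]
                               for s, e in self.contact_events],
            "utterances": [[u.speaker, float(u.start), float(u.end)]
                           for u in self.utterances],
            "child_gap": [float(self.child_gap[0]), float(self.child_gap[1])],
        }


# ---------------------------------------------------------------------------
# track synthesis helpers

def _ou_noise(rng, T: int, dt: float, sd: float, tau: float, dims: int) -> np.ndarray:
    """Mean-reverting (OU) jitter samples, stationary at N(0, sd^2)."""
    a = math.exp(-dt / tau)
    eps = rng.standard_normal((T, dims))
    x = lfilter([math.sqrt(1 - a * a)], [1.0, -a], eps, axis=0)
    return sd * x


def _attention_yaw(
    rng, clock: np.ndarray, spec: ParticipantSpec,
    seat: np.ndarray, partner_seat: np.ndarray, slew: float = math.pi,
) -> np.ndarray:
    """Slew-limited facing yaw (rad, atan2(x, z) convention) driven by an
    exponential-dwell attention schedule over table/partner/away."""
    def yaw_to(target: np.ndarray) -> float:
        d = target - seat
        return math.atan2(d[0], d[2])

    yaw_targets = {
        "table": yaw_to(np.zeros(3)),
        "partner": yaw_to(partner_seat),
        "away": yaw_to(seat * 2.0),  # outward, away from the table
    }
    names = sorted(spec.attention_probs)
    probs = np.array([spec.attention_probs[n] for n in names])
    probs = probs / probs.sum()
    t_end = clock[-1] + (clock[1] - clock[0] if len(clock) > 1 else 1.0)
    switches: list[tuple[float, float]] = []
    t = 0.0
    while t < t_end:
        name = names[rng.choice(len(names), p=probs)]
        switches.append((t, yaw_targets[name]))
        t += rng.exponential(spec.attention_dwell)
    target = np.empty(len(clock))
    times = np.array([s for s, _ in switches])
    vals = np.array([y for _, y in switches])
    idx = np.clip(np.searchsorted(times, clock, side="right") - 1, 0, None)
    target = vals[idx]
    dt = clock[1] - clock[0] if len(clock) > 1 else 1.0
    yaw = np.empty(len(clock))
    yaw[0] = target[0]
    max_step = slew * dt
    for k in range(1, len(clock)):
        err = (target[k] - yaw[k - 1] + math.pi) % (2 * math.pi) - math.pi
        yaw[k] = yaw[k - 1] + np.clip(err, -max_step, max_step)
    return yaw


def _skeleton_from_pose(
    centers: np.ndarray, yaw: np.ndarray, role: str,
    away: np.ndarray | None = None, arm_yaw: float | None = None,
) -> np.ndarray:
    """(T, 10, 3) joint tracks from shoulder-center track + facing yaw.

    Shoulders and head rotate with the attention-driven ``yaw``; the arm
    chain is anchored to ``arm_yaw`` (a fixed toward-the-table direction)
    when given, so hands stay on the table while the torso glances around.
    ``away`` is the horizontal unit vector pointing away from the partner;
    resting hands are biased along it so the cross-pair hand distances sit
    well clear of the contact threshold between scripted contacts.
    """
    T = len(centers)
    f = np.stack([np.sin(yaw), np.zeros(T), np.cos(yaw)], axis=1)  # facing
    left = np.stack([f[:, 2], np.zeros(T), -f[:, 0]], axis=1)
    half = _SHOULDER_HALF[role]
    rise = _HEAD_RISE[role]
    side_bias = 0.25 * away if away is not None else np.zeros(3)
    if arm_yaw is None:
        fa, left_a = f, left
    else:
        fa = np.array([math.sin(arm_yaw), 0.0, math.cos(arm_yaw)])
        left_a = np.array([fa[2], 0.0, -fa[0]])
    out = np.empty((T, N_JOINTS, 3))
    out[:, JointId.shoulder_center] = centers
    out[:, JointId.shoulder_left] = centers + half * left
    out[:, JointId.shoulder_right] = centers - half * left
    out[:, JointId.head] = centers + np.array([0, rise, 0]) + 0.04 * f
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        anchor = centers + sgn * half * left_a
        elbow = anchor + np.array([0, -0.16, 0]) + 0.08 * fa
        wrist = elbow + 0.12 * fa + np.array([0, -0.06, 0])
        hand = wrist + 0.05 * fa + np.array([0, -0.02, 0]) + side_bias
        out[:, JointId[f"elbow_{side}"]] = elbow
        out[:, JointId[f"wrist_{side}"]] = wrist
        out[:, JointId[f"hand_{side}"]] = hand
    return out


def _schedule_times(
    start: float, end: float, count: int, exclude: tuple[float, float],
    min_spacing: float = 1.5, max_spacing: float = 6.0,
) -> list[float]:
    """``count`` times on a regular grid in [start, end), skipping the
    exclusion window (with margin); spacing adapts to the available span."""
    if count == 0:
        return []
    excl_len = max(0.0, min(end, exclude[1] + 2.0) - max(start, exclude[0] - 2.0))
    spacing = np.clip((end - start - excl_len) / count, min_spacing, max_spacing)
    times = []
    t = start
    while t < end and len(times) < count:
        if not (exclude[0] - 2.0 <= t <= exclude[1] + 2.0):
            times.append(t)
        t += spacing
    if len(times) < count:
        raise ProfileError(
            f"duration too short to script {count} events "
            f"(placed {len(times)})"
        )
    return times


def _speech_script(
    profile: DyadProfile, duration: float, child_gap: tuple[float, float]
) -> list[Utterance]:
    """Scripted utterance list realizing the profile's turn structure."""
    first, last = 4.0, duration - 2.0
    burst = profile.speech_burst
    utts: list[Utterance] = []
    if profile.speech_plan == "alternating":
        t, k = first, 0
        while t + burst < last:
            if not (child_gap[0] - 1.0 <= t <= child_gap[1] + 1.0):
                speaker = "parent" if k % 2 == 0 else "child"
                utts.append(Utterance(speaker, t, t + burst))
                k += 1
            t += burst + profile.speech_gap
    elif profile.speech_plan == "child_dominant":
        t = first
        starts: list[float] = []
        while t + burst < last:
            if not (child_gap[0] - 1.0 <= t <= child_gap[1] + 1.0):
                starts.append(t)
            t += 4.0
        if len(starts) < profile.parent_interjections + 2:
            raise ProfileError("duration too short for child_dominant script")
        n = len(starts)
        parent_idx = {
            (k + 1) * n // (profile.parent_interjections + 1)
            for k in range(profile.parent_interjections)
        }
        for i, s in enumerate(starts):
            speaker = "parent" if i in parent_idx else "child"
            utts.append(Utterance(speaker, s, s + burst))
    else:
        raise ProfileError(f"unknown speech plan {profile.speech_plan!r}")
    return utts


def _sensor_pose(rng, target: np.ndarray, nominal_pos: np.ndarray) -> RigidTransform:
    """World->sensor transform for a sensor at ``nominal_pos`` (slightly
    perturbed) whose optical axis (+z) points at ``target``; +x is the
    sensor's left, +y roughly up."""
    pos = nominal_pos + rng.uniform(-0.05, 0.05, size=3)
    z = target - pos
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 1.0, 0.0])
    x = np.cross(up, z)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])  # rows: sensor axes in world coords
    return RigidTransform(R, -R @ pos)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def generate_recording(
    profile: DyadProfile,
    duration: float = 240.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    rate: float = 30.0,
    audio_rate: int = 16000,
    frame_drop: float = 0.05,
    offcam_drop: float = 0.15,
    noise_sd: float = 0.002,
) -> tuple[dict[str, SensorRecording], SessionManifest, GroundTruth]:
    """Synthesize a full two-sensor bundle plus ground truth.

    Returns (recordings, manifest, ground_truth); when ``out_dir`` is
    given the bundle is also written to disk (with ground_truth.yaml).
    """
    if duration <= 0:
        raise ProfileError("duration must be > 0")
    rng = np.random.default_rng(seed)
    manifest = default_geometry()
    seats = manifest.seat_layout
    dt = 1.0 / rate
    T = int(round(duration * rate))
    clock = np.arange(T) * dt

    # scripted child off-camera window (only if the session is long enough)
    if duration >= 100.0:
        gap_start = float(rng.uniform(0.35, 0.55)) * duration
        child_gap = (gap_start, gap_start + 10.0)
    else:
        child_gap = (duration + 1.0, duration + 1.0)  # disabled

    # --- true joint tracks ------------------------------------------------
    tracks: dict[str, np.ndarray] = {}
    specs = {"parent": profile.parent, "child": profile.child}
    for role in ROLES:
        spec = specs[role]
        seat = seats[role]
        other = seats["child" if role == "parent" else "parent"]
        h = _SHOULDER_HEIGHT[role]
        r_horiz = math.sqrt(spec.table_distance_mean**2 - h**2)
        u = seat[[0, 2]] / np.linalg.norm(seat[[0, 2]])
        base = np.array([u[0] * r_horiz, h, u[1] * r_horiz])
        jit = _ou_noise(rng, T, dt, spec.jitter_sd, spec.jitter_tau, 3)
        jit[:, 1] *= 0.3  # torsos barely bob vertically
        centers = base + jit
        yaw = _attention_yaw(rng, clock, spec, seat, other)
        away = seat - other
        away[1] = 0.0
        away = away / np.linalg.norm(away)
        arm_yaw = math.atan2(-seat[0], -seat[2])  # arms toward the table
        tracks[role] = _skeleton_from_pose(centers, yaw, role, away, arm_yaw)
        hand_jit = _ou_noise(rng, T, dt, spec.hand_jitter_sd, spec.jitter_tau, 6)
        tracks[role][:, JointId.hand_left] += hand_jit[:, :3]
        tracks[role][:, JointId.hand_right] += hand_jit[:, 3:]

    # --- scripted hand contacts ------------------------------------------
    contact_times = _schedule_times(
        min(10.0, duration / 6.0), duration - min(5.0, duration / 5.0),
        profile.contact_count, child_gap,
    )
    contact_point = np.array([0.45, 0.05, 0.0])  # table edge between seats
    contact_dur = 0.6
    contact_events: list[tuple[float, float]] = []
    for t0 in contact_times:
        contact_events.append((t0, t0 + contact_dur))
        w = _smoothstep((clock - t0) / 0.2) * _smoothstep(
            (t0 + contact_dur - clock) / 0.2
        )
        w3 = w[:, None]
        tracks["parent"][:, JointId.hand_right] = (
            (1 - w3) * tracks["parent"][:, JointId.hand_right]
            + w3 * (contact_point + np.array([0.01, 0, 0.01]))
        )
        tracks["child"][:, JointId.hand_left] = (
            (1 - w3) * tracks["child"][:, JointId.hand_left]
            + w3 * (contact_point - np.array([0.01, 0, 0.01]))
        )

    # --- sensor poses and clocks ------------------------------------------
    def outward(seat: np.ndarray, height: float, dist: float) -> np.ndarray:
        u = seat[[0, 2]] / np.linalg.norm(seat[[0, 2]])
        return np.array([-u[0] * dist, height, -u[1] * dist])

    # close enough that the two heads subtend a usable azimuth separation
    look = {r: seats[r] + np.array([0, _SHOULDER_HEIGHT[r], 0]) for r in ROLES}
    T_wa = _sensor_pose(rng, look["parent"], outward(seats["parent"], 0.5, 1.1))
    T_wb = _sensor_pose(rng, look["child"], outward(seats["child"], 0.5, 1.1))
    world_from_a = T_wa.inverse()
    world_from_b = T_wb.inverse()
    transform_b_to_a = T_wa.compose(world_from_b)
    offset_b = float(rng.uniform(0.2, 3.0))
    sensor_offsets = {"A": 0.0, "B": offset_b}
    sensor_world_to_local = {"A": T_wa, "B": T_wb}

    # --- speech script and audio ------------------------------------------
    clap_time = 0.8
    utterances = _speech_script(profile, duration, child_gap)

    def render_audio(offset: float) -> np.ndarray:
        n = int(math.ceil((duration + offset) * audio_rate))
        x = np.zeros(n)
        i0 = int(round((clap_time + offset) * audio_rate))
        n_clap = int(0.02 * audio_rate)
        clap_rng = np.random.default_rng(seed + 1)  # same clap in both tracks
        x[i0 : i0 + n_clap] = clap_rng.uniform(-0.95, 0.95, n_clap)
        for u in utterances:
            s = int(round((u.start + offset) * audio_rate))
            m = int(round(u.duration * audio_rate))
            burst_rng = np.random.default_rng(
                seed + 7919 + int(round(u.start * 1000))
            )
            env = np.hanning(m)
            x[s : s + m] += 0.12 * env * burst_rng.standard_normal(m)
        return np.clip(x * 32767, -32767, 32767).astype(np.int16)

    audio = {sid: render_audio(off) for sid, off in sensor_offsets.items()}

    # --- source-angle streams ---------------------------------------------
    angle_streams: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sid in ("A", "B"):
        T_ws = sensor_world_to_local[sid]
        t_list, a_list = [], []
        for u in utterances:
            ts = np.arange(u.start, u.end, 0.05)
            ticks = np.clip(np.round(ts * rate).astype(int), 0, T - 1)
            heads = tracks[u.speaker][ticks, JointId.head]
            local = T_ws.apply(heads)
            az = np.degrees(np.arctan2(local[:, 0], local[:, 2]))
            az = az + rng.normal(0.0, 1.0, len(az))
            t_list.append(ts + sensor_offsets[sid])
            a_list.append(az)
        if t_list:
            angle_streams[sid] = (np.concatenate(t_list), np.concatenate(a_list))
        else:
            angle_streams[sid] = (np.empty(0), np.empty(0))

    # --- skeleton streams with frame drops ---------------------------------
    chess_world = _chessboard_world()
    recordings: dict[str, SensorRecording] = {}
    facing = {"A": "parent", "B": "child"}
    for sid in ("A", "B"):
        T_ws = sensor_world_to_local[sid]
        off = sensor_offsets[sid]
        frames: list[tuple[float, int, np.ndarray]] = []
        for slot, role in enumerate((facing[sid], "child" if facing[sid] == "parent" else "parent")):
            drop_p = frame_drop if role == facing[sid] else offcam_drop
            keep = rng.random(T) >= drop_p
            if role == "child":
                keep &= ~((clock >= child_gap[0]) & (clock < child_gap[1]))
            local = T_ws.apply(tracks[role][keep])
            local = local + rng.normal(0.0, noise_sd, local.shape)
            for t, joints in zip(clock[keep], local):
                frames.append((t + off, slot, joints))
        frames.sort(key=lambda f: (f[0], f[1]))
        skeleton = [
            SkeletonFrame(t, slot, joints,
                          [TrackingState.tracked] * N_JOINTS)
            for t, slot, joints in frames
        ]
        chess_local = T_ws.apply(chess_world) + rng.normal(
            0.0, 0.001, chess_world.shape
        )
        recordings[sid] = SensorRecording(
            sensor_id=sid,
            skeleton_stream=skeleton,
            audio=audio[sid],
            audio_rate=audio_rate,
            source_angle_times=angle_streams[sid][0],
            source_angle_deg=angle_streams[sid][1],
            calibration_points=chess_local,
            calibration_grid=_CHESSBOARD,
            image_timestamps=clock + off,
        )

    gt = GroundTruth(
        seed=seed,
        profile=profile.name,
        clock=clock,
        tracks=tracks,
        transform_b_to_a=transform_b_to_a,
        world_from_a=world_from_a,
        world_from_b=world_from_b,
        clock_offset=offset_b,
        clap_time=clap_time,
        contact_events=contact_events,
        utterances=utterances,
        phase_plan=list(manifest.phase_plan),
        child_gap=child_gap,
    )
    if out_dir is not None:
        write_bundle(recordings, manifest, out_dir,
                     ground_truth=gt.as_yaml_dict())
    return recordings, manifest, gt


def _chessboard_world() -> np.ndarray:
    from .calibration import chessboard_template

    return chessboard_template(*_CHESSBOARD)
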