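"""Voice activity detection, speaker attribution and speech turns.

The VAD is a transparent short-time energy detector: framewise log-energy
against a percentile noise floor mapped through a logistic, with a
sustain requirement.  Attribution matches the sensor's source azimuth
against the azimuths of the participants' heads (from the fused skeleton
series) in the sensor frame.
"""
from __future__ import annotations

import numpy as np

from .errors import TooShort
from .recording_io import resample_to_clock
from .types import (
    AudioActivity,
    DyadSeries,
    JointId,
    RigidTransform,
    SensorRecording,
    Utterance,
)

__all__ = [
    "vad",
    "head_azimuth",
    "attribute_source",
    "annotate_activity",
    "sound_activity_by_participant",
    "count_speech_turns",
]

# azimuth convention: 0 deg along the sensor optical axis (+z), positive
# to the sensor's left (+x)
ATTRIBUTION_TOLERANCE = 15.0  # deg
ATTRIBUTION_MARGIN = 5.0  # deg


def frame_log_energy(
    x: np.ndarray, rate: int, frame: float, hop: float
) -> tuple[np.ndarray, np.ndarray]:
    """(frame start times, log-energy in dBFS-like units)."""
    n_frame = int(round(frame * rate))
    n_hop = int(round(hop * rate))
    if len(x) < n_frame:
        raise TooShort(f"audio has {len(x)} samples, below one {frame}s frame")
    n = 1 + (len(x) - n_frame) // n_hop
    idx = np.arange(n)[:, None] * n_hop + np.arange(n_frame)[None, :]
    frames = x[idx]
    mean_sq = np.mean(frames**2, axis=1)
    log_e = 10.0 * np.log10(mean_sq + 1e-10)
    times = np.arange(n) * n_hop / rate
    return times, log_e


def vad(
    audio: np.ndarray,
    rate: int,
    frame: float = 0.025,
    hop: float = 0.010,
    floor_percentile: float = 10.0,
    floor_min_db: float = -70.0,
    offset_db: float = 6.0,
    scale_db: float = 3.0,
    min_active: float = 0.100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Framewise voice-activity probability and sustained active flags.

    probability = logistic((logE - noise_floor - offset) / scale) with the
    noise floor at the ``floor_percentile`` of frame log-energies (but
    never below ``floor_min_db``); a frame is active when probability >=
    0.5 is sustained for at least ``min_active`` seconds.

    Returns (frame_times, probability, active).
    """
    x = np.asarray(audio, dtype=float)
    if np.issubdtype(np.asarray(audio).dtype, np.integer):
        x = x / 32768.0
    times, log_e = frame_log_energy(x, rate, frame, hop)
    floor = max(float(np.percentile(log_e, floor_percentile)), floor_min_db)
    prob = 1.0 / (1.0 + np.exp(-(log_e - floor - offset_db) / scale_db))
    raw = prob >= 0.5
    min_run = max(1, int(round(min_active / hop)))
    active = np.zeros_like(raw)
    i = 0
    n = len(raw)
    while i < n:
        if raw[i]:
            j = i
            while j < n and raw[j]:
                j += 1
            if j - i >= min_run:
                active[i:j] = True
            i = j
        else:
            i += 1
    return times, prob, active


def head_azimuth(position_world: np.ndarray, sensor_pose: RigidTransform) -> float:
    """Azimuth (deg) of a world point in the sensor frame.

    ``sensor_pose`` maps world coordinates into the sensor frame.
    """
    p = sensor_pose.apply(position_world)
    return float(np.degrees(np.arctan2(p[0], p[2])))


def attribute_source(
    azimuth: float,
    head_positions: dict[str, np.ndarray],
    sensor_pose: RigidTransform,
    tolerance: float = ATTRIBUTION_TOLERANCE,
    margin: float = ATTRIBUTION_MARGIN,
) -> str:
    """Attribute a detected sound to parent/child or 'unattributed'.

    The participant whose head azimuth (in the sensor frame) is nearest
    the source azimuth wins if the mismatch is within ``tolerance`` and
    beats the other participant by at least ``margin`` degrees.
    """
    if not np.isfinite(azimuth):
        return "unattributed"
    diffs: dict[str, float] = {}
    for role, pos in head_positions.items():
        if pos is None or not np.all(np.isfinite(pos)):
            continue
        diffs[role] = abs(azimuth - head_azimuth(pos, sensor_pose))
    if not diffs:
        return "unattributed"
    best = min(diffs, key=diffs.get)
    if diffs[best] > tolerance:
        return "unattributed"
    others = [d for r, d in diffs.items() if r != best]
    if others and min(others) - diffs[best] < margin:
        return "unattributed"
    return best


def annotate_activity(
    recording: SensorRecording,
    dyad: DyadSeries,
    sensor_pose: RigidTransform,
    azimuth_max_gap: float = 0.100,
    **vad_kwargs,
) -> AudioActivity:
    """Run VAD on a sensor's audio and attribute each active frame.

    Frame times are on the recording's clock (``audio_origin`` + frame
    offset); the source-angle stream and the fused head tracks are
    sampled nearest-in-time.
    """
    times, prob, active = vad(recording.audio, recording.audio_rate, **vad_kwargs)
    times = times + recording.audio_origin
    az, az_gap, _ = resample_to_clock(
        recording.source_angle_times, recording.source_angle_deg,
        times, azimuth_max_gap,
    )
    az[az_gap] = np.nan

    heads = {}
    for role, rs in dyad.roles.items():
        pos, gap = rs.joint(JointId.head)
        h, h_gap, _ = resample_to_clock(dyad.clock[~gap], pos[~gap], times, 0.100)
        h[h_gap] = np.nan
        heads[role] = h

    attribution = np.full(len(times), "silence", dtype=object)
    for i in range(len(times)):
        if not active[i]:
            continue
        head_at = {role: heads[role][i] for role in heads}
        attribution[i] = attribute_source(az[i], head_at, sensor_pose)
    return AudioActivity(times=times, probability=prob, active=active,
                         azimuth=az, attribution=attribution)


def sound_activity_by_participant(
    activity: AudioActivity,
    min_duration: float = 0.200,
    bridge: float = 0.150,
) -> list[Utterance]:
    """Per-speaker utterances from the attributed activity stream.

    Maximal runs of active frames with a constant speaker attribution are
    collected; runs of one speaker separated by less than ``bridge``
    seconds merge; utterances shorter than ``min_duration`` are dropped.
    """
    hop = (
        float(activity.times[1] - activity.times[0])
        if len(activity.times) > 1 else 0.010
    )
    runs: list[Utterance] = []
    cur_speaker: str | None = None
    cur_start = 0.0
    cur_end = 0.0
    for t, _, act, _, attr in activity:
        speaker = attr if act and attr in ("parent", "child") else None
        if speaker == cur_speaker and speaker is not None and t <= cur_end + hop * 1.5:
            cur_end = t + hop
            continue
        if cur_speaker is not None:
            runs.append(Utterance(cur_speaker, cur_start, cur_end))
        cur_speaker = speaker
        cur_start, cur_end = t, t + hop
    if cur_speaker is not None:
        runs.append(Utterance(cur_speaker, cur_start, cur_end))

    bridged: list[Utterance] = []
    for u in runs:
        if (
            bridged
            and bridged[-1].speaker == u.speaker
            and u.start - bridged[-1].end < bridge
        ):
            prev = bridged.pop()
            bridged.append(Utterance(prev.speaker, prev.start, u.end))
        else:
            bridged.append(u)
    return [u for u in bridged if u.duration >= min_duration]


def count_speech_turns(utterances: list[Utterance]) -> int:
    """Number of adjacent utterance pairs with different speakers."""
    ordered = sorted(utterances, key=lambda u: u.start)
    return sum(
        1 for a, b in zip(ordered, ordered[1:]) if a.speaker != b.speaker
    )
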