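"""Skeleton stream cleaning and fusion.

Stages, in pipeline order: label each tracked slot as parent or child by
seat proximity, suppress inconsistent frames, merge the two sensors'
streams onto one uniform clock, smooth with a gap-aware moving average,
and cut the session into the protocol phases.

Gaps are first-class: no stage ever interpolates across missing data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySegment, InvalidWindow
from .recording_io import resample_to_clock
from .types import (
    DyadSeries,
    JointId,
    N_JOINTS,
    PhaseSegment,
    Provenance,
    ROLES,
    RoleSeries,
    SessionManifest,
    SkeletonFrame,
)

log = logging.getLogger(__name__)

__all__ = [
    "IdentityAssignment",
    "assign_identity",
    "reject_inconsistent",
    "fuse_streams",
    "smooth",
    "segment_phases",
    "RejectionLog",
    "split_slots",
]


def split_slots(frames: list[SkeletonFrame]) -> dict[int, list[SkeletonFrame]]:
    out: dict[int, list[SkeletonFrame]] = {}
    for f in frames:
        out.setdefault(f.person_slot, []).append(f)
    return out


def _shoulder_centers(frames: list[SkeletonFrame]) -> tuple[np.ndarray, np.ndarray]:
    """(times, centers (N,3) with NaN rows where shoulders are missing)."""
    times = np.array([f.timestamp for f in frames])
    centers = np.full((len(frames), 3), np.nan)
    for i, f in enumerate(frames):
        l = f.position(JointId.shoulder_left)
        r = f.position(JointId.shoulder_right)
        if l is not None and r is not None:
            centers[i] = 0.5 * (l + r)
        else:
            c = f.position(JointId.shoulder_center)
            if c is not None:
                centers[i] = c
    return times, centers


def _windowed_median(times: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Median of ``values`` over a centered time window, per sample."""
    out = np.full_like(values, np.nan)
    for i, t in enumerate(times):
        sel = (times >= t - window / 2) & (times <= t + window / 2)
        chunk = values[sel]
        chunk = chunk[np.isfinite(chunk).all(axis=1)]
        if len(chunk):
            out[i] = np.median(chunk, axis=0)
    return out


@dataclass
class IdentityAssignment:
    """Role labels for each (slot) stream of one sensor."""

    roles: dict[int, str]  # slot -> parent|child
    confidence: dict[int, float]  # slot -> mean margin in [0, 1]
    dropped: dict[int, np.ndarray] = field(default_factory=dict)  # conflict mask
    ambiguous: bool = False

    def role_streams(
        self, streams: dict[int, list[SkeletonFrame]]
    ) -> dict[str, list[SkeletonFrame]]:
        out: dict[str, list[SkeletonFrame]] = {}
        for slot, frames in streams.items():
            role = self.roles.get(slot)
            if role is None:
                continue
            drop = self.dropped.get(slot)
            kept = [
                f for i, f in enumerate(frames)
                if drop is None or not drop[i]
            ]
            out.setdefault(role, []).extend(kept)
        for role in out:
            out[role].sort(key=lambda f: f.timestamp)
        return out


def assign_identity(
    streams: dict[int, list[SkeletonFrame]],
    seat_layout: dict[str, np.ndarray],
    window: float = 1.0,
    conflict_limit: float = 2.0,
) -> IdentityAssignment:
    """Label tracked slots as parent/child by horizontal seat proximity.

    Each slot is assigned the role whose seat is nearest to the slot's
    1-second windowed median shoulder center (horizontal x/z distance).
    Confidence is the margin between the two seat distances normalized by
    the seat separation.  When two slots claim the same seat, the farther
    slot's conflicting frames are dropped; conflicts exceeding
    ``conflict_limit`` seconds flag the assignment as ambiguous.
    """
    seats = {r: np.asarray(p, float) for r, p in seat_layout.items()}
    sep = float(np.linalg.norm((seats["parent"] - seats["child"])[[0, 2]]))
    per_slot_dist: dict[int, dict[str, np.ndarray]] = {}
    per_slot_times: dict[int, np.ndarray] = {}
    roles: dict[int, str] = {}
    confidence: dict[int, float] = {}
    for slot, frames in streams.items():
        times, centers = _shoulder_centers(frames)
        med = _windowed_median(times, centers, window)
        dists = {
            role: np.hypot(med[:, 0] - seat[0], med[:, 2] - seat[2])
            for role, seat in seats.items()
        }
        per_slot_dist[slot] = dists
        per_slot_times[slot] = times
        d_p, d_c = dists["parent"], dists["child"]
        valid = np.isfinite(d_p) & np.isfinite(d_c)
        if not valid.any():
            continue
        votes_parent = int(np.sum(d_p[valid] < d_c[valid]))
        role = "parent" if votes_parent >= valid.sum() / 2 else "child"
        roles[slot] = role
        margin = np.abs(d_p[valid] - d_c[valid]) / sep
        confidence[slot] = float(np.clip(np.mean(margin), 0.0, 1.0))

    assignment = IdentityAssignment(roles=roles, confidence=confidence)
    # resolve two slots claiming one seat: drop the farther slot's frames
    by_role: dict[str, list[int]] = {}
    for slot, role in roles.items():
        by_role.setdefault(role, []).append(slot)
    for role, slots in by_role.items():
        if len(slots) <= 1:
            continue
        mean_d = {
            s: float(np.nanmean(per_slot_dist[s][role])) for s in slots
        }
        keeper = min(slots, key=lambda s: mean_d[s])
        for s in slots:
            if s == keeper:
                continue
            drop = np.ones(len(per_slot_times[s]), dtype=bool)
            assignment.dropped[s] = drop
            del assignment.roles[s]
            t = per_slot_times[s]
            if len(t) and t[-1] - t[0] > conflict_limit:
                assignment.ambiguous = True
                log.warning(
                    "ambiguous identity: slots %s both nearest %s seat; "
                    "dropped slot %s", slots, role, s,
                )
    return assignment


@dataclass
class RejectionLog:
    """Per-dropped-frame record of which consistency rule fired."""

    entries: list[tuple[float, str]] = field(default_factory=list)

    def add(self, timestamp: float, rule: str) -> None:
        self.entries.append((timestamp, rule))

    def __len__(self) -> int:
        return len(self.entries)


def reject_inconsistent(
    frames: list[SkeletonFrame],
    seat: np.ndarray | None = None,
    jump_limit: float = 0.5,
    jump_dt: float = 0.1,
    shoulder_range: tuple[float, float] = (0.15, 0.75),
    seat_radius: float = 1.5,
) -> tuple[list[SkeletonFrame], RejectionLog]:
    """Suppress physically implausible frames.

    A frame is dropped when (a) any joint moved more than ``jump_limit``
    meters from the previous kept frame in under ``jump_dt`` seconds,
    (b) the shoulder-to-shoulder distance leaves ``shoulder_range``, or
    (c) the shoulder center is farther than ``seat_radius`` (horizontally)
    from the assigned seat.
    """
    kept: list[SkeletonFrame] = []
    rejections = RejectionLog()
    prev: SkeletonFrame | None = None
    for f in frames:
        rule = None
        l = f.position(JointId.shoulder_left)
        r = f.position(JointId.shoulder_right)
        if l is not None and r is not None:
            width = float(np.linalg.norm(l - r))
            if not (shoulder_range[0] <= width <= shoulder_range[1]):
                rule = "shoulder_width"
        if rule is None and seat is not None:
            c = f.position(JointId.shoulder_center)
            if c is None and l is not None and r is not None:
                c = 0.5 * (l + r)
            if c is not None:
                horiz = np.hypot(c[0] - seat[0], c[2] - seat[2])
                if horiz > seat_radius:
                    rule = "seat_radius"
        if rule is None and prev is not None:
            dt = f.timestamp - prev.timestamp
            if 0 <= dt < jump_dt:
                both = f.valid_mask() & prev.valid_mask()
                if both.any():
                    step = np.linalg.norm(
                        f.joints[both] - prev.joints[both], axis=1
                    )
                    if np.max(step) > jump_limit:
                        rule = "jump"
        if rule is None:
            kept.append(f)
            prev = f
        else:
            rejections.add(f.timestamp, rule)
    return kept, rejections


def _stream_arrays(frames: list[SkeletonFrame]):
    times = np.array([f.timestamp for f in frames])
    pos = np.stack([f.joints for f in frames]) if frames else np.empty((0, N_JOINTS, 3))
    valid = (
        np.stack([f.valid_mask() for f in frames])
        if frames
        else np.empty((0, N_JOINTS), dtype=bool)
    )
    return times, pos, valid


def fuse_streams(
    streams_a: dict[str, list[SkeletonFrame]],
    streams_b: dict[str, list[SkeletonFrame]],
    clock: np.ndarray,
    rate: float,
    facing: dict[str, str] | None = None,
    max_gap: float = 0.05,
    disagreement: float = 0.10,
) -> DyadSeries:
    """Merge two role-keyed, world-frame, clock-aligned streams.

    Per clock tick and joint: when both sensors contribute within
    ``max_gap``, the facing sensor's value wins if the sensors agree
    within ``disagreement`` meters, else the tick is a gap; a single
    contribution is taken as-is.  Fused samples are always verbatim copies
    of one sensor's sample.
    """
    facing = facing or {"parent": "A", "child": "B"}
    T = len(clock)
    roles: dict[str, RoleSeries] = {}
    for role in ROLES:
        pos = np.full((T, N_JOINTS, 3), np.nan)
        gap = np.ones((T, N_JOINTS), dtype=bool)
        prov = np.zeros((T, N_JOINTS), dtype=np.uint8)
        contrib = {}
        for sid, streams in (("A", streams_a), ("B", streams_b)):
            frames = streams.get(role, [])
            times, p, valid = _stream_arrays(frames)
            if len(times) == 0:
                contrib[sid] = None
                continue
            p_rs, frame_gap, _ = resample_to_clock(times, p, clock, max_gap)
            v_rs, _, _ = resample_to_clock(
                times, valid.astype(float), clock, max_gap
            )
            joint_ok = (~frame_gap[:, None]) & (np.nan_to_num(v_rs) > 0.5)
            contrib[sid] = (p_rs, joint_ok)
        fa, fb = contrib.get("A"), contrib.get("B")
        if fa is not None and fb is not None:
            both = fa[1] & fb[1]
            dist = np.linalg.norm(np.nan_to_num(fa[0]) - np.nan_to_num(fb[0]), axis=2)
            agree = both & (dist <= disagreement)
            conflict = both & ~agree
            pref = fa if facing[role] == "A" else fb
            pref_code = Provenance.A if facing[role] == "A" else Provenance.B
            pos[agree] = pref[0][agree]
            prov[agree] = pref_code
            gap[agree] = False
            if conflict.any():
                log.warning(
                    "%s: %d tick-joints with cross-sensor disagreement > %.2f m",
                    role, int(conflict.sum()), disagreement,
                )
            only_a = fa[1] & ~(fb[1])
            only_b = fb[1] & ~(fa[1])
            pos[only_a] = fa[0][only_a]
            prov[only_a] = Provenance.A
            gap[only_a] = False
            pos[only_b] = fb[0][only_b]
            prov[only_b] = Provenance.B
            gap[only_b] = False
        elif fa is not None:
            pos[fa[1]] = fa[0][fa[1]]
            prov[fa[1]] = Provenance.A
            gap[fa[1]] = False
        elif fb is not None:
            pos[fb[1]] = fb[0][fb[1]]
            prov[fb[1]] = Provenance.B
            gap[fb[1]] = False
        pos[gap] = np.nan
        roles[role] = RoleSeries(positions=pos, gap=gap, provenance=prov)
    return DyadSeries(clock=np.asarray(clock, float), rate=rate, roles=roles)


def masked_moving_average(
    values: np.ndarray, gap: np.ndarray, window: int
) -> np.ndarray:
    """Centered moving average over non-gap samples only.

    ``values`` is (T, ...); ``gap`` has shape (T, ...) broadcastable to it
    (a trailing axis of ``values`` may be absent in ``gap``).  Output is
    NaN wherever ``gap`` is True: gaps stay gaps and never leak into
    neighboring averages.
    """
    values = np.asarray(values, dtype=float)
    gap = np.asarray(gap, dtype=bool)
    if gap.ndim == values.ndim - 1:
        gap = gap[..., None]
    gap = np.broadcast_to(gap, values.shape)
    v = np.where(gap, 0.0, values)
    m = (~gap).astype(float)
    half = window // 2
    T = values.shape[0]
    zeros = np.zeros((1,) + values.shape[1:])
    csum_v = np.cumsum(np.concatenate([zeros, v]), axis=0)
    csum_m = np.cumsum(np.concatenate([zeros, m]), axis=0)
    lo = np.clip(np.arange(T) - half, 0, T)
    hi = np.clip(np.arange(T) + half + 1, 0, T)
    tot_v = csum_v[hi] - csum_v[lo]
    tot_m = csum_m[hi] - csum_m[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = tot_v / tot_m
    out[gap] = np.nan
    return out


def smooth(series: DyadSeries, window: int = 5) -> DyadSeries:
    """Gap-aware centered moving average; window 1 is the identity."""
    if window % 2 == 0 or window < 1:
        raise InvalidWindow(f"window must be odd >= 1, got {window}")
    roles = {}
    for role, rs in series.roles.items():
        sm = masked_moving_average(rs.positions, rs.gap, window)
        roles[role] = RoleSeries(
            positions=sm, gap=rs.gap.copy(), provenance=rs.provenance.copy()
        )
    return DyadSeries(clock=series.clock.copy(), rate=series.rate, roles=roles)


def segment_phases(
    manifest: SessionManifest, recording_end: float
) -> list[PhaseSegment]:
    """Cut [0, recording_end) into the planned protocol phases.

    Consecutive half-open segments start at world time 0 with the planned
    durations; the plan is truncated at the recording end with a warning.
    """
    if not manifest.phase_plan:
        raise EmptySegment("empty phase plan")
    segments: list[PhaseSegment] = []
    t = 0.0
    for name, dur in manifest.phase_plan:
        start, end = t, t + dur
        t = end
        if start >= recording_end:
            log.warning("phase %r starts after recording end; dropped", name)
            continue
        if end > recording_end:
            log.warning("phase %r truncated at recording end %.1f s", name,
                        recording_end)
            end = recording_end
        segments.append(PhaseSegment(name, start, end))
    if not segments:
        raise EmptySegment("recording shorter than the first phase start")
    return segments
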