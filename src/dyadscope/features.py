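"""Kinematic feature suite computed on a fused DyadSeries.

Distances are 3D Euclidean by default (``planar=True`` restricts to the
horizontal x/z plane).  Orientation angles are acute angles in [0, 90]
degrees between horizontally projected shoulder lines and the world z
axis (or between the two partners' shoulder lines), so they are
insensitive to which shoulder is labeled left.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import masked_moving_average
from .types import ContactEvent, DyadSeries, FeatureSeries, JointId, PhaseSegment

__all__ = [
    "shoulder_center_series",
    "distance_to_table",
    "hand_distances",
    "closest_hand_to_table",
    "shoulder_orientation",
    "relative_shoulder_orientation",
    "head_distance",
    "speed",
    "movement_contribution",
    "approach_avoid",
    "count_hand_contacts",
    "summarize",
    "SegmentSummary",
]

_DEGENERATE_LINE = 0.01  # m: shortest usable horizontal shoulder projection


def _norm(v: np.ndarray, planar: bool = False) -> np.ndarray:
    if planar:
        return np.hypot(v[..., 0], v[..., 2])
    return np.linalg.norm(v, axis=-1)


def shoulder_center_series(
    dyad: DyadSeries, role: str
) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint of the two shoulders: (positions (T,3), gap (T,)).

    Gap wherever either shoulder is missing.
    """
    rs = dyad.roles[role]
    l, gl = rs.joint(JointId.shoulder_left)
    r, gr = rs.joint(JointId.shoulder_right)
    gap = gl | gr
    mid = 0.5 * (l + r)
    mid[gap] = np.nan
    return mid, gap


def distance_to_table(
    dyad: DyadSeries, role: str, planar: bool = False
) -> FeatureSeries:
    """Distance from the participant's shoulder center to the table center
    (the world origin)."""
    mid, gap = shoulder_center_series(dyad, role)
    d = _norm(mid, planar)
    d[gap] = np.nan
    return FeatureSeries(
        name="distance_to_table", times=dyad.clock, values=d, gap=gap,
        scope=role, units="m",
    )


def _pair_distance(dyad, role_a, joint_a, role_b, joint_b, planar=False):
    pa, ga = dyad.roles[role_a].joint(joint_a)
    pb, gb = dyad.roles[role_b].joint(joint_b)
    gap = ga | gb
    d = _norm(pa - pb, planar)
    d[gap] = np.nan
    return d, gap


def hand_distances(
    dyad: DyadSeries, planar: bool = False
) -> tuple[FeatureSeries, FeatureSeries]:
    """Cross-pair hand distances: (parent left - child right,
    parent right - child left)."""
    d1, g1 = _pair_distance(dyad, "parent", JointId.hand_left,
                            "child", JointId.hand_right, planar)
    d2, g2 = _pair_distance(dyad, "parent", JointId.hand_right,
                            "child", JointId.hand_left, planar)
    return (
        FeatureSeries("hand_distance_pL_cR", dyad.clock, d1, g1, "dyad", "m"),
        FeatureSeries("hand_distance_pR_cL", dyad.clock, d2, g2, "dyad", "m"),
    )


def head_distance(dyad: DyadSeries, planar: bool = False) -> FeatureSeries:
    d, g = _pair_distance(dyad, "parent", JointId.head,
                          "child", JointId.head, planar)
    return FeatureSeries("head_distance", dyad.clock, d, g, "dyad", "m")


def closest_hand_to_table(
    dyad: DyadSeries, role: str, planar: bool = False
) -> FeatureSeries:
    """Distance of the participant's closest hand to the table center;
    falls back to the single tracked hand, gap when both are missing."""
    rs = dyad.roles[role]
    dists = []
    for joint in (JointId.hand_left, JointId.hand_right):
        p, g = rs.joint(joint)
        d = _norm(p, planar)
        d[g] = np.nan
        dists.append(d)
    stacked = np.stack(dists)
    gap = np.all(np.isnan(stacked), axis=0)
    d = np.full(stacked.shape[1], np.nan)
    with np.errstate(invalid="ignore"):
        d[~gap] = np.nanmin(stacked[:, ~gap], axis=0)
    return FeatureSeries("closest_hand_to_table", dyad.clock, d, gap, role, "m")


def _shoulder_line_unit(dyad: DyadSeries, role: str) -> tuple[np.ndarray, np.ndarray]:
    """Horizontally projected unit shoulder line: ((T,2) [x,z], gap)."""
    rs = dyad.roles[role]
    l, gl = rs.joint(JointId.shoulder_left)
    r, gr = rs.joint(JointId.shoulder_right)
    d = l - r
    horiz = np.stack([d[:, 0], d[:, 2]], axis=1)
    n = np.linalg.norm(horiz, axis=1)
    gap = gl | gr | (n < _DEGENERATE_LINE)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = horiz / n[:, None]
    u[gap] = np.nan
    return u, gap


def shoulder_orientation(dyad: DyadSeries, role: str) -> FeatureSeries:
    """Acute angle [0, 90] deg between the horizontally projected shoulder
    line and the world z axis.

    0 deg: shoulder line along z; 90 deg: along x.  With the default seat
    geometry a torso facing the table center reads 45 deg and one facing
    the partner's seat reads 90 deg.
    """
    u, gap = _shoulder_line_unit(dyad, role)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arccos(np.clip(np.abs(u[:, 1]), 0.0, 1.0)))
    ang[gap] = np.nan
    return FeatureSeries("shoulder_orientation", dyad.clock, ang, gap,
                         role, "deg")


def relative_shoulder_orientation(dyad: DyadSeries) -> FeatureSeries:
    """Acute angle [0, 90] deg between the two partners' horizontally
    projected shoulder lines; 0 deg means face to face."""
    up, gp = _shoulder_line_unit(dyad, "parent")
    uc, gc = _shoulder_line_unit(dyad, "child")
    gap = gp | gc
    with np.errstate(invalid="ignore"):
        dot = np.abs(np.sum(up * uc, axis=1))
        ang = np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))
    ang[gap] = np.nan
    return FeatureSeries("relative_shoulder_orientation", dyad.clock, ang,
                         gap, "dyad", "deg")


def speed(
    positions: np.ndarray, gap: np.ndarray, clock: np.ndarray,
    name: str = "speed", scope: str = "dyad",
) -> FeatureSeries:
    """Speed magnitude of one tracked point via central differences.

    Interior ticks need both neighbors non-gap; endpoints use one-sided
    differences; ticks adjacent to gaps become gaps.
    """
    T = len(clock)
    dt = float(clock[1] - clock[0]) if T > 1 else 1.0
    v = np.full(T, np.nan)
    ok = ~gap
    if T > 2:
        central = ok[:-2] & ok[1:-1] & ok[2:]
        disp = np.linalg.norm(positions[2:] - positions[:-2], axis=1)
        v[1:-1] = np.where(central, disp / (2 * dt), np.nan)
    if T > 1:
        if ok[0] and ok[1]:
            v[0] = np.linalg.norm(positions[1] - positions[0]) / dt
        if ok[-1] and ok[-2]:
            v[-1] = np.linalg.norm(positions[-1] - positions[-2]) / dt
    elif T == 1 and ok[0]:
        v[0] = 0.0
    out_gap = ~np.isfinite(v)
    return FeatureSeries(name, clock, v, out_gap, scope, "m/s")


def movement_contribution(
    speed_parent: FeatureSeries,
    speed_child: FeatureSeries,
    window: float = 1.0,
    eps: float = 1e-3,
) -> tuple[FeatureSeries, FeatureSeries]:
    """Share of the dyad's movement carried by each partner.

    Per tick, mean speeds over the trailing ``window`` seconds give
    c_child = v_c / (v_c + v_p) and c_parent = 1 - c_child; ticks where the
    summed mean speed is below ``eps`` (m/s) are gaps ("no movement").
    """
    clock = speed_parent.times
    dt = float(clock[1] - clock[0]) if len(clock) > 1 else 1.0
    w = max(1, int(round(window / dt)))

    def trailing_mean(fs: FeatureSeries) -> np.ndarray:
        v = np.where(fs.gap, 0.0, fs.values)
        m = (~fs.gap).astype(float)
        csum_v = np.concatenate([[0.0], np.cumsum(v)])
        csum_m = np.concatenate([[0.0], np.cumsum(m)])
        hi = np.arange(len(v)) + 1
        lo = np.clip(hi - w, 0, None)
        tot_m = csum_m[hi] - csum_m[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot_m > 0, (csum_v[hi] - csum_v[lo]) / tot_m, np.nan)

    vp = trailing_mean(speed_parent)
    vc = trailing_mean(speed_child)
    total = vp + vc
    gap = ~np.isfinite(total) | (total < eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_child = np.where(gap, np.nan, vc / total)
    c_parent = np.where(gap, np.nan, 1.0 - c_child)
    return (
        FeatureSeries("movement_contribution", clock, c_parent, gap,
                      "parent", "ratio"),
        FeatureSeries("movement_contribution", clock, c_child, gap,
                      "child", "ratio"),
    )


def approach_avoid(
    distance: FeatureSeries, window: float = 1.0, dead_band: float = 0.01
) -> np.ndarray:
    """Label each tick approaching / moving_apart / stable / gap.

    The windowed derivative of the distance is compared against a
    ``dead_band`` (m/s): shrinking distance means the partners approach.
    """
    clock = distance.times
    dt = float(clock[1] - clock[0]) if len(clock) > 1 else 1.0
    deriv = np.full(len(clock), np.nan)
    ok = ~distance.gap
    if len(clock) > 1:
        dv = np.diff(distance.values) / dt
        valid = ok[1:] & ok[:-1]
        dv[~valid] = np.nan
        deriv[1:] = dv
    w = max(1, int(round(window / dt)))
    sm = masked_moving_average(deriv[:, None], ~np.isfinite(deriv), w)[:, 0]
    labels = np.full(len(clock), "gap", dtype=object)
    defined = np.isfinite(sm)
    labels[defined & (sm < -dead_band)] = "approaching"
    labels[defined & (sm > dead_band)] = "moving_apart"
    labels[defined & (np.abs(sm) <= dead_band)] = "stable"
    return labels


def count_hand_contacts(
    d1: FeatureSeries,
    d2: FeatureSeries,
    threshold: float = 0.10,
    hysteresis: float = 0.02,
    debounce: float = 0.25,
) -> list[ContactEvent]:
    """Debounced hand-contact events from the two cross-pair distances.

    A contact opens when the minimum of the two distances drops below
    ``threshold`` and closes when it exceeds ``threshold + hysteresis``;
    events separated by less than ``debounce`` seconds are merged.
    """
    clock = d1.times
    stacked = np.stack([np.where(d1.gap, np.inf, d1.values),
                        np.where(d2.gap, np.inf, d2.values)])
    m = np.min(stacked, axis=0)
    dt = float(clock[1] - clock[0]) if len(clock) > 1 else 1.0
    events: list[ContactEvent] = []
    in_contact = False
    start = 0.0
    min_d = np.inf
    for i, d in enumerate(m):
        if not in_contact and d < threshold:
            in_contact = True
            start = clock[i]
            min_d = d
        elif in_contact:
            min_d = min(min_d, d)
            if d > threshold + hysteresis:
                events.append(ContactEvent(start, clock[i], float(min_d)))
                in_contact = False
    if in_contact:
        events.append(ContactEvent(start, clock[-1] + dt, float(min_d)))
    merged: list[ContactEvent] = []
    for ev in events:
        if merged and ev.start - merged[-1].end < debounce:
            prev = merged.pop()
            merged.append(ContactEvent(prev.start, ev.end,
                                       min(prev.min_distance, ev.min_distance)))
        else:
            merged.append(ev)
    return merged


@dataclass(frozen=True)
class SegmentSummary:
    feature: str
    scope: str
    phase: str
    mean: float
    min: float
    max: float
    gap_fraction: float
    defined: bool


def summarize(feature: FeatureSeries, segment: PhaseSegment) -> SegmentSummary:
    """Gap-aware statistics of one feature over one protocol phase."""
    sel = (feature.times >= segment.start) & (feature.times < segment.end)
    gap = feature.gap[sel]
    vals = feature.values[sel][~gap]
    gap_fraction = float(np.mean(gap)) if sel.any() else 1.0
    if vals.size == 0:
        return SegmentSummary(feature.name, feature.scope, segment.phase_name,
                              np.nan, np.nan, np.nan, gap_fraction, False)
    return SegmentSummary(
        feature.name, feature.scope, segment.phase_name,
        float(np.mean(vals)), float(np.min(vals)), float(np.max(vals)),
        gap_fraction, True,
    )
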