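import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadscope import features as feat
from dyadscope.recording_io import make_clock
from dyadscope.types import (
    DyadSeries,
    FeatureSeries,
    JointId,
    N_JOINTS,
    PhaseSegment,
    RoleSeries,
)

SQ2 = np.sqrt(2) / 2


def dyad_from_joints(parent=None, child=None, T=10, rate=30.0,
                     parent_gap=None, child_gap=None):
    """Build a DyadSeries from per-joint constant positions (dicts
    JointId -> (3,)); unset joints are gaps."""
    clock = make_clock(0, T / rate, rate)[:T]
    roles = {}
    for role, spec, gap_override in (
        ("parent", parent, parent_gap), ("child", child, child_gap)
    ):
        pos = np.full((T, N_JOINTS, 3), np.nan)
        gap = np.ones((T, N_JOINTS), bool)
        for j, p in (spec or {}).items():
            pos[:, j, :] = np.asarray(p, float)
            gap[:, j] = False
        if gap_override is not None:
            for j, g in gap_override.items():
                gap[:, j] = g
                pos[g, j, :] = np.nan
        roles[role] = RoleSeries(pos, gap, np.zeros((T, N_JOINTS), np.uint8))
    return DyadSeries(clock=clock, rate=rate, roles=roles)


def torso(center, shoulder_line_unit, half=0.17):
    u = np.asarray(shoulder_line_unit, float)
    c = np.asarray(center, float)
    return {
        JointId.shoulder_left: c + half * u,
        JointId.shoulder_right: c - half * u,
    }


class TestShoulderCenterAndDistance:
    def test_midpoint(self):
        d = dyad_from_joints(parent={JointId.shoulder_left: (0, 1, 0),
                                     JointId.shoulder_right: (0.4, 1, 0)})
        mid, gap = feat.shoulder_center_series(d, "parent")
        assert not gap.any()
        np.testing.assert_allclose(mid[0], [0.2, 1, 0])

    def test_coincident_shoulders(self):
        p = (0.3, 0.5, -0.2)
        d = dyad_from_joints(parent={JointId.shoulder_left: p,
                                     JointId.shoulder_right: p})
        mid, _ = feat.shoulder_center_series(d, "parent")
        np.testing.assert_allclose(mid[0], p)

    def test_symmetric_about_origin(self):
        d = dyad_from_joints(parent={JointId.shoulder_left: (0.2, 0, 0.1),
                                     JointId.shoulder_right: (-0.2, 0, -0.1)})
        mid, _ = feat.shoulder_center_series(d, "parent")
        np.testing.assert_allclose(mid[0], 0, atol=1e-12)

    def test_missing_shoulder_is_gap(self):
        d = dyad_from_joints(parent={JointId.shoulder_left: (0, 1, 0)})
        _, gap = feat.shoulder_center_series(d, "parent")
        assert gap.all()

    def test_distance_at_origin_zero(self):
        d = dyad_from_joints(parent=torso((0, 0, 0), (1, 0, 0)))
        fs = feat.distance_to_table(d, "parent")
        np.testing.assert_allclose(fs.values, 0, atol=1e-12)

    def test_distance_hand_computed(self):
        c = (0.6, 0.6, 0.6)
        d = dyad_from_joints(parent={JointId.shoulder_left: c,
                                     JointId.shoulder_right: c})
        fs = feat.distance_to_table(d, "parent")
        assert fs.values[0] == pytest.approx(np.sqrt(1.08), abs=1e-9)

    def test_translation_of_scene_changes_distance(self):
        # distances are to the world origin; translating everything
        # (table included) is tested via the rigid-invariance property below
        pass


class TestHandDistances:
    def test_simple_distance(self):
        d = dyad_from_joints(
            parent={JointId.hand_left: (0, 0, 0), JointId.hand_right: (1, 0, 0)},
            child={JointId.hand_right: (0, 0, 0.8), JointId.hand_left: (1, 0, 0)},
        )
        d1, d2 = feat.hand_distances(d)
        assert d1.values[0] == pytest.approx(0.8)
        assert d2.values[0] == pytest.approx(0.0)

    def test_coincident_pairs_zero(self):
        d = dyad_from_joints(
            parent={JointId.hand_left: (0.1, 0.2, 0.3),
                    JointId.hand_right: (0.4, 0.5, 0.6)},
            child={JointId.hand_right: (0.1, 0.2, 0.3),
                   JointId.hand_left: (0.4, 0.5, 0.6)},
        )
        d1, d2 = feat.hand_distances(d)
        assert d1.values[0] == pytest.approx(0.0, abs=1e-12)
        assert d2.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_gap_propagates(self):
        d = dyad_from_joints(
            parent={JointId.hand_left: (0, 0, 0)},
            child={JointId.hand_left: (1, 0, 0)},
        )
        d1, d2 = feat.hand_distances(d)
        assert d1.gap.all()  # child hand_right missing
        assert d2.gap.all()  # parent hand_right missing


class TestClosestHand:
    def test_min_of_two(self):
        d = dyad_from_joints(parent={JointId.hand_left: (0.2, 0, 0),
                                     JointId.hand_right: (0.5, 0, 0)})
        fs = feat.closest_hand_to_table(d, "parent")
        assert fs.values[0] == pytest.approx(0.2)

    def test_single_hand_fallback(self):
        d = dyad_from_joints(parent={JointId.hand_right: (0.3, 0, 0)})
        fs = feat.closest_hand_to_table(d, "parent")
        assert fs.values[0] == pytest.approx(0.3)
        assert not fs.gap.any()

    def test_both_missing_gap(self):
        d = dyad_from_joints(parent={})
        fs = feat.closest_hand_to_table(d, "parent")
        assert fs.gap.all()

    def test_tie_harmless(self):
        d = dyad_from_joints(parent={JointId.hand_left: (0.3, 0, 0),
                                     JointId.hand_right: (0, 0, 0.3)})
        fs = feat.closest_hand_to_table(d, "parent")
        assert fs.values[0] == pytest.approx(0.3)


class TestShoulderOrientation:
    def test_line_along_z_zero_deg(self):
        d = dyad_from_joints(parent=torso((0.6, 0.3, 0.6), (0, 0, 1)))
        fs = feat.shoulder_orientation(d, "parent")
        assert fs.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_line_along_x_ninety_deg(self):
        d = dyad_from_joints(parent=torso((0.6, 0.3, 0.6), (1, 0, 0)))
        fs = feat.shoulder_orientation(d, "parent")
        assert fs.values[0] == pytest.approx(90.0, abs=1e-9)

    def test_facing_table_center_45_deg(self):
        # torso in the default parent seat facing the origin
        d = dyad_from_joints(parent=torso((0.6, 0.3, 0.6), (-SQ2, 0, SQ2)))
        fs = feat.shoulder_orientation(d, "parent")
        assert fs.values[0] == pytest.approx(45.0, abs=1e-9)

    def test_swap_shoulders_invariant(self):
        u = np.array([0.3, 0.1, 0.9])
        u = u / np.linalg.norm(u)
        c = (0.5, 0.3, 0.5)
        d1 = dyad_from_joints(parent=torso(c, u))
        d2 = dyad_from_joints(parent=torso(c, -u))
        a1 = feat.shoulder_orientation(d1, "parent").values[0]
        a2 = feat.shoulder_orientation(d2, "parent").values[0]
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_vertical_line_degenerate_gap(self):
        d = dyad_from_joints(parent=torso((0.5, 0.3, 0.5), (0, 1, 0)))
        fs = feat.shoulder_orientation(d, "parent")
        assert fs.gap.all()

    def test_range_0_90(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            u = rng.normal(size=3)
            if np.hypot(u[0], u[2]) < 0.05:
                continue
            u = u / np.linalg.norm(u)
            d = dyad_from_joints(parent=torso((0.5, 0.3, 0.5), u))
            v = feat.shoulder_orientation(d, "parent").values[0]
            assert 0.0 <= v <= 90.0


class TestRelativeOrientation:
    def test_face_to_face_zero(self):
        d = dyad_from_joints(
            parent=torso((0.6, 0.35, 0.6), (1, 0, 0)),
            child=torso((0.6, 0.25, -0.6), (1, 0, 0), half=0.12),
        )
        fs = feat.relative_shoulder_orientation(d)
        assert fs.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_lines_ninety(self):
        d = dyad_from_joints(
            parent=torso((0.6, 0.35, 0.6), (1, 0, 0)),
            child=torso((0.6, 0.25, -0.6), (0, 0, 1), half=0.12),
        )
        fs = feat.relative_shoulder_orientation(d)
        assert fs.values[0] == pytest.approx(90.0, abs=1e-9)

    def test_both_facing_table_ninety(self):
        d = dyad_from_joints(
            parent=torso((0.6, 0.35, 0.6), (-SQ2, 0, SQ2)),
            child=torso((0.6, 0.25, -0.6), (SQ2, 0, SQ2), half=0.12),
        )
        fs = feat.relative_shoulder_orientation(d)
        assert fs.values[0] == pytest.approx(90.0, abs=1e-9)
        assert fs.values[0] <= 90.0


class TestSpeed:
    def test_stationary_zero(self):
        d = dyad_from_joints(parent={JointId.head: (1, 1, 1)}, T=20)
        pos, gap = d.roles["parent"].joint(JointId.head)
        fs = feat.speed(pos, gap, d.clock)
        np.testing.assert_allclose(fs.values[~fs.gap], 0, atol=1e-12)

    def test_uniform_motion(self):
        T, rate = 30, 30.0
        clock = make_clock(0, 1, rate)[:T]
        pos = np.zeros((T, 3))
        pos[:, 0] = 0.3 * clock  # 0.3 m/s
        fs = feat.speed(pos, np.zeros(T, bool), clock)
        np.testing.assert_allclose(fs.values, 0.3, atol=1e-9)

    def test_time_reversal_symmetric(self):
        rng = np.random.default_rng(2)
        T = 25
        clock = make_clock(0, T / 30, 30.0)[:T]
        pos = np.cumsum(rng.normal(0, 0.01, (T, 3)), axis=0)
        fwd = feat.speed(pos, np.zeros(T, bool), clock)
        rev = feat.speed(pos[::-1], np.zeros(T, bool), clock)
        np.testing.assert_allclose(fwd.values[1:-1], rev.values[1:-1][::-1],
                                   atol=1e-12)

    def test_gap_propagates_to_neighbors(self):
        T = 20
        clock = make_clock(0, T / 30, 30.0)[:T]
        pos = np.zeros((T, 3))
        gap = np.zeros(T, bool)
        gap[10] = True
        fs = feat.speed(pos, gap, clock)
        assert fs.gap[9] and fs.gap[10] and fs.gap[11]
        assert not fs.gap[8] and not fs.gap[12]


def fseries(values, gap=None, rate=30.0, scope="dyad"):
    values = np.asarray(values, float)
    T = len(values)
    clock = np.arange(T) / rate
    g = np.zeros(T, bool) if gap is None else np.asarray(gap, bool)
    return FeatureSeries("f", clock, values, g, scope)


class TestMovementContribution:
    def test_child_only_moves(self):
        sp = fseries(np.zeros(60), scope="parent")
        sc = fseries(np.full(60, 0.2), scope="child")
        cp, cc = feat.movement_contribution(sp, sc)
        assert cc.values[-1] == pytest.approx(1.0)
        assert cp.values[-1] == pytest.approx(0.0)

    def test_three_to_one_ratio(self):
        sp = fseries(np.full(60, 0.1))
        sc = fseries(np.full(60, 0.3))
        cp, cc = feat.movement_contribution(sp, sc)
        assert cc.values[-1] == pytest.approx(0.75)
        assert cp.values[-1] == pytest.approx(0.25)

    def test_no_movement_gap(self):
        sp = fseries(np.zeros(60))
        sc = fseries(np.zeros(60))
        cp, cc = feat.movement_contribution(sp, sc)
        assert cc.gap.all() and cp.gap.all()

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_shares_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        sp = fseries(np.abs(rng.normal(0.1, 0.05, 90)),
                     gap=rng.random(90) < 0.2)
        sc = fseries(np.abs(rng.normal(0.1, 0.05, 90)),
                     gap=rng.random(90) < 0.2)
        cp, cc = feat.movement_contribution(sp, sc)
        both = ~cp.gap
        np.testing.assert_allclose(cp.values[both] + cc.values[both], 1.0,
                                   atol=1e-12)


class TestApproachAvoid:
    def test_monotone_decrease_approaching(self):
        d = fseries(np.linspace(1.0, 0.2, 90))
        labels = feat.approach_avoid(d)
        assert set(labels[5:]) == {"approaching"}

    def test_constant_stable(self):
        labels = feat.approach_avoid(fseries(np.full(60, 0.7)))
        assert set(labels[2:]) == {"stable"}

    def test_triangle_wave_alternates(self):
        up = np.linspace(0.2, 1.0, 45)
        wave = np.concatenate([up, up[::-1], up, up[::-1]])
        labels = feat.approach_avoid(fseries(wave), window=0.2)
        # oracle: sign of the derivative away from the fold points
        assert set(labels[10:40]) == {"moving_apart"}
        assert set(labels[55:85]) == {"approaching"}
        assert set(labels[100:130]) == {"moving_apart"}


class TestHandContacts:
    def _dip(self, at, width=15, depth=0.03, T=300, base=0.5):
        v = np.full(T, base)
        v[at : at + width] = depth
        return v

    def test_no_dip_no_events(self):
        evs = feat.count_hand_contacts(fseries(np.full(300, 0.5)),
                                       fseries(np.full(300, 0.6)))
        assert evs == []

    def test_single_dip_one_event(self):
        evs = feat.count_hand_contacts(fseries(self._dip(100)),
                                       fseries(np.full(300, 0.6)))
        assert len(evs) == 1
        assert evs[0].min_distance == pytest.approx(0.03)

    def test_close_dips_merge(self):
        # two dips 0.1 s (3 ticks) apart with 0.25 s debounce -> one event
        v = np.full(300, 0.5)
        v[100:110] = 0.03
        v[113:123] = 0.03
        evs = feat.count_hand_contacts(fseries(v), fseries(np.full(300, 0.6)),
                                       debounce=0.25)
        assert len(evs) == 1

    def test_distant_dips_stay_separate(self):
        v = np.full(300, 0.5)
        v[50:60] = 0.03
        v[200:210] = 0.03
        evs = feat.count_hand_contacts(fseries(v), fseries(np.full(300, 0.6)))
        assert len(evs) == 2

    def test_min_over_both_pairs(self):
        evs = feat.count_hand_contacts(fseries(np.full(300, 0.6)),
                                       fseries(self._dip(80)))
        assert len(evs) == 1

    def test_hysteresis_holds_event_open(self):
        v = np.full(300, 0.5)
        v[100:110] = 0.05
        v[110:120] = 0.11  # above threshold but below threshold+hysteresis
        v[120:130] = 0.05
        evs = feat.count_hand_contacts(fseries(v), fseries(np.full(300, 0.6)),
                                       threshold=0.10, hysteresis=0.02)
        assert len(evs) == 1


class TestSummarize:
    SEG = PhaseSegment("free_play", 0.0, 2.0)

    def test_constant(self):
        s = feat.summarize(fseries(np.full(60, 0.5)), self.SEG)
        assert s.mean == s.min == s.max == pytest.approx(0.5)
        assert s.gap_fraction == 0.0
        assert s.defined

    def test_half_gaps(self):
        gap = np.zeros(60, bool)
        gap[::2] = True
        s = feat.summarize(fseries(np.ones(60), gap=gap), self.SEG)
        assert s.gap_fraction == pytest.approx(0.5)

    def test_all_gap_undefined(self):
        s = feat.summarize(fseries(np.ones(60), gap=np.ones(60, bool)),
                           self.SEG)
        assert not s.defined
        assert np.isnan(s.mean)

    def test_segment_restriction(self):
        v = np.concatenate([np.full(30, 1.0), np.full(30, 3.0)])
        s = feat.summarize(fseries(v), PhaseSegment("p", 0.0, 1.0))
        assert s.mean == pytest.approx(1.0)


class TestRigidInvariance:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_distances_invariant_under_world_rigid_motion(self, seed):
        from .conftest import random_rigid

        rng = np.random.default_rng(seed)
        T_w = random_rigid(rng)
        joints_p = {j: rng.normal(size=3) for j in JointId}
        joints_c = {j: rng.normal(size=3) for j in JointId}
        d1 = dyad_from_joints(parent=joints_p, child=joints_c)
        d2 = dyad_from_joints(
            parent={j: T_w.apply(p) for j, p in joints_p.items()},
            child={j: T_w.apply(p) for j, p in joints_c.items()},
        )
        for fn in (feat.hand_distances,):
            a1, a2 = fn(d1)
            b1, b2 = fn(d2)
            np.testing.assert_allclose(a1.values, b1.values, atol=1e-9)
            np.testing.assert_allclose(a2.values, b2.values, atol=1e-9)
        np.testing.assert_allclose(feat.head_distance(d1).values,
                                   feat.head_distance(d2).values, atol=1e-9)

    def test_angles_invariant_under_y_rotation_with_axis(self):
        # rotating the scene about the vertical axis while measuring the
        # angle against the rotated z axis leaves orientations unchanged;
        # equivalently rotate the scene back: checked against closed form
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        Ry = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        rng = np.random.default_rng(8)
        u = rng.normal(size=3)
        u[1] = 0.1
        u = u / np.linalg.norm(u)
        d1 = dyad_from_joints(parent=torso((0.5, 0.3, 0.5), u),
                              child=torso((0.5, 0.3, -0.5), (1, 0, 0)))
        rotated_p = {j: Ry @ p for j, p in torso((0.5, 0.3, 0.5), u).items()}
        rotated_c = {j: Ry @ p for j, p in
                     torso((0.5, 0.3, -0.5), (1, 0, 0)).items()}
        d2 = dyad_from_joints(parent=rotated_p, child=rotated_c)
        # relative orientation needs no axis: strictly invariant
        np.testing.assert_allclose(
            feat.relative_shoulder_orientation(d1).values,
            feat.relative_shoulder_orientation(d2).values, atol=1e-9)
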