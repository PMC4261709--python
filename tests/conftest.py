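import numpy as np
import pytest

from dyadscope.synthetic import (
    DyadProfile,
    ParticipantSpec,
    generate_recording,
    profile_control,
)
from dyadscope.types import (
    JointId,
    N_JOINTS,
    SkeletonFrame,
    TrackingState,
)


def random_rigid(rng):
    """Uniformly random proper rotation (QR of a Gaussian) + translation."""
    from dyadscope.types import RigidTransform

    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return RigidTransform(Q, rng.uniform(-2, 2, 3))


def make_frame(timestamp=0.0, slot=0, center=(0.5, 0.3, 0.5), yaw=0.0,
               missing=()):
    """A plausible seated upper-body frame facing along ``yaw``."""
    c = np.asarray(center, dtype=float)
    f = np.array([np.sin(yaw), 0.0, np.cos(yaw)])
    left = np.array([f[2], 0.0, -f[0]])
    joints = np.zeros((N_JOINTS, 3))
    joints[JointId.shoulder_center] = c
    joints[JointId.shoulder_left] = c + 0.17 * left
    joints[JointId.shoulder_right] = c - 0.17 * left
    joints[JointId.head] = c + [0, 0.22, 0]
    for side, sgn in (("left", 1), ("right", -1)):
        sh = joints[JointId[f"shoulder_{side}"]]
        joints[JointId[f"elbow_{side}"]] = sh + [0, -0.16, 0] + 0.08 * f
        joints[JointId[f"wrist_{side}"]] = joints[JointId[f"elbow_{side}"]] + 0.12 * f
        joints[JointId[f"hand_{side}"]] = joints[JointId[f"wrist_{side}"]] + 0.05 * f
    states = [TrackingState.tracked] * N_JOINTS
    for j in missing:
        states[j] = TrackingState.missing
        joints[j] = np.nan
    return SkeletonFrame(timestamp, slot, joints, states)


def tiny_profile(**kwargs):
    """A fast, low-event profile for short test recordings."""
    base = dict(
        name="tiny",
        parent=ParticipantSpec(table_distance_mean=0.50),
        child=ParticipantSpec(table_distance_mean=0.40),
        movement_leadership=0.5,
        contact_count=3,
        speech_plan="alternating",
    )
    base.update(kwargs)
    return DyadProfile(**base)


@pytest.fixture(scope="session")
def small_recording():
    """30 s in-memory synthetic recording (no disk round trip)."""
    return generate_recording(tiny_profile(), duration=30.0, seed=7)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """30 s synthetic bundle written to disk."""
    path = tmp_path_factory.mktemp("bundle") / "small"
    recordings, manifest, gt = generate_recording(
        tiny_profile(), duration=30.0, seed=7, out_dir=path
    )
    return path, recordings, manifest, gt


@pytest.fixture(scope="session")
def control_run(tmp_path_factory):
    """120 s control-profile bundle processed by the full pipeline."""
    from dyadscope.pipeline import run_pipeline

    bundle = tmp_path_factory.mktemp("ctrl") / "bundle"
    recordings, manifest, gt = generate_recording(
        profile_control(), duration=120.0, seed=11, out_dir=bundle
    )
    out = bundle.parent / "results"
    result = run_pipeline(bundle, out, with_plots=False)
    return {"bundle": bundle, "out": out, "gt": gt, "result": result}
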