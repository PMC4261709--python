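"""Recording-bundle layout: read, write and clock resampling.

A bundle directory holds, per sensor, a skeleton stream, a mono WAV track,
an audio source-angle stream, chessboard calibration points and image
timestamps, plus a session manifest::

    bundle/
      sensorA/skeleton.xml  audio.wav  source_angle.xml
              calibration.xml  image_timestamps.xml
      sensorB/...
      manifest.yaml
      ground_truth.yaml          (synthetic bundles only, optional)

The XML dialects are original, documented stand-ins (the acquisition
hardware's schema is not public); floats are serialized with ``repr`` so
that read(write(x)) round-trips exactly.
"""
from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import yaml

from .errors import BundleIncomplete, EmptyClock, IOFailure, ParseError
from .types import (
    JointId,
    N_JOINTS,
    SensorRecording,
    SessionManifest,
    SkeletonFrame,
    TrackingState,
)

log = logging.getLogger(__name__)

SENSOR_FILES = (
    "skeleton.xml",
    "audio.wav",
    "source_angle.xml",
    "calibration.xml",
    "image_timestamps.xml",
)
KNOWN_TOP = {"sensorA", "sensorB", "manifest.yaml", "ground_truth.yaml",
             "ground_truth_tracks.csv"}


def _fmt(x: float) -> str:
    """Shortest exact decimal representation of a float."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# writers

def _write_skeleton_xml(frames: list[SkeletonFrame], path: Path) -> None:
    root = ET.Element("skeleton_stream")
    for f in frames:
        fe = ET.SubElement(
            root, "frame",
            timestamp=_fmt(f.timestamp), person_slot=str(int(f.person_slot)),
        )
        for j in JointId:
            p = f.joints[j]
            attrs = {"id": j.name, "state": f.states[j].value}
            if f.states[j] != TrackingState.missing:
                attrs.update(x=_fmt(p[0]), y=_fmt(p[1]), z=_fmt(p[2]))
            ET.SubElement(fe, "joint", **attrs)
    ET.ElementTree(root).write(path, encoding="unicode")


def _write_angle_xml(times: np.ndarray, deg: np.ndarray, path: Path) -> None:
    root = ET.Element("source_angle_stream")
    for t, a in zip(times, deg):
        ET.SubElement(root, "sample", timestamp=_fmt(t), azimuth=_fmt(a))
    ET.ElementTree(root).write(path, encoding="unicode")


def _write_calibration_xml(rec: SensorRecording, path: Path) -> None:
    root = ET.Element("calibration")
    if rec.calibration_grid is not None:
        rows, cols, spacing = rec.calibration_grid
        root.set("rows", str(int(rows)))
        root.set("cols", str(int(cols)))
        root.set("spacing", _fmt(spacing))
    if rec.calibration_points is not None:
        for p in rec.calibration_points:
            ET.SubElement(root, "point", x=_fmt(p[0]), y=_fmt(p[1]), z=_fmt(p[2]))
    ET.ElementTree(root).write(path, encoding="unicode")


def _write_timestamps_xml(times: np.ndarray, path: Path) -> None:
    root = ET.Element("image_timestamps")
    for t in times:
        ET.SubElement(root, "image", timestamp=_fmt(t))
    ET.ElementTree(root).write(path, encoding="unicode")


def write_bundle(
    recordings: dict[str, SensorRecording],
    manifest: SessionManifest,
    path: str | Path,
    ground_truth: dict | None = None,
) -> Path:
    """Write a bundle directory readable by :func:`read_bundle`.

    Output is deterministic: identical inputs produce byte-identical files.
    """
    from scipy.io import wavfile

    path = Path(path)
    if set(recordings) != {"A", "B"}:
        raise ValueError("recordings must be keyed 'A' and 'B'")
    try:
        path.mkdir(parents=True, exist_ok=True)
        for sid, rec in sorted(recordings.items()):
            d = path / f"sensor{sid}"
            d.mkdir(exist_ok=True)
            _write_skeleton_xml(rec.skeleton_stream, d / "skeleton.xml")
            wavfile.write(d / "audio.wav", rec.audio_rate,
                          np.asarray(rec.audio, dtype=np.int16))
            _write_angle_xml(rec.source_angle_times, rec.source_angle_deg,
                             d / "source_angle.xml")
            _write_calibration_xml(rec, d / "calibration.xml")
            _write_timestamps_xml(rec.image_timestamps, d / "image_timestamps.xml")
        man = {
            "phase_plan": [[name, float(dur)] for name, dur in manifest.phase_plan],
            "seat_layout": {
                role: [float(v) for v in pos]
                for role, pos in sorted(manifest.seat_layout.items())
            },
            "table_center": [float(v) for v in manifest.table_center],
            "participants": manifest.participants,
        }
        (path / "manifest.yaml").write_text(
            yaml.safe_dump(man, sort_keys=True, default_flow_style=None)
        )
        if ground_truth is not None:
            (path / "ground_truth.yaml").write_text(
                yaml.safe_dump(ground_truth, sort_keys=True, default_flow_style=None)
            )
    except OSError as exc:  # unwritable target, disk full, ...
        raise IOFailure(f"cannot write bundle at {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# readers

def _parse_float(text: str | None, path: Path, what: str) -> float:
    try:
        v = float(text)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ParseError(f"{path}: bad {what}: {text!r}") from None
    return v


def _read_skeleton_xml(path: Path) -> list[SkeletonFrame]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    frames: list[SkeletonFrame] = []
    prev_t = -np.inf
    for i, fe in enumerate(root.iter("frame")):
        t = _parse_float(fe.get("timestamp"), path, f"timestamp in frame {i}")
        if t < 0:
            raise ParseError(f"{path}: frame {i}: negative timestamp {t}")
        if t < prev_t:
            raise ParseError(
                f"{path}: frame {i}: decreasing timestamp {t} after {prev_t}"
            )
        prev_t = t
        joints = np.full((N_JOINTS, 3), np.nan)
        states = [TrackingState.missing] * N_JOINTS
        for je in fe.iter("joint"):
            name = je.get("id")
            try:
                j = JointId[name]  # type: ignore[index]
            except KeyError:
                raise ParseError(f"{path}: frame {i}: unknown joint {name!r}") from None
            state = TrackingState(je.get("state", "tracked"))
            states[j] = state
            if state != TrackingState.missing:
                joints[j] = [
                    _parse_float(je.get(ax), path, f"{name}.{ax} in frame {i}")
                    for ax in ("x", "y", "z")
                ]
        try:
            frames.append(SkeletonFrame(t, int(fe.get("person_slot", 0)),
                                        joints, states))
        except ValueError as exc:
            raise ParseError(f"{path}: frame {i}: {exc}") from exc
    return frames


def _read_angle_xml(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    times, deg = [], []
    for i, se in enumerate(root.iter("sample")):
        times.append(_parse_float(se.get("timestamp"), path, f"timestamp, sample {i}"))
        deg.append(_parse_float(se.get("azimuth"), path, f"azimuth, sample {i}"))
    return np.asarray(times), np.asarray(deg)


def _read_calibration_xml(path: Path):
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    grid = None
    if root.get("rows") is not None:
        grid = (
            int(root.get("rows")),
            int(root.get("cols")),
            _parse_float(root.get("spacing"), path, "spacing"),
        )
    pts = [
        [_parse_float(pe.get(ax), path, f"point {i}.{ax}") for ax in ("x", "y", "z")]
        for i, pe in enumerate(root.iter("point"))
    ]
    points = np.asarray(pts) if pts else None
    return points, grid


def _read_timestamps_xml(path: Path) -> np.ndarray:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return np.asarray(
        [
            _parse_float(ie.get("timestamp"), path, f"image timestamp {i}")
            for i, ie in enumerate(root.iter("image"))
        ]
    )


def read_bundle(path: str | Path) -> tuple[dict[str, SensorRecording], SessionManifest]:
    """Read a bundle directory; unknown extra files are ignored with a warning."""
    from scipy.io import wavfile

    path = Path(path)
    if not path.is_dir():
        raise BundleIncomplete(f"{path} is not a directory")
    for entry in sorted(path.iterdir()):
        if entry.name not in KNOWN_TOP:
            log.warning("ignoring unknown bundle entry %s", entry)

    man_path = path / "manifest.yaml"
    if not man_path.is_file():
        raise BundleIncomplete(f"missing {man_path}")
    try:
        raw = yaml.safe_load(man_path.read_text())
        manifest = SessionManifest(
            phase_plan=[(str(n), float(d)) for n, d in raw["phase_plan"]],
            seat_layout={k: np.asarray(v, float) for k, v in raw["seat_layout"].items()},
            table_center=np.asarray(raw.get("table_center", [0, 0, 0]), float),
            participants=raw.get("participants", {}),
        )
    except (yaml.YAMLError, KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{man_path}: {exc}") from exc

    recordings: dict[str, SensorRecording] = {}
    for sid in ("A", "B"):
        d = path / f"sensor{sid}"
        for fname in SENSOR_FILES:
            if not (d / fname).is_file():
                raise BundleIncomplete(f"missing {d / fname}")
        rate, audio = wavfile.read(d / "audio.wav")
        if audio.ndim != 1:
            raise ParseError(f"{d / 'audio.wav'}: expected mono audio")
        points, grid = _read_calibration_xml(d / "calibration.xml")
        ang_t, ang_d = _read_angle_xml(d / "source_angle.xml")
        try:
            recordings[sid] = SensorRecording(
                sensor_id=sid,
                skeleton_stream=_read_skeleton_xml(d / "skeleton.xml"),
                audio=audio,
                audio_rate=int(rate),
                source_angle_times=ang_t,
                source_angle_deg=ang_d,
                calibration_points=points,
                calibration_grid=grid,
                image_timestamps=_read_timestamps_xml(d / "image_timestamps.xml"),
            )
        except ValueError as exc:
            raise ParseError(f"{d}: {exc}") from exc
    return recordings, manifest


def read_ground_truth(path: str | Path) -> dict | None:
    """Scalar ground truth of a synthetic bundle, or None if absent."""
    p = Path(path) / "ground_truth.yaml"
    if not p.is_file():
        return None
    return yaml.safe_load(p.read_text())


# ---------------------------------------------------------------------------
# clock resampling

def make_clock(start: float, end: float, rate: float) -> np.ndarray:
    """Uniform clock [start, end) at ``rate`` Hz."""
    n = int(np.floor((end - start) * rate))
    return start + np.arange(n) / rate


def resample_to_clock(
    times: np.ndarray,
    values: np.ndarray,
    clock: np.ndarray,
    max_gap: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-in-time resampling onto a uniform clock; no interpolation.

    Each clock tick takes the input sample closest in time if that sample is
    within ``max_gap`` seconds, else the tick is a gap.  Emitted values are
    always exact copies of input samples.

    Returns ``(out_values, gap_mask, source_index)`` where ``source_index``
    is -1 at gaps.
    """
    clock = np.asarray(clock, dtype=float)
    if clock.size == 0:
        raise EmptyClock("resample target clock is empty")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values)
    out_shape = (len(clock),) + values.shape[1:]
    gap = np.ones(len(clock), dtype=bool)
    idx = np.full(len(clock), -1, dtype=int)
    if times.size:
        right = np.searchsorted(times, clock)
        left = np.clip(right - 1, 0, len(times) - 1)
        right = np.clip(right, 0, len(times) - 1)
        d_left = np.abs(clock - times[left])
        d_right = np.abs(times[right] - clock)
        nearest = np.where(d_right < d_left, right, left)
        dist = np.minimum(d_left, d_right)
        ok = dist <= max_gap
        idx[ok] = nearest[ok]
        gap = ~ok
    out = np.full(out_shape, np.nan, dtype=float)
    if values.size:
        out[~gap] = values[idx[~gap]]
    return out, gap, idx
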