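"""End-to-end orchestration: calibrate -> preprocess -> extract -> audio
-> report.

Every numeric threshold lives in :class:`PipelineConfig`; a YAML config
file overrides the defaults and CLI flags override the file.  Outputs are
plain CSV/YAML plus PNG panels; summary numbers are written once to
``summary.csv`` and the report reads them from there.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audio as audio_mod
from . import features as feat
from .calibration import CalibrationResult, align_clocks, apply_transform, calibrate_bundle
from .errors import EmptyReport, StageError
from .recording_io import make_clock, read_bundle
from .skeleton import (
    assign_identity,
    fuse_streams,
    reject_inconsistent,
    segment_phases,
    smooth,
    split_slots,
)
from .types import DyadSeries, JointId, PhaseSegment, Provenance, ROLES

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_report",
           "preprocess_bundle"]


@dataclass
class PipelineConfig:
    clock_rate: float = 30.0
    max_gap: float = 0.05
    smoothing_window: int = 5
    fusion_disagreement: float = 0.10
    jump_limit: float = 0.5
    jump_dt: float = 0.1
    shoulder_min: float = 0.15
    shoulder_max: float = 0.75
    seat_radius: float = 1.5
    contact_threshold: float = 0.10
    contact_hysteresis: float = 0.02
    contact_debounce: float = 0.25
    contribution_window: float = 1.0
    planar_distances: bool = False
    vad_frame: float = 0.025
    vad_hop: float = 0.010
    audio_sensor: str = "A"

    @classmethod
    def from_yaml(cls, path: str | Path | None, **overrides) -> "PipelineConfig":
        data: dict = {}
        if path is not None:
            data.update(yaml.safe_load(Path(path).read_text()) or {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    calibration: CalibrationResult
    dyad: DyadSeries
    segments: list[PhaseSegment]
    features: dict[tuple[str, str], feat.FeatureSeries]
    contacts: list
    summaries: list[feat.SegmentSummary]
    utterances: list
    turn_count: int
    activity: object | None = None


def preprocess_bundle(
    recordings, manifest, config: PipelineConfig
) -> tuple[CalibrationResult, DyadSeries, list[PhaseSegment], dict]:
    """Calibrate, align, label, reject, fuse and smooth one bundle."""
    calib = calibrate_bundle(recordings)
    rec_a = recordings["A"]
    rec_b = align_clocks(calib.sync, recordings["B"])

    world_streams: dict[str, dict[str, list]] = {}
    rejection_logs: dict[str, object] = {}
    for sid, rec, T_ws in (
        ("A", rec_a, calib.world_from_a),
        ("B", rec_b, calib.world_from_b),
    ):
        frames = [apply_transform(T_ws, f) for f in rec.skeleton_stream]
        slots = split_slots(frames)
        ident = assign_identity(slots, manifest.seat_layout)
        by_role = ident.role_streams(slots)
        cleaned: dict[str, list] = {}
        for role, stream in by_role.items():
            kept, rej = reject_inconsistent(
                stream,
                seat=manifest.seat_layout[role],
                jump_limit=config.jump_limit,
                jump_dt=config.jump_dt,
                shoulder_range=(config.shoulder_min, config.shoulder_max),
                seat_radius=config.seat_radius,
            )
            cleaned[role] = kept
            rejection_logs[f"{sid}:{role}"] = rej
        world_streams[sid] = cleaned

    all_times = [
        f.timestamp
        for sid in world_streams
        for role in world_streams[sid]
        for f in world_streams[sid][role]
    ]
    t_end = max(all_times) + 1.0 / config.clock_rate if all_times else 0.0
    clock = make_clock(0.0, max(t_end, 1.0 / config.clock_rate), config.clock_rate)
    fused = fuse_streams(
        world_streams.get("A", {}),
        world_streams.get("B", {}),
        clock,
        config.clock_rate,
        max_gap=config.max_gap,
        disagreement=config.fusion_disagreement,
    )
    dyad = smooth(fused, config.smoothing_window)
    segments = segment_phases(manifest, t_end)
    return calib, dyad, segments, rejection_logs


def extract_features(
    dyad: DyadSeries, config: PipelineConfig
) -> dict[tuple[str, str], feat.FeatureSeries]:
    """The full plotted feature suite, keyed by (name, scope)."""
    planar = config.planar_distances
    out: dict[tuple[str, str], feat.FeatureSeries] = {}

    def put(fs: feat.FeatureSeries) -> None:
        out[(fs.name, fs.scope)] = fs

    for role in ROLES:
        put(feat.distance_to_table(dyad, role, planar))
        put(feat.closest_hand_to_table(dyad, role, planar))
        put(feat.shoulder_orientation(dyad, role))
    d1, d2 = feat.hand_distances(dyad, planar)
    put(d1)
    put(d2)
    put(feat.relative_shoulder_orientation(dyad))
    put(feat.head_distance(dyad, planar))
    speeds = {}
    for role in ROLES:
        pos, gap = dyad.roles[role].joint(JointId.head)
        speeds[role] = feat.speed(pos, gap, dyad.clock,
                                  name="head_speed", scope=role)
        put(speeds[role])
    c_par, c_chi = feat.movement_contribution(
        speeds["parent"], speeds["child"], window=config.contribution_window
    )
    put(c_par)
    put(c_chi)
    return out


def run_pipeline(
    bundle_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    with_audio: bool = True,
    with_plots: bool = True,
) -> PipelineResult:
    """Run every stage on a bundle and write the results directory."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise StageError(name, exc) from exc

    recordings, manifest = stage("read", read_bundle, bundle_path)
    calib, dyad, segments, rejections = stage(
        "preprocess", preprocess_bundle, recordings, manifest, config
    )

    calib_out = {
        "rotation_b_to_a": [float(v) for v in calib.transform_b_to_a.rotation.ravel()],
        "translation_b_to_a": [float(v) for v in calib.transform_b_to_a.translation],
        "rmse_pair": float(calib.rmse_pair),
        "rmse_world": float(calib.rmse_world),
        "clock_offset": float(calib.sync.offset),
        "clap_time_a": float(calib.sync.clap_time_a),
        "clap_time_b": float(calib.sync.clap_time_b),
    }
    (out / "calibration_result.yaml").write_text(yaml.safe_dump(calib_out))

    with (out / "rejections.log").open("w") as fh:
        for key, rej in sorted(rejections.items()):
            for t, rule in rej.entries:
                fh.write(f"{key}\t{t:.3f}\t{rule}\n")

    rows = []
    for role in ROLES:
        rs = dyad.roles[role]
        for j in JointId:
            pos = rs.positions[:, j, :]
            gap = rs.gap[:, j]
            prov = rs.provenance[:, j]
            for k in range(dyad.n_ticks):
                rows.append(
                    (dyad.clock[k], role, j.name, pos[k, 0], pos[k, 1],
                     pos[k, 2], bool(gap[k]), Provenance(prov[k]).name)
                )
    pd.DataFrame(
        rows, columns=["time", "role", "joint", "x", "y", "z", "gap",
                       "provenance"]
    ).to_csv(out / "dyad_series.csv", index=False)

    features = stage("extract", extract_features, dyad, config)
    feat_frames = []
    for (name, scope), fs in sorted(features.items()):
        feat_frames.append(pd.DataFrame({
            "time": fs.times, "feature": name, "scope": scope,
            "value": fs.values, "gap": fs.gap, "units": fs.units,
        }))
    pd.concat(feat_frames).to_csv(out / "features.csv", index=False)

    contacts = stage(
        "events", feat.count_hand_contacts,
        features[("hand_distance_pL_cR", "dyad")],
        features[("hand_distance_pR_cL", "dyad")],
        threshold=config.contact_threshold,
        hysteresis=config.contact_hysteresis,
        debounce=config.contact_debounce,
    )
    pd.DataFrame(
        [(c.start, c.end, c.min_distance) for c in contacts],
        columns=["start", "end", "min_distance"],
    ).to_csv(out / "events.csv", index=False)

    summaries = [
        feat.summarize(fs, seg) for fs in features.values() for seg in segments
    ]
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out / "summary.csv", index=False
    )

    utterances: list = []
    turn_count = 0
    activity = None
    if with_audio:
        rec_audio = recordings[config.audio_sensor]
        if config.audio_sensor == "B":
            rec_audio = align_clocks(calib.sync, rec_audio)
        activity = stage(
            "audio", audio_mod.annotate_activity,
            rec_audio, dyad, calib.sensor_pose(config.audio_sensor),
            frame=config.vad_frame, hop=config.vad_hop,
        )
        pd.DataFrame({
            "time": activity.times,
            "probability": activity.probability,
            "active": activity.active,
            "azimuth": activity.azimuth,
            "attribution": activity.attribution,
        }).to_csv(out / "audio_activity.csv", index=False)
        utterances = audio_mod.sound_activity_by_participant(activity)
        turn_count = audio_mod.count_speech_turns(utterances)
        pd.DataFrame(
            [(u.speaker, u.start, u.end) for u in utterances],
            columns=["speaker", "start", "end"],
        ).to_csv(out / "utterances.csv", index=False)

    (out / "run_log.json").write_text(json.dumps({
        "config": asdict(config),
        "config_digest": config.digest(),
        "n_ticks": int(dyad.n_ticks),
        "n_contacts": len(contacts),
        "n_utterances": len(utterances),
        "turn_count": int(turn_count),
        "phases": [[s.phase_name, s.start, s.end] for s in segments],
    }, indent=2, sort_keys=True))

    result = PipelineResult(
        calibration=calib, dyad=dyad, segments=segments, features=features,
        contacts=contacts, summaries=summaries, utterances=utterances,
        turn_count=turn_count, activity=activity,
    )
    if with_plots:
        stage("report", render_report, out)
    return result


def render_report(results_dir: str | Path, out_file: str | Path | None = None) -> Path:
    """Render PNG panels + an HTML report from a results directory.

    Summary numbers are read from ``summary.csv`` (single source of
    truth, never recomputed here).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results = Path(results_dir)
    feats_path = results / "features.csv"
    if not feats_path.is_file():
        raise EmptyReport(f"no features.csv under {results}")
    df = pd.read_csv(feats_path)
    if df.empty:
        raise EmptyReport("features.csv is empty")
    summary = pd.read_csv(results / "summary.csv")

    colors = {"parent": "tab:green", "child": "tab:blue", "dyad": "tab:gray"}
    pngs: list[str] = []

    def series(name, scope):
        sel = df[(df.feature == name) & (df.scope == scope)]
        v = sel.value.to_numpy().copy()
        v[sel.gap.to_numpy().astype(bool)] = np.nan  # gaps render as blanks
        return sel.time.to_numpy(), v

    def panel(fname, title, plotter):
        fig, ax = plt.subplots(figsize=(9, 2.8))
        plotter(ax)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("time (s)")
        fig.tight_layout()
        p = results / fname
        fig.savefig(p, dpi=110)
        plt.close(fig)
        pngs.append(fname)

    def dist_panel(ax):
        for role in ROLES:
            t, v = series("distance_to_table", role)
            ax.plot(t, v, color=colors[role], lw=0.8, label=role)
        ax.set_ylabel("m")
        ax.legend(fontsize=7)

    panel("panel_distance_to_table.png", "shoulder center to table center",
          dist_panel)

    def hands_panel(ax):
        for name, style in (("hand_distance_pL_cR", "-"),
                            ("hand_distance_pR_cL", "--")):
            t, v = series(name, "dyad")
            ax.plot(t, v, style, color="tab:purple", lw=0.8, label=name)
        ax.set_ylabel("m")
        ax.legend(fontsize=7)

    panel("panel_hand_distances.png", "cross-pair hand distances", hands_panel)

    def orient_panel(ax):
        for role in ROLES:
            t, v = series("shoulder_orientation", role)
            ax.plot(t, v, color=colors[role], lw=0.8, label=role)
        ax.axhline(45, color="red", lw=0.8)  # toward-table reference
        ax.axhline(90, color="purple", lw=0.8)  # toward-partner reference
        ax.set_ylabel("deg")
        ax.set_ylim(0, 95)
        ax.legend(fontsize=7)

    panel("panel_shoulder_orientation.png", "shoulder orientation vs z axis",
          orient_panel)

    def rel_panel(ax):
        t, v = series("relative_shoulder_orientation", "dyad")
        ax.plot(t, v, color="tab:gray", lw=0.8)
        ax.axhline(0, color="red", lw=0.8)
        ax.axhline(45, color="green", lw=0.8)
        ax.axhline(90, color="purple", lw=0.8)
        ax.set_ylabel("deg")
        ax.set_ylim(-5, 95)

    panel("panel_relative_orientation.png", "relative shoulder orientation",
          rel_panel)

    def contribution_panel(ax):
        t, cp = series("movement_contribution", "parent")
        _, cc = series("movement_contribution", "child")
        ax.fill_between(t, 0, np.nan_to_num(cc), color=colors["child"],
                        alpha=0.6, label="child share")
        ax.fill_between(t, np.nan_to_num(cc),
                        np.nan_to_num(cc) + np.nan_to_num(cp),
                        color=colors["parent"], alpha=0.6, label="parent share")
        ax2 = ax.twinx()
        th, hv = series("head_distance", "dyad")
        ax2.plot(th, hv, color="red", lw=0.9, label="head distance")
        ax2.set_ylabel("m")
        ax.set_ylabel("share")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7, loc="upper left")

    panel("panel_contribution.png",
          "movement contribution with head distance", contribution_panel)

    utt_path = results / "utterances.csv"
    if utt_path.is_file():
        utts = pd.read_csv(utt_path)

        def raster_panel(ax):
            if utts.empty:
                ax.annotate("no attributed activity", (0.5, 0.5),
                            xycoords="axes fraction", ha="center")
            else:
                for _, row in utts.iterrows():
                    y = 1 if row.speaker == "parent" else 0
                    ax.plot([row.start, row.end], [y, y],
                            color=colors[row.speaker], lw=6, solid_capstyle="butt")
            ax.set_yticks([0, 1])
            ax.set_yticklabels(["child", "parent"])
            ax.set_ylim(-0.5, 1.5)

        panel("panel_sound_activity.png", "sound activity by participant",
              raster_panel)

    html = ["<html><head><title>dyad report</title></head><body>",
            "<h1>Dyad interaction report</h1>"]
    for png in pngs:
        html.append(f'<img src="{png}" style="display:block"/>')
    html.append("<h2>Phase summaries</h2>")
    html.append(summary.to_html(index=False, float_format="%.3f"))
    html.append("</body></html>")
    out_path = Path(out_file) if out_file else results / "report.html"
    out_path.write_text("\n".join(html))
    return out_path
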