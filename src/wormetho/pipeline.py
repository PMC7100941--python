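"""End-to-end orchestration: recording -> masks -> skeletons -> kinematics
-> ethogram -> stimulus-aligned summaries, with persisted intermediates,
a YAML-round-trippable configuration and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import wormetho
from wormetho import ethogram as eg
from wormetho import kinematics as km
from wormetho import posture as po
from wormetho import register as rg
from wormetho import segment as sg
from wormetho.core import StimulusEvent
from wormetho.synthworm import (
    GroundTruth,
    SyntheticRecording,
    pixel_to_world,
    world_to_pixel,
)


@dataclass
class PipelineConfig:
    """All tunables of the analysis chain, with the standard defaults.

    Thresholds: pause below 0.02 cycles/s, turn below 0.5x the average
    head-tail distance, 0.25 s minimum bout, 0.18 phase-velocity jump.
    """

    frame_rate_hz: float = 20.0
    pixel_size_mm: float = 0.0125
    stimulus_protocol: str = "single"  # single | double-2s | train-15s
    pause_threshold_cyc_s: float = km.PAUSE_OMEGA_THRESHOLD
    turn_headtail_factor: float = eg.TURN_HEADTAIL_FACTOR
    min_segment_s: float = eg.MIN_SEGMENT_S
    spike_jump_threshold: float = km.SPIKE_JUMP_THRESHOLD
    spike_jump_per_second: bool = False
    segmentation_panel: list[str] = field(
        default_factory=lambda: ["otsu", "triangle", "mean", "isodata"])
    dark_worm: bool = True
    refine_segmentation: bool = False
    n_skeleton_points: int = po.N_POINTS
    max_complex_gap_s: float = 2.0
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("pause_threshold_cyc_s", "turn_headtail_factor",
                     "min_segment_s", "spike_jump_threshold",
                     "frame_rate_hz", "pixel_size_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunManifest:
    input_checksum: str
    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _checksum_file(path: Path) -> str:
    return _sha256(path.read_bytes())


def load_recording(indir) -> SyntheticRecording:
    """Load a recording directory (stack.tif, meta.json, stimuli.json)."""
    import tifffile

    indir = Path(indir)
    stack = tifffile.imread(indir / "stack.tif")
    with open(indir / "meta.json") as fh:
        meta = json.load(fh)
    events = []
    if (indir / "stimuli.json").exists():
        with open(indir / "stimuli.json") as fh:
            events = [StimulusEvent.from_dict(d) for d in json.load(fh)]
    n = len(stack)
    truth = GroundTruth(
        states=np.array([""] * n, dtype=object),
        timestamps=np.asarray(meta["timestamps_s"], dtype=float),
        centroid_mm=np.full((n, 2), np.nan),
        skeletons_mm=np.full((n, po.N_POINTS, 2), np.nan),
        phase_cycles=np.full(n, np.nan),
        phase_velocity=np.full(n, np.nan),
        stage_mm=np.asarray(meta["stage_mm"], dtype=float),
        head_tail_mm=np.full(n, np.nan),
        frame_rate_hz=meta["frame_rate_hz"],
        worm_length_mm=meta.get("worm_length_mm", 1.0),
        pixel_size_mm=meta["pixel_size_mm"],
        events=events,
    )
    return SyntheticRecording(
        stack=stack,
        timestamps=truth.timestamps,
        stage_mm=truth.stage_mm.copy(),
        truth=truth,
        events=events,
    )


def run(
    recording: SyntheticRecording | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    make_plots: bool = False,
) -> dict:
    """Execute the full analysis chain on one recording.

    Stages run in order segmentation -> registration -> posture ->
    kinematics -> ethogram; every intermediate is persisted under
    ``out_dir``.  Deterministic given config and inputs.  Returns a dict
    of in-memory results including the manifest.
    """
    if isinstance(recording, (str, Path)):
        recording = load_recording(recording)
    config = config or PipelineConfig(
        frame_rate_hz=recording.frame_rate_hz,
        pixel_size_mm=recording.pixel_size_mm,
    )
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        input_checksum=_sha256(np.ascontiguousarray(recording.stack).tobytes()),
        config=asdict(config),
        version=wormetho.__version__,
    )
    stack = recording.stack
    n = len(stack)
    fps = config.frame_rate_hz
    px = config.pixel_size_mm
    shape = stack[0].shape

    # --- segmentation -----------------------------------------------------
    panel = {k: sg.DEFAULT_PANEL[k] for k in config.segmentation_panel}
    seg_cfg = sg.SegmentationConfig(dark_worm=config.dark_worm, panel=panel)
    masks, quality = sg.segment_stack(stack, seg_cfg,
                                      refine=config.refine_segmentation)
    quality.to_csv(out / "segmentation_quality.csv", index=False)
    ok = np.array([m.quality == sg.QUALITY_OK for m in masks])
    manifest.stages["segment"] = {
        "frames": n, "ok": int(ok.sum()),
        "failed": int((~ok).sum()),
    }

    # --- registration -----------------------------------------------------
    shifts = rg.estimate_frame_shifts(stack.astype(float),
                                      [m.mask for m in masks])
    traj = rg.integrate_stage_motion(shifts, recording.stage_mm[0],
                                     pixel_size_mm=px)
    traj.to_csv(out / "stage_trajectory.csv")
    manifest.stages["register"] = {
        "frames": n,
        "interpolated": int(np.sum(traj.source == "interpolated")),
    }

    # --- posture ----------------------------------------------------------
    skeletons = []
    for i, m in enumerate(masks):
        if m.quality != sg.QUALITY_OK:
            skeletons.append(po.Skeleton(
                np.full((config.n_skeleton_points, 2), np.nan), frame=i,
                complex=True))
            continue
        skeletons.append(po.midline_simple(m, config.n_skeleton_points))
    complex_idx = po.flag_complex_frames(skeletons)
    complex_flags = np.zeros(n, dtype=bool)
    complex_flags[complex_idx] = True
    for i in complex_idx:
        skeletons[i] = po.Skeleton(
            np.full((config.n_skeleton_points, 2), np.nan), frame=int(i),
            complex=True)

    # orient using the stimulus anchors (targets known to be at the head)
    px_events = []
    for ev in recording.events:
        tgt_px = world_to_pixel(np.asarray(ev.target_mm),
                                traj.position_mm[min(ev.frame, n - 1)],
                                px, shape)[0]
        px_events.append(StimulusEvent(
            time_s=ev.time_s, frame=ev.frame,
            target_mm=(float(tgt_px[0]), float(tgt_px[1])),
            current_mA=ev.current_mA, duration_ms=ev.duration_ms))
    oriented, flips, requests = po.correct_head_tail(skeletons, px_events)
    manifest.stages["posture"] = {
        "complex_frames": int(complex_flags.sum()),
        "flips": int(flips.sum()),
        "annotation_requests": [asdict(r) for r in requests],
    }

    # eigenbasis from non-coiled oriented skeletons
    ht_px = np.array([sk.head_tail_distance if not sk.complex else np.nan
                      for sk in oriented])
    avg_ht_px = eg.average_head_tail(ht_px)
    basis_sample = [
        sk for sk, h in zip(oriented, ht_px)
        if not sk.complex and not np.isnan(h)
        and h >= config.turn_headtail_factor * avg_ht_px
    ]
    basis = po.build_eigenbasis(basis_sample)
    basis.to_csv(out / "eigenbasis.csv")
    modes, mode_flags = po.project_series(oriented, basis)
    modes, missing, repaired = po.interpolate_complex(
        modes, complex_flags | mode_flags, fps, basis, oriented,
        max_gap_s=config.max_complex_gap_s)
    if repaired is not None:
        oriented = repaired
    # Head-tail evidence for the turn rule.  Mode-interpolated skeletons
    # cannot reproduce a deep coil, so on repaired/complex frames the
    # mask itself testifies: a preserved loop-center hole marks a
    # self-occluding coil (head folded onto the body, head-tail distance
    # collapsed); a complex frame without a hole stays unknown.
    ht_px = np.empty(n)
    for i, sk in enumerate(oriented):
        if not sk.complex and not sk.reconstructed and not np.isnan(
                sk.points).any():
            ht_px[i] = sk.head_tail_distance
        elif masks[i].preserved_holes:
            ht_px[i] = 0.0
        else:
            ht_px[i] = np.nan

    sk_rows = []
    for t, sk in enumerate(oriented):
        for j, (x, y) in enumerate(sk.points):
            sk_rows.append((t, j, x, y, sk.complex, sk.reconstructed))
    pd.DataFrame(
        sk_rows, columns=["frame", "point", "x_px", "y_px", "complex",
                          "reconstructed"],
    ).to_csv(out / "skeletons.csv", index=False)

    # --- kinematics -------------------------------------------------------
    cen_px = np.array([
        np.argwhere(m.mask).mean(axis=0)[::-1] if m.mask.any()
        else (np.nan, np.nan)
        for m in masks])
    cen_mm = np.array([
        pixel_to_world(cen_px[i], traj.position_mm[i], px, shape)[0]
        for i in range(n)])
    smoothed = km.smooth_centroid(cen_mm, recording.timestamps)
    head_mm = np.array([
        pixel_to_world(sk.points[0], traj.position_mm[i], px, shape)[0]
        if not np.isnan(sk.points).any() else (np.nan, np.nan)
        for i, sk in enumerate(oriented)])
    vel = km.velocity_from_track(smoothed, head_mm, fps)
    phi, undef = km.phase(modes)
    omega = km.phase_velocity(phi, fps)
    omega, sign_flipped = km.align_phase_sign(omega, vel.signed_mm_s)
    ps = km.remove_phase_spikes(
        omega, fps, jump_threshold=config.spike_jump_threshold,
        jump_per_second=config.spike_jump_per_second,
        undefined=undef | missing)
    if ps.removed.mean() > 0.5:
        manifest.warnings.append(
            "more than half of all frames removed by spike filtering; "
            "recording marked low-quality")
    kin = km.kinematics_table(recording.timestamps, vel, modes, phi, ps)
    kin["centroid_x_mm"] = smoothed[:, 0]
    kin["centroid_y_mm"] = smoothed[:, 1]
    kin.to_csv(out / "kinematics.csv", index=False)
    manifest.stages["kinematics"] = {
        "removed_frames": int(ps.removed.sum()),
        "phase_sign_flipped": bool(sign_flipped),
    }

    # --- ethogram ---------------------------------------------------------
    raw_states = eg.flag_states(
        ps.omega_cyc_s, ht_px, avg_ht_px,
        pause_threshold=config.pause_threshold_cyc_s,
        turn_factor=config.turn_headtail_factor)
    etho = eg.enforce_min_duration(raw_states, fps, config.min_segment_s,
                                   timestamps=recording.timestamps)
    etho.to_csv(out / "ethogram.csv")
    etho.segments.to_csv(out / "segments.csv", index=False)
    with open(out / "stimuli.json", "w") as fh:
        json.dump([ev.to_dict() for ev in recording.events], fh, indent=2)
    manifest.stages["ethogram"] = {
        "n_segments": len(etho.segments),
        "state_counts": {
            s: int(np.sum(etho.states == s))
            for s in np.unique(etho.states)},
    }

    escapes = {}
    for ev in recording.events:
        escapes[ev.time_s] = eg.escape_distance(
            smoothed, recording.timestamps, ev)

    config.to_yaml(out / "config.yaml")
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.outputs[f.name] = _checksum_file(f)
    manifest.to_json(out / "manifest.json")

    results = {
        "masks": masks,
        "quality": quality,
        "stage": traj,
        "skeletons": oriented,
        "basis": basis,
        "modes": modes,
        "phase": phi,
        "phase_series": ps,
        "velocity": vel,
        "centroid_mm": smoothed,
        "ethogram": etho,
        "escapes": escapes,
        "manifest": manifest,
        "animal": eg.AnimalSeries(
            timestamps=recording.timestamps,
            states=etho.states,
            omega=ps.omega_cyc_s,
            centroid_mm=smoothed,
            events=list(recording.events)),
    }
    if make_plots:
        plot_run(results, out)
    return results


def analyze_skeletons(
    skeletons: list,
    frame_rate_hz: float,
    pixel_size_mm: float,
    timestamps: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    events: list[StimulusEvent] | None = None,
) -> dict:
    """Kinematics and ethogram from an already-tracked skeleton series.

    For data that arrives as oriented skeletons (px) rather than imagery —
    another tracker's output, or a simulation — this runs the posture
    projection, phase-velocity and behavioral-flagging stages only.
    """
    config = config or PipelineConfig(frame_rate_hz=frame_rate_hz,
                                      pixel_size_mm=pixel_size_mm)
    fps = frame_rate_hz
    n = len(skeletons)
    if timestamps is None:
        timestamps = np.arange(n) / fps

    ht_px = np.array([
        sk.head_tail_distance if not np.isnan(sk.points).any() else np.nan
        for sk in skeletons])
    avg_ht = eg.average_head_tail(ht_px)
    basis_sample = [
        sk for sk, h in zip(skeletons, ht_px)
        if not sk.complex and not np.isnan(h)
        and h >= config.turn_headtail_factor * avg_ht]
    basis = po.build_eigenbasis(basis_sample)
    modes, mode_flags = po.project_series(skeletons, basis)

    cen_mm = np.array([
        sk.points.mean(axis=0) * pixel_size_mm
        if not np.isnan(sk.points).any() else (np.nan, np.nan)
        for sk in skeletons])
    head_mm = np.array([
        sk.points[0] * pixel_size_mm
        if not np.isnan(sk.points).any() else (np.nan, np.nan)
        for sk in skeletons])
    smoothed = km.smooth_centroid(cen_mm, timestamps)
    vel = km.velocity_from_track(smoothed, head_mm, fps)

    phi, undef = km.phase(modes)
    omega = km.phase_velocity(phi, fps)
    omega, _ = km.align_phase_sign(omega, vel.signed_mm_s)
    ps = km.remove_phase_spikes(
        omega, fps, jump_threshold=config.spike_jump_threshold,
        jump_per_second=config.spike_jump_per_second,
        undefined=undef | mode_flags)
    raw = eg.flag_states(ps.omega_cyc_s, ht_px, avg_ht,
                         pause_threshold=config.pause_threshold_cyc_s,
                         turn_factor=config.turn_headtail_factor)
    etho = eg.enforce_min_duration(raw, fps, config.min_segment_s,
                                   timestamps=timestamps)
    return {
        "ethogram": etho,
        "basis": basis,
        "modes": modes,
        "phase": phi,
        "phase_series": ps,
        "velocity": vel,
        "centroid_mm": smoothed,
        "animal": eg.AnimalSeries(
            timestamps=timestamps, states=etho.states,
            omega=ps.omega_cyc_s, centroid_mm=smoothed,
            events=list(events or [])),
    }


# ---------------------------------------------------------------------------
# cohort summaries


STATE_COLORS = {"forward": "#4c72b0", "reverse": "#c44e52",
                "pause": "#ccb974", "turn": "#55a868", "missing": "#cccccc"}


def summarize(
    animals: list[eg.AnimalSeries],
    out_dir: str | Path,
    groups: dict[str, list[int]] | None = None,
    window_s: tuple[float, float] = (-10.0, 30.0),
    grid_step_s: float = 0.05,
    make_plots: bool = True,
) -> dict[str, eg.PopulationSummary]:
    """Stimulus-aligned cohort summaries, optionally split into groups.

    ``groups`` maps a label to animal indices; by default the whole cohort
    forms one group "all".  Writes one summary CSV (and figure set) per
    group.
    """
    if not animals:
        raise ValueError("empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rates = {round(1.0 / np.median(np.diff(a.timestamps)), 3)
             for a in animals if len(a.timestamps) > 1}
    if len(rates) > 1:
        import warnings

        warnings.warn(
            f"cohort mixes frame rates {sorted(rates)}; traces are "
            "resampled onto the common summary grid", stacklevel=2)
    groups = groups or {"all": list(range(len(animals)))}
    summaries = {}
    for label, idx in groups.items():
        group = [animals[i] for i in idx]
        summ = eg.align_to_stimulus(group, window_s, grid_step_s)
        summ.label = label
        summ.to_csv(out / f"summary_{label}.csv")
        summaries[label] = summ
        if make_plots:
            plot_population(summ, [animals[i] for i in idx],
                            out / f"figures_{label}")
    return summaries


def plot_population(summary: eg.PopulationSummary,
                    animals: list[eg.AnimalSeries], out_dir) -> None:
    """Ethogram raster and state-fraction / ω / escape-distance curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(8, 0.25 * max(len(animals), 4) + 1))
    for row, an in enumerate(animals):
        ev_t = an.events[0].time_s if an.events else 0.0
        t = an.timestamps - ev_t
        for s in STATE_COLORS:
            sel = an.states == s
            if sel.any():
                ax.scatter(t[sel], np.full(sel.sum(), row), s=4, marker="|",
                           color=STATE_COLORS[s], label=s if row == 0 else None)
    ax.axvline(0, color="orange", lw=1)
    ax.set_xlabel("time relative to stimulus (s)")
    ax.set_ylabel("animal")
    ax.legend(loc="upper right", fontsize=7, markerscale=3)
    fig.tight_layout()
    fig.savefig(out / "ethogram_raster.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(3, 1, figsize=(8, 8), sharex=True)
    for s in ("forward", "reverse", "pause", "turn"):
        axes[0].plot(summary.t_rel_s, summary.fractions[s],
                     color=STATE_COLORS[s], label=s)
    axes[0].set_ylabel("fraction of animals")
    axes[0].legend(fontsize=8)
    axes[1].plot(summary.t_rel_s, summary.mean_omega, color="k")
    axes[1].fill_between(summary.t_rel_s,
                         summary.mean_omega - summary.sem_omega,
                         summary.mean_omega + summary.sem_omega,
                         alpha=0.3, color="k")
    axes[1].set_ylabel("phase velocity (cycles/s)")
    axes[2].plot(summary.t_rel_s, summary.mean_escape_mm, color="k")
    axes[2].fill_between(summary.t_rel_s,
                         summary.mean_escape_mm - summary.sem_escape_mm,
                         summary.mean_escape_mm + summary.sem_escape_mm,
                         alpha=0.3, color="k")
    axes[2].set_ylabel("escape distance (mm)")
    axes[2].set_xlabel("time relative to stimulus (s)")
    for ax in axes:
        ax.axvline(0, color="orange", lw=1)
    fig.tight_layout()
    fig.savefig(out / "state_fractions.png", dpi=120)
    plt.close(fig)


def plot_run(results: dict, out_dir) -> None:
    """Single-run diagnostic figure: ethogram strip over ω trace."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    etho = results["ethogram"]
    ps = results["phase_series"]
    t = etho.timestamps
    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(9, 4), sharex=True,
                                   height_ratios=[1, 3])
    for s, color in STATE_COLORS.items():
        sel = etho.states == s
        if sel.any():
            ax0.scatter(t[sel], np.zeros(sel.sum()), s=12, marker="|",
                        color=color, label=s)
    ax0.set_yticks([])
    ax0.legend(fontsize=6, ncol=5, loc="upper center")
    ax1.plot(t, ps.omega_cyc_s, lw=0.8, color="k")
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel("phase velocity (cycles/s)")
    fig.tight_layout()
    fig.savefig(out / "run_overview.png", dpi=120)
    plt.close(fig)
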