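"""Synthetic single-worm recordings with full ground truth.

The generator scripts a worm through forward / reverse / pause / turn
segments, producing per-frame skeletons, centroids, undulation phase and a
tracking-stage trajectory, then rasterizes the body into a bright-field
image stack over a textured background.  A separate generator produces
dual-excitation (490/440 nm) fluorescence stacks encoding a known
laser-induced temperature field for testing the thermometry chain.

Model: the body midline is an arc-length parameterized curve whose tangent
angle is a traveling sinusoid,

    theta(s, t) = A * sin(2*pi*(s/lambda - phi(t))),   s in [0, 1],

with lambda ~ 0.9 body lengths, so the first two posture modes of the
resulting angle profiles form a quadrature pair.  Forward crawling advances
phi at the undulation frequency; reversals run phi backwards and the
centroid retreats.  An omega turn is a smoothly ramped constant-curvature
coil applied to the anterior ~70% of the body: the head sweeps around to
approach the tail, collapsing the head-tail distance and (at full bend)
enclosing an interior background hole, which is exactly what the
segmentation and flagging stages must survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter, map_coordinates

from wormetho.core import StimulusEvent, arc_length_resample

N_SKELETON_POINTS = 49

VALID_STATES = ("forward", "reverse", "pause", "turn")


# ---------------------------------------------------------------------------
# schedules


@dataclass
class ScheduleSegment:
    """One scripted bout of behavior.

    speed is centroid speed in mm/s (0 for pause), frequency the undulation
    rate in cycles/s, amplitude the tangent-angle amplitude in rad.
    """

    state: str
    duration_s: float
    speed_mm_s: float = 0.0
    frequency_hz: float = 0.5
    amplitude_rad: float = 0.7

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise ValueError(
                f"invalid state {self.state!r} in segment "
                f"(duration {self.duration_s} s); must be one of {VALID_STATES}"
            )
        if self.duration_s <= 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration_s}")
        if self.state == "pause" and self.speed_mm_s != 0:
            raise ValueError("pause segments must have speed 0")


@dataclass
class LocomotionSchedule:
    """A scripted locomotion program plus acquisition parameters."""

    segments: list[ScheduleSegment]
    seed: int = 0
    frame_rate_hz: float = 20.0
    pixel_size_mm: float = 0.0125
    worm_length_mm: float = 1.0
    #: undulation wavelength in body lengths
    wavelength_bl: float = 0.9
    #: peak total bend angle of an omega turn (rad)
    turn_bend_rad: float = 1.7 * np.pi
    #: fraction of a turn segment spent ramping the bend up (and down)
    turn_ramp_frac: float = 0.3
    #: heading random-walk intensity, rad/sqrt(s) (0 = perfectly straight runs)
    heading_noise: float = 0.05
    #: relaxation time for amplitude changes between segments (s)
    amplitude_tau_s: float = 0.2
    #: tracking-stage first-order follow gain per frame (0 = stage fixed)
    stage_gain: float = 0.15
    stimulus_times_s: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule has no segments")
        if not (5.0 <= self.frame_rate_hz <= 100.0):
            raise ValueError("frame rate out of supported range")

    @property
    def duration_s(self) -> float:
        return float(sum(seg.duration_s for seg in self.segments))

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "frame_rate_hz": self.frame_rate_hz,
            "pixel_size_mm": self.pixel_size_mm,
            "worm_length_mm": self.worm_length_mm,
            "wavelength_bl": self.wavelength_bl,
            "turn_bend_rad": float(self.turn_bend_rad),
            "turn_ramp_frac": self.turn_ramp_frac,
            "heading_noise": self.heading_noise,
            "amplitude_tau_s": self.amplitude_tau_s,
            "stage_gain": self.stage_gain,
            "stimulus_times_s": list(self.stimulus_times_s),
            "segments": [
                {
                    "state": s.state,
                    "duration_s": s.duration_s,
                    "speed_mm_s": s.speed_mm_s,
                    "frequency_hz": s.frequency_hz,
                    "amplitude_rad": s.amplitude_rad,
                }
                for s in self.segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LocomotionSchedule":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        segs = [ScheduleSegment(**d) for d in data.pop("segments")]
        return cls(segments=segs, **data)


def escape_schedule(
    seed: int = 0,
    pre_s: float = 10.0,
    reverse_s: float = 3.0,
    turn_s: float = 1.5,
    post_s: float = 10.0,
    frequency_hz: float = 0.5,
    speed_mm_s: float = 0.15,
    **kwargs,
) -> LocomotionSchedule:
    """The canonical escape motif: forward, then reverse -> turn -> forward.

    A stimulus event is scheduled at the forward/reverse boundary, i.e. the
    moment the scripted escape begins.
    """
    segs = [
        ScheduleSegment("forward", pre_s, speed_mm_s, frequency_hz),
        ScheduleSegment("reverse", reverse_s, speed_mm_s, 1.5 * frequency_hz),
        ScheduleSegment("turn", turn_s, 0.02, frequency_hz),
        ScheduleSegment("forward", post_s, 1.4 * speed_mm_s, 1.4 * frequency_hz),
    ]
    return LocomotionSchedule(
        segments=segs, seed=seed, stimulus_times_s=[pre_s], **kwargs
    )


def cohort_schedule(seed: int, duration_s: float = 120.0,
                    **kwargs) -> LocomotionSchedule:
    """A varied scripted program for cohort studies.

    Forward runs, pauses, and a full escape motif (reverse -> omega turn ->
    accelerated forward) with bout durations and rates drawn once from the
    seed; the stimulus is scheduled at the escape onset.  Total duration is
    exact: the last forward run absorbs the remainder.
    """
    rng = np.random.default_rng(seed)
    f0 = rng.uniform(0.4, 0.6)  # baseline undulation rate, cycles/s
    v0 = rng.uniform(0.12, 0.18)  # baseline speed, mm/s
    segs = [
        ScheduleSegment("forward", rng.uniform(20, 28), v0, f0),
        ScheduleSegment("pause", rng.uniform(4, 8), 0.0, f0),
        ScheduleSegment("forward", rng.uniform(8, 12), v0, f0),
        ScheduleSegment("reverse", rng.uniform(3, 5), 1.2 * v0,
                        rng.uniform(0.7, 0.9)),
        ScheduleSegment("turn", rng.uniform(1.2, 1.8), 0.02, f0),
        ScheduleSegment("forward", rng.uniform(18, 25), 1.4 * v0, 1.3 * f0),
        ScheduleSegment("pause", rng.uniform(4, 7), 0.0, f0),
    ]
    used = sum(s.duration_s for s in segs)
    segs.append(ScheduleSegment("forward", max(duration_s - used, 5.0),
                                v0, f0))
    stim_time = sum(s.duration_s for s in segs[:3])  # escape onset
    post_anchor = sum(s.duration_s for s in segs[:6]) + 2.0
    return LocomotionSchedule(
        segments=segs, seed=seed,
        stimulus_times_s=[stim_time, post_anchor], **kwargs)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Per-frame truth for a synthetic recording.  All positions in mm."""

    states: np.ndarray  # (n,) str
    timestamps: np.ndarray  # (n,) s
    centroid_mm: np.ndarray  # (n, 2) x, y
    skeletons_mm: np.ndarray  # (n, 49, 2), head at index 0
    phase_cycles: np.ndarray  # (n,)
    phase_velocity: np.ndarray  # (n,) cycles/s, signed
    stage_mm: np.ndarray  # (n, 2)
    head_tail_mm: np.ndarray  # (n,)
    frame_rate_hz: float
    worm_length_mm: float
    pixel_size_mm: float
    events: list[StimulusEvent] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.states)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.timestamps,
                "state": self.states,
                "centroid_x_mm": self.centroid_mm[:, 0],
                "centroid_y_mm": self.centroid_mm[:, 1],
                "phase_cycles": self.phase_cycles,
            }
        )


def _smoothstep(u: np.ndarray | float) -> np.ndarray | float:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _turn_bend_profile(u: float, ramp: float) -> float:
    """Trapezoidal bend envelope over turn progress u in [0, 1]."""
    if u < ramp:
        return float(_smoothstep(u / ramp))
    if u > 1.0 - ramp:
        return float(_smoothstep((1.0 - u) / ramp))
    return 1.0


# anterior bend window for omega turns: curvature confined to s in [s0, s1]
_TURN_S0, _TURN_S1 = 0.02, 0.70


def _turn_shape(s: np.ndarray) -> np.ndarray:
    """Cumulative bend fraction W(s): 0 before the coil, 1 after it.

    The curvature density is a raised cosine on [s0, s1]; W is its integral,
    so multiplying by the total bend angle gives the tangent-angle increment.
    """
    u = np.clip((s - _TURN_S0) / (_TURN_S1 - _TURN_S0), 0.0, 1.0)
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def _skeleton_from_angles(angles: np.ndarray, length_mm: float) -> np.ndarray:
    """Integrate tangent angles (one per inter-point gap) to a midline."""
    ds = length_mm / len(angles)
    steps = ds * np.column_stack([np.cos(angles), np.sin(angles)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pts - pts.mean(axis=0)


def generate_track(schedule: LocomotionSchedule) -> GroundTruth:
    """Simulate the scripted locomotion program into per-frame ground truth.

    Deterministic for a fixed schedule (including its seed).
    """
    rng = np.random.default_rng(schedule.seed)
    fps = schedule.frame_rate_hz
    dt = 1.0 / fps
    L = schedule.worm_length_mm
    n_pts = N_SKELETON_POINTS
    # tangent angles are sampled at gap midpoints
    s_mid = (np.arange(n_pts - 1) + 0.5) / (n_pts - 1)
    turn_w = _turn_shape(s_mid)

    # frame -> segment assignment
    seg_edges = np.cumsum([seg.duration_s for seg in schedule.segments])
    n_frames = int(round(seg_edges[-1] * fps))
    timestamps = np.arange(n_frames) * dt

    states = np.empty(n_frames, dtype=object)
    centroid = np.zeros((n_frames, 2))
    skeletons = np.zeros((n_frames, n_pts, 2))
    phase = np.zeros(n_frames)
    omega = np.zeros(n_frames)
    head_tail = np.zeros(n_frames)

    # evolving state
    phi = 0.0
    heading = rng.uniform(0, 2 * np.pi)
    pos = np.zeros(2)
    amp = schedule.segments[0].amplitude_rad
    alpha_amp = 1.0 - np.exp(-dt / schedule.amplitude_tau_s)

    # pre-draw each turn's heading change so it is independent of frame rate
    turn_dpsi = {
        i: np.pi * (0.8 + 0.4 * (rng.random() - 0.5))
        for i, seg in enumerate(schedule.segments)
        if seg.state == "turn"
    }

    seg_idx = 0
    seg_start_t = 0.0
    heading_at_turn_start = heading
    for i in range(n_frames):
        t = timestamps[i]
        while seg_idx < len(seg_edges) - 1 and t >= seg_edges[seg_idx] - 1e-9:
            seg_idx += 1
            seg_start_t = seg_edges[seg_idx - 1]
            heading_at_turn_start = heading
        seg = schedule.segments[seg_idx]
        states[i] = seg.state

        bend = 0.0
        if seg.state == "turn":
            u = (t - seg_start_t) / seg.duration_s
            bend = schedule.turn_bend_rad * _turn_bend_profile(
                u, schedule.turn_ramp_frac
            )
            # heading swings through the turn
            heading = heading_at_turn_start + turn_dpsi[seg_idx] * _smoothstep(u)

        # record the state at t_i ...
        phase[i] = phi
        centroid[i] = pos
        if seg.state == "forward":
            omega[i] = seg.frequency_hz
        elif seg.state == "reverse":
            omega[i] = -seg.frequency_hz
        else:
            omega[i] = 0.0

        # body: tangent from head to tail points opposite the heading
        angles = (
            (heading + np.pi)
            + amp * np.sin(2 * np.pi * (s_mid / schedule.wavelength_bl - phi))
            + bend * (turn_w - turn_w.mean())
        )
        sk = _skeleton_from_angles(angles, L) + pos
        skeletons[i] = sk
        head_tail[i] = np.linalg.norm(sk[0] - sk[-1])

        # ... then advance to t_{i+1}
        phi += omega[i] * dt
        move = np.array([np.cos(heading), np.sin(heading)])
        if seg.state == "forward":
            pos = pos + seg.speed_mm_s * dt * move
        elif seg.state == "reverse":
            pos = pos - seg.speed_mm_s * dt * move
        elif seg.state == "turn" and seg.speed_mm_s > 0:
            pos = pos + seg.speed_mm_s * dt * move
        amp += (seg.amplitude_rad - amp) * alpha_amp
        if seg.state in ("forward", "reverse") and schedule.heading_noise > 0:
            heading += schedule.heading_noise * np.sqrt(dt) * rng.standard_normal()

    # tracking stage follows the centroid with a first-order lag
    stage = np.zeros((n_frames, 2))
    stage[0] = centroid[0]
    g = schedule.stage_gain
    for i in range(1, n_frames):
        stage[i] = stage[i - 1] + g * (centroid[i] - stage[i - 1])

    truth = GroundTruth(
        states=np.array(states, dtype=object),
        timestamps=timestamps,
        centroid_mm=centroid,
        skeletons_mm=skeletons,
        phase_cycles=phase,
        phase_velocity=omega,
        stage_mm=stage,
        head_tail_mm=head_tail,
        frame_rate_hz=fps,
        worm_length_mm=L,
        pixel_size_mm=schedule.pixel_size_mm,
    )
    truth.events = [
        make_stimulus_event(truth, t_s) for t_s in schedule.stimulus_times_s
    ]
    return truth


def make_stimulus_event(
    truth: GroundTruth,
    time_s: float,
    current_mA: float = 75.0,
    duration_ms: float = 100.0,
    head_fraction: float = 0.2,
) -> StimulusEvent:
    """Build a stimulus event targeted at the worm's anterior at `time_s`.

    The target sits at the arc-length midpoint of the anterior fifth,
    mirroring the tracking system's head-targeting rule, using the skeleton
    of the frame immediately before onset (the one-frame targeting lag).
    """
    frame = int(np.searchsorted(truth.timestamps, time_s - 1e-9))
    frame = min(max(frame, 0), truth.n_frames - 1)
    target_frame = max(frame - 1, 0)
    sk = arc_length_resample(truth.skeletons_mm[target_frame], 201)
    idx = int(round(head_fraction / 2 * 200))
    target = sk[idx]
    return StimulusEvent(
        time_s=float(time_s),
        frame=frame,
        target_mm=(float(target[0]), float(target[1])),
        current_mA=current_mA,
        duration_ms=duration_ms,
    )


# ---------------------------------------------------------------------------
# rendering


@dataclass
class Optics:
    """Rendering parameters for the bright-field image stack."""

    image_shape: tuple[int, int] = (160, 160)
    background_level: float = 0.75
    worm_level: float = 0.25
    #: additive Gaussian noise, as a fraction of contrast
    noise_frac: float = 0.02
    #: static background texture amplitude (intensity units)
    texture_amp: float = 0.05
    texture_sigma_px: float = 1.5
    worm_width_mm: float = 0.065
    #: soft body-edge width in px (anti-aliasing band)
    edge_px: float = 1.0
    dark_worm: bool = True
    dtype: str = "uint8"
    seed: int = 0


@dataclass
class SyntheticRecording:
    """A rendered recording: images, metadata, and the generating truth."""

    stack: np.ndarray  # (n, H, W)
    timestamps: np.ndarray
    stage_mm: np.ndarray  # reported stage positions
    truth: GroundTruth
    events: list[StimulusEvent]
    true_masks: np.ndarray | None = None  # (n, H, W) bool
    out_of_view: list[int] = field(default_factory=list)
    optics: Optics | None = None

    @property
    def n_frames(self) -> int:
        return len(self.stack)

    @property
    def frame_rate_hz(self) -> float:
        return self.truth.frame_rate_hz

    @property
    def pixel_size_mm(self) -> float:
        return self.truth.pixel_size_mm


def _width_profile(s: np.ndarray, width_mm: float) -> np.ndarray:
    """Half-width (radius) along the body: elliptical taper, sharp tips."""
    return 0.5 * width_mm * np.sqrt(np.clip(1.0 - (2 * s - 1) ** 2, 0.0, 1.0))


def world_to_pixel(
    points_mm: np.ndarray,
    stage_mm: np.ndarray,
    pixel_size_mm: float,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Map world mm -> (col, row) px for a camera centered on the stage."""
    points_mm = np.atleast_2d(points_mm)
    cy, cx = (image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0
    rel = (points_mm - np.asarray(stage_mm)) / pixel_size_mm
    return rel + np.array([cx, cy])


def pixel_to_world(
    points_px: np.ndarray,
    stage_mm: np.ndarray,
    pixel_size_mm: float,
    image_shape: tuple[int, int],
) -> np.ndarray:
    points_px = np.atleast_2d(points_px)
    cy, cx = (image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0
    return (points_px - np.array([cx, cy])) * pixel_size_mm + np.asarray(stage_mm)


def _rasterize_worm(
    skeleton_mm: np.ndarray,
    stage_mm: np.ndarray,
    optics: Optics,
    pixel_size_mm: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Distance-field rasterization -> (alpha, hard mask, fully_in_view)."""
    H, W = optics.image_shape
    pts = arc_length_resample(skeleton_mm, 6 * N_SKELETON_POINTS)
    s = np.linspace(0, 1, len(pts))
    radii_px = _width_profile(s, optics.worm_width_mm) / pixel_size_mm
    px = world_to_pixel(pts, stage_mm, pixel_size_mm, optics.image_shape)
    cols, rows = px[:, 0], px[:, 1]

    rmax = radii_px.max() + optics.edge_px + 1
    in_view = (
        (cols.min() >= -rmax)
        and (cols.max() <= W - 1 + rmax)
        and (rows.min() >= -rmax)
        and (rows.max() <= H - 1 + rmax)
    )

    r0 = int(max(0, np.floor(rows.min() - rmax)))
    r1 = int(min(H, np.ceil(rows.max() + rmax) + 1))
    c0 = int(max(0, np.floor(cols.min() - rmax)))
    c1 = int(min(W, np.ceil(cols.max() + rmax) + 1))
    alpha = np.zeros((H, W), dtype=np.float32)
    mask = np.zeros((H, W), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return alpha, mask, False

    gr, gc = np.mgrid[r0:r1, c0:c1]
    # signed distance to the tube: min over samples of (|p - c_j| - r_j)
    d = np.full(gr.shape, np.inf, dtype=np.float32)
    chunk = 64
    for j0 in range(0, len(pts), chunk):
        j1 = min(j0 + chunk, len(pts))
        dr = gr[..., None] - rows[j0:j1]
        dc = gc[..., None] - cols[j0:j1]
        dist = np.sqrt(dr * dr + dc * dc) - radii_px[j0:j1]
        d = np.minimum(d, dist.min(axis=-1))
    a = np.clip(0.5 - d / optics.edge_px, 0.0, 1.0)
    alpha[r0:r1, c0:c1] = a
    mask[r0:r1, c0:c1] = a >= 0.5
    return alpha, mask, bool(in_view)


def render_frames(
    truth: GroundTruth,
    optics: Optics | None = None,
    keep_masks: bool = True,
    stage_report_noise_mm: float = 0.0,
) -> SyntheticRecording:
    """Rasterize a ground-truth track into a noisy bright-field stack.

    The background is a static world-anchored texture, so frame-to-frame
    stage motion is recoverable by registering frame edges.  Frames where
    the worm leaves the field of view are listed in ``out_of_view`` rather
    than silently truncated.
    """
    if truth.n_frames == 0:
        raise ValueError("empty ground truth")
    optics = optics or Optics()
    if optics.worm_width_mm >= truth.worm_length_mm:
        raise ValueError("worm width must be smaller than worm length")
    H, W = optics.image_shape
    rng = np.random.default_rng(optics.seed)
    px = truth.pixel_size_mm

    # periodic world texture (units: intensity)
    tex_n = 512
    texture = gaussian_filter(
        rng.standard_normal((tex_n, tex_n)), optics.texture_sigma_px, mode="wrap"
    )
    texture *= optics.texture_amp / max(texture.std(), 1e-12)

    n = truth.n_frames
    if optics.dark_worm:
        bg_level, worm_level = optics.background_level, optics.worm_level
    else:
        bg_level, worm_level = optics.worm_level, optics.background_level
    contrast = abs(bg_level - worm_level)

    stack = np.empty((n, H, W), dtype=np.float32)
    masks = np.zeros((n, H, W), dtype=bool) if keep_masks else None
    out_of_view: list[int] = []
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    for i in range(n):
        sx, sy = truth.stage_mm[i] / px
        if optics.texture_amp > 0:
            coords = np.array([rr + sy - cy, cc + sx - cx])
            bg = bg_level + map_coordinates(
                texture, coords.reshape(2, -1), order=3, mode="grid-wrap"
            ).reshape(H, W)
        else:
            bg = np.full((H, W), bg_level)
        alpha, mask, ok = _rasterize_worm(
            truth.skeletons_mm[i], truth.stage_mm[i], optics, px
        )
        frame = bg * (1 - alpha) + worm_level * alpha
        if optics.noise_frac > 0:
            frame = frame + optics.noise_frac * contrast * rng.standard_normal(
                (H, W)
            )
        stack[i] = frame
        if masks is not None:
            masks[i] = mask
        if not ok:
            out_of_view.append(i)

    if optics.dtype == "uint8":
        stack = np.clip(stack * 255.0, 0, 255).astype(np.uint8)
    elif optics.dtype == "uint16":
        stack = np.clip(stack * 65535.0, 0, 65535).astype(np.uint16)

    stage_rep = truth.stage_mm.copy()
    if stage_report_noise_mm > 0:
        stage_rep = stage_rep + stage_report_noise_mm * rng.standard_normal(
            stage_rep.shape
        )
    return SyntheticRecording(
        stack=stack,
        timestamps=truth.timestamps.copy(),
        stage_mm=stage_rep,
        truth=truth,
        events=list(truth.events),
        true_masks=masks,
        out_of_view=out_of_view,
        optics=optics,
    )


def simulate(schedule: LocomotionSchedule, optics: Optics | None = None,
             **render_kwargs) -> SyntheticRecording:
    """Convenience: generate_track + render_frames."""
    return render_frames(generate_track(schedule), optics, **render_kwargs)


# ---------------------------------------------------------------------------
# persistence


def save_recording(rec: SyntheticRecording, outdir) -> None:
    """Write stack (TIFF), ground-truth table (CSV) and stimulus log (JSON)."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "stack.tif", rec.stack)
    rec.truth.to_dataframe().to_csv(outdir / "ground_truth.csv", index=False)
    meta = {
        "frame_rate_hz": rec.frame_rate_hz,
        "pixel_size_mm": rec.pixel_size_mm,
        "timestamps_s": rec.timestamps.tolist(),
        "stage_mm": rec.stage_mm.tolist(),
        "out_of_view": rec.out_of_view,
    }
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh)
    with open(outdir / "stimuli.json", "w") as fh:
        json.dump([e.to_dict() for e in rec.events], fh, indent=2)


# ---------------------------------------------------------------------------
# thermometry stacks


@dataclass
class ThermoTruth:
    """Ground truth for a synthetic dual-channel thermometry recording."""

    amplitude_C: float
    sigma_um: float
    tau_s: float
    slope_per_C: float
    pixel_um: float
    center_px: tuple[float, float]  # (row, col)
    pulse_onsets_s: np.ndarray
    timestamps: np.ndarray

    def delta_T_field(self, t_s: float, shape: tuple[int, int]) -> np.ndarray:
        """Analytic true temperature-change field at time t (°C)."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        r2 = (rr - self.center_px[0]) ** 2 + (cc - self.center_px[1]) ** 2
        sigma_px = self.sigma_um / self.pixel_um
        g = np.exp(-r2 / (2 * sigma_px**2))
        h = 0.0
        for t0 in self.pulse_onsets_s:
            if t_s >= t0:
                h += np.exp(-(t_s - t0) / self.tau_s)
        return self.amplitude_C * h * g

    def roi_mean_peak(self, roi_diameter_px: float, dt_after_onset: float) -> float:
        """Closed-form mean of the Gaussian ΔT over a centered circular ROI."""
        R = roi_diameter_px / 2.0
        sigma_px = self.sigma_um / self.pixel_um
        disk_avg = (2 * sigma_px**2 / R**2) * (1 - np.exp(-(R**2) / (2 * sigma_px**2)))
        return float(
            self.amplitude_C * np.exp(-dt_after_onset / self.tau_s) * disk_avg
        )


@dataclass
class ThermoStack:
    """Dual-excitation stack: full 490 nm series + 440 nm endpoint frames."""

    ch490: np.ndarray  # (n, H, W) float32
    ch440_start: np.ndarray
    ch440_end: np.ndarray
    timestamps: np.ndarray
    pulse_onsets_s: np.ndarray
    truth: ThermoTruth


def generate_thermo_stack(
    amplitude_C: float = 0.7,
    sigma_um: float = 20.0,
    tau_s: float = 2.5,
    slope_per_C: float = 0.02,
    n_pulses: int = 25,
    pulse_period_s: float = 6.0,
    frame_rate_hz: float = 20.0,
    shape: tuple[int, int] = (128, 128),
    pixel_um: float = 0.6233,
    base_440: float = 1000.0,
    base_ratio: float = 1.0,
    drift_440_frac: float = 0.05,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> ThermoStack:
    """Render a dual-channel BCECF stack encoding a known ΔT field.

    The temperature-insensitive 440 nm channel drifts linearly between its
    start and end frames (emulating dye redistribution); the 490/440 ratio
    carries a spatial Gaussian ΔT with instantaneous rise at each pulse
    onset and exponential decay (time constant ``tau_s``).  Pulses repeat
    every ``pulse_period_s`` (the stimulation cadence used for temperature
    characterization).
    """
    if slope_per_C == 0:
        raise ValueError("ratio-per-°C slope must be nonzero")
    if amplitude_C < 0:
        raise ValueError("pulse amplitude must be >= 0")
    if sigma_um <= 0 or tau_s <= 0:
        raise ValueError("spatial sigma and decay constant must be positive")

    rng = np.random.default_rng(seed)
    H, W = shape
    n_frames = int(round(n_pulses * pulse_period_s * frame_rate_hz))
    timestamps = np.arange(n_frames) / frame_rate_hz
    # first onset after a baseline window of 1 s
    onsets = 1.0 + pulse_period_s * np.arange(n_pulses)
    center = ((H - 1) / 2.0, (W - 1) / 2.0)

    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    sigma_px = sigma_um / pixel_um
    g = np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma_px**2)
    ).astype(np.float32)

    # temporal envelope: sum of causal exponentials
    h = np.zeros(n_frames, dtype=np.float64)
    for t0 in onsets:
        active = timestamps >= t0 - 1e-12
        h[active] += np.exp(-(timestamps[active] - t0) / tau_s)

    total = n_frames
    t_frac = timestamps / timestamps[-1] if n_frames > 1 else np.zeros(1)
    ch440_start = np.full((H, W), base_440, dtype=np.float32)
    ch440_end = ch440_start * (1.0 + drift_440_frac)
    # ratio(x, y, t) = base_ratio + slope * ΔT(x, y, t)
    ch490 = np.empty((total, H, W), dtype=np.float32)
    for i in range(total):
        ratio = base_ratio + slope_per_C * amplitude_C * h[i] * g
        b440 = base_440 * (1.0 + drift_440_frac * t_frac[i])
        frame = ratio * b440
        if noise_frac > 0:
            frame = frame + noise_frac * base_440 * rng.standard_normal((H, W))
        ch490[i] = frame
    if noise_frac > 0:
        ch440_start = ch440_start + noise_frac * base_440 * rng.standard_normal(
            (H, W)
        ).astype(np.float32)
        ch440_end = ch440_end + noise_frac * base_440 * rng.standard_normal(
            (H, W)
        ).astype(np.float32)

    truth = ThermoTruth(
        amplitude_C=amplitude_C,
        sigma_um=sigma_um,
        tau_s=tau_s,
        slope_per_C=slope_per_C,
        pixel_um=pixel_um,
        center_px=center,
        pulse_onsets_s=onsets,
        timestamps=timestamps,
    )
    return ThermoStack(
        ch490=ch490,
        ch440_start=ch440_start,
        ch440_end=ch440_end,
        timestamps=timestamps,
        pulse_onsets_s=onsets,
        truth=truth,
    )
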