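"""Translational and phase-velocity kinematics.

Translational velocity comes from the robustly spline-smoothed centroid
track, signed by the angle between the movement direction and the
centroid-to-head orientation vector.  Phase velocity comes from the angle
of the first two eigenworm coefficients: φ = tan⁻¹(−a₂/a₁), evaluated
with the full-quadrant arctangent and unwrapped over time, so ω = dφ/dt
is a signed undulation rate in cycles/s (positive = forward wave).
Frames where the phase derivative is dominated by noise — near-zero
(a₁, a₂), i.e. physiologically impossible jumps in ω — are removed by a
per-frame jump threshold plus a peak-based exclusion window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks

#: per-frame change in ω above which a frame is physiologically impossible
SPIKE_JUMP_THRESHOLD = 0.18  # cycles/s (per frame by default; see remove_phase_spikes)
PAUSE_OMEGA_THRESHOLD = 0.02  # cycles/s


@dataclass
class VelocitySeries:
    speed_mm_s: np.ndarray
    theta_rad: np.ndarray  # angle movement vs orientation, [0, pi]
    signed_mm_s: np.ndarray


@dataclass
class PhaseSeries:
    phi_cycles: np.ndarray  # unwrapped
    omega_cyc_s: np.ndarray
    removed: np.ndarray  # bool
    removal_reason: np.ndarray  # '' | 'jump' | 'peak-window' | 'undefined'
    domega_dt: np.ndarray


# ---------------------------------------------------------------------------
# centroid smoothing


def smooth_centroid(
    track_mm: np.ndarray,
    timestamps: np.ndarray | None = None,
    frame_rate_hz: float | None = None,
    n_robust_iter: int = 3,
) -> np.ndarray:
    """Penalized-spline smoothing with robustness iterations.

    The smoothing parameter is chosen by generalized cross-validation;
    residual outliers are down-weighted with Tukey's bisquare over a few
    iterations, so a single bad centroid (segmentation glitch) barely
    deflects the curve.  NaN frames are interpolated through.
    """
    track = np.asarray(track_mm, dtype=float)
    n = len(track)
    if n < 10:
        raise ValueError("need at least 10 frames to smooth a track")
    if timestamps is None:
        if frame_rate_hz is None:
            raise ValueError("provide timestamps or a frame rate")
        timestamps = np.arange(n) / frame_rate_hz
    t = np.asarray(timestamps, dtype=float)
    good = ~np.isnan(track).any(axis=1)
    if not good.any():
        raise ValueError("track has no valid frames")

    out = np.empty_like(track)
    for k in range(track.shape[1]):
        y = track[good, k]
        x = t[good]
        w = np.ones_like(y)
        for _ in range(max(n_robust_iter, 1)):
            spl = make_smoothing_spline(x, y, w=w)
            r = y - spl(x)
            mad = np.median(np.abs(r - np.median(r)))
            scale = max(6.0 * mad, 1e-12)
            u = np.clip(r / scale, -1, 1)
            w = (1 - u**2) ** 2 + 1e-6
        out[:, k] = spl(t)
    return out


def heading_sign(
    centroid_mm: np.ndarray,
    head_mm: np.ndarray,
) -> VelocitySeries:
    """Sign translational motion by movement vs body orientation.

    θ is the angle between the frame-to-frame centroid movement vector and
    the centroid→head orientation vector; motion is forward (positive) for
    θ < π/2 and reverse for θ > π/2.  Zero-length movement carries the
    previous sign.  Speeds are per-frame displacements; multiply by the
    frame rate for mm/s, or pass a smoothed track sampled in seconds.
    """
    c = np.asarray(centroid_mm, dtype=float)
    h = np.asarray(head_mm, dtype=float)
    n = len(c)
    move = np.vstack([[0, 0], np.diff(c, axis=0)])
    orient = h - c
    theta = np.full(n, np.nan)
    sign = np.ones(n)
    prev_sign = 1.0
    for i in range(n):
        m = move[i]
        o = orient[i]
        nm, no = np.linalg.norm(m), np.linalg.norm(o)
        if nm < 1e-12 or no < 1e-12 or np.isnan(m).any() or np.isnan(o).any():
            sign[i] = prev_sign
            continue
        cosang = np.clip(m @ o / (nm * no), -1, 1)
        theta[i] = np.arccos(cosang)
        sign[i] = 1.0 if theta[i] < np.pi / 2 else -1.0
        prev_sign = sign[i]
    speed = np.linalg.norm(move, axis=1)
    return VelocitySeries(speed_mm_s=speed, theta_rad=theta,
                          signed_mm_s=sign * speed)


def velocity_from_track(
    smoothed_mm: np.ndarray,
    head_mm: np.ndarray,
    frame_rate_hz: float,
) -> VelocitySeries:
    """Speed (mm/s) and signed velocity from a smoothed world track."""
    vs = heading_sign(smoothed_mm, head_mm)
    return VelocitySeries(
        speed_mm_s=vs.speed_mm_s * frame_rate_hz,
        theta_rad=vs.theta_rad,
        signed_mm_s=vs.signed_mm_s * frame_rate_hz,
    )


# ---------------------------------------------------------------------------
# phase


def phase(modes: np.ndarray, eps: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped undulation phase from the (a1, a2) quadrature pair.

    φ = atan2(−a₂, a₁), unwrapped over time and reported in cycles.  The
    principal value matches tan⁻¹(−a₂/a₁) wherever that is defined; the
    full-quadrant form plus unwrapping is what makes the phase continuous
    across quadrant boundaries.  Frames with a₁ ≈ a₂ ≈ 0 have no defined
    phase and are flagged.

    Returns (phi_cycles, undefined_flags).
    """
    A = np.asarray(modes, dtype=float)
    a1, a2 = A[:, 0], A[:, 1]
    undefined = (np.abs(a1) < eps) & (np.abs(a2) < eps)
    undefined |= np.isnan(a1) | np.isnan(a2)
    raw = np.arctan2(-a2, a1)
    filled = raw.copy()
    if undefined.any() and (~undefined).any():
        idx = np.arange(len(raw))
        filled[undefined] = np.interp(idx[undefined], idx[~undefined],
                                      raw[~undefined])
    phi = np.unwrap(filled) / (2 * np.pi)
    phi[np.isnan(raw)] = np.nan
    return phi, undefined


def phase_velocity(phi_cycles: np.ndarray, frame_rate_hz: float) -> np.ndarray:
    """ω = dφ/dt, central differences inside, one-sided at the ends."""
    phi = np.asarray(phi_cycles, dtype=float)
    return np.gradient(phi) * frame_rate_hz


def align_phase_sign(
    omega: np.ndarray,
    signed_v: np.ndarray,
    min_speed_mm_s: float = 0.02,
) -> tuple[np.ndarray, bool]:
    """Tie the global sign of ω to the translational heading.

    A recording-derived eigenworm basis fixes mode signs only up to
    convention, so the winding direction of (a1, a2) is arbitrary; the
    worm's translational direction is the physical anchor (forward motion
    must carry a forward-traveling wave).  The product sign(ω)·sign(v) is
    positive on both forward and reverse frames when the convention is
    right, so a negative majority vote flips ω globally.

    Returns (possibly flipped ω, whether a flip was applied).
    """
    omega = np.asarray(omega, dtype=float)
    v = np.asarray(signed_v, dtype=float)
    ok = (
        ~np.isnan(omega)
        & ~np.isnan(v)
        & (np.abs(v) > min_speed_mm_s)
        & (np.abs(omega) > PAUSE_OMEGA_THRESHOLD)
    )
    score = np.sum(np.sign(omega[ok]) * np.sign(v[ok]))
    if score < 0:
        return -omega, True
    return omega, False


def remove_phase_spikes(
    omega: np.ndarray,
    frame_rate_hz: float,
    jump_threshold: float = SPIKE_JUMP_THRESHOLD,
    jump_per_second: bool = False,
    peak_stats: tuple[float, float] | None = None,
    undefined: np.ndarray | None = None,
) -> PhaseSeries:
    """Drop frames whose phase velocity changes implausibly fast.

    Two rules: (i) frames where |dω/dt| exceeds ``jump_threshold`` —
    interpreted by default as a per-frame change in ω of 0.18 cycles/s
    (set ``jump_per_second`` to read it as 0.18 cycles/s²); (ii) peaks in
    |dω/dt| higher than mean + 3 std (statistics from ``peak_stats``, a
    reference population's (mean, std), or from the recording itself),
    with frames within half the peak width before and after each peak
    removed.  A recording losing more than half its frames is marked
    low-quality via the returned flags (caller decides what to do).
    """
    w = np.asarray(omega, dtype=float).copy()
    n = len(w)
    dw = np.gradient(w)  # per-frame change in ω, cycles/s
    if jump_per_second:
        dw_rate = dw * frame_rate_hz  # cycles/s²
    else:
        dw_rate = dw
    removed = np.zeros(n, dtype=bool)
    reason = np.array([""] * n, dtype=object)

    if undefined is not None:
        removed |= np.asarray(undefined, dtype=bool)
        reason[np.asarray(undefined, dtype=bool)] = "undefined"

    with np.errstate(invalid="ignore"):
        jump = np.abs(dw_rate) > jump_threshold
    jump &= ~np.isnan(dw_rate)
    reason[jump & ~removed] = "jump"
    removed |= jump

    mag = np.abs(np.nan_to_num(dw_rate))
    if peak_stats is not None:
        mu, sd = peak_stats
    else:
        mu, sd = float(mag.mean()), float(mag.std())
    height = mu + 3 * sd
    if sd > 0:
        peaks, props = find_peaks(mag, height=height, width=1e-6,
                                  rel_height=0.5)
        for p, width in zip(peaks, props["widths"]):
            half = width / 2.0
            lo = max(0, int(np.floor(p - half)))
            hi = min(n, int(np.ceil(p + half)) + 1)
            newly = np.zeros(n, dtype=bool)
            newly[lo:hi] = True
            reason[newly & ~removed] = "peak-window"
            removed |= newly

    w[removed] = np.nan
    phi_dummy = np.full(n, np.nan)
    return PhaseSeries(phi_cycles=phi_dummy, omega_cyc_s=w, removed=removed,
                       removal_reason=reason, domega_dt=dw_rate)


def kinematics_table(
    timestamps: np.ndarray,
    velocity: VelocitySeries,
    modes: np.ndarray,
    phi: np.ndarray,
    ps: PhaseSeries,
):
    """Assemble the per-frame kinematics table written by the pipeline."""
    import pandas as pd

    n = len(timestamps)
    df = pd.DataFrame({
        "frame": np.arange(n),
        "time_s": timestamps,
        "speed_mm_s": velocity.speed_mm_s,
        "signed_v_mm_s": velocity.signed_mm_s,
        "theta_rad": velocity.theta_rad,
    })
    for k in range(modes.shape[1]):
        df[f"a{k+1}"] = modes[:, k]
    df["phi_cycles"] = phi
    df["omega_cyc_s"] = ps.omega_cyc_s
    df["removed_flag"] = ps.removed
    df["removal_reason"] = [str(r) for r in ps.removal_reason]
    return df
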