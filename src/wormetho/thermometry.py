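"""Ratiometric (BCECF / TRIS) thermometry of targeted laser pulses.

The pH-sensitive dye BCECF in temperature-sensitive TRIS buffer converts
local heating into a change of the 490/440 nm excitation ratio.  The
temperature-insensitive 440 nm channel is captured only at the start and
end of a session and linearly interpolated per pixel; the ratio change
relative to a 3-frame pre-stimulus baseline, divided by the calibrated
Δratio-per-°C slope (pre/post session fits averaged), yields ΔT(x, y, t).
The headline number is the mean ΔT over a 60 px (37.4 μm) circular ROI at
the beam center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_ROI_DIAMETER_PX = 60
DEFAULT_ROI_DIAMETER_UM = 37.4
N_BASELINE_FRAMES = 3


@dataclass
class ThermoCalibration:
    slope_pre: float  # Δratio per °C
    slope_post: float
    residual_pre: float = 0.0
    residual_post: float = 0.0

    @property
    def slope(self) -> float:
        """Average of the pre- and post-experiment calibration slopes."""
        return 0.5 * (self.slope_pre + self.slope_post)


def interpolate_insensitive(
    start_frame: np.ndarray,
    end_frame: np.ndarray,
    timestamps: np.ndarray,
) -> np.ndarray:
    """Per-pixel linear interpolation of the 440 nm channel over time."""
    if start_frame is None or end_frame is None:
        raise ValueError("both 440 nm endpoint frames are required")
    a = np.asarray(start_frame, dtype=float)
    b = np.asarray(end_frame, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if len(t) == 1:
        frac = np.zeros(1)
    else:
        frac = (t - t[0]) / (t[-1] - t[0])
    return a[None] + frac[:, None, None] * (b - a)[None]


def fit_calibration_session(
    ratios: np.ndarray, temperatures_C: np.ndarray
) -> tuple[float, float]:
    """OLS fit of mean ratio vs temperature for one calibration session.

    Returns (slope per °C, rms residual).  Needs at least two set points.
    """
    r = np.asarray(ratios, dtype=float)
    T = np.asarray(temperatures_C, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 temperature set points per session")
    coef = np.polyfit(T, r, 1)
    resid = r - np.polyval(coef, T)
    return float(coef[0]), float(np.sqrt(np.mean(resid**2)))


def calibrate(
    ratios_pre: np.ndarray,
    temps_pre: np.ndarray,
    ratios_post: np.ndarray,
    temps_post: np.ndarray,
    residual_warn_frac: float = 0.05,
) -> ThermoCalibration:
    """Fit the Δratio/ΔT slope before and after stimulation and average.

    A residual above ``residual_warn_frac`` of the session's ratio range
    (non-linear or non-monotone ratio vs T) triggers a warning.
    """
    import warnings

    s_pre, r_pre = fit_calibration_session(ratios_pre, temps_pre)
    s_post, r_post = fit_calibration_session(ratios_post, temps_post)
    for name, resid, vals in (("pre", r_pre, ratios_pre),
                              ("post", r_post, ratios_post)):
        rng = np.ptp(np.asarray(vals, dtype=float))
        if rng > 0 and resid > residual_warn_frac * rng:
            warnings.warn(
                f"{name}-session calibration residual {resid:.3g} exceeds "
                f"{residual_warn_frac:.0%} of the ratio range; fit may be "
                "non-linear", stacklevel=2)
    return ThermoCalibration(slope_pre=s_pre, slope_post=s_post,
                             residual_pre=r_pre, residual_post=r_post)


def compute_ratio_stack(
    ch490: np.ndarray,
    ch440_start: np.ndarray,
    ch440_end: np.ndarray,
    timestamps: np.ndarray,
    dark_offset: float = 0.0,
) -> np.ndarray:
    """490/440 ratio per frame, with the 440 estimate interpolated in time."""
    est440 = interpolate_insensitive(ch440_start, ch440_end, timestamps)
    num = np.asarray(ch490, dtype=float) - dark_offset
    den = est440 - dark_offset
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
    return ratio


def align_average_pulses(
    stack: np.ndarray,
    timestamps: np.ndarray,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = (-0.5, 4.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Average pulse-aligned windows of a stack pixel-wise.

    Windows are defined in frames around each onset on a common relative
    grid; overlapping windows are an error naming the offending pulses.
    Returns (mean stack over pulses, relative times of the window frames).
    """
    t = np.asarray(timestamps, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if len(onsets) == 0:
        raise ValueError("need at least one pulse onset")
    if len(onsets) > 1:
        span = window_s[1] - window_s[0]
        gaps = np.diff(np.sort(onsets))
        bad = np.flatnonzero(gaps < span)
        if bad.size:
            raise ValueError(
                f"alignment windows overlap for pulses {bad[0]} and "
                f"{bad[0] + 1}: spacing {gaps[bad[0]]:.2f} s < window "
                f"{span:.2f} s")
    dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
    pre_frames = int(round(-window_s[0] / dt))
    post_frames = int(round(window_s[1] / dt))
    windows = []
    for t0 in onsets:
        i0 = int(np.searchsorted(t, t0 - 1e-9))
        lo, hi = i0 - pre_frames, i0 + post_frames
        if lo < 0 or hi > len(stack):
            continue
        windows.append(stack[lo:hi])
    if not windows:
        raise ValueError("no pulse window fits inside the recording")
    mean_stack = np.mean(windows, axis=0)
    t_rel = (np.arange(-pre_frames, post_frames)) * dt
    return mean_stack, t_rel


def delta_ratio_to_temperature(
    mean_stack: np.ndarray,
    cal: ThermoCalibration,
    n_baseline: int = N_BASELINE_FRAMES,
) -> np.ndarray:
    """ΔT(x, y, t) = (ratio - pre-stimulus baseline) / averaged slope.

    The baseline is the pixel-wise mean of the ``n_baseline`` frames
    immediately before the pulse (the stack must start pre-stimulus).
    """
    if cal.slope == 0:
        raise ValueError("calibration slope is zero")
    if len(mean_stack) < n_baseline:
        raise ValueError(
            f"need at least {n_baseline} pre-stimulus frames for a baseline")
    baseline = mean_stack[:n_baseline].mean(axis=0)
    return (mean_stack - baseline[None]) / cal.slope


def circular_roi_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    diameter_px: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    if (
        center[0] - diameter_px / 2 < -0.5
        or center[1] - diameter_px / 2 < -0.5
        or center[0] + diameter_px / 2 > shape[0] - 0.5
        or center[1] + diameter_px / 2 > shape[1] - 0.5
    ):
        raise ValueError("ROI does not fit inside the field of view")
    return r2 <= (diameter_px / 2) ** 2


def beam_center(delta_T: np.ndarray, smooth_px: float = 4.0) -> tuple[int, int]:
    """Estimate the beam center as the arg-max of the time-maximum ΔT map.

    The map is Gaussian-smoothed first: the raw per-pixel time-max is an
    extreme-value statistic whose arg-max wanders under photon noise.
    """
    from scipy.ndimage import gaussian_filter

    peak_map = np.nanmax(delta_T, axis=0)
    if smooth_px > 0:
        peak_map = gaussian_filter(peak_map, smooth_px)
    idx = np.unravel_index(np.nanargmax(peak_map), peak_map.shape)
    return int(idx[0]), int(idx[1])


def peak_temperature(
    delta_T: np.ndarray,
    roi_diameter_px: float = DEFAULT_ROI_DIAMETER_PX,
    center: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Mean ΔT over the beam-centered circular ROI, per frame, plus its max."""
    if center is None:
        center = beam_center(delta_T)
    roi = circular_roi_mask(delta_T.shape[1:], center, roi_diameter_px)
    series = delta_T[:, roi].mean(axis=1)
    return series, float(np.nanmax(series))


def analyze_pulse_stack(
    ch490: np.ndarray,
    ch440_start: np.ndarray,
    ch440_end: np.ndarray,
    timestamps: np.ndarray,
    onsets_s: np.ndarray,
    cal: ThermoCalibration,
    roi_diameter_px: float = DEFAULT_ROI_DIAMETER_PX,
    window_s: tuple[float, float] = (-0.5, 4.0),
    dark_offset: float = 0.0,
) -> dict:
    """Full chain: ratio -> pulse-aligned average -> ΔT -> ROI peak series."""
    ratio = compute_ratio_stack(ch490, ch440_start, ch440_end, timestamps,
                                dark_offset)
    mean_stack, t_rel = align_average_pulses(ratio, timestamps, onsets_s,
                                             window_s)
    n_base = int(np.sum(t_rel < 0))
    n_base = max(min(n_base, N_BASELINE_FRAMES), 1)
    # baseline = the 3 frames immediately pre-stimulus
    pre = np.flatnonzero(t_rel < 0)
    base_idx = pre[-N_BASELINE_FRAMES:] if len(pre) >= N_BASELINE_FRAMES else pre
    baseline = mean_stack[base_idx].mean(axis=0)
    if cal.slope == 0:
        raise ValueError("calibration slope is zero")
    delta_T = (mean_stack - baseline[None]) / cal.slope
    series, peak = peak_temperature(delta_T, roi_diameter_px)
    return {
        "t_rel_s": t_rel,
        "delta_T": delta_T,
        "roi_series_C": series,
        "peak_C": peak,
        "n_pulses": len(np.atleast_1d(onsets_s)),
    }
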