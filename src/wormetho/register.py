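"""Stage-motion registration, coordinate calibrations, and head targeting.

The tracking stage moves to keep the worm in view, so the camera's pixel
frame slides over the world.  Stage motion is recovered from image content
by subpixel phase correlation of worm-free frame edges (DFT-based
registration with local upsampling); pairwise shifts at lags 1, 2 and 3
are combined to suppress accumulated noise, and the integrated trajectory
is anchored at the reported stage start position.  Affine calibrations map
pixels to stage millimetres and galvanometer volts to pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from wormetho.core import arc_length_resample


@dataclass
class CalibrationTransform:
    """Affine map y = A x + b between two planar coordinate systems."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if np.linalg.cond(self.matrix) > 1e6:
            raise ValueError("calibration matrix is singular or near-singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "CalibrationTransform":
        inv = np.linalg.inv(self.matrix)
        return CalibrationTransform(inv, -inv @ self.offset, self.residual)

    def to_json(self, path) -> None:
        import datetime

        data = {
            "matrix": self.matrix.tolist(),
            "offset": self.offset.tolist(),
            "residual": self.residual,
            "timestamp": datetime.datetime.now().isoformat(),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationTransform":
        with open(path) as fh:
            data = json.load(fh)
        return cls(np.array(data["matrix"]), np.array(data["offset"]),
                   data.get("residual", 0.0))


def _affine_fit(src: np.ndarray, dst: np.ndarray) -> CalibrationTransform:
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 3:
        raise ValueError("need at least 3 point pairs for an affine fit")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError("calibration points are collinear")
    X = np.hstack([src, np.ones((len(src), 1))])
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    A = coef[:2].T
    b = coef[2]
    pred = src @ A.T + b
    residual = float(np.sqrt(((pred - dst) ** 2).sum(axis=1).mean()))
    return CalibrationTransform(A, b, residual)


def calibrate_stage(
    pixel_positions: np.ndarray, stage_positions_mm: np.ndarray
) -> CalibrationTransform:
    """Fit the pixel -> mm map from a tracked stationary object.

    When the stage moves by Δ mm, a stationary object appears to move by
    -A⁻¹Δ px; equivalently its world position, pixel-mapped plus stage
    position, is constant.  The least-squares affine fit absorbs axis
    inversions and rotations.  Requires ≥ 3 non-collinear observations.
    """
    return _affine_fit(pixel_positions, stage_positions_mm)


def calibrate_galvo(
    voltages: np.ndarray, beam_pixels: np.ndarray
) -> tuple[CalibrationTransform, CalibrationTransform]:
    """Fit volt -> pixel (and its inverse) from observed burn spots."""
    fwd = _affine_fit(voltages, beam_pixels)
    return fwd, fwd.inverse()


# ---------------------------------------------------------------------------
# shift estimation


def edge_region_mask(
    shape: tuple[int, int],
    border_frac: float = 0.15,
    worm_mask: np.ndarray | None = None,
    worm_dilate_px: int = 5,
) -> np.ndarray:
    """Border annulus of the frame, minus a dilated worm mask."""
    H, W = shape
    bh, bw = int(round(border_frac * H)), int(round(border_frac * W))
    region = np.zeros((H, W), dtype=bool)
    region[:bh] = region[-bh:] = True
    region[:, :bw] = region[:, -bw:] = True
    if worm_mask is not None and worm_mask.any():
        grown = ndimage.binary_dilation(worm_mask, iterations=worm_dilate_px)
        region &= ~grown
    return region


@dataclass
class ShiftEstimate:
    dx: float  # columns (x), px
    dy: float  # rows (y), px
    confident: bool = True


def estimate_shift(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    region: np.ndarray | None = None,
    upsample: int = 100,
    min_texture: float = 1e-3,
) -> ShiftEstimate:
    """Subpixel translation of ``frame_b`` relative to ``frame_a``.

    Phase correlation with local DFT upsampling.  Pixels outside ``region``
    are replaced by the region mean so the worm body (which moves
    independently of the stage) cannot bias the estimate.  A textureless
    region yields a low-confidence (0, 0) estimate instead of noise.

    The returned (dx, dy) is the displacement of the camera window over
    the static scene from a to b — i.e. the stage motion in pixels; scene
    content appears to move by the negative of this.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if region is not None:
        a = np.where(region, a, a[region].mean() if region.any() else 0.0)
        b = np.where(region, b, b[region].mean() if region.any() else 0.0)
        texture = min(a[region].std(), b[region].std()) if region.any() else 0.0
    else:
        texture = min(a.std(), b.std())
    if texture < min_texture * max(abs(a).max(), abs(b).max(), 1.0):
        return ShiftEstimate(0.0, 0.0, confident=False)

    # Hann windowing suppresses spectral leakage from the non-periodic
    # crop; a two-pass (integer then subpixel-residual) estimate removes
    # the window-mismatch bias that grows with shift magnitude.
    win = np.outer(np.hanning(a.shape[0]), np.hanning(a.shape[1]))

    def _pcc(x, y, factor):
        sh, _, _ = phase_cross_correlation(
            (x - x.mean()) * win, (y - y.mean()) * win,
            upsample_factor=factor, normalization=None,
        )
        return sh

    coarse = _pcc(a, b, 1)
    rolled = np.roll(b, (int(coarse[0]), int(coarse[1])), axis=(0, 1))
    fine = _pcc(a, rolled, upsample)
    shift = np.array([int(coarse[0]), int(coarse[1])]) + fine
    # skimage returns the (row, col) offset registering b onto a, which
    # with our (x=col, y=down-row) convention is the camera/stage motion
    return ShiftEstimate(dx=float(shift[1]), dy=float(shift[0]))


@dataclass
class StageTrajectory:
    position_mm: np.ndarray  # (n, 2)
    source: np.ndarray  # (n,) str: "reported" | "estimated" | "interpolated"

    def __len__(self) -> int:
        return len(self.position_mm)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "x_mm": self.position_mm[:, 0],
                "y_mm": self.position_mm[:, 1],
                "source": self.source,
            }
        ).to_csv(path, index=False)


def _edge_strips(shape: tuple[int, int], border_frac: float) -> list[tuple]:
    """Four border strips, each tagged with its long (accurate) axis."""
    H, W = shape
    bh = max(int(round(border_frac * H)), 16)
    bw = max(int(round(border_frac * W)), 16)
    return [
        ((slice(0, bh), slice(0, W)), "x"),
        ((slice(H - bh, H), slice(0, W)), "x"),
        ((slice(0, H), slice(0, bw)), "y"),
        ((slice(0, H), slice(W - bw, W)), "y"),
    ]


def estimate_strip_shift(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    worm_mask: np.ndarray | None = None,
    border_frac: float = 0.15,
    worm_dilate_px: int = 5,
    upsample: int = 100,
) -> ShiftEstimate:
    """Stage shift from the worm-free edge strips of a frame pair.

    Each of the four border strips is registered independently (strips the
    dilated worm mask touches are dropped).  A strip constrains its long
    axis far better than its short axis — the fixed-window bias scales
    inversely with window extent — so only the long-axis component of each
    strip is kept: x from the top/bottom strips, y from the left/right
    ones.  Falls back to the whole-frame estimate when the worm
    contaminates every strip of one orientation.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    grown = None
    if worm_mask is not None and worm_mask.any():
        grown = ndimage.binary_dilation(worm_mask, iterations=worm_dilate_px)
    comp = {"x": [], "y": []}
    for (rows, cols), axis in _edge_strips(a.shape, border_frac):
        if grown is not None and grown[rows, cols].any():
            continue
        est = estimate_shift(a[rows, cols], b[rows, cols], upsample=upsample)
        if est.confident:
            comp[axis].append(est.dx if axis == "x" else est.dy)
    if not comp["x"] or not comp["y"]:
        return estimate_shift(a, b, upsample=upsample)
    return ShiftEstimate(float(np.mean(comp["x"])), float(np.mean(comp["y"])))


def estimate_frame_shifts(
    stack: np.ndarray,
    worm_masks: list[np.ndarray] | None = None,
    lags: tuple[int, ...] = (1, 2, 3),
    border_frac: float = 0.15,
    upsample: int = 100,
) -> dict[int, np.ndarray]:
    """Pairwise stage shifts (dx, dy) px at each requested lag.

    Entry ``[lag][i]`` is the stage displacement over frames
    ``i-lag -> i`` (NaN for ``i < lag`` or low-confidence estimates).
    """
    n = len(stack)
    out = {lag: np.full((n, 2), np.nan) for lag in lags}
    for lag in lags:
        for i in range(lag, n):
            wm = None
            if worm_masks is not None:
                wm = worm_masks[i] | worm_masks[i - lag]
            est = estimate_strip_shift(stack[i - lag], stack[i], wm,
                                       border_frac, upsample=upsample)
            if est.confident:
                out[lag][i] = (est.dx, est.dy)
    return out


def integrate_stage_motion(
    shifts: dict[int, np.ndarray],
    start_mm: np.ndarray,
    cal: CalibrationTransform | None = None,
    pixel_size_mm: float | None = None,
) -> StageTrajectory:
    """Integrate pairwise shifts into a stage trajectory in mm.

    The per-frame increment is the average of the lag-1 shift with the
    lag-2 and lag-3 shifts scaled to per-frame units, which suppresses the
    accumulation of independent per-pair noise.  The pixel increments are
    mapped through the linear part of the calibration (or an isotropic
    pixel size) and cumulatively summed from the reported start position.
    """
    if cal is None and pixel_size_mm is None:
        raise ValueError("provide a calibration or a pixel size")
    lags = sorted(shifts)
    n = len(shifts[lags[0]])
    inc_px = np.zeros((n, 2))
    interpolated = np.zeros(n, dtype=bool)
    for i in range(1, n):
        cands = []
        for lag in lags:
            if i >= lag and not np.isnan(shifts[lag][i]).any():
                cands.append(shifts[lag][i] / lag)
        if cands:
            inc_px[i] = np.mean(cands, axis=0)
        else:
            interpolated[i] = True
    # fill gaps by linear interpolation over increments
    if interpolated.any() and (~interpolated[1:]).any():
        idx = np.arange(n)
        goodi = idx[1:][~interpolated[1:]]
        for k in range(2):
            inc_px[interpolated, k] = np.interp(idx[interpolated], goodi,
                                                inc_px[goodi, k])

    if cal is not None:
        inc_mm = inc_px @ cal.matrix.T
    else:
        inc_mm = inc_px * pixel_size_mm
    pos = np.cumsum(inc_mm, axis=0) + np.asarray(start_mm, dtype=float)
    source = np.array(
        ["interpolated" if f else "estimated" for f in interpolated],
        dtype=object,
    )
    source[0] = "reported"
    return StageTrajectory(position_mm=pos, source=source)


def to_world(
    pixel_points: np.ndarray,
    stage_mm: np.ndarray,
    cal: CalibrationTransform,
) -> np.ndarray:
    """world = affine(pixel) + stage position."""
    return cal.apply(pixel_points) + np.asarray(stage_mm, dtype=float)


def from_world(
    world_points: np.ndarray,
    stage_mm: np.ndarray,
    cal: CalibrationTransform,
) -> np.ndarray:
    inv = cal.inverse()
    return inv.apply(np.asarray(world_points, dtype=float)
                     - np.asarray(stage_mm, dtype=float))


# ---------------------------------------------------------------------------
# head targeting


def target_head(
    skeleton,
    fraction: float = 0.2,
    speed_mm_s: float | None = None,
    frame_rate_hz: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Laser target on the worm's anterior, plus the predicted lag error.

    The target sits at arc-length ``fraction / 2`` from the head tip — the
    midpoint of the anterior body fraction (default: anterior fifth).  The
    predicted targeting error is the worm displacement over one frame
    interval, the latency between the frame used for targeting and the
    pulse.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if getattr(skeleton, "complex", False):
        raise ValueError("cannot target a complex (coiled) frame")
    if not getattr(skeleton, "oriented", True):
        raise ValueError("skeleton must be oriented to know the head")
    pts = skeleton.points if hasattr(skeleton, "points") else np.asarray(skeleton)
    fine = arc_length_resample(pts, 1001)
    target = fine[int(round(fraction / 2 * 1000))]
    lag_err = None
    if speed_mm_s is not None and frame_rate_hz is not None:
        lag_err = speed_mm_s / frame_rate_hz
    return target, lag_err
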