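"""Midline extraction, eigenworm posture decomposition, complex-frame
repair and head-tail orientation.

A worm's posture is summarized by the tangent-angle profile of its midline
(49 points, 48 angle samples).  Principal modes ("eigenworms") of the
mean-subtracted angle profiles span almost all crawling postures with four
components; during sinusoidal crawling the first two form a quadrature
pair, so the angle of (a1, a2) tracks progression through the undulation
cycle.  Frames where the body self-occludes (omega coils) defeat the
boundary-based midline finder and are instead repaired by interpolating
the mode coefficients through time and reconstructing the skeleton from
the interpolated posture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks, savgol_filter
from skimage import measure

from wormetho.core import arc_length_resample, polyline_length
from wormetho.segment import BinaryMask, QUALITY_OK

N_POINTS = 49
N_ANGLES = N_POINTS - 1
DEFAULT_K = 4


@dataclass
class Skeleton:
    """Ordered midline of the worm in pixel coordinates, head at index 0."""

    points: np.ndarray  # (N, 2) as (x, y) px
    frame: int = 0
    oriented: bool = False
    complex: bool = False
    reconstructed: bool = False

    @property
    def arc_length(self) -> float:
        return polyline_length(self.points)

    @property
    def head(self) -> np.ndarray:
        return self.points[0]

    @property
    def tail(self) -> np.ndarray:
        return self.points[-1]

    @property
    def head_tail_distance(self) -> float:
        return float(np.linalg.norm(self.points[0] - self.points[-1]))

    def flipped(self) -> "Skeleton":
        return Skeleton(self.points[::-1].copy(), self.frame, self.oriented,
                        self.complex, self.reconstructed)


def tangent_angles(points: np.ndarray) -> np.ndarray:
    """Tangent angle per inter-point gap, unwrapped along the body."""
    d = np.diff(np.asarray(points, float), axis=0)
    return np.unwrap(np.arctan2(d[:, 1], d[:, 0]))


@dataclass
class EigenwormBasis:
    """Orthonormal tangent-angle modes plus the ensemble mean profile."""

    modes: np.ndarray  # (K, M)
    mean_profile: np.ndarray  # (M,)
    explained_variance: np.ndarray  # (K,) fractions

    @property
    def k(self) -> int:
        return self.modes.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.modes.T,
                          columns=[f"mode{i+1}" for i in range(self.k)])
        df["mean_profile"] = self.mean_profile
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EigenwormBasis":
        import pandas as pd

        df = pd.read_csv(path)
        mode_cols = [c for c in df.columns if c.startswith("mode")]
        modes = df[mode_cols].to_numpy().T
        return cls(modes=modes, mean_profile=df["mean_profile"].to_numpy(),
                   explained_variance=np.full(len(mode_cols), np.nan))


# ---------------------------------------------------------------------------
# midline finding


def _mask_is_complex(mask: BinaryMask) -> bool:
    if mask.preserved_holes:
        return True
    m = mask.mask
    filled = ndimage.binary_fill_holes(m)
    if (filled & ~m).sum() > 0.01 * m.sum():
        return True
    return False


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of the mask as (x, y) points."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    c = max(contours, key=len)  # rows, cols
    return c[:, ::-1]  # -> (x, y)


def _smooth_closed(points: np.ndarray, sigma: float) -> np.ndarray:
    return np.column_stack(
        [ndimage.gaussian_filter1d(points[:, k], sigma, mode="wrap")
         for k in range(2)]
    )


def _boundary_curvature(points: np.ndarray) -> np.ndarray:
    """Signed curvature of a closed polyline (per vertex)."""
    d = np.gradient(points, axis=0)
    dd = np.gradient(d, axis=0)
    num = d[:, 0] * dd[:, 1] - d[:, 1] * dd[:, 0]
    den = (d[:, 0] ** 2 + d[:, 1] ** 2) ** 1.5
    return num / np.maximum(den, 1e-12)


def _find_tips(contour: np.ndarray, curvature: np.ndarray) -> tuple[int, int]:
    """Two boundary points of maximal convex curvature, roughly half a
    perimeter apart; ties broken by maximal separation."""
    n = len(contour)
    kappa = np.concatenate([curvature, curvature[: n // 4]])
    peaks, props = find_peaks(kappa, height=0)
    peaks = np.unique(peaks % n)
    if len(peaks) < 2:
        peaks = np.argsort(curvature)[-4:]
    best = None
    for ii in range(len(peaks)):
        for jj in range(ii + 1, len(peaks)):
            i, j = int(peaks[ii]), int(peaks[jj])
            sep = abs(i - j)
            sep = min(sep, n - sep) / n  # fraction of perimeter
            if sep < 0.3:
                continue
            score = curvature[i] + curvature[j]
            key = (score, sep)
            if best is None or key > best[0]:
                best = (key, (i, j))
    if best is None:
        i, j = int(np.argmax(curvature)), 0
        j = (i + n // 2) % n
        return i, j
    return best[1]


def midline_simple(mask: BinaryMask, n_points: int = N_POINTS,
                   tip_extend_px: float = 1.0) -> Skeleton:
    """Boundary-splitting midline finder for simple (non-coiled) postures.

    The boundary is split at the two curvature-extremal tip points, the two
    sides are arc-length matched, and the midline is their pointwise mean,
    resampled to ``n_points``.  Curvature is measured on a smoothed copy of
    the contour but the sides keep the raw (subpixel) boundary geometry.
    The half-intensity boundary clips the tapered tips by roughly the
    anti-aliasing edge width, so each end is extended by ``tip_extend_px``
    along its end tangent.  Self-occluding masks (preserved loop hole)
    raise the complex flag instead of emitting a skeleton.
    """
    if mask.quality != QUALITY_OK:
        raise ValueError(f"mask quality is {mask.quality!r}, not ok")
    if _mask_is_complex(mask):
        return Skeleton(points=np.full((n_points, 2), np.nan),
                        frame=mask.frame, complex=True)
    contour = _boundary(mask.mask)
    smoothed = _smooth_closed(contour, sigma=2.0)
    kappa = _boundary_curvature(smoothed)
    i, j = _find_tips(smoothed, kappa)
    if i > j:
        i, j = j, i
    side_a = contour[i : j + 1]
    side_b = np.concatenate([contour[j:], contour[: i + 1]])[::-1]
    m = 4 * n_points
    a = arc_length_resample(side_a, m)
    b = arc_length_resample(side_b, m)
    mid = 0.5 * (a + b)
    # light smoothing along the body knocks down boundary-staircase noise
    mid = np.column_stack(
        [ndimage.gaussian_filter1d(mid[:, k], 3.0, mode="nearest")
         for k in range(2)]
    )
    if tip_extend_px > 0:
        d0 = mid[0] - mid[6]
        d0 /= max(np.linalg.norm(d0), 1e-9)
        d1 = mid[-1] - mid[-7]
        d1 /= max(np.linalg.norm(d1), 1e-9)
        mid = np.vstack([mid[0] + tip_extend_px * d0, mid,
                         mid[-1] + tip_extend_px * d1])
    mid = arc_length_resample(mid, n_points)
    return Skeleton(points=mid, frame=mask.frame)


def midline_series(masks, n_points: int = N_POINTS,
                   tip_extend_px: float = 1.0) -> list[Skeleton]:
    """Midlines for a mask series; failed masks become complex frames."""
    out = []
    for i, m in enumerate(masks):
        if m.quality != QUALITY_OK:
            out.append(Skeleton(np.full((n_points, 2), np.nan), frame=i,
                                complex=True))
        else:
            out.append(midline_simple(m, n_points, tip_extend_px))
    return out


def flag_complex_frames(
    skeletons: list[Skeleton],
    rel_length_tol: float = 0.25,
    window: int = 41,
) -> np.ndarray:
    """Indices needing posture-space repair: frames whose midline failed
    outright plus skeleton-length outliers vs a running median."""
    if not skeletons:
        raise ValueError("empty skeleton series")
    n = len(skeletons)
    lengths = np.array(
        [np.nan if sk.complex else sk.arc_length for sk in skeletons]
    )
    flags = np.array([sk.complex for sk in skeletons])
    good = ~np.isnan(lengths)
    if good.any():
        med = np.full(n, np.nanmedian(lengths))
        half = window // 2
        for t in range(n):
            lo, hi = max(0, t - half), min(n, t + half + 1)
            v = lengths[lo:hi]
            v = v[~np.isnan(v)]
            if v.size:
                med[t] = np.median(v)
        with np.errstate(invalid="ignore"):
            outlier = np.abs(lengths - med) > rel_length_tol * med
        flags |= np.where(np.isnan(lengths), True, outlier)
    return np.flatnonzero(flags)


# ---------------------------------------------------------------------------
# eigenworm basis


def _centered_angles(skeleton_points: np.ndarray) -> np.ndarray:
    """Tangent-angle profile with the body-frame rotation removed."""
    ang = tangent_angles(skeleton_points)
    return ang - ang.mean()


def build_eigenbasis(
    skeletons: list[Skeleton] | np.ndarray,
    k: int = DEFAULT_K,
    min_samples: int = 100,
) -> EigenwormBasis:
    """Principal modes of the centered tangent-angle profiles.

    Mode signs follow a fixed convention (largest-magnitude element
    positive) so the basis is deterministic; the overall winding direction
    of (a1, a2) is later tied to the worm's translational heading.
    """
    if isinstance(skeletons, np.ndarray):
        profiles = [
            _centered_angles(p) for p in skeletons if not np.isnan(p).any()
        ]
    else:
        profiles = [
            _centered_angles(sk.points)
            for sk in skeletons
            if not sk.complex and not np.isnan(sk.points).any()
        ]
    if len(profiles) < min_samples:
        raise ValueError(
            f"need at least {min_samples} non-complex skeletons to build a "
            f"basis, got {len(profiles)}"
        )
    X = np.array(profiles)
    mean_profile = X.mean(axis=0)
    Xc = X - mean_profile
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(len(X) - 1, 1)
    modes = vt[:k]
    # deterministic sign convention
    for m in range(k):
        idx = np.argmax(np.abs(modes[m]))
        if modes[m][idx] < 0:
            modes[m] = -modes[m]
    return EigenwormBasis(
        modes=modes,
        mean_profile=mean_profile,
        explained_variance=var[:k] / var.sum(),
    )


def project_modes(skeleton: Skeleton, basis: EigenwormBasis,
                  require_oriented: bool = True) -> np.ndarray:
    """Mode coefficients a_1..a_K of one skeleton.

    The sign of every coefficient depends on which end is called the head,
    so projection demands an oriented skeleton unless explicitly waived.
    """
    if require_oriented and not skeleton.oriented:
        raise ValueError("skeleton must be head-tail oriented before "
                         "projection (mode signs depend on head choice)")
    prof = _centered_angles(skeleton.points) - basis.mean_profile
    return basis.modes @ prof


def project_series(
    skeletons: list[Skeleton], basis: EigenwormBasis,
    require_oriented: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Project a series; complex frames yield NaN rows.

    Returns (modes array (n, K), complex/missing flag array).
    """
    n = len(skeletons)
    A = np.full((n, basis.k), np.nan)
    flags = np.zeros(n, dtype=bool)
    for t, sk in enumerate(skeletons):
        if sk.complex or np.isnan(sk.points).any():
            flags[t] = True
            continue
        A[t] = project_modes(sk, basis, require_oriented=require_oriented)
    return A, flags


def reconstruct_angles(a: np.ndarray, basis: EigenwormBasis) -> np.ndarray:
    return basis.mean_profile + a @ basis.modes


# ---------------------------------------------------------------------------
# complex-frame interpolation


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    out = []
    n = len(flags)
    t = 0
    while t < n:
        if flags[t]:
            u = t
            while u < n and flags[u]:
                u += 1
            out.append((t, u))
            t = u
        else:
            t += 1
    return out


def interpolate_complex(
    modes: np.ndarray,
    complex_flags: np.ndarray,
    frame_rate_hz: float,
    basis: EigenwormBasis | None = None,
    skeletons: list[Skeleton] | None = None,
    max_gap_s: float = 2.0,
    smooth_window_s: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, list[Skeleton] | None]:
    """Repair complex frames by interpolating mode trajectories over time.

    Each mode is fitted with a GCV-smoothed spline over the non-complex
    frames and evaluated across complex runs; runs longer than
    ``max_gap_s`` (and runs touching the recording boundary) are marked
    missing rather than fabricated.  All frames receive light temporal
    smoothing (window <= 0.25 s) which mops up minor per-frame midline
    errors.  If a basis and the original skeletons are supplied, skeletons
    for repaired frames are rebuilt from the interpolated posture and
    flagged ``reconstructed``.

    Returns (completed modes, missing flags, skeletons or None).
    """
    modes = np.array(modes, dtype=float)
    n, k = modes.shape
    flags = np.asarray(complex_flags, dtype=bool).copy()
    missing = np.zeros(n, dtype=bool)
    t_all = np.arange(n) / frame_rate_hz
    good = ~flags & ~np.isnan(modes).any(axis=1)
    if good.sum() < 4:
        raise ValueError("too few non-complex frames to interpolate")

    max_gap = int(round(max_gap_s * frame_rate_hz))
    for a, b in _runs(~good):
        if a == 0 or b == n or (b - a) > max_gap:
            missing[a:b] = True

    out = modes.copy()
    fill = ~good & ~missing
    if fill.any():
        for j in range(k):
            spl = make_smoothing_spline(t_all[good], modes[good, j])
            out[fill, j] = spl(t_all[fill])
    out[missing] = np.nan

    # light smoothing of all defined frames
    win = int(round(smooth_window_s * frame_rate_hz))
    if win % 2 == 0:
        win += 1
    if win >= 5:
        defined = ~missing
        for a, b in _runs(defined):
            if b - a > win:
                out[a:b] = savgol_filter(out[a:b], win, polyorder=3, axis=0)

    recon: list[Skeleton] | None = None
    if basis is not None and skeletons is not None:
        recon = list(skeletons)
        lengths = [sk.arc_length for sk in skeletons
                   if not sk.complex and not np.isnan(sk.points).any()]
        L = float(np.median(lengths))
        centroids = np.array([
            sk.points.mean(axis=0) if not np.isnan(sk.points).any()
            else (np.nan, np.nan)
            for sk in skeletons
        ])
        rotations = np.array([
            tangent_angles(sk.points).mean()
            if not sk.complex and not np.isnan(sk.points).any() else np.nan
            for sk in skeletons
        ])
        good_c = ~np.isnan(rotations)
        rot_interp = np.interp(t_all, t_all[good_c],
                               np.unwrap(rotations[good_c]))
        cen_interp = np.column_stack([
            np.interp(t_all, t_all[~np.isnan(centroids[:, 0])],
                      centroids[~np.isnan(centroids[:, 0]), 0]),
            np.interp(t_all, t_all[~np.isnan(centroids[:, 1])],
                      centroids[~np.isnan(centroids[:, 1]), 1]),
        ])
        for t in np.flatnonzero(fill):
            ang = reconstruct_angles(out[t], basis)
            ang = ang - ang.mean() + rot_interp[t]
            ds = L / len(ang)
            steps = ds * np.column_stack([np.cos(ang), np.sin(ang)])
            pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            pts = pts - pts.mean(axis=0) + cen_interp[t]
            recon[t] = Skeleton(points=pts, frame=skeletons[t].frame,
                                oriented=skeletons[t].oriented,
                                complex=False, reconstructed=True)
    return out, missing, recon


# ---------------------------------------------------------------------------
# head-tail correction


@dataclass
class AnnotationRequest:
    frame: int
    reason: str


def correct_head_tail(
    skeletons: list[Skeleton],
    stimuli: list | None = None,
    anchors: list[tuple[int, np.ndarray]] | None = None,
    jump_factor: float = 0.5,
    tie_tol: float = 1e-6,
) -> tuple[list[Skeleton], np.ndarray, list[AnnotationRequest]]:
    """Orient every skeleton head-first using stimulus anchors.

    At each anchor frame the endpoint nearer the stimulus target (known to
    be at the head) is set as head; the orientation then propagates forward
    and backward choosing, per frame, the endpoint assignment that
    minimizes head displacement.  Anchors whose target is equidistant from
    both endpoints produce an annotation request instead of a silent
    choice, as do propagation steps whose best head jump exceeds
    ``jump_factor`` body lengths.

    `anchors` are (frame, head_position) pairs in the same coordinates as
    the skeletons; `stimuli` are StimulusEvent-like objects whose
    ``target_mm``/``frame`` must already be in skeleton coordinates (the
    pipeline converts world targets to pixels before calling).

    Returns (oriented series, flip mask vs input, annotation requests).
    """
    n = len(skeletons)
    anchor_list: list[tuple[int, np.ndarray]] = []
    requests: list[AnnotationRequest] = []
    if stimuli:
        for ev in stimuli:
            anchor_list.append((int(ev.frame), np.asarray(ev.target_mm, float)))
    if anchors:
        anchor_list.extend((int(f), np.asarray(p, float)) for f, p in anchors)
    anchor_list = [
        (f, p) for f, p in anchor_list
        if 0 <= f < n and not skeletons[f].complex
        and not np.isnan(skeletons[f].points).any()
    ]
    if not anchor_list:
        raise ValueError(
            "no usable head anchor: provide a stimulus event or annotate "
            "the head in one frame"
        )

    flip = np.zeros(n, dtype=bool)
    decided = np.zeros(n, dtype=bool)
    body_l = np.median([sk.arc_length for sk in skeletons
                        if not np.isnan(sk.points).any()])

    def head_of(t: int, flipped: bool) -> np.ndarray:
        pts = skeletons[t].points
        return pts[-1] if flipped else pts[0]

    for f, target in sorted(anchor_list):
        d0 = np.linalg.norm(head_of(f, False) - target)
        d1 = np.linalg.norm(head_of(f, True) - target)
        if abs(d0 - d1) <= tie_tol * max(d0, d1, 1.0):
            requests.append(AnnotationRequest(
                frame=f, reason="anchor equidistant from both endpoints"))
            continue
        flip[f] = d1 < d0
        decided[f] = True

    if not decided.any():
        raise ValueError("all anchors ambiguous; head annotation required")

    def propagate(t_from: int, t_to: int, step: int) -> None:
        prev = t_from
        for t in range(t_from + step, t_to, step):
            if decided[t]:
                prev = t
                continue
            if np.isnan(skeletons[t].points).any():
                continue
            ref = head_of(prev, flip[prev])
            d0 = np.linalg.norm(head_of(t, False) - ref)
            d1 = np.linalg.norm(head_of(t, True) - ref)
            flip[t] = d1 < d0
            decided[t] = True
            if abs(t - prev) > 1:
                # crossing a complex gap: the worm may have reoriented
                # while unobserved, so endpoint continuity is unreliable
                requests.append(AnnotationRequest(
                    frame=t, reason=f"orientation propagated across a "
                    f"{abs(t - prev)}-frame gap; annotate to confirm"))
            elif min(d0, d1) > jump_factor * body_l:
                requests.append(AnnotationRequest(
                    frame=t, reason="head jump exceeds threshold; "
                    "verify orientation"))
            prev = t

    # each frame takes its orientation from the nearest anchor, mirroring
    # the forward-and-backward sweep from every stimulus frame
    anchor_frames = sorted(np.flatnonzero(decided))
    propagate(anchor_frames[0], -1, -1)
    propagate(anchor_frames[-1], n, +1)
    for a, b in zip(anchor_frames[:-1], anchor_frames[1:]):
        mid = (a + b) // 2
        propagate(a, mid + 1, +1)
        propagate(b, mid, -1)

    oriented = []
    for t, sk in enumerate(skeletons):
        new = sk.flipped() if flip[t] else Skeleton(
            sk.points.copy(), sk.frame, sk.oriented, sk.complex,
            sk.reconstructed)
        new.oriented = True
        oriented.append(new)
    return oriented, flip, requests
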