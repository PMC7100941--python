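"""Single-worm segmentation: threshold polling, fast-marching refinement,
and loop-aware hole filling.

The chain follows the tracking-microscope convention for variable imaging
conditions: a panel of histogram threshold methods is polled per frame and
the candidate whose largest connected component is closest to the expected
worm area wins; the winning mask seeds a fast-marching refinement whose
front speed decays with intensity deviation from the seed statistics;
finally interior holes are filled unless they look like the center of a
looped (omega-coiled) worm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, graph, measure, morphology

QUALITY_OK = "ok"
QUALITY_SUSPECT = "suspect"
QUALITY_FAILED = "failed"

#: default threshold panel, name -> callable(image) -> threshold
DEFAULT_PANEL = {
    "otsu": filters.threshold_otsu,
    "triangle": filters.threshold_triangle,
    "mean": filters.threshold_mean,
    "isodata": filters.threshold_isodata,
}


@dataclass
class BinaryMask:
    """A per-frame worm mask with provenance and quality flags."""

    mask: np.ndarray  # 2D bool
    frame: int = 0
    method: str = ""
    threshold: float = np.nan
    quality: str = QUALITY_OK
    preserved_holes: list[int] = field(default_factory=list)  # hole areas, px

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def n_components(self) -> int:
        return int(ndimage.label(self.mask)[1])


@dataclass
class SegmentationConfig:
    dark_worm: bool = True
    #: expected worm area in px; None -> estimated from an init window
    expected_area_px: float | None = None
    min_area_px: int = 20
    #: loop-hole selection band, as fractions of body area
    hole_area_frac: tuple[float, float] = (0.02, 0.40)
    hole_min_solidity: float = 0.7
    #: fast-marching arrival-time threshold (px traveled at unit speed)
    fmm_arrival: float = 5.0
    #: bound on how far the refinement may move the seed boundary (px)
    fmm_bound_px: int = 3
    panel: dict = field(default_factory=lambda: dict(DEFAULT_PANEL))


def expected_worm_area(
    length_mm: float, width_mm: float, pixel_size_mm: float
) -> float:
    """Area prior for an elliptically tapered worm body, in pixels."""
    # integral of the elliptical width profile: (pi/4) * L * w
    return (np.pi / 4) * (length_mm / pixel_size_mm) * (width_mm / pixel_size_mm)


def _foreground(image: np.ndarray, t: float, dark_worm: bool) -> np.ndarray:
    return image < t if dark_worm else image > t


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum(mask, lab, range(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def poll_thresholds(
    image: np.ndarray,
    config: SegmentationConfig,
    expected_area_px: float | None = None,
) -> tuple[float, str, pd.DataFrame]:
    """Poll the histogram-threshold panel and pick the best candidate.

    The winner minimizes |area(largest component) - expected area|.  Returns
    (threshold, method name, audit table of all candidates).

    Raises
    ------
    ValueError
        If the image is degenerate (no intensity range) or no candidate
        yields an object above the minimum area ("no object").
    """
    image = np.asarray(image)
    if image.max() == image.min():
        raise ValueError("degenerate image: constant intensity, no threshold")
    expected = expected_area_px or config.expected_area_px
    if expected is None:
        raise ValueError("expected worm area not set")

    rows = []
    for name, fn in config.panel.items():
        try:
            t = float(fn(image))
        except Exception:  # pragma: no cover - method failure on odd input
            continue
        fg = _foreground(image, t, config.dark_worm)
        area = int(_largest_component(fg).sum()) if fg.any() else 0
        rows.append({"method": name, "threshold": t, "largest_area": area})
    audit = pd.DataFrame(rows)
    audit["area_error"] = (audit["largest_area"] - expected).abs()
    valid = audit[audit["largest_area"] >= config.min_area_px]
    if valid.empty:
        raise ValueError("no object: every polled threshold yields no worm-sized component")
    best = valid.loc[valid["area_error"].idxmin()]
    t_best = float(best["threshold"])
    # a threshold cutting into a unimodal (empty) histogram separates the
    # noise tail, not an object: demand real contrast on the object itself
    fg = _largest_component(_foreground(image, t_best, config.dark_worm))
    bg_vals = image[~fg].astype(float)
    fg_vals = image[fg].astype(float)
    bg_spread = 1.4826 * np.median(np.abs(bg_vals - np.median(bg_vals)))
    contrast = abs(np.median(bg_vals) - np.median(fg_vals))
    if contrast < 5.0 * max(bg_spread, 1e-12):
        raise ValueError(
            "no object: foreground-background contrast indistinguishable "
            "from background noise")
    return t_best, str(best["method"]), audit


def refine_fast_marching(
    image: np.ndarray, seed: BinaryMask, config: SegmentationConfig
) -> BinaryMask:
    """Refine a seed mask by fast marching from its intensity core.

    The worm-mode intensity μ_w is the seed median and the background mode
    μ_b the median of a surrounding ring; the front travels at speed
    1 / (1 + (ΔI/σ)²) with ΔI = I - μ_w and σ = |μ_b - μ_w| / 3, starting
    from seed pixels close to the worm mode.  Pixels reached within the
    configured arrival time join the mask; seed pixels whose intensity is
    background-like (spillover) are dropped.  The correction is bounded:
    the result always contains an eroded seed core and is contained in a
    dilated seed.
    """
    if not seed.mask.any():
        raise ValueError("seed mask is empty")
    image = np.asarray(image, dtype=float)

    selem = morphology.disk(config.fmm_bound_px)
    dilated = ndimage.binary_dilation(seed.mask, selem)
    eroded = ndimage.binary_erosion(seed.mask, selem)

    mu_w = float(np.median(image[seed.mask]))
    # background sampled from an annulus beyond the march region, so an
    # under-covering seed does not contaminate the estimate with worm flesh
    outer = ndimage.binary_dilation(dilated, morphology.disk(2))
    ring = outer & ~dilated
    if not ring.any():
        ring = dilated & ~seed.mask
    mu_b = float(np.median(image[ring])) if ring.any() else mu_w + 1.0
    delta = max(abs(mu_b - mu_w), 1e-6)
    sigma = delta / 3.0

    dev = np.abs(image - mu_w)
    core = seed.mask & (dev < 0.5 * delta)
    if not core.any():
        core = seed.mask
    cost = 1.0 + ((image - mu_w) / sigma) ** 2

    # restrict the march to the dilated band to keep it cheap and bounded
    cost_masked = np.where(dilated, cost, np.inf)
    mcp = graph.MCP_Geometric(cost_masked)
    arrival, _ = mcp.find_costs(np.argwhere(core))
    # grow only into reachable worm-like pixels; keep worm-like seed pixels
    # and drop background-like (spillover) ones
    refined = (arrival <= config.fmm_arrival) & dilated & (dev < 0.5 * delta)
    refined |= seed.mask & (dev <= 0.75 * delta)
    refined |= eroded & core
    refined = _largest_component(refined)
    return BinaryMask(
        mask=refined,
        frame=seed.frame,
        method=seed.method + "+fmm",
        threshold=seed.threshold,
        quality=seed.quality,
    )


def fill_holes_keep_loops(
    mask: BinaryMask, config: SegmentationConfig
) -> BinaryMask:
    """Fill interior holes except those matching the center of a looped worm.

    A hole survives if its area lies within the configured band relative to
    the body area and its solidity is high (compact, not a ragged
    segmentation failure).  Preserved hole areas are recorded for audit and
    downstream complex-frame flagging.
    """
    m = mask.mask
    filled = ndimage.binary_fill_holes(m)
    holes = filled & ~m
    if not holes.any():
        return BinaryMask(m.copy(), mask.frame, mask.method, mask.threshold,
                          mask.quality, [])
    body_area = int(filled.sum())
    lo, hi = config.hole_area_frac
    out = filled.copy()
    preserved: list[int] = []
    for region in measure.regionprops(measure.label(holes)):
        frac = region.area / body_area
        if lo <= frac <= hi and region.solidity > config.hole_min_solidity:
            coords = tuple(region.coords.T)
            out[coords] = False
            preserved.append(int(region.area))
    return BinaryMask(out, mask.frame, mask.method, mask.threshold,
                      mask.quality, preserved)


def segment_frame(
    image: np.ndarray,
    config: SegmentationConfig,
    frame: int = 0,
    expected_area_px: float | None = None,
    refine: bool = True,
) -> BinaryMask:
    """Full per-frame chain: poll -> largest component -> FMM -> hole rules."""
    try:
        t, method, _ = poll_thresholds(image, config, expected_area_px)
    except ValueError:
        return BinaryMask(
            np.zeros(np.asarray(image).shape, bool),
            frame=frame, method="none", quality=QUALITY_FAILED,
        )
    fg = _largest_component(_foreground(np.asarray(image), t, config.dark_worm))
    bm = BinaryMask(fg, frame=frame, method=method, threshold=t)
    if refine:
        bm = refine_fast_marching(image, bm, config)
    bm = fill_holes_keep_loops(bm, config)
    bm.frame = frame
    if bm.area < config.min_area_px:
        bm.quality = QUALITY_FAILED
    elif bm.n_components != 1:
        bm.quality = QUALITY_SUSPECT
    return bm


def segment_stack(
    stack: np.ndarray,
    config: SegmentationConfig,
    init_window: int = 20,
    refine: bool = False,
) -> tuple[list[BinaryMask], pd.DataFrame]:
    """Segment a recording.

    If no expected worm area is configured, it is bootstrapped as the median
    largest-component area over an initialization window segmented with the
    panel's consensus (median) threshold.  Returns the masks and a per-frame
    quality table (frame, method, threshold, area, n_components, flag).
    """
    stack = np.asarray(stack)
    expected = config.expected_area_px
    if expected is None:
        areas = []
        for i in range(min(init_window, len(stack))):
            img = stack[i]
            ts = []
            for fn in config.panel.values():
                try:
                    ts.append(float(fn(img)))
                except Exception:
                    pass
            t = float(np.median(ts))
            areas.append(_largest_component(
                _foreground(img, t, config.dark_worm)).sum())
        expected = float(np.median(areas))

    masks = []
    rows = []
    for i, img in enumerate(stack):
        bm = segment_frame(img, config, frame=i,
                           expected_area_px=expected, refine=refine)
        masks.append(bm)
        rows.append(
            {
                "frame": i,
                "method": bm.method,
                "threshold": bm.threshold,
                "area": bm.area,
                "n_components": bm.n_components,
                "n_preserved_holes": len(bm.preserved_holes),
                "flag": bm.quality,
            }
        )
    return masks, pd.DataFrame(rows)


def save_masks(masks: list[BinaryMask], quality: pd.DataFrame, outdir) -> None:
    """Write masks as a packed multi-page TIFF plus the CSV quality table."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = np.stack([m.mask for m in masks]).astype(np.uint8) * 255
    tifffile.imwrite(outdir / "masks.tif", stack)
    quality.to_csv(outdir / "segmentation_quality.csv", index=False)
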