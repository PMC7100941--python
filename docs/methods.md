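# Methods

`wormetho` reimplements, as a tested library, the offline analysis chain
of a worm-tracking microscope that delivers targeted infrared heat pulses
to freely crawling *C. elegans* and quantifies the escape response.  This
note records the models, the parameter choices, and what the synthetic
validation does and does not establish.

## Posture model and phase velocity

A worm's midline is sampled at N = 49 points (48 tangent-angle samples);
the per-frame angle profile, with its mean (the body's rigid rotation)
removed, lives almost entirely in a four-dimensional "eigenworm" space.
During sinusoidal crawling the first two modes form a quadrature pair, so
the undulation state is the angle of the coefficient pair:

    φ = tan⁻¹(−a₂ / a₁),    ω = dφ/dt  (cycles/s).

We evaluate φ with the full-quadrant arctangent `atan2(−a₂, a₁)` and
unwrap over time; the two-quadrant form is honored as the principal
value, but a continuous phase needs the full quadrant.  ω is a central
difference (one-sided at the ends).  Positive ω is a head-to-tail wave,
i.e. forward crawling.

**Basis provenance and sign.**  The eigenworm basis is computed from the
recording itself (SVD of the centered angle profiles, excluding coiled
frames), with an option to load an external basis from CSV.  A
recording-derived basis fixes mode signs only up to convention, so the
winding direction of (a₁, a₂) is arbitrary; we anchor it physically by a
majority vote of sign(ω)·sign(v) over moving frames, where v is the
signed translational velocity.  That product is positive on both forward
and reverse frames when the convention is right, so the vote is
insensitive to the forward/reverse mix of the recording.

**Spike removal.**  Where a₁ ≈ a₂ ≈ 0 the phase is noise-dominated.
Frames are removed by two rules: (i) a per-frame change of ω exceeding
0.18 cycles/s (a configuration flag reads the same number as
0.18 cycles/s² instead — the per-frame reading is the default and is what
the tests pin down); (ii) peaks of |dω/dt| above mean + 3 std (statistics
from the recording by default, or from a supplied reference population),
with frames within half the peak width on each side removed.  On
spike-free synthetic data under 1% of frames are removed; the 3-std rule
by construction clips the extreme tail of its own statistic, so scattered
single-frame removals on clean data are expected, not a defect.

## Behavioral flagging

Four states with a fixed precedence:

1. **turn** — head-tail distance below 0.5 × its per-recording average.
   The average is the median over non-turn-candidate frames (frames above
   half the overall median), which is robust to the turns themselves.
   Coiled frames defeat the simple midline finder, and a posture-space
   reconstruction cannot reproduce a deep coil, so on those frames the
   segmenter's preserved loop-center hole is taken as the coil signature
   (head-tail evidence collapsed); a complex frame without a hole stays
   unknown.
2. **pause** — |ω| < 0.02 cycles/s.
3. **forward / reverse** — sign of ω.
4. **missing** — ω removed by the spike filter and no turn evidence.

Turn is tested first because coiled frames have no reliable phase.
Bouts shorter than 0.25 s (5 frames at 20 Hz, 4 at 15 Hz; the bound is in
seconds) are reassigned iteratively, shortest first: if both neighbors
agree the bout takes their state, otherwise it merges into the longer
neighbor (ties to the preceding one).  Boundary bouts are exempt — their
true extent is unobserved.  The procedure is deterministic, idempotent,
and never invents a label; an exhaustive independently-coded oracle
verifies it on random sequences.

## Segmentation

Histogram threshold methods (Otsu, triangle, mean, isodata — the panel is
configurable) are polled per frame; the winner minimizes the distance of
its largest component's area from the expected worm area (bootstrapped as
the median area over an initialization window, or supplied from a
length/width prior).  A contrast gate rejects "objects" whose median
intensity sits within 5 robust standard deviations of the background —
a threshold cutting into a unimodal histogram separates noise, not worm.

The polled mask can seed a fast-marching refinement: the front travels at
speed 1/(1 + (ΔI/σ)²) with ΔI the deviation from the worm-mode intensity
(seed median) and σ a third of the worm-background mode separation
(background sampled from an annulus beyond the march region, so an
under-covering seed cannot contaminate it).  Pixels reached within a
fixed arrival time and resembling worm intensity join the mask;
background-like seed pixels (spillover) are dropped; the correction is
bounded by an eroded-seed/dilated-seed sandwich.  Interior holes are then
filled unless they look like the center of a looped worm: area within
[2%, 40%] of the body and solidity above 0.7.  Smaller holes are speckle;
larger ones indicate failure.

## Skeletons and complex frames

The midline finder extracts the boundary (subpixel iso-contour), finds
the two tips as curvature maxima separated by roughly half the perimeter,
splits the boundary into two sides, arc-length-matches them, and averages.
The half-intensity contour clips the tapered tips by about the optical
edge width, so each end is extended by 1 px along its end tangent
(configurable; square-ended test objects use 0).  Self-occluding frames —
flagged by preserved loop holes, skeleton-length outliers beyond ±25% of
a running median, or outright failure — are repaired by interpolating the
mode coefficients across the gap with GCV-smoothed splines and rebuilding
the skeleton from the interpolated posture at the interpolated position
and rotation; such skeletons carry a `reconstructed` flag and, as noted
above, are not trusted for the turn rule.  Gaps longer than 2 s (or
touching the recording boundary) are marked missing, not fabricated.
All frames receive light Savitzky-Golay smoothing of the modes
(window ≤ 0.25 s), which mops up small per-frame midline errors.

**Head-tail orientation.**  Each stimulus is aimed at the head, so the
skeleton endpoint nearer the recorded target is the head at that frame;
orientation propagates forward and backward from each anchor (each frame
is decided by its nearest anchor), choosing per frame the assignment that
minimizes head displacement.  Two situations are flagged for annotation
rather than silently decided: an anchor equidistant from both endpoints,
and propagation across a complex-frame gap — during a deep coil the head
and tail tips approach each other, so endpoint continuity across the gap
is genuinely unreliable.  Multi-stimulus protocols (e.g. 15 s trains)
anchor every inter-coil block, which is how the end-to-end tests are
scripted.  Dorsoventral flips are assumed absent within a recording.

## Stage registration and coordinates

Stage motion is recovered from the static background: the four border
strips of each frame (minus any strip the dilated worm mask touches) are
registered by Hann-windowed phase correlation with DFT upsampling, in two
passes — integer alignment by rolling, then the subpixel residual — which
removes the window-mismatch bias that otherwise grows with shift size.
Only each strip's long-axis component is kept: the short-axis estimate of
a 24 px strip carries a bias inversely proportional to the window extent.
Pairwise shifts at lags 1, 2 and 3 are combined as the mean of
(s₁, s₂/2, s₃/3) per frame to suppress accumulated noise, cumulatively
summed, converted to mm, and anchored at the reported stage start
position.  When reported and estimated positions both exist mid-recording
the estimate wins (anchored to the reported start).

Pixel↔world and volt↔pixel maps are least-squares affine fits requiring
at least three non-collinear points; coordinates are 0-based pixels
(origin top-left, x right, y down) and world millimetres.  The laser
target sits at the arc-length midpoint of the anterior fifth
(fraction/2 from the head tip), and the predicted targeting error is the
worm displacement over one frame interval — the latency between the
targeting frame and the pulse.

## Translational velocity

The mask centroid in world mm is smoothed per axis with a GCV-penalized
smoothing spline plus Tukey-bisquare robustness iterations (a 10σ
centroid glitch deflects the curve by under 1σ).  Speed is the derivative
magnitude; the sign comes from the angle θ between the movement vector
and the centroid→head orientation vector: positive for θ < π/2.  Zero
movement carries the previous sign to avoid chatter at rest.

## Thermometry

The 490/440 nm BCECF excitation ratio in TRIS buffer reports local
temperature.  The temperature-insensitive 440 nm channel is captured only
at the session start and end and linearly interpolated per pixel; the
ratio stack is pulse-aligned (windows must not overlap; pulses arrive
every 6 s) and averaged; Δratio relative to the mean of the 3 frames
immediately pre-stimulus, divided by the calibration slope (ordinary
least squares of ratio vs temperature over the 23-26 °C set points,
pre- and post-session fits averaged), gives ΔT(x, y, t).  The headline
series is the mean over a 60 px (37.4 μm at 0.6233 μm/px) circular ROI at
the beam center, estimated as the arg-max of the Gaussian-smoothed
(σ = 4 px) time-max ΔT map — the raw per-pixel time-max is an
extreme-value statistic whose arg-max wanders under noise.  An optional
dark offset (default 0) is subtracted before the ratio.

## The synthetic generator

`synthworm` scripts a worm through forward/reverse/pause/turn bouts with
full ground truth.  Study conditions are the defaults: 20 Hz frames
(so 5 frames = 0.25 s exactly), 1 mm worm, 0.0125 mm/px (80 px body in a
160×160 px field), width 65 μm with an elliptical taper, undulation
amplitude 0.7 rad on a tangent-angle sinusoid of wavelength 0.9 body
lengths, speeds 0.12-0.2 mm/s, undulation rates 0.3-1 cycles/s.  Phase
advances +f·dt on forward frames, −f·dt on reverse, freezes otherwise.
An omega turn is a raised-cosine curvature bump on the anterior 70% of
the body, ramped up and down over 30% of the bout each side, peak total
bend 1.7π rad: the plateau head-tail ratio (~0.43) sits below the 0.5
turn threshold and the rendered coil encloses a background hole of
roughly 10-17% of body area — inside the hole-preservation band.  The
tracking stage follows the centroid with a first-order lag; frames are
rasterized by a signed-distance body model with a 1 px anti-aliased edge
over a static world-anchored background texture (Gaussian speckle,
σ = 1.5 px, 5% amplitude) plus 2% additive noise, quantized to 8 bits.
The thermometry generator encodes a spatial Gaussian ΔT (default
σ = 20 μm) with instantaneous rise and exponential decay (τ = 2.5 s) in
the 490/440 ratio, with a linear 5% drift of the 440 channel.

What the generator does **not** emulate — and hence what green tests do
not establish about real recordings: foraging head swings and other
non-sinusoidal posture content, dorsoventral asymmetry, speed/frequency
fluctuation within a bout, bacterial lawns and debris, illumination
drift, motion blur, genuine omega-turn biomechanics (the coil here is a
kinematic shape, not a simulation), and any behavioral response model —
escape statistics of real worms (response probabilities, arousal
durations, habituation curves) require real recordings and are out of
scope.

## Validation conditions and problem sizes

The test suite regenerates everything it needs at run time.  Headline
checks (also recomputed by `scripts/acceptance.py`): ethogram recovery on
a 20-animal cohort of 120 s recordings (2,400 frames each) with per-frame
agreement ≥ 95% away from scripted transitions and no interior bout under
0.25 s; median cleaned ω within 1% of the generating frequency on
analytic mode circles at 0.3/0.5/1.0 cycles/s; exact agreement of the
flagging and minimum-bout rules with brute-force oracles (10,000 random
frames; 1,000 random sequences); subpixel shifts in [−10, 10] px
recovered within 0.05 px and a 1,000-frame integrated stage trajectory
within 0.5 px RMSE at 2% noise; midline RMSE under 1 px across undulation
amplitudes; 100% head-tail flip recovery from one stimulus anchor;
ROI-averaged peak ΔT within 2% of the analytic disk average at 25 pulses
per amplitude with R² > 0.999 linearity across amplitudes.  Rendered
end-to-end runs in the suite use shorter (~20-25 s) recordings; the
image-free cohort path uses ground-truth skeletons, which is exactly the
interface the posture stage presents to the kinematics stages.

## Known limitations

- Orientation across a self-occluding gap is resolved by anchors, not
  imagery; a single-stimulus recording whose only anchor precedes an
  omega turn can leave the post-turn block mis-oriented (it is flagged
  for annotation, mirroring the interactive step of the original
  workflow).
- Mode-space reconstruction of coiled frames is a smooth bridge, not a
  coil; turn geometry on those frames comes from the mask's preserved
  hole.
- The fast-marching refinement assumes a roughly bimodal local intensity
  neighborhood; heavily textured backgrounds would need the polarity
  flag and possibly a wider speed-map σ.
- `estimate_shift` assumes the scene outside the worm is static; moving
  debris violates the model and surfaces as low-confidence or outlier
  shifts (mitigated, but not eliminated, by the lag-averaged
  integration).
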