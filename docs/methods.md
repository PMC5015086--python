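# Methods

## Optical model and conventions

All propagation uses the paraxial (Fresnel) transfer function on the
discrete FFT frequency grid,

    H(fx, fy; z) = exp(i 2πz/λ) · exp(−iπλz (fx² + fy²)),

with λ = 633 nm and an effective object-plane pitch of 30 µm/pixel.  The
kernel has unit modulus, so propagation conserves the l2 norm exactly and
`H(−z) = conj(H(z))` makes forward and backward propagation exact
inverses.  The paraxial form is valid because the arena sits ≥ 135 mm from
the sensor while the field of view is ~61 mm; `OpticsConfig.paraxial_ok`
checks `z_min ≥ 2·max(FOV)`.  The exact angular-spectrum propagator is
used only in the test suite as an independent oracle; at this aperture the
two agree to a relative l2 difference of ~1e−5.

Sign convention (fixed package-wide): `propagate(field, z)` with z > 0
carries a field from an object plane toward the sensor; a hologram
recorded with the object at depth z is refocused with `propagate(·, −z)`.
Applying the conjugate kernel instead is mathematically identical; one
convention is implemented and documented here.  Coordinates: x along
sensor columns, y along rows (gravity +y), z along the optical axis from
the sensor plane, origin at the top-left of the hologram plane.

## Synthetic data generator

No recordings ship with the package, so the generator is the ground-truth
source for every downstream test.

**Objects.** A fly is an opaque ellipse (default body length 3 mm — a
nominal adult *Drosophila*, exposed as a parameter — axis ratio 0.4) with
thin line "legs" (default six, 3 px wide, 25–28 px long).  Masks are
rasterized analytically (pixel centers inside the ellipse or within half a
line width of a leg segment).

**Forward model.** The unit plane wave is multiplied by the farthest fly's
transmission mask, Fresnel-propagated to the next fly's plane, multiplied
again, and so on to the sensor — so near flies correctly shadow far ones.
A Born-type superposition is deliberately not used; multiplicative
sequential transmission is what a real occlusion does.  Recorded frame:
`|E|² · background_level` (default 0.5 of full scale), optionally times a
smooth quadratic shading surface (emulating window aberrations), plus
zero-mean Gaussian sensor noise (default σ = 0.01 ≈ 2% of background),
clipped to [0, 1].  Fringe visibility leaves < 1% of pixels clipped at the
defaults.  Everything is deterministic given the seed.

**Motion.** Each fly runs a three-state chain: with per-frame probability
`switch_prob` (default 0.1 at 100 fps) the state is redrawn from the
target occupancy fractions (default resting 0.6 / walking 0.3 / flying
0.1), which makes those fractions the exact stationary distribution; mean
dwell in state i is `1/(switch_prob·(1−π_i))` frames (≈ 0.25 s resting).
Real flies dwell far longer; the faster clock is a deliberate compromise
so occupancy statistics converge within sessions of a few thousand
frames.  Walkers are pinned to an arena face and move in-plane at
2–15 mm/s; flyers move freely at 50–300 mm/s; walls reflect.  A scripted
gravity free-fall (9.81 m/s² along +y, clamped at the floor) can be
injected for event-detection tests.  The default arena is the 70 × 35 ×
55 mm box starting 140 mm from the sensor, with the 70 × 35 face toward
the camera (the only orientation consistent with the sensor field of
view); sessions shrink it to the field of view, and validation sessions
additionally inset it by 2.5 mm so a fly's full silhouette (body plus leg
reach) never clips the frame border — clipping would register as an area
jump and be screened as an occlusion.

**What the generator does not model:** wing-beat aerodynamics, partial
transparency of wings, photorealistic texture, camera MTF, motion blur,
partial coherence.  Passing tests therefore demonstrate the numerical
chain against an idealized opaque-silhouette world, not performance on
any particular camera.

## Enhancement and segmentation

Background is the pixelwise arithmetic mean over frames (streaming).  A
consequence worth knowing: an object that never moves is absorbed into
the background and becomes invisible to segmentation — in long recordings
the averaging window must be long compared to resting bouts.
Enhancement subtracts the background, shifts to a nonnegative range, and
box-filters (default 5 px: larger than the fringe period, smaller than
appendage scale) so transparent-wing texture does not fragment the body
at thresholding.

The automatic threshold is the midpoint between the first two modes of
the smoothed intensity histogram (dark fly mode, bright background mode).
Two maxima only count as distinct modes if the valley between them drops
below 20% of the smaller peak; a unimodal histogram's wiggles never do,
in which case the function falls back to an Otsu split with a warning.
Segmentation takes everything below threshold, opens with a disk of
**diameter** 10 px (the stated appendage scale; radius-vs-diameter was
ambiguous, diameter matches the 3–5 px leg widths), labels components,
drops those below 25% of the nominal body ellipse area (≈ 785 px), and
returns intensity-weighted centroids.  Measured on synthetic flies at
default noise, the mean centroid error is ≈ 0.08% of body length —
comfortably below the 5% specification bound, because the generator has
no pose jitter or wing texture.

## Tracking and occlusion screening

Association minimizes total Euclidean distance between predicted track
positions and detections (solved exactly with `linear_sum_assignment`).
Prediction is constant-velocity when two samples exist, else the last
position.  Links are gated at `max_link_px` (default 200 px ≈ 2 body
lengths) against both the prediction and the last observed position, so
no track ever contains a jump beyond the gate.  Unmatched detections
start tracks; tracks unmatched for more than 5 frames terminate.

Occlusion screening flags frames where a track's area deviates from its
running median by more than 50% or another track is within 150 px
(≈ 1.5 body lengths).  Short mutual overlaps (≤ 0.5 s) between exactly
two tracks are resolved by comparing post-overlap continuations against
constant-velocity extrapolation of both pre-overlap tracks; the cheaper
pairing wins, ties and longer/many-object overlaps mark the frames
excluded.  Single-fly statistics use only tracks whose every frame is
clean — the exclusion is structural (the behavior stage only ever sees
the screened track list), not a post-hoc filter.

## Depth from focus

Per detection: crop 150×150 px around the centroid from the *unsmoothed*
background-subtracted frame (the moving average exists for segmentation;
it averages away exactly the fine fringes that carry depth), subtract the
crop mean, apply a Tukey window (α = 0.5), zero-pad to 256×256, FFT once.
Per depth on the 135–200 mm, 1 mm grid: multiply by a Gaussian low-pass
(σ = 0.5 × Nyquist; narrower filters measurably degrade depth accuracy
because the discriminating fringes live near Nyquist/2) and by the
Fresnel kernel at −z, inverse transform, record

    F(z) = Σ |field|  over the central crop-support region (160×160).

Only the 1D curve is stored.  Two numerical choices matter and were fixed
by synthetic calibration:

- **Extremum sense.**  Since |H| ≡ 1 the l2 norm of the reconstruction is
  z-invariant; concentrating a fixed-l2 field onto a compact silhouette
  *lowers* its l1 norm, so the in-focus plane is the **minimum** of F(z).
  The implementation keeps the sense configurable, and the synthetic
  ground-truth recovery test asserts the default.
- **Support restriction.**  Summing over the full padded grid adds the
  defocus/twin halo spreading in the zero-pad margin, which grows
  monotonically with z, tilts the curve, and biases the extremum by
  several millimeters at the far end of the range.  Restricting the sum
  to the crop support removes the tilt (measured single-shot RMS error
  drops from ≈ 3 mm to ≈ 0.7 mm).

Extrema are found per-sample, refined by a cubic spline fitted over ±5
samples and evaluated at z_step/100 (never moving more than one grid step;
grid-boundary extrema are returned flagged).  Peak quality is the
prominence divided by a robust estimate of the curve's point-to-point
noise (1.4826·MAD of the second difference / √6): genuine focus dips
score in the hundreds, blank or pure-noise crops stay below ~30, and dips
truncated at the grid boundary fall in between — the default floor is 35.
Multi-pass selection: a unique qualifying peak wins; with several, the
one nearest the track's previous depth wins; otherwise the frame is left
as a gap for post-processing.  Objects of this size have a centimeter-
scale depth of focus, so two flies in one crop merge into a single broad
dip unless their depths are far apart; the tracking prior is what keeps
identities on the right branch.

An independent cross-check metric (`variance_metric_curve`) maximizes the
variance of the reconstructed amplitude over the same support — a classic
reconstruction-stack criterion sharing nothing with the l1 statistic.
The two agree within 2 grid steps on ≥ 95% of synthetic fixtures
(100% in the shipped acceptance run; the variance of reconstructed
*intensity* was also evaluated and rejected as a reference — it carries a
systematic ≈ +6 mm bias for objects this large).

## 3D post-processing

Pixel tracks convert to metric via x = col·pitch, y = row·pitch.  Missing
depths are linearly interpolated in time between measured seeds
(leading/trailing gaps take the nearest seed); tracks with fewer than two
seeds are dropped with a log entry.  The sparse-velocity correction walks
from an anchor sample to the first sample whose displacement exceeds the
per-axis uncertainty — transverse 0.15 mm (5% of the 3 mm body),
longitudinal 2 mm (this package's own synthetic depth calibration) — and
replaces the span by uniform motion between its raw endpoints; spans that
never cross the gate collapse to their mean with zero speed.  Sweeps
repeat to a fixed point (≤ 10 iterations), which makes the operation
idempotent.  The correction applies to all three axes.  Speeds (mm/s,
piecewise constant over spans) feed the ethograms; sub-uncertainty motion
is indistinguishable from rest by construction.

## Behavior statistics

Occupancy is a normalized 3D histogram over the arena at 0.3 × 0.3 × 1 mm
bins; out-of-arena positions are clipped into boundary bins and logged.
Closest-distance PDFs use full 3D Euclidean distances between
simultaneous flies (frames with fewer than two flies are skipped).
Ethograms threshold 3D speed at rest ≤ 1 mm/s < walk ≤ 15 mm/s < fly —
both thresholds are this package's calibration against the synthetic
state model, not measured values — with an optional majority filter
against single-frame flicker.  Rapid-vertical events are contiguous runs
of |v_vertical| ≥ 50 mm/s lasting ≥ 3 frames (the vertical axis defaults
to y, where gravity points).  Event rendering refocuses each frame's crop
at its estimated depth and writes inverted-grayscale amplitude images
(dark fly on white) with a 2 mm scale bar.

## Pipeline and I/O

`run_pipeline` makes two streaming passes (background, then everything
else); depth estimation happens inline per detection so no stage holds
the recording in memory.  All CSV outputs carry headers with units (px,
mm, s, mm/s); the run report (JSON) includes per-stage counts, the
single-fly track fraction, dropped tracks with reasons, the config echo,
the seed, and MD5 checksums of every CSV — identical seed and config
reproduce identical checksums.  Frames are read from multi-page TIFF or
numerically sorted TIFF/PNG directories; 8/16-bit data normalize to
[0, 1] floats.

## Problem sizes used in validation

Tests and the acceptance script run on a 512×512 sensor cut of the
geometry (same pitch, wavelength, and z grid as the full 1024×2048
instrument) with 30–120 frame sessions, 50–100 single-shot holograms per
statistical check, and truth-only (unrendered) sessions of 5 × 5000
frames for occupancy statistics — sizes chosen so the whole suite
completes in minutes while every estimate retains comfortable margin over
its tolerance.

## Known limitations

- A permanently stationary fly vanishes into the time-averaged background.
- Depth accuracy is object-size limited (centimeter-scale depth of focus
  for millimeter objects); the ±2 mm figure relies on the support-
  restricted metric and is validated only against the synthetic forward
  model.
- Overlap resolution handles exactly two flies over short gaps; larger
  clusters are excluded rather than disentangled.
- No twin-image suppression, phase retrieval, or partial-coherence
  modeling; the reconstruction is amplitude-only.
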