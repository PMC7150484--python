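# Methods

## Contour model and evolution

The tracker is a morphological realization of the Chan–Vese two-region
model. The lesion is represented by a binary embedding `u` whose 1-region
interior defines the contour (level set 1/2); the Chan–Vese energy is
driven entirely by the mean intensities c₁ (inside) and c₂ (outside), so
the model assumes the preprocessed lesion is approximately homogeneous and
darker (or brighter) than its surroundings — edge information is not used,
which is what makes the scheme robust to the low-contrast boundaries of
HIFU ultrasound.

One iteration composes balloon → attachment → smoothing → overflow guard.
Three numerical choices matter and were fixed after the alternatives
demonstrably failed:

* **Attachment contour.** The sign test applies at the contour of the
  embedding the iteration *started* with, not of the post-balloon
  intermediate. With the post-balloon contour the unit dilation and the
  sign-test recession cancel exactly and the contour freezes about 12 px
  short of the target on a noiseless disk (DSC 0.89 instead of 0.999).
  The standalone `attachment_step` still defaults to the gradient of its
  own input; `evolve_iteration` passes the pre-balloon contour explicitly.
* **Alternating compound smoothing.** A single fixed order SI(IS(·)) is
  shrink-biased (and IS(SI(·)) growth-biased); for 3-px segments the bias
  is negligible, for 15-px segments it is about one pixel of boundary per
  pass, enough to defeat the unit balloon. Repetitions therefore alternate
  the two orders, the classical smoothing cycle of morphological snakes;
  the parity is threaded through the per-frame iteration index.
* **The single large segment.** 𝒦₁₅ is implemented as *one* 15-px line
  segment (orientation configurable, default 0°, i.e. along the image
  rows' columns). With a one-element family the centred sup-inf/inf-sup
  compound degenerates into a directional closing and (on the alternate
  parity) opening by the segment: structures thinner than 15 px along the
  segment are removed, large regions are untouched. Extending 𝒦₁₅ to
  several orientations under the same centred semantics turns the compound
  into a discrete mean-curvature flow of strength ≈ h² ≈ 28 px²/iteration
  (h = 7.5 px half-length), which shrinks a 30-px lesion faster than the
  unit balloon re-inflates it and collapses the contour within 50
  iterations at every orientation count tried (4–16). The multi-orientation
  variant remains available through `k15_orientations` for large lesions;
  the single segment is the stable default and matches the operator's
  purpose of fine-structure removal. A corollary is a minimum feature
  size: 𝒦₁₅ cannot track lesions narrower than 15 px along its segment.

Structuring segments are clipped at the image border (out-of-grid pixels
are ignored in the extrema, and the balloon erosion uses `border_value=1`
for the same policy), so border behaviour is governed by the overflow
guard rather than by padding. The guard measures, on the contour of the
previous embedding, the fraction f of pixels whose attachment force points
outward; if f > τ (default 0.5, "most") while the candidate contour
touches the border, the iteration keeps only non-growing changes
(`candidate ∧ previous`). The scope is configurable
(`overflow_scope: border|global`); the border reading is the default
because overflow is a truncation pathology.

Region means use an ε = 10⁻⁸-regularized denominator for empty regions and
flag them degenerate; a vanished 1-region raises a tracking-lost error
carrying the last valid mask, which the pipeline logs and then freezes
rather than aborting the run — losing the lesion is a reportable clinical
condition, not a crash.

Ties in the attachment sign test (force exactly zero) leave the pixel
unchanged. `iters_per_frame` defaults to 5: inter-frame motion on the
phantoms is ≲ 2 px and five iterations give the contour a comfortable
margin to re-converge each frame while keeping a 128² frame under ~5 ms.

## Preprocessing

Denoising is a grayscale opening followed by closing with a disk of radius
κ = 2 px — speckle grains have spatial structure, and rank filters remove
them without blurring region boundaries. Contrast enhancement is an affine
window `[m − k·s, m + k·s]` (k = 2) from the mean/SD of the *initial*
lesion ROI; the window is resolved once on the first frame and then frozen
for the whole run, so the mapping does not drift as the lesion leaves the
initial ROI. The anechoic bladder, far darker than the lesion, clips to 0 —
distractor removal falls out of the windowing rather than an explicit
segmentation. Denoise-then-enhance order is fixed (the window statistics
should be computed on the despeckled image).

## Movement monitor

MI uses the plug-in joint-histogram estimator with 64 equal-width bins over
[0, 1] (frames are normalized). The estimator bias for independent data is
(B−1)²/2N ≈ 0.12 nats at 128², which is why decisions are *relative*: the
baseline is the first cross-frame MI (reference frame vs first cadence
checkpoint), and the alarm threshold is 0.6× baseline. The reference is the
last stable checkpoint frame, not frame 0, so slow drift absorbed by the
tracker does not accumulate into false alarms. While alarmed, stability is
judged between consecutive checkpoint frames (the scene may never again
match the pre-jump reference); one stable checkpoint (configurable) clears
the alarm and refreshes the reference. MI and NCC both run on preprocessed
frames, matching the pipeline order.

NCC searches per-axis displacements with magnitude in [a, b] = [0, 30] px
around the template's original position; ties break toward the smallest
displacement, then row-major. The moving force **m** (matched template
centre + stored template-to-centroid offset − current centroid) is rounded
to integers and split over α = 5 frames by repeated ceiling division, so
the per-frame shifts sum to **m** exactly (m = (5,0), α = 2 → (3,0) then
(2,0)). While the alarm stands, contour evolution pauses and only the
moving force applies; the planner's gate reads the alarm flag directly.
Cadence 10 at 30 FPS is a one-third-second monitoring period; none of the
monitor constants is physically derived, and all are config keys.

## Focus planner

"One quarter of the centre" is read as the lesion scaled by 1/2 in each
linear dimension about its centroid (area ratio 1/4 up to pixelization),
intersected with the lesion — a concentric sub-region, not an erosion to
25 % area. Masks under 16 px raise a too-small error (a quarter-area region
of a few pixels has no extent); the 3D assembler converts that into a
zero-focus layer. The 5 mm grid is anchored at the region centroid so the
plan is translation-equivariant with the lesion; a grid point is kept when
its nearest pixel is inside the region. Foci are reported in mm as
(x, y) = (col, row) with origin at the top-left pixel centre; device
coordinates are the caller's concern.

## Synthetic phantoms

Speckle is per-pixel multiplicative gamma noise with unit mean (shape k,
scale 1/k); k = 9 (σ/μ = 1/3) is the default texture, a moderately noisy
fully-developed-speckle surrogate. The phantom renders a hypoechoic
elliptical lesion (0.35) on brighter background (0.6) with optional
brighter internal blobs (which travel with the lesion and count as lesion
interior — the clinical target is the outer contour), an optional anechoic
bladder (0.05), and a motion schedule of linear drift, sinusoidal row
oscillation, axis deformation in quadrature with it, and step jumps.
Frames are reproducible per (seed, frame index).

Four study phantoms are frozen in `hifutrack.synth`:

* `standard_phantom` — 120 frames, drift (0, 0.05) px/frame, oscillation
  1.5 px / 40 frames, 3 % deformation, one internal blob; the end-to-end
  benchmark.
* `fine_structure_phantom` — a background-intensity echogenic band, 8 px
  thick, crossing the lesion vertically (built from overlapping blobs).
  Small segments let the contour carve along the band; the 15-px segment
  bridges it. A compact interior blob does *not* separate the operator
  sets (both track it equally well); the band is the geometry that does.
* `jump_phantom` — a small lesion (semi-axes 8 × 13 px) with a single
  (20, 0) px jump at frame 40. The lesion size is chosen so the jump fully
  de-overlaps it with ~4 px clearance: with smaller clearance the unaided
  region-based tracker occasionally crawls back and re-captures the
  lesion, which would measure contour dynamics rather than the monitor.
* `truncated_phantom` — the lesion cut by the bottom border with an
  adjacent bladder; the configuration in which an unguarded contour
  overflows along the border into the bladder.

What the phantoms do **not** emulate: point-spread-function blur and
range-dependent resolution, attenuation/shadowing, log-compression
artefacts, out-of-plane motion, and non-affine tissue deformation. Passing
on these phantoms therefore demonstrates the algorithmic properties
(convergence, fine-structure insensitivity, guard and monitor logic,
planner geometry) — not clinical-grade accuracy on real HIFU video.

## Problem sizes

Default frames are 128×128 at 0.25 mm/px — an ROI-scale grid on which the
full suite and the acceptance script each run in under a minute on one
core; every quantity is defined per-pixel and scales to larger frames
unchanged. The acceptance script uses 120-frame runs for tracking and
monitoring, 20 seeded repetitions for the operator-set contrast, 10 for
the jump study, and 200 iterations for the guard study.

## Known limitations

* 𝒦₁₅'s minimum feature size (15 px along the segment) bounds the smallest
  trackable lesion; the segment orientation is a free axis choice.
* The monitor corrects pure translations; rotation or deformation during a
  large movement is re-absorbed only after the alarm clears and evolution
  resumes.
* Hausdorff distance assumes isotropic pixel spacing (anisotropic spacing
  is rejected, not silently averaged).
* The guard suppresses *all* growth while active; a truncated lesion that
  genuinely grows (e.g. moving into view) re-expands only once its contour
  leaves the border or the outward-force fraction drops below τ.
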