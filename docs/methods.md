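# Methods

`perivasc` quantifies perivascular Müller-glial Ca²⁺ activity around single
retinal capillaries and the 3-D glial ensheathment of capillary surfaces.
This note documents the models, conventions, defaults and limitations of
each stage, and the design choices made where the procedure admitted more
than one reasonable reading.

## The imaging model and its quantification

A recording consists of a glial Ca²⁺-indicator channel (Fluo-4) imaged over
time and a static vessel-label channel (SR101) showing one capillary.  Two
readouts are computed per vessel.

**ΔF/F₀.**  For a region of interest extending a half-width
`max(3·diameter, 10 µm)` from the vessel center (both the "three vessel
diameters" and the "~10 µm" conventions are honoured; the larger wins and
the value used is reported),

    ΔF/F₀(t) = (F(t) − F₀) / F₀

with F₀ the ROI mean over all frames preceding the puff onset, and the
reported value the post-onset maximum.

**Vessel-centric z-score profile.**

1. *Frame averages.*  Baseline = the `n_avg_frames` frames immediately
   preceding the puff onset; peak = `n_avg_frames` frames centered on the
   argmax frame of the ΔF/F₀ series, clipped to the recording (counts
   recorded).  Default `n_avg_frames = 9`, the midpoint of the 8–10 frames
   conventionally averaged.
2. *Baseline subtraction.*  ΔF image = peak average − baseline average.
3. *Stalk masking.*  Müller stalks are bright hotspots that would dominate
   the profile.  Pixels strictly above the (100 − p)-th percentile of the
   *peak average* (not baseline-subtracted) are masked; the binary mask is
   dilated with a full 3×3 structuring element; masked pixels of the ΔF
   image become NaN and are excluded from every downstream mean, z and
   peak.  Defaults p = 3 (midpoint of the 2–4 % convention) and 2 dilation
   iterations (the first of "two–three").  Strict inequality at the
   threshold means a constant image yields an empty mask.
4. *Straightening.*  Curved capillaries are resampled into vessel-centric
   coordinates: rows follow the centerline at ≤ 1 px arc spacing, columns
   are signed perpendicular offsets.  Bilinear interpolation; a sample is
   excluded whenever any of its four corners is excluded or off-image.
   The half-width must be ≥ 20 µm so profiles always extend at least
   20 µm on either side of the vessel.
5. *Collapse.*  Columns are averaged over all non-excluded rows for the
   whole in-focus length.  A column with no usable samples is an error
   (the caller must widen the field or reject the vessel) rather than a
   silently missing distance.
6. *z-scoring.*  z(d) = ΔF(d)/σ with a single scalar σ per profile.
7. *Bilateral peaks.*  Left/right peak z are the maxima of z in the
   windows [r_v, r_v + 10 µm] outward from the vessel wall on each side
   (lumen samples are excluded from the search but retained in the
   exported profile), and

       ave_peak_z = (left_peak_z + right_peak_z) / 2   (exactly).

8. *Display.*  The vessel channel is carried through the same
   straighten/collapse geometry and rescaled so its profile maximum is
   exactly 5 — a display convention for overlaying the vessel on z-score
   plots, not a measurement.

**The noise scale σ.**  σ must be independent of the evoked signal.  The
default ("temporal") estimate is the pooled per-pixel standard deviation of
the individual baseline frames about their across-frame mean (unbiased
per-pixel variances, averaged, square-rooted), computed after applying the
stalk mask.  This estimates the single-frame, single-pixel noise floor and
is deliberately computed in image space: estimating it from straightened
(interpolated) samples shrinks the apparent noise by the bilinear weight
factor and inflates every z by up to ~40 % on curved vessels.  A far-field
spatial alternative (SD of the collapsed ΔF profile beyond 15 µm — note
this measures noise at the collapsed-profile scale, so its z-values are not
comparable to the temporal convention) and an explicit override are
configurable.  σ = 0 (noise-free input) is an error instructing an explicit
override rather than a silent division.

**Vessel geometry.**  The vessel channel is thresholded with Otsu's method
(an unattended default standing in for by-eye identification); exactly one
connected component is required — fields with several vessels or branch
points must be cropped upstream.  The centerline is the skeleton of the
mask, Gaussian-smoothed (σ = 2 px) and resampled; the radius is half the
full-width-at-half-maximum of the collapsed perpendicular vessel profile
(sub-pixel, robust to the half-pixel bias of mask-based estimates).
Whether a segment is "fully in the plane of focus" is not detectable from
a single 2-D channel, so `in_focus` is a caller-set flag, checked but
never inferred.

## The synthetic movie generator

The generator emulates the study conditions rather than any particular
dataset: a 256 × 256 px field at 0.4 µm/px and 0.5 s/frame (the recording
frame rate and field size are configuration defaults, not claims), a
straight 4-µm-diameter capillary crossing the field center, a 1.5-µm
perivascular sheath annulus, 40 stalk hotspots of radius 2 µm, a dim
uniformly responsive background, and an ATP puff at frame 12 whose
activation wavefront expands radially at 15 µm/s from the field edge.
Amplitudes default to sheath 5, stalk 25, background 0.5 on a baseline of
100, with per-pixel per-frame Gaussian noise of SD 1 (Poisson noise is
available behind a flag).  Choices worth recording:

* The vessel tube is an antialiased hard disk (pixel value ≈ area
  coverage) convolved with a 1-px Gaussian, so the blurred tube's
  half-maximum sits exactly at the nominal radius — without antialiasing
  the rendered radius carries a +½ px quantisation bias.
* The stalk count is set so stalk pixels occupy ~4–5 % of the field —
  consistent with one Müller stalk per 10–15 µm of retina and, by design,
  at least the area that the top-percentile masking step removes.  (If
  stalks covered less than the masked percentile, the threshold would dip
  into the sheath annulus and the dilated mask would excise the very
  signal being measured.)
* The background responds only outside stalks and the sheath annulus, so
  the constructed annulus ΔF equals `sheath_amplitude` exactly and the
  ground-truth peak z is `sheath_amplitude / noise_sd`.
* The dispersed ("rd10-like") mode redistributes the annulus mass by an
  isotropic Gaussian displacement (σ = `dispersion_sd_um`) of its
  generating points, deposited bilinearly and reflected at the field
  boundary — signal is displaced, never removed, so total evoked signal is
  conserved exactly at fixed amplitudes.
* Determinism: one `numpy` generator seeded from the spec drives
  dispersion, stalk placement and noise in a fixed order; identical specs
  give bit-identical movies.  Cohort seeds derive from
  `SeedSequence((seed, condition_index, movie_index))`.

What the generator does *not* emulate: optical sectioning and a real PSF,
hemodynamics (the vessel is static), photobleaching, indicator kinetics
(activation is a step, not a Ca²⁺ transient), and structured biological
background.  Passing recovery tests therefore demonstrates correctness of
the measurement pipeline on data satisfying these assumptions, not
performance on real recordings.

## The voxel phantom and ensheathment analytics

Labeled volumes use a fixed role map (background, lumen, endothelium,
pericyte, glia, neuron classes; neuron processes carry per-process label
ids from 10 upward).  The phantom is a cylindrical capillary along a
chosen axis: lumen, a closed endothelial wall (2 voxels), optional
pericyte patches on the wall, and a 2-voxel glial shell with programmable
gaps specified as (axial span, angular span) surface regions.  Neuron
processes are radial spokes that reach the wall only inside gaps; a
pericyte-targeted process gets the wall beneath its footprint relabeled as
pericyte.  Default scale: 60 × 48 × 48 voxels at 0.5 µm isotropic, vessel
radius 2.5 µm, vessel depth 50 µm (an IVP-like depth).

Analysis is face-based with 6-connectivity: surface faces are voxel faces
between a wall voxel and an exterior (non-wall, non-lumen) voxel, each
classified by its outside voxel's role.  This makes the coverage fraction
a ratio of integer face counts and enforces the conservation identity
glia faces + gap faces = total faces exactly.  Gaps are connected
components of non-glia faces; two faces are adjacent iff they share a
geometric voxel edge (edges identified by their midpoints on a doubled
integer grid — exact, no distance heuristics).  Contacts are per-process
face components; the contacted element is pericyte if any face of the
component has a pericyte inside voxel, else endothelium (pericytes lie
external to the endothelium, so a pericyte at the surface is what is
touched).  Gap plexus assignment bins the component's centroid depth with
caller-suppliable boundaries, default 25 and 70 µm (between the ~0, ~50
and ~90 µm depths of the three plexuses).  The minimum size or basement
lamina criteria of a "gap" in annotated EM are not modeled; a gap here is
a declared face-component convention.  Ground truth (coverage, per-gap
face counts, contact table) is computed at construction by direct face
counting, and gap regions must be pairwise non-adjacent for the recorded
gap count to equal the component count.

## Group statistics

Groups (one value per vessel) are summarised as mean ± SD.  Normality is
checked with the Jarque–Bera moment test, JB = (n/6)(S² + (K−3)²/4) with
non-excess kurtosis, p from the χ²(2) tail.  If both groups pass at
α = 0.05 the comparison is a t-test — Welch by default, since group sizes
in such designs routinely differ (a pooled-variance option is retained);
otherwise a rank-sum test is used, and the test actually applied is always
reported.  What to do when normality fails is this package's declared
policy (rank-sum), as is treating groups with n < 4 (where the moment test
cannot run) as unrejectable, i.e. t-tested.  Both paired and unpaired
modes exist; unpaired is the default.  Significance is declared at
p < 0.05, with no multiple-testing correction.

## Problem sizes used in the test suite

Simulation-backed tests run at three scales chosen to keep the suite
self-contained: the nominal 256-px field for single-movie checks; a 128-px
field (same pixel size, same 20-µm profile extent, stalk count scaled with
field area) for the 20-seed-per-level parameter-recovery sweep and the
15-per-condition tight-vs-dispersed cohort; and a 48-px field at 1 µm/px
for the 1000-repetition null calibration of the gated comparison, with 12
movies per group — matching the study-scale cohort sizes (~11–21 vessels)
and large enough for the t and rank-sum approximations to hold (at n ≤ 4
the rank-sum p-values are too granular to reject at 0.05 at all).

## Known limitations

* Segmentation assumes a single unbranched tube; no branch handling.
* The centerline is 2-D; out-of-plane curvature is not modeled, matching
  the in-focus-segment analysis convention.
* The temporal σ assumes stationary noise across the baseline window;
  slow drift would inflate it.
* Coverage analytics require the vessel wall to be voxel-closed; leaky
  hand-edited volumes fail validation rather than producing a number.
* The Jarque–Bera gate has low power at realistic group sizes, so mildly
  non-normal groups are usually t-tested; this mirrors the reported
  workflow rather than best current practice.
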