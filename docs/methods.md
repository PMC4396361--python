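# Methods

## Scope and data model

The package analyses orientation preference and retinotopy in the mouse
superficial superior colliculus from two modalities: per-trial unit firing
rates recorded along electrode penetrations, and single-channel wide-field
calcium-imaging stacks with a stimulus schedule.  All orientations are
axial quantities in degrees on [0, 180); directional data (drift
directions) live on [0, 360).  Axial statistics double the angles, operate
on unit vectors exp(2iφ), and halve angular results back.

### Angle conventions

* `direction_deg` is the drift direction of motion (0° = nasal-to-temporal,
  90° = upward).  The spatial orientation of a drifting grating is
  perpendicular to its motion: grating orientation = (direction + 90)
  mod 180, so an upward-drifting grating is horizontal (0°).
* `collapse_directions` labels collapsed responses by direction mod 180
  (the motion axis); pipelines that need physical grating orientation
  convert first.  Both conventions are exposed because unit-level index
  arithmetic (OI, DSI) is convention-free while map comparisons are not.
* The concentric angle at visual-field position (x, y) (head-centred; x to
  the animal's right, y up, z forward) is (90° − atan2(y, x)) mod 180: 90°
  (vertical) on the temporal horizontal axis, 0° (horizontal) directly
  above the nose, undefined at the centre of vision.  It is invariant under
  positive rescaling of (x, y) and under point reflection, so it can be
  computed from azimuth/elevation alone via (sin az, tan el).

### Head geometry

Monitor-plane points (cm relative to the monitor centre) map to head
coordinates by translating with the monitor offset and distance (default
29.5 cm) and rotating by head pitch (about x, applied first) then roll
(about z).  Positive pitch tilts the head nose-down, raising the apparent
elevation of the monitor; at 90° a point straight ahead maps to straight
above.  The rotation order is a package convention (the composed rotation
differs only at second order for the small angles involved), and
`fit_head_angles` makes results robust to moderate errors in either angle.

## Imaging pipeline

1. **Event responses.**  ΔF/F = (R_s − R_0)/R_0, with R_s the mean
   intensity from onset + 0.3 s to offset + 2 s and R_0 the mean over
   [onset − 3 s, onset + 0.3 s).  A frame belongs to a window iff its
   midpoint lies in [start, end): at 1.8 Hz the windows are not
   frame-aligned and the midpoint rule makes membership unambiguous.
   Events whose windows leave the recording are skipped and logged; pixels
   with non-positive baseline are masked.
2. **Reference correction.**  When a visually non-responsive reference ROI
   is configured, each trial response is divided by 1 + (reference-ROI
   response), cancelling slow shared fluorescence changes.  Correction
   precedes spatial filtering.
3. **Smoothing.**  Map smoothing uses a 2D Gaussian, σ = 33 µm (3 px at
   11.04 µm/px), applied to per-condition *mean* maps with mask-aware
   normalisation.  The per-trial responses entering the ANOVA are left
   unsmoothed: trial statistics should not inherit the display filter, and
   smoothing trials would correlate neighbouring pixels' tests without
   changing any per-pixel null distribution.  Axial maps are smoothed on
   the complex field amplitude·exp(2i·angle) so angles near the 0/180 wrap
   average correctly.
4. **Maps.**  Retinotopy: per-pixel argmax of trial-mean patch responses
   (ties to the lowest patch id, logged; non-positive best responses
   masked).  Orientation: per-pixel R(φ) = max of the two opposite drift
   directions sharing grating orientation φ, clamped at 0; angle =
   ½·arg Σ R(φ)e^{2iφ}; amplitude = mean response over all stimuli.
   Significance: one-way fixed-effects ANOVA across the four orientations
   (opposite directions pooled); a pixel constant in every trial gets
   p = 1, zero within-group variance with real group differences gives
   p = 0.  Single-condition maps subtract the mean over all directions.
5. **Retinotopy interpolation.**  Per-patch mean maps are fitted, after
   subtracting a 0.1 ΔF/F-percentage-point pedestal (floored at 0; a
   relative-to-maximum variant is a config switch), with an axis-aligned
   elliptical 2D Gaussian (offset fixed at 0, centroid-initialised).  The
   reported amplitude adds the pedestal back so the 0.4-percentage-point
   inclusion threshold applies on the original response scale.  Included
   patch centres are interpolated piecewise-linearly on their Delaunay
   triangulation from pixel space to monitor cm — defined only inside the
   convex hull, and inherently fold-removing — then carried through the
   head transform to azimuth/elevation.
6. **Concentric prediction and comparison.**  Each hull pixel gets the
   concentric angle of its visual-field position; nasal ipsilateral pixels
   (azimuth sign set by `ipsi_azimuth_sign`, hemisphere-dependent) are set
   to horizontal.  The map is smoothed axially with σ = 132 µm, emulating
   receptive-field and light scatter.  The comparison pools pixels valid in
   both maps whose per-condition mean response reaches 0.5 percentage
   points in *every* condition (strict reading; an any-condition switch is
   provided), computes the Fisher–Lee circular correlation on doubled
   angles, bins signed axial differences into 18 × 10° bins centred on 0,
   and can attach a permutation p-value obtained by shuffling the pixel
   pairing.

## Electrophysiology pipeline

Units are aggregated from per-trial tables; the evoked rate is the maximum
over directions of (mean stimulus rate − mean inter-stimulus rate), floored
at 0, and units below 2 Hz are excluded.  The preferred orientation entering
penetration statistics is, by default, the orientation with the largest
collapsed (opposite-pair-averaged) response; vector-average and
fixed-κ von Mises alternatives are available.  Per penetration the circular
mean and variance are computed; the ensemble is tested by the shuffle test
(median circular variance against size-preserving permutations of the
pooled preferences, Fisher–Yates, single seeded generator) and the
penetration means by a Rayleigh test on doubled angles with the standard
small-sample correction.

With 8 stimulus directions the argmax preference is quantised to four
orientations, which produces ties between the real and permuted statistics;
the add-one estimator (1 + #{null ≤ real})/(1 + N) counts ties against the
hypothesis, so the test runs slightly conservative (empirically ≈ 0.03–0.05
type-I error at α = 0.05) and can never report p = 0.

## Circular correlation and head-angle fitting

The circular correlation is the Fisher–Lee T-linear association coefficient
evaluated in its O(n) computational form on doubled angles; a pairwise-sum
transcription serves as the test oracle.  This coefficient is invariant
under a constant rotation of either sample.  That invariance has a direct
consequence: a head *roll* rotates every predicted concentric angle by the
same constant, so a grid search maximising the correlation cannot identify
roll.  `fit_head_angles` therefore scores each (pitch, roll) candidate by
the mean axial alignment ⟨cos 2(measured − predicted)⟩ — 1 for perfect
agreement, 0 for unrelated maps — and reports the correlation profile
alongside for sensitivity inspection.  Profiles whose best alignment stays
below 0.2 are flagged unidentifiable.

## Synthetic data

The imaging generator emulates a GCaMP6s-labelled sSC imaged at 1.8 Hz and
11.04 µm/px while 3 s stimuli (retinotopic patches, then full-screen
gratings in 8 directions) are shown with a ≥ 9 s interstimulus interval.
Stimulus onsets are locked to the acquisition frame clock, as triggered
acquisition systems do; a free-running stimulus clock would alias the
indicator kernel against the 1.8 Hz sampling and inject a signal-
proportional noise mode shared by all pixels.  Fluorescence is
F0 · (1 + drift) · (1 + Σ events amplitude × kernel) + shot noise, with a
mono-exponential indicator kernel (τ = 1.5 s, GCaMP6s-like saturating rise
and decay), a sinusoid-plus-trend drift (0.3 % amplitude, 300 s period,
0.5 % trend) and 1 % per-frame Gaussian shot noise.  A 10 × 10 px corner
region is visually unresponsive to serve as the reference ROI.

Ground truth: retinotopy is an affine map from pixels to the monitor plane
spanning 33 cm over 96 px, i.e. ≈ 55° of azimuth per mm of tissue — the
approximate retinotopic magnification of the mouse colliculus — with the
represented field kept clear of the centre of vision, as in a typical
contralateral imaging window.  Patch responses are Gaussian in retinotopic
space (σ = 5 cm receptive-field scatter, 3 % peak ΔF/F).  Grating responses
are an untuned pedestal (1 % ΔF/F; the tissue responds to every
orientation) plus a κ = 1 von Mises bump (2.5 % peak) centred on the rule's
angle: `concentric` (the concentric angle at the pixel's position, nasal
ipsilateral horizontal), `random_smooth` (a smooth orientation field
independent of retinotopy) or `uniform_null` (no orientation tuning; the
pedestal is raised by the bump's circular mean so overall responsiveness
matches).

The electrophysiology generator draws one receptive field per penetration
(contralateral box, azimuth 5–50°, elevation −20–30°), a penetration-level
preferred orientation per rule (concentric at the RF, uniform random, or
none), unit preferences scattered axially (von Mises κ = `within_kappa`),
and Poisson trial spike counts of a κ = 1 von Mises tuning curve (2 Hz
baseline, 8 Hz modulation, 3 s windows) over 16 drift directions in 22.5°
steps — the resolution at which penetration preferences were determined,
which matters because a coarser set quantises the argmax preference and
ties make the shuffle test conservative.  Peak evoked rates sit near 10 Hz
against the 2 Hz inclusion threshold, as in the recordings this emulates.

What the generator does *not* emulate: vascular and hemodynamic artefacts,
focal blur/optics, eye movements, bursting or adaptation, correlated noise
between units, receptive-field scatter within a penetration, or folded/
non-affine retinotopy.  Passing tests therefore demonstrate the
correctness and calibration of the analysis under its stated model, not
robustness to every artefact of real preparations.

## Numerical choices

* Resultants below 1e−12 of the total weight count as zero (undefined
  means/preferences raise, or mask the pixel).
* `circ_diff_axial` wraps into (−90, 90]; exact ±90 ties return +90.
* Permutation p-values use the add-one estimator; all permutations come
  from one `numpy.random.Generator` seeded per call.
* The von Mises fit profiles the preferred angle on a 0.25° grid with the
  amplitude/baseline pair solved linearly at each angle (amplitude floored
  at 0), then refines the best angle by bounded scalar minimisation; flat
  curves return amplitude 0 and are flagged unreliable.
* The Rayleigh p-value uses the exp(√(1+4n+4(n²−Rn²)) − (1+2n)) correction.
* Patch Gaussian fits run bounded Levenberg–Marquardt (trf) with
  centroid initialisation; non-convergence yields `included=False` with a
  diagnostic message rather than an exception.
* Gaussian smoothing uses zero-padded convolution normalised by the
  smoothed mask, so masked-out pixels carry no weight and borders are not
  darkened.
* Pixel coordinates are 0-based row-major with the origin top-left; all
  σ are stated in µm and converted via `pixel_size_um`.

## Problem sizes in the tests and acceptance script

End-to-end imaging checks run a 96 × 96 px session with 5 repetitions of a
4 × 4 patch grid and 10 repetitions of 8 directions (≈ 2000 s of simulated
recording, ≈ 3600 frames); shuffle-test calibration uses 500 null and 200
columnar ensembles of 20 penetrations × 8 units with 2000 shuffles each;
the single-ensemble shuffle test uses the full 10,000.  These sizes give
≈ 4000 comparison pixels and sub-percent Monte-Carlo error on the reported
rates while keeping a full run in tens of seconds.

## Known limitations

* The hemifield boundary for the ipsilateral-horizontal rule is azimuth 0
  relative to the nose axis; eye-centred coordinates and corneal
  refraction are out of scope.
* The 0.5 % per-condition response filter is the strict (every-condition)
  reading; datasets with strongly anisotropic responsiveness may prefer
  the any-condition switch.
* The concentric comparison's permutation p-value treats pixels as
  exchangeable units, ignoring their spatial correlation; it is reported
  as a descriptive index, not a substitute for per-animal inference.
* `fit_head_angles` is an exhaustive grid search; resolution is the grid
  step, and pitch/roll trade off weakly when the imaged field is small.
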