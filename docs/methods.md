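# Methods

This note records the models behind each stage of `flsquant`, the
parameter choices that matter, and what the synthetic validation does
and does not establish about real microscopy data.

## The measurement problem

Filopodia-like structures (FLS) are parallel actin bundles nucleated on
a PI(4,5)P₂-containing supported lipid bilayer and imaged as confocal
z-stacks (typically 1 µm z-steps over 30–60 µm, ~0.16 µm pixels). The
quantities of interest are: the per-structure path length from the
bilayer plane; the field-level z-extent of an actin-binding probe
relative to actin (a displacement readout); per-track growth/shrinkage
rates from time lapses; and population-level length statistics. FLS in
a stationary balance of growth and shrinkage have lengths well described
by an exponential distribution above the detection threshold, so the
3 µm-shifted exponential is the package's null model for length samples
and departures from it (log-histogram curvature) are the signature of
length-perturbing treatments.

## Detection

**Binarization.** Each z-slice is lightly smoothed (Gaussian,
`smooth_sigma_px = 0.7` px by default) and thresholded. The default
threshold is background median + k robust standard deviations with
k = 3, where the robust SD is 1.4826 × the median absolute deviation —
the usual MAD-to-σ convention; raw un-scaled MAD would make "3 MAD"
pass ~2% of pure-noise pixels. Otsu and fixed-value thresholds are
selectable. Components with fewer than `min_size_px = 4` pixels are
discarded, which also removes isolated noise pixels from area profiles.
The pre-smoothing exists because the perimeter measure below counts
pixel edges: single-pixel boundary jitter inflates it and depresses
circularity; σ ≈ 0.7 px suppresses the jitter without erasing the thin
upper shaft of a structure (larger σ measurably truncates tips).

**Geometry per slice.** Connected components use 8-connectivity.
Area is pixel count × pixel area. The perimeter is the *crack length* —
the number of exposed pixel edges × pixel size — so a digitized square
scores circularity 4πA/P² = π/4 exactly at any size. Note a crack-length
consequence: a digitized disc scores ≈ π²r²/(4(2r+1))² · 16 → π²/16 ≈
0.62 asymptotically and less at small radii, so the 0.5 circularity
criterion implicitly requires bases several pixels across. Centroids are
unweighted; coordinates are pixel-centre, 0-based, converted to µm.

**z-linking.** Paths are seeded from every base-slice component and
extended greedily upward: a component at z+1 joins the open path whose
top it overlaps most (in pixels); with no overlap, the nearest top
centroid within `max_step_xy = 1 µm` is used. Ties go to the larger top
component, then to the earlier-seeded path. One component extends at
most one path, a slice with no admissible continuation terminates the
path (no gap closing), and components that never join a path are
discarded. Branch events are flagged on the path for audit. Path length
is the cumulative 3-D distance through the component centroids; a
single-slice candidate has length 0. The centroid chain is exact for
straight structures and a (slight) underestimate for curved ones; no
sub-voxel curve fitting is attempted.

**Admission.** `FilterCriteria` keeps candidates with path length
≥ 3 µm, base area ≤ 20 µm² and base circularity ≥ 0.5 — boundary values
inclusive exactly as written.

## Probe displacement

Per-slice above-threshold areas (same binarization as detection) give,
per field: the **actin extent** (first slice above the base with zero
actin area; if none, the profile length with a truncation flag — never a
silent cap), the **probe extent** (first slice with probe area ≤ ½ the
actin area; a slice with zero actin area qualifies regardless of the
probe value, which makes probe extent ≤ actin extent a theorem for any
pair of profiles, noisy or not), and their ratio (undefined and flagged
when the actin extent is 0). Normalized z-profiles divide each field's
per-slice areas by that channel's area in the first slice above the
base; group means carry t-based 95% CIs across fields (zero-width for a
single field). Intensity profiles along one structure average a 5×5
pixel box centred on the nearest pixel to each slice's centroid,
subtract a per-channel background, and normalize to the base slice
(flagged invalid if the base value does not exceed background).

## Tracking

Frame-to-frame identity uses base-centroid distance (bases are
membrane-anchored, so they move least): mutual nearest neighbours are
linked first, then remaining pairs by increasing distance, one-to-one,
within `max_link_dist = 1 µm`; unmatched detections start new tracks and
a missed frame terminates a track. Tracks need ≥ 6 consecutive frames
(2 min at the default 20 s interval) for inclusion. The aligned profile
sets T = 0 at each track's first detection and reports mean ± SEM over
all tracks present at each relative time point (SEM 0 with n = 1,
reported alongside n).

## Length statistics

The shifted-exponential location is fixed at the 3 µm detection
threshold rather than estimated: lengths below it are excluded by the
FLS definition, not censored observations. The MLE is closed-form,
λ̂ = 1/(mean − location); the CI uses the exact pivot 2λT ~ χ²₂ₙ
(T = Σ(xᵢ − location)), which has exact finite-sample coverage — the
asymptotic log-normal interval is avoided deliberately. Log-frequency
histograms bin from the location upward (default 2 µm bins; the bin
width used in published histograms is not standardized, so it is a
parameter); linearity is summarized by R² over bins with ≥ 10 events
(the log of a small Poisson count is too noisy to diagnose shape), and
the heavy-tail signature by the one-sided p-value of a positive
quadratic term. Group comparisons of per-field means use pairwise Welch
t-tests with Sidak adjustment (1 − (1 − p)^m and the matching
per-comparison CI level) — deliberately robust plumbing rather than a
pooled-variance ANOVA.

## Assays

Densitometry takes band intensities, not gel images: each band's
background is the mean of its strips (two above, two below), negative
corrected intensities clip to zero with a warning, and the pellet
fraction is pellet/(pellet+supernatant) × 100 (undefined and flagged
when both are zero). The 4PL fit is unweighted least squares over all
replicate points in (bottom, top, log₁₀EC50, hill) parameterization,
multi-started over five EC50 quantiles × three Hill slopes so a poor
start cannot masquerade as non-convergence; non-convergence and
non-positive Hill slopes on ascending data are flagged, never silently
defaulted. Fold changes divide EC50s with a CI propagated on the log
scale from the Gauss–Newton covariance. Dose-response software differs
on whether replicates are fitted individually or as means; fitting all
points unweighted is the package default, and pre-averaging replicates
before the call reproduces the other convention.

## The synthetic scene model

Structures render as constant-intensity **tapered cylinders**: a
`base_radius = 1.5 µm` membrane attachment narrowing linearly to a
`fls_radius = 0.35 µm` shaft over `base_taper = 2 µm`, blurred by a
separable Gaussian PSF (σxy = 0.1 µm, σz = 0.3 µm) on a uniform
background with additive Gaussian noise (σ = 10% of the structure
amplitude by default; Poisson shot noise is a toggle). The flared base
is a modelling choice with two motivations: real FLS bases are
µm²-scale membrane attachments (the 20 µm² admission cap presumes as
much), and the crack-length circularity of a small digitized disc falls
below the 0.5 criterion, so zero-width lines would be rejected by the
very filter they are meant to exercise. Default geometry: ~50
structures in a 60 × 60 µm field with ≥ 4 µm base separation
(dart-throwing placement; density per field is not standardized in
published data, so the default keeps structures separable and is
explicitly arbitrary), tilts ≤ 8° from the z-axis, 30 µm stacks at 1 µm
z-spacing, 0.16 µm pixels. Lengths are shifted-exponential
(rate 0.25 µm⁻¹ above 3 µm → mean 7 µm); a two-component mixture
(`heavy_tail_mix`, secondary rate 0.05 µm⁻¹) emulates
length-perturbing conditions. The probe channel shares each structure's
geometry truncated at `probe_fraction` of its length, and its voxel
support is constrained to the actin support (the probe decorates a
prefix of the structure by construction).

Time-lapse lengths follow a two-state telegraph process (growth and
shrinkage at 1.5 µm/min by default, per-minute catastrophe/rescue
switching, absorption at zero length, Poisson nucleation of new
structures); frames default to 20 s over 10 min. Photobleaching fixes a
per-structure boundary at the bleach frame: material below it renders at
`bleach_survival` of full intensity, the boundary only moves down as
shrinkage consumes old material, and regrowth above it is bright.

**What the generator does not emulate:** depth-dependent attenuation,
spherical aberration, uneven illumination, bundle curvature or
crossing/merging structures, probe binding kinetics, and camera-specific
noise beyond the Gaussian/Poisson options. Passing recovery tests on
these scenes therefore demonstrates that the measurement chain is
correct and unbiased *under the stated image model*, not that detection
is robust to every real-world artefact; on real data the threshold
method, base-slice location and channel mapping must be set per dataset
(they are config options, with the base-slice choice left to the user
because bilayer-plane identification is instrument-specific).

## Validation conditions

- *Count/length recovery*: 10 fields × 50 structures at 10% noise;
  detection is expected to be exhaustive (count equal to truth) with
  median |length error| well under the 1 µm z-step.
- *Extent-ratio recovery* uses near-monodisperse scenes (location 30 µm,
  rate 5 µm⁻¹ → lengths 30–30.7 µm). This is deliberate: with the
  extent definitions above, the field-level ratio equals the per-FLS
  truncation fraction only when lengths are nearly uniform — for a wide
  exponential spread the probe extent tracks the point where the
  survival count halves while the actin extent tracks the maximum
  length, and the ratio is analytically smaller than the truncation
  fraction. The near-uniform scene isolates the statistic's intended
  meaning.
- *Tracking recovery*: pure growth at 1.5 µm/min, 60 s frames, 10
  frames, 20 structures; the aligned-profile slope is read by ordinary
  least squares.
- *Telegraph stationarity* is checked on replicate simulations started
  at 15 µm (far from the absorbing boundary, where the symmetric process
  mean is a martingale); single-run slope CIs are not used because the
  ensemble-mean path is autocorrelated.
- Simulation sizes throughout (fields, replicate counts, frame counts)
  are chosen to give stable statistics on a single CPU in minutes.

## Numerical conventions

All geometry is reported in µm (z indices appear only in debug
columns); CSV output is comma-separated UTF-8 with a header row, '.'
decimal and a fixed float format, so identical configuration + seed
gives byte-identical files. Randomness flows exclusively through
`numpy.random.default_rng(seed)`; scene, dynamics and CLI all accept
seeds. Degenerate inputs (empty fields, zero actin extent, base at
background, both bands zero, non-convergent fits) warn and flag rather
than raise wherever a partial result is still meaningful; parameter
validation errors raise `ValueError` with the offending field named.

## Known limitations

- The centroid-chain path length underestimates curved structures.
- No gap closing in z or time: a single dropped slice/frame splits a
  structure or track; this is the conservative reading of the
  consecutive-frame inclusion rule.
- The greedy z-linker is not globally optimal for dense, crossing
  structures (it matches an exhaustive max-overlap assignment on
  separable scenes, which is the regime the admission filters select
  for anyway).
- Extent statistics quantify displacement as defined; they are not
  general colocalization coefficients (Pearson/Manders are out of
  scope).
- The 4PL covariance (and hence fold-change CIs) is the Gauss–Newton
  approximation; for publication-grade intervals on small designs,
  profile likelihood would be preferable.
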