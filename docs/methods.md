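# Methods

## The problem

When a natural killer (NK) cell recognises a target, it forms an immune
synapse and secretes lytic granules — secretory lysosomes ~100–800 nm in
diameter — through its own cortical actin layer. Super-resolution (3D
structured-illumination, ~100 nm lateral resolution) images of the synapse
show that activation does not clear cortical F-actin from the synapse
centre; instead the mesh opens up, and whether a rigid granule can reach
the membrane is a geometric question about the gaps in that mesh. This
package turns that question into a reproducible measurement pipeline:
mesh-hole parameterisation, distance-transform penetrability prediction, 3D
granule localisation and docking statistics, ring geometry, microcluster
kinematics, colocalisation and resolution fits — validated end to end on
synthetic data with exact ground truth.

## Coordinate and unit conventions

Arrays are row-major; pixel `(r, c)` has its centre at physical position
`(x, y) = (c·px, r·px)` with `px` the pixel size. Plane height is
`z0_offset + index·z_step`; "surface" is height 0, and stacks are analysed
to a default depth of 1.0 µm. All reported quantities are physical (nm or
µm); intervals are half-open `[lo, hi)` except the last bin of a partition,
which is closed so fractions conserve 100%.

## Mesh holes

A hole is an 8-connected component of actin-negative pixels inside the
central synapse region; filaments implicitly use the complementary
4-connectivity, avoiding the topological paradox of both tilings being
8-connected. Components below a resolution floor (default 0.01 µm², the
square of the ~100 nm resolution limit) are discarded; holes touching the
region border are flagged and retained by default (a switch excludes
them). Segmentation defaults to Otsu computed within the central region
only, because the bright peripheral actin ring would skew a global
threshold; percentile and fixed thresholds are available, and binary input
passes through untouched so fixtures are analysed exactly.

The summary gap width is `sqrt(mean hole area)` — the side of the
square with the mean area. This convention maps a 0.2 µm² mean hole to
~447 nm and 0.04 µm² to 200 nm; the equivalent-circle diameter
(`2·sqrt(A/π)`, 505 nm for 0.2 µm²) is deliberately not used. The rule is
recorded in output metadata.

## Penetrability

`distance_map` is the exact Euclidean distance transform of the hole set,
reported centre-to-centre: a hole pixel's value is the distance from its
centre to the centre of the nearest actin pixel, 0 on actin. For
penetrability, what matters is the clearance between a granule centred on a
hole-pixel centre and the actin *material*, which begins at the near edge
of the nearest actin pixel — half a pixel closer than that pixel's centre.
A pixel is therefore penetrable by a granule of radius ρ iff

    EDT − ½·px ≥ ρ        (inclusive threshold)

evaluated in integer-squared-pixel arithmetic (`EDT² ≥ (ρ/px + ½)²` with
EDT² an exact integer), so there is no floating-point ambiguity at
equality. On a fixture of square holes of side `s` with `s` and `ρ` integer
multiples of the pixel size, the penetrable region per hole is then exactly
the inner square of side `s − 2ρ` — the analytic identity the acceptance
fixtures rely on (e.g. 100 holes of side 630 nm at granule diameter
100 nm → exactly 28.09% of a 10×10 µm region). When ρ is a half-integer
number of pixels (250 nm diameter at 10 nm/px) no symmetric pixel rule can
remove an odd number of pixel columns from a hole, and the computed
fraction sits one pixel-rim above the analytic value (4.68% vs 4.5% on the
18-hole, 750 nm fixture — within the ±0.25 uncertainty quoted for the
measurement this fixture mirrors). Equivalently, the penetrable set equals
morphological erosion of the hole set by the disc of offsets with norm
< ρ/px + ½; the test suite checks this duality against `scipy` erosion and
the distance map against an O(n²) brute-force nearest-actin search.

Penetrable fractions are reported as percentages of the central region and
are monotone non-increasing in granule diameter by construction. Domains
are connected components of the smallest-band mask (default 200 nm), each
labelled with the largest band diameter whose granule fits through its
widest point (largest inscribed disc, i.e. the component's maximum
clearance), coloured blue→red over 200–800 nm; per-domain centroid
distances are measured from the synapse centre (ring centroid, or the
declared centre for fixtures).

## Ring geometry and the central region

The published definition of an actin ring — a broad band of intense
peripheral staining around a dim centre — is qualitative, so the package
operationalises it on the radial mean-intensity profile about the cell
centroid: a ring is present iff the peripheral profile maximum exceeds the
central baseline (mean over the inner 30% of the cell radius) by a
configurable ratio (default 2.0). Inner and outer diameters are read where
the profile crosses half-way between baseline and peak on either side of
the peak, with linear interpolation between 1-px annular bins; asymmetric
rings therefore report effective (profile-averaged) diameters. The sizing
rule is recorded in output metadata. The central region is the inner-ring
disc intersected with the cell mask; fixtures may declare an explicit
central region instead, which decouples penetrability measurements from the
ring heuristic.

## Granules

Detection: 3D local maxima of the lightly smoothed stack above a robust
threshold (median + 8·MAD by default), localised by background-subtracted
intensity-weighted centroids; peaks closer than ~300 nm in-plane merge into
a single detection rather than being double-counted, mirroring the
instrument's separation limit.

Diameter: a symmetric 2D Gaussian is fitted at the brightest plane and the
PSF removed in quadrature, `d = sqrt(max(FWHM² − FWHM_psf², 0))`, floored
at the 100 nm resolution limit. Quadrature subtraction is exact for
Gaussian-shaped objects; accordingly the synthetic generator renders each
granule as a sphere-equivalent Gaussian whose intrinsic FWHM equals its
true diameter (see below), which makes the estimator self-consistent and
lets parameter-recovery tests probe detection, fitting and noise rather
than a shape-model mismatch.

Docking statistics: height strata use 250 nm bins over 0–1 µm; lateral
distances to the penetrable map ignore the axial coordinate (the measured
quantity is in-plane polarisation); and the docking odds ratio per axial
bin (100 nm bins over 0–900 nm) is

    OR = [p/(1−p)] / [f/(1−f)]

with `p` the fraction of the bin's granules whose lateral centroid lies on
a penetrable pixel of the 200 nm mask and `f` the penetrable fraction of
the central region. This is the standard 2×2 odds ratio on (granule on/off
penetrable) vs (area penetrable/not): OR ≈ 1 for uniformly scattered
granules (calibrated by a 100-replicate null test), > 1 for preferential
docking, with p ∈ {0, 1} reported explicitly as 0 / +∞ and empty bins as
undefined (NaN), never as 0. Ring-relative statistics partition particle
signal by the inner/outer ring borders (three fractions summing to 100% of
in-field signal) and profile it in fixed-width annuli normalised by annulus
area; image input uses thresholded-signal weighting by default, tables of
detections use counts. The MTOC is the single-brightest-blob special case
of the same machinery.

## Dynamics, colocalisation, resolution

Tracking is greedy nearest-neighbour linking with a per-frame gate (default
1.5 µm at 1 s frame interval, above the ~1 µm/s top microcluster speed) and
a one-frame gap tolerance; per-track outputs are mean speed (path length /
duration), net displacement, and a centripetal index (net displacement
toward a supplied centre / path length, +1 for straight inward motion).
Colocalisation is the plain Pearson correlation of paired intensities
within a mask, which is affine-invariant in either channel and undefined
(raised) for constant channels. Resolution measurements fit a sum of 1–2
Gaussians plus constant baseline to a 1D profile, initialised at the
highest profile peaks (leftmost on ties), reporting
`FWHM = 2·sqrt(2·ln 2)·σ` per component.

## The synthetic-data generator

The generator emulates the study conditions, not the biophysics:

* **Mesh fixtures** — regular grids of identical square/circular holes with
  ≥ 1 µm border margins, all dimensions integer multiples of a 10 nm fixture
  pixel, so hole areas and penetrable geometry are analytically exact.
* **Actin images** — a cell disc with a bright peripheral annulus (default
  inner/outer 8/10 µm) and an interior mesh carved with non-overlapping
  circular holes whose areas follow a log-normal with stated mean/SD:
  activated preset 0.25 µm² mean (published regime > 0.2 µm²), inhibitory
  preset 0.05 µm² (< 0.07 µm²). The literal filament network is not
  modelled; only the measured statistics matter for validation.
* **Granule stacks** — granules on a well-separated jittered grid (or
  explicit positions), true diameters Normal(251, 40) nm truncated at
  120 nm, heights uniform over 0–1 µm or "docked" (two-thirds within
  250 nm of the surface). Each granule is rendered as a 3D Gaussian of
  intrinsic FWHM equal to its diameter, blurred by the PSF in quadrature
  (100 nm lateral / 250 nm axial FWHM), default 40 nm pixels and 125 nm
  z-step, Poisson shot noise over a flat background.
* **Rings** — uniform annuli between stated diameters (inner 0 degenerates
  to a disc).
* **Movies** — microclusters starting on a peripheral circle at evenly
  spaced, jittered angles (clusters form all around the periphery and stay
  laterally resolvable), moving radially inward at constant per-cluster
  speeds drawn uniformly from 0.25–1.0 µm/s, imaged at 1 frame/s.
* **Two-channel pairs** — a shared clustered structure plus independent
  Gaussian noise whose variance is set from the signal variance to give a
  chosen expected Pearson correlation.

Every generator writes one ground-truth record per rendered object and is
deterministic given its seed. What the generator does **not** emulate —
filamentous mesh texture, anisotropic/asymmetric PSFs, spectral bleed,
stage drift, granule motion during acquisition, multi-cell scenes — bounds
what passing tests show: they validate the measurement chain under the
stated optical model, not robustness to every artefact of real SIM data.

## Numerical choices and degenerate inputs

Thresholding at equality is inclusive throughout (distance ≥ radius);
penetrability comparisons use exact integer arithmetic. Otsu on a constant
image, an empty granule table, a missing ring, an all-hole distance map,
f ∈ {0, 1} baselines, and flat fit profiles all raise typed errors rather
than returning silent defaults. Statistical summaries report NaN only where
the quantity is genuinely undefined and flagged as such (e.g. distances to
an empty penetrable mask). Tie-breaks: the larger component wins cell
segmentation; two-component fits initialise at the two highest peaks,
leftmost first.

## Problem sizes

Validation runs use 10×10 µm fixtures at 10 nm/px (10⁶ pixels), simulated
synapses of 12 µm at 40 nm/px, granule cohorts of up to 2,014 spots across
56 fields of 9-plane stacks, 100-replicate null calibrations of the odds
ratio, and 200-grid brute-force oracles — sizes chosen so the whole suite
and the acceptance script each complete in well under a minute to a few
minutes on a single CPU while keeping sampling error far below the
tolerances tested.

## Known limitations

* Penetrability is 2D (in-plane clearance); no 3D mesh penetrability and no
  granule deformation beyond the rigid-sphere assumption.
* The segmentation and connectivity used by the original analysis software
  are not published; both are configurable here and the defaults are the
  package's own choices, recorded in output metadata.
* Whether the original penetrability threshold was inclusive or strict is
  unknowable; inclusive (≥) is the default and the alternative is one flag
  away.
* Ring sizing via the radial mean profile under-resolves strongly
  non-circular rings.
* The tracker is a gated greedy nearest-neighbour linker: adequate for the
  sparse, radially moving clusters simulated here, not for dense crossing
  trajectories.
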