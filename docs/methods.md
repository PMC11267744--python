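# Methods

This note documents the models, conventions and numerical choices behind
`safmap`, and what the synthetic validation does and does not establish.

## Scientific setting

Short association fibres (SAF) connect mainly adjacent cortical areas within
the superficial white matter. In the early visual stream, the retinotopic
organisation principle predicts SAF between V1, V2 and V3 only where the
connected patches represent the same visual-field coordinates. Because the
connected patches can be mapped independently with fMRI retinotopy, this
prediction gives a rare *in vivo* validation target for sub-millimetre
diffusion tractography of SAF. `safmap` implements the analysis stack for
that validation: retinotopic sub-area parcellation, tractography with a
matched null model, streamline-to-surface connection assignment, 18×18
connectivity statistics, and exact element-wise significance testing.

## SNR and phase-map smoothing

Per vertex, the SNR of a phase-encoded fMRI time-series is the magnitude of
its discrete-Fourier spectrum at the stimulus frequency divided by the
standard deviation of the magnitude spectrum. Two conventions are
configurable and documented here because the choice is genuinely open:

* the DC bin is always excluded from the spectrum statistics;
* by default the stimulus bin itself is also excluded from the standard
  deviation (`exclude_stimulus_bin=True`), so a strong response does not
  inflate its own noise estimate. The test suite pins both conventions
  against a direct DFT-summation oracle.

Smoothing replaces each vertex value by the mean over its closed 1-ring
(centre included), restricted to vertices with SNR ≥ 5, repeated 4 times.
Low-SNR vertices receive smoothed values but never contribute; a vertex with
no reliable vertex in its neighbourhood keeps its value, so the operation
degenerates gracefully to the identity. Polar angle wraps at 360° and is
smoothed with the circular (unit-vector) mean; eccentricity with the linear
mean. In the exactly antipodal case the mean vector vanishes and the vertex
keeps its value (tie-break, tested). Linear smoothing is contraction-like:
the value range never grows (property-tested).

## Sub-area segmentation

Per area, vertices passing the SNR gate are split by smoothed polar angle
into upper visual hemifield (angle strictly inside (0°, 180°), i.e. ventral
cortex) and lower hemifield (dorsal); boundary angles go to the dorsal set.
Eccentricity is min–max normalised over the area's included vertices and cut
at 1/3 and 2/3 — bins equally spaced in the visual field, corresponding to
≈ 0.89–2.59°, 2.59–4.30° and 4.30–6° for the mapped 0.89–6° range. Bins are
half-open, lower-inclusive, with the last bin closed (deterministic
tie-break at the cuts). Sub-areas are numbered 1–3 dorsal and 4–6 ventral,
central to peripheral; global indices are `area*6 + local` over V1, V2, V3.

Degenerate inputs: an area with fewer than 6 reliable vertices is an error;
an empty hemifield within an area is an error by default because downstream
block bookkeeping assumes all 18 sub-areas can exist — passing
`require_both_hemifields=False` returns the empty sets instead. Vertices
failing the SNR gate are omitted from the parcellation entirely, so
sub-areas contain only retinotopically reliable cortex.

## Tractography

Both trackers propagate bidirectionally from a regular 4×4×4 grid of seed
points per seed voxel with fixed 0.2 mm steps, a 30° cap on the angle
between successive step directions, and a retained-length window of
3–120 mm. The curvature threshold is interpreted as the per-step angle cap —
the simplest faithful reading; it is configurable.

* **ODF tracker**: the ODF is represented non-parametrically as amplitudes
  over a fixed 642-direction icosphere tessellation (antipodally symmetric);
  no spherical-harmonic machinery. The next direction is drawn with
  probability ∝ trilinearly interpolated amplitude among tessellation
  directions within the cone and above the 0.1 threshold; the initial
  direction is drawn ∝ amplitude over all directions, and the second half of
  the streamline starts from the antipodal direction. A walker stops when no
  direction is admissible; amplitudes decay to zero at the grid boundary, so
  leaving the volume terminates naturally.
* **Null tracker**: identical mechanics, but the next direction is uniform
  in the same cone (the initial direction uniform on the sphere) and
  propagation is confined to the white-matter mask (interpolated mask value
  ≥ 0.5); a walker terminates on its first point outside the mask, which
  places null terminations just inside the cortex. Each of the 10 repeats
  per hemisphere uses an independent stream spawned from the seed. Null
  streamlines pass the same length window before counting — whether the
  original analysis filtered null lengths is not documented, and applying
  the identical window is the fair-comparison default.

Voxel↔mm conversion uses a voxel-centre affine convention with 0-based
indices. Step lengths are exact up to float accumulation (~1e-13 per step);
tests allow 1e-6.

## Connection assignment

The cortical ribbon is modelled as a constant-thickness (default 2 mm)
normal offset of the grey/white interface mesh. A point is inside the
cortex when its signed distance along the nearest inner-triangle normal
lies in [0, thickness] (with a lateral guard of the same scale). The
nearest triangle is found from k-d-tree centroid candidates with exact
point–triangle distances; ties at equal distance go to the lowest triangle
index, making endpoint resolution deterministic. This nearest-triangle
reading of "the surrounding vertices" is one defensible interpretation of
an endpoint's surface neighbourhood; it is isolated behind
`CorticalRibbon.nearest_triangle` so alternatives can be swapped in.

Per streamline: (1) segments whose midpoint is inside the ribbon count as
intracortical, and a streamline with intracortical length fraction > 0.8 is
rejected; (2) the termination of each end is the first (last) point inside
the cortex, resolved to the nearest triangle within a 2 mm tolerance;
(3) the subset rule assigns the end to the sub-area containing *all three*
triangle vertices, rejecting border-straddling terminations. Accepted pairs
are normalised so i ≤ j; assignment is invariant to reversing the point
order (tested). Self connections (i = j) are zeroed in the count matrix.

## Matrices, ratios, significance

Percent matrices normalise each unique off-diagonal element by the total
count over all pairs (×100), so the upper-triangle sum is exactly 100; this
holds through hemisphere averaging, which is performed on percent matrices
(not pooled counts), matching the group-averaging procedure. Closeness is
the per-element mean of reciprocal streamline lengths (1/mm); elements with
no streamline are NaN (undefined), never zero. Intra-area blocks are
reported (they are interpreted as false positives, there being no evidence
for intra-area SAF) — never silently dropped. Block contributions are
computed on the group-averaged percent matrix by default; per-hemisphere
matrices are emitted so the other order is available.

The Poisson test is exact and one-tailed with the tail inclusive of the
observed value, `P(X ≥ S)`; discreteness therefore makes it conservative,
which the type-I calibration quantifies. For a zero null mean, p = 1 if
S = 0 and 0 otherwise. Null means are kept as non-integer means of the 10
repeats. The paired t-test uses the one-sided alternative "mean difference
> 0"; zero-variance elements are resolved by the t-statistic's limits
(p = 0 for positive mean, p = 1 otherwise) — these degenerate rules are
explicit so they are testable. No multiple-testing correction is applied;
each element is tested at α = 0.05 on its own (α configurable, 0.01
reported as an option).

## Synthetic cortex: what it emulates, and what not

The generator produces a folded rectangular sheet (sinusoidal folds emulate
gyri/sulci; fold ridges run orthogonal to the eccentricity axis so that
endpoint localisation is exercised on curved cortex), three parallel area
bands V1|V2|V3 sharing borders, eccentricity rising linearly along the
sheet over 0.89–6° (the mapped range of the emulated experiment), polar
angle sweeping 90°→270° per band with mirror reversals at the shared
borders, Gaussian phase noise, and an SNR map with an exact unreliable
fraction. Planted tractograms are U-shaped arcs whose ends sit 0.4 mm above
a triangle wholly contained in the intended sub-area; interior arc points
are clamped below the local surface because U-fibres follow the white
matter under the folds (without this, arcs crossing gyral folds run mostly
inside the cortical band and are correctly removed by the 80 % filter).
The ODF field carries an isotropic baseline (0.12, just above the 0.1
threshold) beneath the pial surface plus Watson-like lobes
(`peak·|d·t|^30`, tube radius 1.2 mm) along planted bundle paths; the
white-matter mask is by construction the set of voxels with maximum
amplitude > 0.1.

Deliberate simplifications: no BOLD physics or haemodynamics, no realistic
DWI signal or spherical deconvolution, no inter-hemisphere anatomical
variability (hemispheres share geometry and differ only in random seeds),
no registration error between diffusion and surface space, and fold
geometry far simpler than real occipital cortex. Passing tests therefore
establish the *internal* consistency and statistical calibration of the
analysis — that planted connectivity is recovered and that the tests
control type-I error under the null — not performance on acquired data,
where gyral bias, crossing fibres and registration error dominate.

### Validation study conditions

The default validation configuration plants, per hemisphere, 600
retinotopic, 6 non-retinotopic and 10 intra-area streamlines (96 %
retinotopic). Non-retinotopic noise connects anatomically adjacent but
retinotopically mismatched sub-areas (eccentricity-neighbour pairs),
emulating the endpoint misassignment that gyral bias produces; its count is
at the scale of the null means, embodying the hypothesis that
non-retinotopic connectivity is artefactual. Problem sizes are the
package's desk-scale choices: 6 synthetic hemispheres (the in-vivo study
analysed 18), a 45×24 mm sheet at 1 mm vertex spacing, a 1 mm ODF grid,
and null seeding subsampled to 24 cortical voxels by an even spatial stride
(the stride keeps null termination coverage spread over the sheet; a random
subsample at this density leaves adjacent elements without null coverage).
The 4×4×4 per-voxel seed grid, 10 null repeats, and all tracking and
filtering parameters are at their full values. The type-I calibration uses
the full 18 hemispheres (it is cheap). Under these conditions the pipeline
reaches planted-pair recovery ≥ 99 %, per-block Poisson sensitivity 1.0 and
specificity ≥ 0.9 across seeds.

## Known limitations

* The ODF tracker samples directions ∝ amplitude; over an isotropic
  baseline this is weakly selective, so bundle-following fidelity depends
  on the peak-to-baseline ratio. The validation pipeline therefore uses
  planted tractograms as the primary truth-bearing input; `tractogram_
  source='odf'` exercises the tracker end to end but is not the default.
* The constant-thickness ribbon has no true pial surface; strongly curved
  or touching folds could misclassify points where offset surfaces would
  self-intersect. Fold amplitude/wavelength defaults stay well clear of
  this regime.
* Amplitude thresholds are compared with a 1e-6 epsilon to absorb float32
  storage rounding of threshold-valued amplitudes.
* With few hemispheres the paired t-test's degenerate zero-variance rules
  carry real weight; with ≥ 6 hemispheres they are rarely exercised.
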