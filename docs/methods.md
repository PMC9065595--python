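# Methods

`veinfem` implements the modelling chain used to study mechanical injury
of cerebral veins during head impacts: build a subject-specific
finite-element (FE) head mesh from a segmented MR image, embed the
venous system as beam elements extracted from a vessel mask, validate
displacement predictions against measured curves with CORA, and
post-process vein-beam trajectories into axial strain / strain-rate
maps that are compared against microbleed locations with tract-level
nonparametric statistics.  The explicit FE solve itself is out of scope:
the package produces the solver input deck and consumes the solver's
nodal output.

## Image-based hexahedral meshing (`hexmesh`)

Each non-background voxel of a tissue label image becomes one 8-node
hexahedral element; nodes sit on voxel corners and are shared between
neighbours, so per-part element counts equal per-label voxel counts by
construction.  Coordinates follow the NIfTI convention: 0-based voxel
indices, voxel centres at integer coordinates, world = affine @ (i,j,k,1)
in mm.

*Lone voxels.*  A 6-connected island of one label, of size at most
`lone_max` (default 1), whose entire 6-neighbour shell carries a single
other non-background label, is reassigned to that label before meshing.
Islands touching the image border are never reassigned (they are not
enclosed).

*CSF layer.*  `ensure_csf_layer` dilates the CSF label into
brain/background voxels that are adjacent to both CSF and skull (two
passes by default), then enforces the invariant directly: no brain voxel
may remain 6-adjacent to a skull voxel.  The final sweep guarantees the
invariant even where the CSF could not propagate within the requested
passes; without it the property would depend on gap topology.

*Smoothing.*  Surface and tissue-interface nodes (corners whose eight
incident voxels disagree) are relaxed by Taubin lambda/mu smoothing
(lambda = 0.5, mu = -0.53, 10 pass pairs by default).  Every step is
quality-gated: a node update that would push any incident element's
scaled Jacobian below `jac_min` (default 0.2) — or its stable time step
below `dt_min` when materials are supplied — is reverted, in up to four
rejection sweeps per step.  Topology is never modified.  The scaled
Jacobian is the min/max ratio of the eight corner Jacobian determinants;
the gate default 0.2 reflects that voxel meshes legitimately contain
moderately distorted surface elements after smoothing and that the
histogram, not a hard floor at 0.5, is the quality metric of interest.

*Quality report.*  Per element: scaled Jacobian, aspect ratio (max/min
edge), characteristic length (volume / largest face area), and the
explicit stable time step `dt = L/c` with
`c = sqrt(E(1-nu) / ((1+nu)(1-2nu) rho))` — units E in MPa, rho in
kg/m^3, L in mm, dt in s.  Face-sharing element pairs between parts
that must not touch (white matter against CSF, grey matter against
skull) are listed as violations.

*Membranes.*  The dura is emitted as one 4-node shell per face between a
skull element and a CSF/brain element.  The falx (tentorium) lies on the
surface where the Euclidean distance transforms of the left and right
hemispheres (cerebrum and cerebellum) cross, restricted to a corridor
within two voxels of either structure; on odd-width gaps the zero-level
voxel pairs with its positive-side neighbour, a deterministic tie-break.
Shells re-use existing solid node ids (common-node tie) and carry a
section thickness (dura 1.0 mm, falx/tentorium 0.5 mm by default).
Shells are geometrically linear 4-node quads with a section flag; a
higher interpolation order would not change the voxel-scale geometry.

*Positioning.*  The mesh is rigidly rotated so the plane through the two
porion landmarks and the orbitale (the Frankfort plane) is horizontal
with the inter-porion line along +y, anisotropically scaled about the
mid-porion point to target head length/width/height, and the centre of
gravity is placed at the occipital condyle plus per-axis fractions of
the head dimensions.  The default fractions (0.0872, 0, 0.1555) are
anthropometric constants and should be overridden per population.

## Vein centerlines and beam mesh (`veins`)

The binary vein mask is skeletonised by 3-D medial-axis thinning
(scikit-image); local radii come from the Euclidean distance transform
(EDT).  Thinning output is cleaned in several radius-aware steps, each
needed because thinning artifacts scale with tube radius:

1. terminal spurs no longer than 1.5x the junction's EDT radius are
   removed; at an end-cap, where the medial surface degenerates into a
   web with a single long continuation, the longest chain is kept as
   the centerline's own tip;
2. adjacent junction voxels are contracted, and junction pairs joined
   by connectors shorter than the local vessel diameter are merged —
   one clean junction per anatomical branching point;
3. terminal branches are pruned when their distal mean EDT diameter
   falls below `min_diameter` (default 0.33 mm) or when they are bare
   one-voxel chains (local 3^3 mask occupancy <= 4.5), i.e. rasterised
   sub-voxel structures.  "Distal" excludes chain voxels within the
   parent's radius of the junction, which belong to the parent vessel.

Chains are smoothed with a 5-point moving average (interior voxels
only) to remove the digital staircase that otherwise inflates arc
length by 5–15%, and terminal ends are extended by a distance-ridge
march: straight steps along the local axis are allowed as long as the
full cross-section persists laterally (flat end-caps), otherwise the
heading follows the EDT ridge until the value drops below the endpoint
level, which marks the true vessel end.  Paths are resampled to an
arc-length spacing of at least `min_node_distance` (default 1 mm), with
radii linearly interpolated along arc length; radii in the terminal cap
region inherit the first interior value because the EDT there measures
the cap, not the wall.

On seeded tube and branching-tree phantoms this recovers total
centerline length to within ~5% and mean radius to well under half a
voxel.  Known limits: tubes with sub-voxel radius rasterised obliquely
have no recoverable centerline; at Y-junctions the medial axis
genuinely deviates from an idealised point-branching polyline by up to
about one vessel diameter, which dominates the residual length error.

Each consecutive node pair becomes a 2-node beam element with an
annular (hollow circular) cross-section: outer diameter d = sum of the
two node radii, wall thickness from the linear regression
`h = 0.0732 d + 0.0411` (mm), which was fitted to individually measured
literature values (R^2 = 0.81); `fit_thickness_regression` refits from
any user-provided (d, h) table and returns slope, intercept, R^2 and the
two-sided slope p-value.  Diameters below ~0.096 mm make 2h >= d and
raise.  The wall material is linear elastic with a single modulus
E = 3.63 MPa — the secant slope of the linear region of axial
stress-strain tests on human cerebral veins, after excluding the toe
region — and Poisson ratio 0.45 (near-incompressible soft tissue).
`elastic_modulus_from_curve` computes the secant over a caller-given
strain window, or over the widest window where the local slope is at
least half its maximum when no window is given.

## Solver deck I/O (`keyword_io`)

Meshes are serialised to a comma-separated keyword deck (`*NODE`,
`*ELEMENT_SOLID/SHELL/BEAM`, `*SECTION_BEAM`, `*MAT_ELASTIC`, `*PART`,
`*CONSTRAINED_BEAM_IN_SOLID`).  The annular beam section is written as a
tube with outer/inner diameters (d, d - 2h); the coupling card ties the
vein beam part to every brain solid part, delegating the kinematic
constraint of beam nodes inside solid elements to the solver.  Unit
system mm-ms-g (stress in MPa), stated in the header.  The reader
inverts the writer on this subset (unknown cards pass through verbatim
with a warning), and write-read-write is byte-stable because all floats
are emitted at fixed 1e-6 precision.

## CORA curve rating (`cora`)

Two sub-methods on a common uniform time base (linear resampling to the
coarser curve's step):

* corridor: per-sample score 1 inside the inner corridor
  (+-a_0 * peak of |reference|), 0 outside the outer (+-b_0 * peak),
  linear in between; averaged over the evaluation interval, which runs
  from the first sample with |reference| >= a_thres * peak to the last
  with |reference| >= b_thres * peak;
* cross-correlation: the shift delta* maximising normalised
  cross-correlation within +-d_max * T (ties to the smallest |shift|)
  gives the shape rating (clipped at zero for negative correlation),
  the phase rating (1 below d_min * T, 0 above d_max * T, linear
  between) and the size rating (ratio of summed squared amplitudes over
  the aligned overlap, smaller over larger).

Total = w_corridor * corridor + w_cross * (0.5 shape + 0.25 size +
0.25 phase), all clipped to [0, 1].  Parameters live in explicit
presets: `"default"` weights corridor and cross-correlation 0.5/0.5;
`"giordano"` — the configuration used for brain-displacement rating,
where corridors would require repeat experiments — sets the corridor
weight to zero (a_0 = 0.05, b_0 = 0.5, a_thres = 0.03, b_thres = 0.075,
d_min = 0.01, d_max = 0.12, unit exponents).  Totals map onto ISO/TR
9790 biofidelity bins (excellent > 0.86, good > 0.65, fair > 0.44,
marginal > 0.26); the bin edges are configurable because published
usages of the scale differ slightly at the marginal boundary.

## Strain post-processing (`strain`)

From beam node coordinates sampled every 0.5 ms: engineering axial
strain eps(t) = (L(t) - L0)/L0 per element (L = inter-node distance),
strain rate by central differences on the stored grid (one-sided at the
ends), in 1/s.  Engineering strain matches how vessel failure strains
are reported experimentally.  Per-element peaks are maxima over the
stored samples (no sub-sample interpolation).  Peaks are scattered into
a reference image grid at the voxel containing each element's
*undeformed* (t0) midpoint — keeping the map registered to the model
image — via inverse affine + floor; collisions keep the maximum;
midpoints outside the grid are dropped, warned about and counted.

The sparse map is smoothed by a max dilation then a mean-of-non-zero
dilation over a spherical footprint of radius 5 mm (the fslmaths
dilF/dilM semantics; the footprint radius, not a Gaussian sigma, is the
kernel parameter).  Pass 1 is extensive; pass 2 never exceeds the pass-1
maximum.

## Tract statistics (`roistats`)

The tract atlas is expanded by one modal-label dilation (background
voxels take the most frequent neighbouring label in the 3^3
neighbourhood; existing labels are never overwritten; ties go to the
lowest id) so that the sparse vein elements fall inside tract extents.
A tract is "with microbleed" iff at least one microbleed-mask voxel
lies in its dilated extent.  Elements — not voxels — are the
statistical unit; each element is assigned by its midpoint voxel, using
the raw unsmoothed peaks.

Group comparison uses the two-tailed Mann-Whitney U test: exact
enumeration when n1*n2 <= 10^4 and the pooled sample is tie-free,
otherwise the tie-corrected normal approximation without continuity
correction (so the k = 2 Dunn z is identical).  Per-tract comparison
uses the tie-corrected Kruskal-Wallis H (df = k-1; all-identical data
returns H = 0, p = 1 rather than erroring) followed by Dunn's pairwise
z tests from pooled ranks with the tie term, two-sided, Bonferroni
m = k(k-1)/2.  Summaries per group/tract: n, median, mean, sample SD
and the 95th percentile by linear interpolation between order
statistics.  Tracts with fewer than 40 elements are flagged low-count
and can be excluded in a sensitivity re-run.

## Phantoms (`phantoms`) — what they emulate and what they do not

All inputs are generated with seeded NumPy generators and are
bit-reproducible.

* `head_phantom`: nested tissue ellipsoids (scalp 90/75/81 mm semi-axes
  down to white matter, ~3 mm voxels on a 64^3 grid, +-2% seeded jitter)
  with a one-voxel mid-sagittal CSF plane splitting the hemispheres, a
  one-voxel axial CSF plane above an inferior cerebellum compartment,
  and a guaranteed >= 1-voxel CSF layer between brain and skull.
* `vessel_phantom`: branching tube trees (trunks 10–14 mm, branches
  6–9 mm, radii 0.6–1.1 mm shrinking 0.8x per generation, branching
  angle 32 degrees, mild tortuosity) rasterised at the 0.33 mm vein-mask
  resolution, with the generating polylines and radii returned as
  ground truth.  New growth keeps clear of previously laid tubes so
  distinct branches never merge in the mask, and stubs shorter than a
  few radii are dropped from both mask and truth — otherwise the truth
  would claim geometry the mask does not resolve.
* `motion_generator`: `rigid` integrates a half-sine rotational
  acceleration pulse (presets 20/40 rad/s peak velocity x 30/60 ms
  duration) into a strain-free rigid rotation; `affine` ramps a linear
  map with closed-form element strain; `smooth-field` superposes
  localized Gaussian displacement bumps (optionally radial-expansion
  bumps, which stretch elements of every orientation) over an optional
  global affine background.
* `plant_microbleeds` places a small voxel cluster at the peak-strain
  voxel of the tract with the highest 95th-percentile strain (or a
  seeded random tract), intersected with that tract.
* `cora_pair` produces a reference waveform and a shifted/scaled/noisy
  copy with the perturbation recorded.

The phantoms capture the *contracts* of real data (nested tissues,
tubular vessels with known calibre, isometry-dominated head motion with
localized strain concentration, microbleeds co-located with high
strain) but none of its texture: no segmentation noise, no partial
voluming, no contact mechanics, no physiologic vessel tapering, and
tract "atlases" are rectangular blocks.  Passing tests therefore
demonstrate algorithmic correctness at known ground truth, not clinical
performance.

## End-to-end experiment (`workflow`)

`microbleed_recovery_experiment(seed)` runs: vessel phantom (four
trees, three branch generations, ~100–200 beam elements) ->
centerlines -> beam mesh -> smooth-field motion with a radial
high-strain bump centred in the best-populated block tract plus a mild
global stretch/shear background -> strain peaks -> peak voxel map ->
microbleeds planted in the top-strain tract -> dilated atlas ->
with/without-microbleed group comparison.  Recovery means the
with-group median and 95th percentile exceed the without-group's with
Mann-Whitney p < 0.05.  Across seeded replicates the recovery rate is
>= 90% (observed ~100% over 140 development seeds); problem sizes were
chosen so a full 100-seed replicate runs in a few minutes on one CPU.

## Numerical choices and degenerate inputs

* Scaled-Jacobian gate 0.2, smoothing 10 Taubin pairs; 0 iterations is
  an exact identity.
* Element-to-voxel assignment floors the continuous voxel coordinate —
  boundary points resolve deterministically toward the lower index.
* Mann-Whitney with all values identical returns U = n1 n2 / 2, p = 1.
* Zero-variance CORA references raise (undefined correlation); random
  walk pairs are clipped into [0, 1].
* Zero initial beam length raises, naming the offending elements;
  coincident resampled centerline nodes are merged before beam
  construction so zero-length elements cannot arise from extraction.
* All seeds are plain integers below 2^31; a fixed seed reproduces
  every generator output bit-for-bit.
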