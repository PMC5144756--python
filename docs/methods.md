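# Methods

This note records the models implemented in `tractatlas`, the parameters
that matter, the numerical choices made where the design was open, what the
synthetic data does and does not emulate, and known limitations.

## Coordinate conventions

All geometry is kept in world RAS millimeters. Voxel indices are 0-based;
masks carry a `voxel_to_world` affine. TrackVis streamlines are converted
to world mm on load via the header affine (delegated to nibabel, which
implements the voxmm/corner conventions of the format); polydata files are
assumed to store world coordinates already. The atlas frame places the
midsagittal plane at x = 0: reflection (x → −x), bilateral distances, and
hemisphere splitting all refer to that plane. Synthetic cohorts are built
mirror-symmetric about x = 0, and groupwise registration keeps the group
mean at identity, so the synthetic atlas frame satisfies the convention by
construction; with real data the input group frame is assumed
AC-PC-aligned with a midline at x = 0.

## Fiber distance and affinity

Fibers are resampled to `n_points` (default 15) equal-arclength points.
The default distance is the mean corresponding-point distance, minimized
over the forward and reversed orderings of the second fiber, making it
orientation-invariant, symmetric, and zero on identical fibers. A
symmetrized mean closest-point distance is available as an alternative;
being a per-point minimum it is never larger than the corresponding-point
mean. With `bilateral=True` the distance is the minimum of the direct
distance and the distance to the mirrored fiber, equivalently the maximum
of the two Gaussian affinities; this is what lets one cluster span both
hemispheres. Affinity is `exp(-d²/σ²)`.

Pairwise distance matrices are computed per resampling point with Gram
matrices (`‖a−b‖² = ‖a‖² + ‖b‖² − 2a·b`), i.e. p small GEMMs instead of a
4-D broadcast. The cancellation in this form limits self-distance accuracy
to ~1e-8 mm, far below any scale of interest here.

## Entropy-based registration

The cost of a moving fiber set against a pool is
`−Σ_i log(mean_j exp(−d_ij²/σ²) + ε)` with ε = 1e−12 guarding underflow
when a fiber is far from the whole pool. Lower cost means the moving
fibers sit in denser parts of the pool's fiber distribution. The sigma
schedule is (20, 10, 5, 2) mm — the stated endpoints of the multiscale
schedule, filled in with a roughly geometric ladder for coarse-to-fine
stability.

Affines are parameterized as translation · rotation (ZYX Euler) · scale ·
shear about the moving set's centroid, with scales in log space so the
determinant stays positive. Optimization is a derivative-free Powell
search applied to one parameter group at a time (translation → rotation →
scale → shear), with bounded steps; a group's result is accepted only if
it lowers the cost, so the objective is non-increasing along the accepted
trajectory. Gradients of the objective through the min-over-orderings
distance are unreliable, which is why a direct-search method is used.

Groupwise registration sweeps the subjects in leave-one-out fashion per
sigma level (one sweep per level by default) and, after each sweep,
composes every transform with the inverse of the group-average matrix.
This "mean removal" is what makes the registration unbiased: the group
frame cannot drift toward any subject. The arithmetic matrix mean is used;
for the small jitters considered here it stays orientation-preserving.
Registration subsamples a fixed, seeded set of fibers per subject once per
run (not redrawn per iteration), which keeps runs reproducible.

The b-spline stage refines each subject with a cubic free-form
displacement field over the padded group bounding box, coarse-to-fine
through (4³, 6³, 8³) control grids, under the same objective at the finest
sigma. Control displacements are the spline coefficients (evaluated with
`map_coordinates(order=3, prefilter=False)`) and are clipped to 0.4× the
control spacing as a folding guard. Grid transforms are forward-only; no
inverse is provided. Patient-to-atlas registration is affine only by
default, matching the application pipeline; the b-spline stage exists for
atlas building.

## Nyström spectral embedding

Degrees are estimated from the sample block's row sums: for sample fiber
i, `d_i = Σ_j A_ij` over the m samples, and for any fiber x the extension
degree is the sum of its affinity row to the samples. The embedding of x
is its degree-normalized affinity row projected onto the sample
eigenvectors, scaled by 1/eigenvalue. Using the identical estimator at fit
and extension time has two consequences worth the choice: a sample fiber's
out-of-sample embedding reproduces its fitted coordinate exactly, and with
m = N the construction coincides with the dense normalized-cuts embedding
(the property the dense-oracle test checks). The alternative — degrees
estimated from sample-plus-extension blocks via the inverse of the sample
affinity — was rejected because the Gaussian kernel block is frequently
near-singular (near-duplicate fibers), making the inverse numerically
fragile. All p retained eigenpairs are used as coordinates, including the
leading one; it is nearly constant across fibers and is harmless to
k-means. Eigenvalues are floored at 1e−12 before the 1/λ scaling. Fibers
whose mean affinity to every sample is below 1e−8 (i.e. geometrically off
the atlas) are placed at the origin and flagged; the flag propagates into
the application-time outlier flag.

Defaults at full scale are the study conditions: 800 clusters, 2500
Nyström samples, 10,000 fibers per subject at ≥60 mm length for
clustering; 20,000 fibers per subject at ≥40 mm for registration. The
clustering kernel width (σ = 30 mm) and embedding dimensionality (p = 20)
are not pinned down by those conditions; 30 mm matches bundle-scale
separation for 40–120 mm fibers, and 20 eigenvectors comfortably exceed
the intrinsic dimensionality of the synthetic scenes. K-means uses
k-means++ seeding with 10 restarts and a fixed seed; labels are
canonicalized by descending cluster size so runs are comparable.

## Outlier rejection and atlas statistics

Per round: leave-one-subject-out fiber probabilities within each cluster,
rejection of fibers below `μ_c − 2 s_c`, then re-embedding and
re-clustering of the survivors. The Nyström sample is reused minus its
rejected members rather than redrawn, keeping rounds comparable. Final
per-cluster (μ_c, s_c, n_c) statistics are computed on the surviving
fibers and stored in the atlas together with the surviving resampled
fibers; at application time a patient fiber's probability is its mean
affinity to the stored training fibers of its assigned cluster
(subject-level exclusion is impossible for a new subject), and the stored
statistics drive the same 2-SD rule.

Cluster presence is defined as ≥1 non-outlier fiber assigned (in either
hemisphere); the threshold is configurable. Hemisphere labels use a
point-fraction rule: ≥80% of points at x < 0 → left, ≥80% at x > 0 →
right, otherwise commissural.

## Signed distance and tract volume

The signed distance field of a mask is `+EDT(background) − EDT(foreground)`
with anisotropic voxel spacings honored, i.e. distances between voxel
centers, matching a brute-force nearest-voxel search exactly. Tract
evaluation resamples fibers to ≤1 mm steps and takes the minimum of the
trilinearly interpolated field; points outside the volume contribute a
positive clamp and set a flag. Distances are therefore measured to the
mask's voxelization rather than a triangulated surface model; the two
agree to within about half a voxel, and dropping the meshing step removes
a dependency without changing the statistic's meaning. A minimum of
exactly 0 (boundary contact) counts as intersecting. Tract volume counts
distinct voxels (default 2 mm) touched by fibers resampled at half-voxel
steps, reported in cc; it depends on the voxel size, which is therefore
explicit.

## Synthetic data

`synthdata` generates brain-scale scenes: six default bundles (vertical
arc, C-shaped arc, long straight runs, a hook, a cingulum-like arc) with
centerlines 80–120 mm long in one hemisphere, mirrored about x = 0 for
bilateral scenes, with smooth per-fiber offsets of 2.5 mm dispersion drawn
from spline-interpolated Gaussian control points. Minimum inter-bundle
separation (~25 mm) is an order of magnitude above the dispersion, so the
planted partition is unambiguous. Outlier fibers are smooth random
polylines spanning the scene box — plausible-but-wrong trajectories rather
than white noise, mimicking spurious fibers present in only one subject.
Cohorts apply per-subject affine jitter (defaults up to ±10 mm, ±10°,
scale 0.9–1.1 in the test scenarios); the drawn jitters are centered so
their group mean is the identity, because any groupwise registration can
recover transforms only up to the group mean, and an uncentered 3-subject
draw would make inverse-recovery ill-posed. The tumor model deletes fibers
entering a sphere and pushes surviving points radially outward with a
Gaussian falloff; it is a deliberately simple stress test of assignment
robustness, not a biophysical model of edema or infiltration.

What passing tests on this data do *not* show: robustness to realistic
tractography noise (kinked or truncated fibers, seeding-density bias),
to anatomically adjacent bundles separated by less than the kernel width,
or to the fiber-count imbalance of real whole-brain tractography. The
synthetic scenes establish correctness of the machinery under the stated
statistical structure, not clinical performance.

## Problem sizes

Desk-scale runs use 5-subject cohorts with 6 bilateral bundles of 25
fibers (~316 fibers/subject), k = 6, m = 400 Nyström samples, 100–400
fibers per subject for registration/clustering, and 10–15 resampling
points. These sizes were chosen so the full pipeline — groupwise
registration, two outlier rounds, atlas application — completes in a few
minutes on one CPU while leaving every statistical margin (bundle
separation vs. dispersion, outlier fraction vs. rejection threshold) at
the same ratios that hold at full scale.

## Known limitations

- Affine mean removal uses the arithmetic matrix mean, valid for small
  deviations; large rotations would call for a log-Euclidean mean.
- The b-spline stage optimizes all control points jointly with a very
  small Powell budget; it reduces planted smooth warps but is not a
  production nonrigid registrar.
- The entropy objective is optimized by local search from identity;
  initial misalignments far beyond the coarsest sigma (≫20 mm
  translation, ≫30° rotation) can fall outside its capture range.
- Bilateral clusters mean a structure present in only one hemisphere is
  still "present"; per-hemisphere presence requires combining
  `cluster_presence` with the hemisphere labels.
- TRK output does not carry cluster labels (format has no cell data);
  polydata formats do.
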