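# Methods

This note records the models behind each module, the numerical choices
that were genuinely open, and what the synthetic phantoms do and do not
establish about real material.

## Cross-sectional geometry

A section is a binary mask of cortical bone with isotropic pixel
spacing; columns are mediolateral (x), rows anteroposterior (y). TA is
the area of the mask with its enclosed cavity filled; filling flood-fills
the complement from the image border with the standard topological
pairing (cortex 8-connected, background 4-connected) so a diagonal
cortical wall cannot leak. A mask with more than one 8-connected
component, or one touching the image border, is rejected — an open ring
whose cavity drains to the border is indistinguishable from a solid
section, so border contact is treated as the detectable proxy for a
broken ring.

Each cortical pixel contributes as a solid square, adding the s⁴/12
self-moment to the parallel-axis term. Against point-mass pixels this
roughly halves the resolution needed for 1% agreement with continuum
values on elliptical-annulus phantoms; the freeware tools this mirrors
do not document their pixel model, so the convergence suite (spacing at
min(semi-axis)/50) is what anchors accuracy. Imax/Imin are eigenvalues
of [[Ix, −Ixy], [−Ixy, Iy]]; the principal-axis angle is
½·atan2(2·Ixy, Ix − Iy), reported in (−90°, 90°] measured
counterclockwise from the mediolateral axis. Total bone length for
section placement is always user input; the package never estimates it.

Phantom oracles use the elliptical-annulus closed forms (TA = πab,
Ix = π/4·(a_o b_o³ − a_i b_i³), …) with rotation handled by rotating the
second-moment tensor, exact at any angle.

## Dental volumetrics

The tooth model is a labeled voxel grid (background/enamel/dentine/pulp;
cementum merged into dentine) with two user-supplied reference planes
perpendicular to the occlusal (z) axis: the cervical (CEJ) plane and the
root-bifurcation plane. Both are validated, never inferred — CEJ
placement on real scans is a judgment call this package does not try to
automate. A voxel belongs to a region iff its center does; the same rule
drives the phantom rasterizer, so voxel counting is an unbiased area/
volume estimator.

Vcervix is the entire pulp system above the bifurcation plane (coronal
chamber plus cervix canal) and Vbranch the canal volume below it; the
Keene bands are half-open ([0,25), [25,50), [50,75), [75,100]) so the
one-decimal printed limits (24.9 etc.) classify unambiguously.

HMH thresholds are plateau midpoints per material interface. For noisy
volumes `segment_tissues` offers a median denoiser over a spherical
(Euclidean-ball) footprint: banded thresholding misreads any blurred
dentine/background boundary as pulp if a linear filter is used (the
partial-volume effect), while an order-statistic filter preserves
plateaus; the ball footprint, rather than a cubic window, keeps the
curvature bias on thin root canals negligible (volume bias < 0.1% on the
shell phantom at 5%-of-contrast noise).

The EDJ surface is the marching-cubes triangulation of the coronal
dentine+pulp region, keeping only triangles with enamel just beyond
them (probed on both sides of each face, so winding conventions do not
matter). The indicator is first smoothed with a fixed sub-voxel Gaussian
(σ = 0.6 voxel): triangulating the raw binary mask carries a +6–8%
staircase bias on curved interfaces regardless of resolution, while the
sub-voxel kernel recovers the interface crossing without displacing it —
measured bias on the hemispherical phantom is within ±1.5% across 16–33
voxels per dentine radius, against the 3% tolerance the module promises.
σ is a fixed numerical constant of the estimator, not a tuning knob.

The occlusal basin plane is found from the top-surface height map of
the enamel: grayscale hole-filling (morphological reconstruction by
erosion) identifies the central concavity enclosed by the cusp rim; the
plane passes through the basin's lowest enamel voxel. A monotone cap has
no basin; the plane then falls back to the lowest occlusal enamel voxel
and is flagged. Lateral metrics re-count volumes and EDJ faces inside
the slab between the CEJ and basin planes with the same center-inclusion
rule.

Phantom geometry: enamel cap of thickness t over a dentine hemisphere
(radius R) holding a hemispherical pulp chamber (radius p), on a
cylindrical root whose canal (radius p) splits at the bifurcation plane
into two half-radius branches. All oracle volumes are sphere/cylinder
closed forms; an optional spherical-cap dimple of known depth gives the
basin-plane test its ground truth (the removed enamel is a two-sphere
lens, also closed-form). The balanced variant solves
L = 3b + 4p/3 so that Vcervix = Vbranch exactly, pinning the VBI to the
50% band edge; its default voxel (p/24, with the bifurcation offset and
root length exact voxel multiples) keeps the voxel-counted VBI within a
fraction of a percent of 50.

Convergence caveat: the "2% at ≥16 voxels across the dentine radius"
statement holds for structures at the crown scale. The branch canals are
the smallest features (radius p/2); they need roughly ≥5 voxels across
their own radius before Vbranch settles inside 2%, which the default
test phantoms provide.

## Thickness mapping

The shape diameter function casts `n_rays` rays per vertex in a cone of
`cone_half_angle` about the inward normal; each ray's length is its
first exit through the mesh, rays deviating from the per-vertex median
by more than `outlier_sd` standard deviations are discarded, and the
value is the mean of the survivors weighted by 1/(1 + angle-to-normal).
Defaults (60°, 30 rays, 1 SD) follow the published filter description;
all are exposed. Cone directions are a deterministic low-discrepancy
spiral — the seed only rotates it — and the per-vertex frame is built
from the lowest-index neighbor edge, an intrinsic construction, so
values are reproducible bit-for-bit under a fixed seed and invariant
under rigid motion to floating-point accuracy (~1e-8 absolute; exact
1e-9 equality is not attainable after a float rotation of the
vertices). Ray–mesh intersection is a vectorized Möller–Trumbore over
all faces, chunked to bound memory, with origins offset by
1e-6 × bounding-box diagonal to skip self-hits.

Interpretation caveat: on thin shells a wide cone lets most rays miss
the opposite wall and cross the lumen, so wall-thickness readings
require a narrow cone (the phantom suites use 15°); the wide default
matches the filter's original local-diameter use. The outlier trim
targets concave fossil geometry; on noiseless convex phantoms it is the
dominant source of vertex-to-vertex dispersion, which is why the
ray-count convergence check relaxes it.

Colorization maps [min, max] affinely onto the blue→red scale (a
constant field maps to the midpoint), optionally quantized into bins.

## Trait clustering

Distances are mismatch proportions over pairwise-complete traits; the
per-pair denominators are returned so small overlaps are visible.
Missing-data policy: a trait constant among its observed values is a
dummy and excluded; pairs sharing no observed trait are an error rather
than an imputation. WPGMA is implemented directly (the merged cluster's
distance to a third is the unweighted mean of its constituents') so the
tie rule can be fixed: the lowest-index pair merges first. With tied
distances — common for mismatch fractions on few traits — the tree
therefore depends on input order by construction; tie-free inputs give
order-independent trees. "Squared-interval" clustering (the default)
squares the distances before agglomeration; the alternative reading,
squared Euclidean distance on raw binary vectors, is proportional for
binary data and reachable with `square_first=False` on pre-squared
input. Merge tables use the SciPy linkage layout, so cutting, cophenetic
distances and plotting interoperate with `scipy.cluster.hierarchy`.

## Craniometric morphospace

PCA is computed on the Pearson correlation matrix: eigenvalues sum to
the number of variables, each variable enters standardized, and the
variance share of component k is 100·λk/p. Signs are fixed by making
each component's largest-magnitude loading positive. Missing data:
complete-case by default, per-variable mean imputation as the
alternative; with 23 variables even modest missingness can leave fewer
complete rows than variables, at which point the correlation matrix is
singular and the adequacy statistics refuse rather than regularize.
KMO is computed from anti-image partial correlations (off-diagonal of
the scaled inverse correlation matrix); Bartlett's statistic is
−(n−1−(2p+5)/6)·ln det R on p(p−1)/2 df, with p-values floored at
1e-300. Group ellipses scale covariance eigen-axes by
√(λ·χ²₂(confidence)); groups under 3 members are skipped with a
warning and collinear groups flagged degenerate. No component rotation
is offered.

## Synthetic data: what passing tests show

The generators emulate geometry and sampling, not biology: hollow
ellipses are not bone microarchitecture, the shell tooth has no crown
relief beyond an optional dimple, trait noise is independent
label-flipping, and craniometric tables are homoscedastic Gaussians
with shared covariance. Passing suites therefore establish that the
estimators are correct and convergent on known geometry — not that
segmentation choices, wear, or population structure in real material
are handled; those remain the analyst's judgment. Default study
conditions used by the suites: annulus rasters at min(semi-axis)/50
spacing; tooth phantoms at 0.15 mm voxels (33 across the dentine
radius); two planted trait clusters of 10 individuals, 30 traits, 5%
flip noise; two craniometric groups of 100 with a 3·SD offset on five
of 23 variables. These sizes keep the full test suite under a few
minutes on one core.

## Interfaces

The package is a library: the importable API plus the narrative scripts
in `examples/` are the interface, with TIFF+JSON-sidecar and CSV/PLY/
Newick helpers in `paleomorph.io` for interchange with imaging and
phylogenetics tools. No console entry point is installed; each example
is a template for the corresponding command-line workflow.
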