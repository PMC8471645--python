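# Methods

This note records the models, conventions, and numerical choices behind
`maskrepro`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design being analysed

The pipeline targets paired test–retest segmentation studies: each subject
is scanned twice (here emulating a prostate cohort whose second scan is an
in-bore biopsy procedure, with the gland compressed by the needle-guiding
probe and the patient prone rather than supine), and each scan is segmented
by several methods — a manual reference plus CNN-based methods of graded
quality. Labels are fixed as 0 = background, 1 = peripheral zone (PZ),
2 = remaining zones (non-PZ); the whole gland (WP) is their union, and
non-PZ can equivalently be derived by subtracting PZ from WP. For methods
that predict WP and PZ independently, `compose_wp_pz` clips PZ voxels
falling outside WP (set-difference reading) before deriving non-PZ.
Volumes are canonicalized on load to slice × row × column axis order via
the NIfTI affine, so the plane-dependent 2D diameters are well defined.

## Post-processing

The largest 3D connected component (default 26-connectivity) is retained
*per zone* (PZ and non-PZ separately), and WP is re-derived by merging
afterwards; applying the rule to WP instead could preserve a PZ satellite
glued to non-PZ. Ties between equal-sized components are broken by keeping
the component containing the lexicographically smallest voxel index — the
rule is otherwise non-deterministic, and determinism is required for
reproducible reports. An empty zone is logged, not raised: simulated
gross failures must flow through the pipeline, not crash it.

## Shape features

All 14 features are computed in physical millimetres.

**Surface mesh.** Marching cubes (scikit-image's Lewiner variant) at
iso-level 0.5 on the bounding-box crop of the mask, zero-padded and passed
through a Gaussian anti-aliasing filter of σ = 0.8 voxels per axis
(pad = ⌈3σ⌉+1 so the surface always closes). Meshing the raw binary grid
instead inflates surface area by ≈ 8.5% through staircase artifacts, which
would make sphericity of a digitized sphere ≈ 0.92; with anti-aliasing the
test suite measures, on 0.5 mm phantoms, volume bias under 1% and area
error under 1% (sphere sphericity ≈ 0.993). σ was fixed by this bias/area
trade-off: larger σ shaves convex volume (curvature shrinkage ∝ σ²·H),
smaller σ readmits staircase area. Masks whose smoothed peak does not
reach the iso-level (a single voxel, a single-slice sheet) fall back to
meshing the binary grid, so degenerate masks still mesh; the frozen
regression values for a unit voxel under this fallback are volume 1/6 mm³
and hull diameters 1 mm. Vertices are computed in index space and scaled
by the spacing in float64, making the spacing-scaling laws (volume ×s³,
area ×s², lengths ×s) exact to floating precision. The filter runs in
float64 and is quantized to float32 so the separable filter's axis-order
rounding cannot break symmetry under axis permutation. The convention
string is recorded in report provenance (`mesh_method`).

**Known asymmetry.** Marching cubes re-triangulates ambiguous cells
differently after an axis permutation: surface area is stable to ~1e-8
relative but enclosed volume shifts by a sub-voxel amount (~2.5e-5 relative
on a ~2100 mm³ phantom; both scikit-image variants behave identically).
Voxel-coordinate features (voxel volume, axis lengths, elongation,
flatness) are exactly invariant under 90° axis-aligned rotation; mesh
features are asserted invariant to 1e-4 relative.

**Features.** Mesh volume by signed tetrahedra (divergence theorem;
requires a watertight, consistently wound mesh — a flipped face raises),
surface area as the triangle-area sum, voxel volume as count × voxel
volume. Axis lengths are 4√λᵢ from the population covariance (divisor N)
of foreground voxel-center coordinates — the 4√λ convention presumes the
population form, and for a solid ellipsoid λᵢ = (semi-axis)²/5 gives the
analytic check. Maximum diameters are vertex-pair distances computed on
the convex hull (the maximum is attained there; exactness preserved,
complexity reduced), with the 2D variants measured on hull projections:
"slice" drops the slice coordinate (row–column plane), "column" the column
coordinate (slice–row plane), "row" the row coordinate (slice–column
plane). Degenerate masks: empty masks raise; a single voxel yields zero
axis lengths and NaN elongation/flatness with a warning; NaN feature rows
propagate to complete-case exclusion in the statistics.

## Agreement statistics

"Two-way random, single score" ICC is implemented as Shrout–Fleiss
ICC(2,1), absolute agreement:

ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)),

with the F-based confidence bounds using the Satterthwaite degrees of
freedom of McGraw & Wong (the test suite cross-checks both estimate and CI
against `pingouin`'s ICC(A,1), and the estimate against a brute-force
sums-of-squares oracle to 1e-10). Conventions for edge cases: a table with
zero total variance, or with exactly identical columns, has perfect
agreement by definition (ICC = 1, CI [1, 1], the first with a warning);
CI bounds are clipped to [−1, 1] and forced to bracket the estimate.
Rows with missing values are dropped (complete case) — single-score ICC
needs a full n × k table. The permutation test uses a fast vectorized
point-estimate path (`icc_point_batch`) over row subsets.

Other choices, each recorded where it matters: CI-overlap significance
treats touching intervals as overlapping (the conservative reading);
a method is "comparable" to the reference on a feature when the CIs overlap
or the method's ICC is at least as high. Wilcoxon drops zero differences
(classical variant, not Pratt), using the exact null for small tie-free
samples and the tie-corrected normal approximation otherwise (scipy's
policy). Benjamini–Hochberg is the step-up procedure via statsmodels; in
the pipeline the default correction family is the per-region set of
volume-comparison tests (`bh_family="region"`), with a pooled option —
the family definition is genuinely a modelling choice, so it is exposed
rather than hard-coded. Bland–Altman uses bias ± 1.96·SD with the sample
(n−1) standard deviation. The inter-scan volume change is summarized as
the median of per-subject percentage differences, 100·(scan2−scan1)/scan1.

## Quality-control filtering and the permutation test

A subject is excluded when its quality score is strictly below the
threshold (default 85) on either scan; a score exactly at the threshold is
kept. The permutation test excludes the same *number* of subjects (both
scans together — the filter's exclusion unit is the patient) uniformly at
random, recomputes ICC(2,1) on the remainder for each of `runs` draws
(default 1000), and counts permuted values ≥ the observed post-filter ICC;
ties count toward the null. Significance is n_ge < 0.05·runs (< 50/1000).
Sampling is one `Generator.choice(n, n_excluded, replace=False)` call per
run, in run order, from `numpy.random.default_rng(seed)` — documented so
results replay exactly across platforms. The acceptance suite measures the
rule's type-I error at ≈ 5% (exact binomial band over 200 replicate
experiments at 200 permutations) and its power ≥ 90% when the excluded
subjects carry gross failures.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
with closed-form ground truth; it does not attempt anatomical realism.

Organ model: WP is a superellipsoid |x/a|^p + |y/b|^p + |z/c|^p ≤ 1
(default exponent p = 2.5, slightly boxier than an ellipsoid), with
semi-axes drawn per subject from a log-normal volume (mean 42 cm³,
SD 12 cm³ — a typical gland volume that spans ~13–14 axial slices at 3 mm)
and in-plane/slice axis ratios uniform in (0.78, 0.98). PZ is the
posterior part of a shell between the WP surface and an inner surface
scaled by 1 − 0.35; non-PZ is the rest, so the zones partition WP by
construction. Grids use the study's spacing (3.0 × 0.5 × 0.5 mm), with a
per-subject sub-voxel center jitter (shared by both scans) so rasterization
is not artificially symmetric.

Scan 2 compresses the anterior–posterior semi-axis by the factor
`scan2_compression` (default 0.90) and rescales the other two axes by
1/√0.90, preserving analytic volume exactly — the generator-level analogue
of a probe-compressed gland whose volume is unchanged but whose shape
ratios shift; this is what drives the designed collapse of
elongation/flatness/sphericity ICC while volume ICC stays high. With
probability 0.4 a method's scan-2 mask additionally loses its last
occupied slice, emulating the one-slice-fewer tendency of second-scan
segmentations and producing the small negative inter-scan volume bias the
volume-comparison table detects.

Method error: each method's mask is the ground truth displaced by a smooth
random radial field — white noise smoothed to an 8 mm correlation length,
normalized, scaled to the method's amplitude in mm, and softly bounded at
2.5× amplitude (tanh) so a blob can be placed provably disconnected.
Amplitude 0 reproduces the ground truth bit-exactly. Default amplitudes
(manual 0.4, nnunet3d 0.7, nnunet2d 1.0, vnet 2.2 mm) are calibrated so
the error ordering manual < nnU-Net-3D < nnU-Net-2D < V-Net is a designed,
seed-robust property — with the V-Net-like method separated enough that
its PZ feature ICCs stay lowest despite randomly landing gross failures —
echoing the qualitative ordering such studies report without targeting any
printed value. Non-manual masks additionally receive, with probability
0.15, a small disconnected spurious blob (0.3–1% of gland volume, placed
in-plane beyond the noise bound; these barely move volume features but
corrupt the maximum-diameter features, which is why the post-processing
comparison is assessed there) and, with probability 0.05, a gross failure
(global erosion/dilation by 3–4 mm). Quality scores are
100 − 2.5·(mean method error) − 18·(any gross failure) + N(0, 3) per
subject × scan, clipped to [0, 100]: ordinary subjects score ≈ 95–98,
gross failures ≈ 75–80, so the default threshold of 85 separates them, with
the score noise leaving the correlation imperfect as a real QC model's
would be. Per-subject RNG streams are spawned from the master seed and the
subject index, so any subject regenerates identically regardless of batch.

What the generator does *not* emulate — and therefore what passing tests do
not establish about clinical data: MRI intensities and intensity-dependent
segmentation behavior, anatomically realistic gland/zone geometry,
biomechanically plausible deformation fields, spatially structured
(e.g. apex/base-localized) CNN errors, and per-method quality scores (the
fabricated score is per subject × scan, shared across methods, whereas a
real QC model scores each segmentation).

## Pipeline

`run_analysis` executes load → optional post-processing → per-region
feature extraction → statistics, emitting tidy tables keyed by
(region, method, feature) plus provenance (software version, mesh
convention, seed, options, a digest of the cohort keys). The three study
variants — with post-processing, without, and with quality filtering — are
flag selections, and subjects with incomplete scan × method coverage are
excluded with a logged warning. When quality filtering is active the ICC
tables are computed on the kept subset while the permutation test uses the
full table, one test per region × method for the configured feature
(default voxel volume), with per-test seeds spawned deterministically from
the master seed. Results are canonical in subject/method/feature order, so
reports are invariant to manifest row order.

## Problem sizes

The test suite validates phantoms at 0.5 mm isotropic spacing (the
ellipsoid check uses ~200k foreground voxels), the ICC oracle on 1000
random 10×2 tables, parameter recovery at n = 500 and CI coverage over
1000 replicates at n = 62, the largest-component rule against flood-fill
enumeration on ~500 random 15³ masks, permutation calibration over 200
replicate experiments at 200 permutations, and the end-to-end cohort at
the full design size (62 subjects, four methods, three regions, both
scans). Unit tests of the generator and pipeline use coarsened in-plane
spacing (1.5 mm) and smaller cohorts, which leaves the design unchanged
while keeping grids small.

## Known limitations

- ICC confidence bounds follow one (standard) convention; other software
  conventions can differ in the third decimal, so CI-overlap verdicts near
  the boundary are convention-sensitive.
- The anti-aliased mesh slightly biases volumes of convex bodies downward
  (< 1% at 0.5 mm spacing) and rounds corners of genuinely sharp objects;
  diameters of box-like shapes read ~2% short.
- At 3 mm slice spacing, surface area of anisotropically sampled bodies
  carries a few percent error; in a paired design this largely cancels
  between scans, which is what the reproducibility statistics measure.
- DSC between two empty masks is undefined and raised as an error;
  pipeline DSC records are NaN when either region is empty.
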