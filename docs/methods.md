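# Methods

This note documents the models, algorithms, parameter defaults and
numerical choices behind `connatlas`, and what the synthetic phantom
does and does not emulate.

## Streamline geometry (`tract`)

Streamlines are polylines in world millimetres (RAS). Geodesic length
is the sum of segment norms. **Total winding** is the sum of unsigned
turning angles between consecutive segments; zero-length segments are
skipped. A streamline is a *loop* when it winds strictly more than
360°; unsigned angles mean loops in either direction count. Any planar
convex closed polyline winds exactly 360°, which the tests exploit as
an analytic oracle.

**Resampling** is linear interpolation at n equally spaced arc-length
positions with endpoints pinned; resampling can only shorten a polyline
(chord inequality). The **MDF distance** between two streamlines is the
smaller of the mean point-wise distances in direct and reversed order
after resampling both to n points; n defaults to 12, the customary
QuickBundles working resolution. MDF is symmetric, non-negative, and
zero for identical or exactly reversed streamlines.

**Compression** honours a hard error contract — the output is a subset
of the input points including both endpoints, and every removed point
lies within `max_error` of the retained polyline — implemented as
Ramer–Douglas–Peucker recursion, whose split rule discards a point only
against a chord that survives into the output. The default bound is
0.2 mm, the setting used for the reference tractograms this toolkit is
designed around.

**Point transforms** map p′ = A·p + D(A·p), with D a displacement field
interpolated trilinearly on its own grid. Points outside the field's
support raise by default; a zero-displacement fallback is available.
Rigid transforms preserve length to 1e-9 relative, which is tested.

Tractograms read and write TRK/TCK through nibabel (TRK carries the
grid header; TCK does not, so a unit grid is assumed on read) and a
plain-text container: a commented header with dim/voxsize/affine, one
`x y z` point per line, `#streamline` lines delimiting streamlines,
with `repr`-exact floats so the text round trip is bit-faithful.

## Dissection (`dissect`)

Parcellations are integer label volumes with a table (code, name,
hemisphere L/R/M, RGB, centroid). **Dilation** toward the white matter
assigns each unlabeled WM-mask voxel within `radius` mm (default use
case: 2 mm) the label of the nearest labelled voxel by Euclidean
voxel-center distance; ties go to the lower code. It is implemented as
a per-label distance-transform stack, which is O(labels × grid) memory
— adequate for the tested sizes; a tiled variant would be needed for
very large label sets at 1 mm whole-brain resolution.

**Endpoint assignment** looks up the voxel containing each terminal
point (nearest-voxel-center convention, `rint`); a streamline is kept
only when both endpoints carry distinct nonzero labels. Self
connections are excluded — whether they should instead populate the
matrix diagonal is left as an open modelling question; the diagonal is
structurally zero here. Lookup is exact-voxel with no search radius,
appropriate when tractography terminates inside (dilated) gray matter,
which the phantom guarantees by construction.

**QuickBundles** clustering is the classic single pass: a streamline
joins the first cluster whose centroid is within the threshold (MDF),
else founds a new one; centroids are running means of flip-aligned
resampled streamlines. **Bundle cleaning** first removes loops, then
scores each streamline by a cluster tree built at thresholds
{10, 5, 2.5} mm: the score is the mean over levels of the streamline's
cluster size fraction, and streamlines scoring below 0.2 are dropped.
The exact published form of the tree-length score is not available in
the main text this follows, so the score above is a documented
best-effort reconstruction that keeps the 0.2 cut; coherent bundles
score near 1 at every level and pass unchanged, isolated streamlines
score near 1/n and fail. Bundles of ≤2 streamlines skip the outlier
stage. Cleaning is idempotent on the tested bundle geometries.

Length filtering keeps streamlines in the inclusive band [20, 200] mm.
NOS and length matrices are computed **after** cleaning.

## Atlas construction (`atlas`, `pipeline`)

**TDI.** Each streamline increments each voxel it traverses at most
once. Traversal is exact: every segment is marched through the grid by
its half-integer plane crossings, so no voxel is skipped however
briefly the polyline clips it (a fixed-step sampler can only
undercount, which the tests verify against a slab-method intersection
oracle).

**SPAM.** Per bundle, the subject TDIs are binarised at ≥1 streamline,
summed across subjects, and divided by S; only voxels reached by at
least one subject are stored, so probabilities lie in (0, 1]. The mean
TDI averages raw counts over all S subjects including absentees.

**Group matrices.** consistency = subjects with ≥1 streamline;
numbStlines = mean NOS over *all* subjects; length = mean of
per-subject mean lengths over the subjects having the connection.

**Consensus thresholding.** Candidates are the observed pairs with
consistency ≥ max(ceil(c_min·S), 1) (a never-observed pair has no
bundle to keep). Candidates split into intra-hemispheric (both L or
both R) and inter-hemispheric (everything else, midline M included)
classes, then into `n_bins` equal-count quantile bins of group mean
length (default n_bins = 10; the bin count is not prescribed by the
method's sources). The per-bin retention target is the rounded mean,
over subjects, of the subject's existing connections of that class
falling in the bin (by group mean length, with open outer bins); the
target most consistent candidates are kept, with fully specified
tie-breaks — higher consistency, then higher mean NOS, then
lexicographic pair — so the output is deterministic. c_min defaults to
0 at build time; the 30% consistency figure is an application-time
recommendation, and both knobs are exposed.

## Atlas file format (`atlas_io`)

HDF5 with three groups. `header`: nsubjects, dim, voxsize, affine,
gmregions (UTF-8 strings), gmcodes, gmcolors, gmcoords. `matrices`:
consistency (int64), numbStlines and length (float64), all N×N.
`atlas`: one dataset per bundle named `{min}_{max}` by region code,
each N×4 int64 — voxel x, y, z indices plus the per-voxel subject
count. Indices are written 0-based; the reader accepts an explicit
base or auto-detects a 1-based file from the coordinate range against
`dim`. The reader validates every shape and the count ≤ nsubjects
invariant and raises a format error naming the offending dataset; no
partial model is ever returned. Chunking/compression of third-party
files is not reproduced.

Volume exports: per-bundle probability volumes, and a 4-D RGB volume in
which each bundle's colour is the mean of its endpoint-region colours
and each voxel's colour the probability-weighted average over the
bundles traversing it.

## Atlas application (`apply`)

All thresholds are inclusive (≥). `c_thr` compares consistency/S as a
fraction, so "30%" means ceil(0.30·S) subjects. Scalar statistics use
population (1/n) standard deviation. Missing connections carry an
explicit invalid flag rather than zeros, because 0 is a legal scalar
mean. Inputs must already live on the atlas grid — there is no silent
resampling; registration belongs upstream.

Lesion load is probability-weighted (the fraction definition is this
package's choice; the unweighted voxel fraction is reported alongside
for transparency). Loads are in [0, 1], equal 1 for a lesion covering
the whole thresholded support, and are monotone under lesion growth.
ROI queries use support intersection (a bundle "connects" ROIs when its
thresholded support meets ≥2 distinct labels), not endpoint-region
identity; both semantics are defensible and this one is documented.

## Validation statistics (`metrics`)

Percent change between acquisitions is (c₂−c₁)/c₁·100, defined only
where both connectomes are valid and the baseline is nonzero (never
±inf). Bland–Altman: bias = mean difference, limits = bias ± 1.96 ×
sample SD (ddof 1). Lin's CCC uses population (1/n) moments,
2·cov/(varx+vary+(Δmean)²), with a 95% CI from the Fisher z transform
using the asymptotic variance of the z-transformed coefficient — the
CI method is this package's documented choice. |CCC| ≤ |Pearson r|
always (the bias-correction factor is ≤1). Pearson correlations across
connection sets are corrected with Benjamini–Hochberg FDR (q = 0.05
default) via statsmodels; constant sets are excluded with a log record.
Coverage counts distinct thresholded bundles per voxel of a supplied
gray-white interface mask, with histograms overall and per voxel-class
label (a voxel-based stand-in for a surface gyral/sulcal split, which
is out of scope for this toolkit). Display log-scaling is a plotting
matter only; stored counts are raw.

## The phantom (`phantom`)

The phantom emulates the *inputs* of the pipeline with known ground
truth, at desk scale: a 48³ voxel, 1 mm grid centred on the origin;
two 8³ block regions per hemisphere (left: voxel x below the midline);
four ground-truth connections — one intra-hemispheric pair per
hemisphere and two homotopic inter-hemispheric pairs — each present in
every subject (π = 1) with Poisson(5) streamlines (min 1), 1 mm
Gaussian jitter, distinct scalar values 0.4/0.5/0.6/0.7 on a 0.2
background, no noise. Pipeline-level tests use 20 subjects, a cohort
size at which every consistency and recovery property is exercised
while the suite stays fast.

Streamlines are quadratic arcs between per-edge anchors with a
perpendicular apex bump — curved enough to exercise winding and exact
TDI traversal, but winding far below 360°. Loop and off-axis outlier
streamlines are explicit injector options, not defaults. Geometry is
laid out so that bundle supports stay disjoint: edges sharing a region
anchor ±3 mm apart in z, and intra- vs inter-hemispheric arcs bow into
opposite z lanes (apex −6 vs +6 mm). Arc chords are ~30 mm, so all
lengths fall inside the 20–200 mm dissection band even under jitter.

Scalar maps paint each present edge's value over its *jitter envelope*
— a tube of radius 1 + 2.5σ mm around the mean arc, extended 2 mm past
the anchors — rather than over one subject's sampled streamlines. This
guarantees that any voxel a plausible realisation of the bundle can
reach carries the edge value, which is what makes exact per-bundle
recovery at p_thr = 0.5 achievable by construction; later-listed edges
overwrite earlier ones in the (disjoint by design) rare overlaps.
Presence draws for the scalar map re-use the tractogram's random
stream, so a subject's map and tractogram always agree on which edges
exist.

Per-subject randomness comes from
`SeedSequence(master_seed, spawn_key=(subject_index, purpose))`, with
purpose 0 for geometry and 1 for scalar noise, so regenerating any
piece with the same seed is bit-identical.

**What passing phantom tests do not show.** The phantom has no
crossing-fibre geometry, no registration error, no partial-volume
effects, no gyral termination bias, and its bundles are spatially
disjoint tubes — real bundles interdigitate heavily (corpus callosum
confluence being the extreme case), so exact scalar recovery is a
property of the phantom's design, not a claim about real data. The
phantom validates the bookkeeping and the algorithms' contracts, not
tractography fidelity.

## Numerical choices and degenerate inputs

- Coordinates are world mm RAS throughout; voxel indices are 0-based;
  voxel i spans [i−0.5, i+0.5) along each axis.
- Fully degenerate streamlines (all points identical) resample to n
  copies of the point; winding of <3 effective points is 0.
- Empty tractograms dissect to empty bundle sets and zero matrices;
  empty retained sets assemble to a valid zero-bundle atlas.
- A lesion sphere smaller than half a voxel off-center may select no
  voxel; a center outside the grid yields an empty mask with a warning.
- All apply/metric operations are deterministic for fixed inputs; the
  only randomness in the package lives in the phantom and is seeded.

## Known limitations

- The outlier score is a reconstruction (see above); bundles whose
  true outlier structure depends on the unpublished score details may
  be filtered differently.
- Per-label distance transforms make dilation memory-heavy for
  many-hundred-label parcellations.
- TCK files carry no grid metadata; the plain-text or TRK containers
  should be preferred when the grid matters.
- The CLI `metrics` command compares exactly two acquisitions of one
  subject; cohort-level aggregation is left to the library API.
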