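# Methods

This note documents the models, algorithms and numerical choices behind
`atlasforge`, and what its synthetic tests do and do not demonstrate.

## Problem setting

Enhancer-trap screens in larval zebrafish produce many transgenic lines,
each expressing Gal4 or Cre in a line-specific subset of neurons.  To make
such a library searchable, every line's confocal stack must be brought into
a common 3D reference space: each larva is imaged with two channels — the
line's reporter and a broadly expressed reference marker — the reference
channel is registered to a fixed reference brain, and the induced transform
is applied to the reporter.  Registered specimens of a line are averaged,
masked to the brain, and stored in an atlas that supports spatial and
anatomical queries, intersectional (Gal4 × Cre) prediction, coverage
statistics and covering-set selection.

## Intensity conditioning

**Saturation normalization.** Intensities are rescaled so that the top
0.01% of voxels saturate at 1.0 (`fraction = 1e-4` by default).  The
saturation point is the order statistic at sorted index
`ceil((1 - f)·(N - 1))` — the "higher" quantile method — rather than an
interpolated quantile.  The interpolated definition is *not* idempotent
(re-normalizing an already normalized stack keeps rescaling it by a factor
just below one), whereas the order statistic is exactly idempotent and
matches the sort-and-index oracle used in the tests.

**Spectral unmixing.** Channels acquired simultaneously leak into each
other; with a known 2×2 mixing matrix (an input, estimated upstream from
fluorophore spectra) the true abundances are the voxelwise linear solve,
with negative (noise-driven) solutions clipped to zero.

**Stitching.** Rostral and caudal tiles are fused by exhaustive search over
integer offsets (all three axes, since mounting shifts are 3D) maximizing
the Pearson correlation over the candidate overlap; at least 8 voxels of
y-overlap are required.  The fused volume blends the overlap with a linear
ramp along y and copies single-tile voxels verbatim.  The best NCC is
returned so callers can reject implausible stitches (pure-noise tiles
correlate near zero at every offset).

**Depth attenuation.** Single-orientation confocal stacks lose signal with
imaging depth.  Each specimen's residual exponential decay coefficient is
estimated by a weighted log-linear fit of the ratio of its reference
channel's suprathreshold slice means to the template's, as a function of
depth; both channels are then multiplied by `exp(+c·z)`.  The estimator
returns 0 when fewer than four usable slices exist.  The pipeline applies
this correction by default (`correct_attenuation`); without it, thresholded
footprints of deep structures shrink after normalization.

## Registration

**Metric.** Normalized cross-correlation (NCC) is the Pearson correlation
of voxel intensities between two congruent volumes, optionally restricted
to a mask.  It is invariant to positive affine intensity rescaling, and a
zero-variance evaluation domain raises an error rather than returning 0, so
quality tables never silently contain degenerate comparisons.

**Transform model.** 3×4 affine matrices mapping floating physical
coordinates (µm) to reference physical coordinates, in three families:
rigid (6 dof), rigid + anisotropic scale (9), full affine (12).
Parameters are translations (µm), per-axis rotations (degrees), log-scales
and shears, composed as `Rz·Ry·Rx·H·S` about the volume's intensity
centroid.

**Optimizer.** A derivative-free coordinate-wise line search with step
halving, run over a factor-2 Gaussian smooth-and-decimate pyramid (default
3 levels), starting from an identity transform that aligns the intensity
centroids.  Each level starts with a translation step of 4× its step floor
and terminates when the step falls below `min_step` µm (coarser levels
stop at proportionally larger floors); rotation steps are tied to the
translation schedule (degrees ↔ µm), scale/shear steps start at 0.02 per
pyramid scale.  Iterations per level are capped at 60 sweeps.  The
optimizer is deterministic, and nonrigid warping is deliberately out of
scope — pipelines may ingest externally warped volumes.

On half-resolution phantoms the rigid recovery error is typically ≤ 0.7°
and ≤ 1 µm for mounting-scale perturbations (≤ 10° rotation, ≤ 10 µm
translation), and a 5% anisotropic scale is recovered to ±0.005.

**Resampling.** Output grids are pulled through the inverse transform with
trilinear interpolation (metric evaluations), nearest neighbour (masks), or
clipped cubic splines (final reporter reformats — sharper thresholded
footprint boundaries than trilinear, with undershoot clipped to keep
intensities non-negative).

## Reference selection from a calibration set

Duplicate scans of the same larva (scanned, remounted, rescanned) bound the
achievable registration quality: after registering both scans to a
candidate reference, the NCC between them measures how consistently that
candidate aligns identical anatomy.  Candidates are ranked by the mean
duplicate-scan NCC of the reference channel over all calibration specimens.

The reference-channel comparison is masked to exclude pixels outside the
expression pattern.  The mask is the intersection of the candidate's
suprathreshold footprint (> 10% of its saturated maximum, a configurable
threshold) with both warped scans' own footprints.  The intersection
matters: restricted to the candidate footprint alone, a poorly aligned scan
pair contributes a mix of expressing and background voxels, and that
two-cluster structure *inflates* the Pearson correlation enough to rank bad
references above good ones.  The reporter channel is compared unmasked,
because a sparse reporter pattern need not overlap the reference pattern.

The synthetic check ranks the generating template against a "crumpled" copy
(the template resampled through a large smooth random displacement field —
a deformation affine registration cannot absorb).  The calibration scans
for this comparison use low read noise (σ = 0.01) so that the
alignment-consistency signal, rather than the detector noise floor,
dominates the duplicate-scan NCC; with realistic noise both candidates sit
at the same noise-limited ceiling and the ranking carries no information.
This is the margin-limiting experiment of the package: the template wins
sign-stably but by a few parts in a thousand, matching the small but
rankable spreads such calibration studies report.

## Atlas construction

**Averaging.** Each line's volume is the voxelwise mean of ≥ 3 registered
specimens (fewer only with an explicit override), each saturation-normalized
first with per-input quantiles so dim larvae are not swamped.  Averaging
fills in structure missing from individual larvae through variegated
expression; a structure present in 2 of 3 specimens averages to 2/3
intensity.

**Brain mask.** The mean of the two broad reference channels is binarized
by Otsu's threshold computed over the *full* volume, background included.
Otsu over nonzero voxels — an alternative we evaluated — separates bright
from dim *tissue* and cuts the faded brain periphery (Dice ≈ 0.58 against
the phantom's analytic boundary); with the background included the
threshold separates tissue from background and recovers the boundary (Dice
≥ 0.99).  The binarization is morphologically closed with a spacing-aware
ellipsoidal footprint (default radius 4 µm), components under 1000 voxels
(at 1 µm isotropic; scale for other grids) are dropped, and internal holes
are filled in 3D and slice-wise along z.  A user-supplied mask overrides
the automatic one, and the atlas records which it got (`mask_provenance`),
since real masks are routinely hand-refined.

**Storage.** An atlas is a directory: `atlas.json` (grid spec, line table,
term→ROI map), one NIfTI-1 per line volume, `brain_mask.nii`,
`annotations.tsv`, and a BED-like `integrations.tsv` (0-based, half-open).
NIfTI headers are in mm; micrometre spacings are written as µm × 10⁻³ and
converted back on read.

## Search, intersection, coverage

A voxel is "fluorescent" when its normalized intensity reaches τ.  The
search default is **τ = 0.1**; there is no field-standard cutoff, so the
threshold is a prominent, logged parameter rather than a constant.  ROI searches count fluorescent voxels per line inside the region
and report both the ROI fraction and the line fraction, leaving the ranking
normalization to the caller; ties break lexicographically.  Term queries
match annotations case-insensitively and run a spatial search when the atlas
carries an ROI mask for the term.

Intersection prediction uses a stricter default, **τ_strong = 0.5**: a
co-expression call should rest on robust signal in both lines.  The binary
mask `(a ≥ τ_a) ∧ (b ≥ τ_b)` is accompanied by a graded strength map
(voxelwise minimum), because averaged volumes encode labeling frequency,
not single-cell certainty — intermingled distinct cell types can produce
overlapping averages without true co-expression.

Coverage is the fraction of brain-mask voxels a line labels at τ; one τ is
forced per report so per-line fractions and the union are comparable.

## Covering sets

"Minimal overlap" is formalized as an overlap-penalized greedy objective:
repeatedly add the candidate maximizing
`(new template voxels) − λ·(voxels already covered)`, restricted to the
template, stopping at the coverage target, at non-positive gains, or at
`max_lines`.  At λ = 0 this is the classic greedy maximum-coverage
algorithm with its (1 − 1/e) guarantee, checked against exhaustive subset
enumeration on instances with ≤ 12 candidates; λ = 1 (default) strictly
discourages double-labeling.  Coverage is computed on binary footprints,
not graded intensities, because screening concerns which neurons are
genetically accessible.  Reported overlap is the fraction of template
voxels covered at least twice.  Ties break by line id, so results are
independent of candidate order.

## Synthetic data

The generator emulates the statistics the pipeline must survive:

| feature | model | default |
|---|---|---|
| brain shape | ellipsoid, analytic membership mask | semi-axes 42 × 70 × 55 µm |
| reference texture | smoothed seeded noise, ±35% | σ = 3 voxels |
| structures | Gaussian blobs; soft capsules on polylines | — |
| variegation | Bernoulli keep per structure per specimen | p = 0.9 |
| mounting jitter | rigid (optionally scaled) affine, shared by channels | ±5°, ±5 µm |
| depth attenuation | exp(−c·z) before noise | c = 0.004/µm |
| noise | Gaussian read noise, optional Poisson | σ = 0.02 |

The default grid is 96 × 160 × 64 voxels at the native 1 × 1 × 2 µm
spacing; the test suite and the acceptance script run the same physical
brain at half resolution (48 × 80 × 32 at 2 × 2 × 4 µm), a problem size
chosen so that every registration completes in about a second and full
cohorts simulate in minutes.  Every generator is a pure function of
(spec, seed): identical inputs are bit-identical, and ground truth (masks,
true transforms, exact footprints, overlap matrices) always accompanies the
volumes.

What the phantoms do **not** model: the optical PSF, photobleaching,
nonrigid inter-individual shape variation, skin/agarose autofluorescence,
and real anatomical texture.  Passing phantom tests therefore demonstrates
the correctness of the computation — exact search counts, exact coverage
algebra, faithful transform recovery under the modeled corruptions — not
the biological fidelity achievable on real stacks, where nonrigid residuals
dominate and production pipelines add a B-spline warping stage.

## End-to-end recovery and its limits

On a simulated 5-line, 3-specimen cohort the pipeline recovers per-line
thresholded footprints at Dice ≈ 0.88–0.96 against the noiseless planted
truth, with the automatic brain mask at Dice ≥ 0.99.  The residual is
dominated not by registration (using the true transforms changes Dice by
< 0.01) but by the biology the phantom deliberately includes: a structure
expressed in only 1 of 3 specimens averages to a third of its intensity and
its τ = 0.1 contour genuinely shrinks.  That is the same reason the
original protocol sets a *minimum* of three larvae per line and prefers
more.

## Known limitations

- Affine-only: no nonrigid stage; accuracy on real data is bounded by
  inter-individual nonrigid variation unless externally warped volumes are
  supplied.
- The coordinate-descent optimizer is local; initial misorientations beyond
  ~15–20° are outside its capture range (real mounting protocols keep
  orientation far tighter).
- Reference ranking discriminates weakly when all candidates are
  structurally sound and noise dominates — as in the low-margin experiment
  above; with many real candidate brains the spread is likewise small.
- Term search is exact-match over annotation strings; no ontology-graph
  expansion.
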