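# Methods

This note documents the models, numerical choices and known limitations of
the three analysis stages and of the synthetic generators used to validate
them. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Histology: trainable pixel classification and wound metrics

**Model.** Per-pixel features are the raw RGB channels plus, at each
smoothing scale (default 1, 2, 4, 8 px), per-channel Gaussian smoothings and
Gaussian gradient magnitudes — 3 + 6·S features. The classifier is a
random forest (100 trees, fixed `random_state`), the standard open baseline
for scribble-trained segmentation of stained tissue. Scribble rasters use
0 = unlabeled and class-code + 1 otherwise, because the background class
itself has code 0 in class maps. Training requires at least 50 scribbled
pixels per class (a missing class is an error naming that class), subsamples
at most 4000 pixels per class, and holds out a stratified 20% whose accuracy
is stored on the model. Determinism: one seeded RNG drives subsampling and
the forest.

**Metrics.** Pixel area is `pixel_size_um**2`; rasters are indexed
(row, col); labels are 0-based. For a heart, class areas are summed over its
serial sections *before* forming ratios, giving one value per heart —
per-section ratios can be obtained by calling the same function per section.
Wound % uses intact muscle only as the denominator (the alternative,
muscle + wound, would change values by roughly the wound percentage itself;
the muscle-only definition is the one implemented). Collagen-in-wound % is
defined within the wound, collagen/(fibrin+collagen), and set to 0 for a
heart with no wound pixels rather than NaN. Exclusion masks (valves) are
applied before any counting, so a masked pixel can never contribute to any
area; masks are user-supplied — no automatic valve detection is attempted.

**Leukocyte counts.** Cells are Laplacian-of-Gaussian blobs; a detection
counts only if its center lies in the muscle region and its raw intensity
exceeds an absolute floor (default mean + 5 SD of the image), which
suppresses spurious LoG responses on noise-only images. Density is
1000·count/muscle-area-µm². The muscle region is a binary mask or the
muscle class of a trained classifier.

## 4D tracking

**Enhancement.** Per-frame difference of Gaussians with σ₁ = r/√3 for a
nominal cell radius r (the band-pass scale that maximizes response for a
ball of that radius) and σ₂ = 2σ₁, scaled per axis by the voxel size so
that anisotropic z is handled correctly; σ below one voxel is clamped with
a warning. Constant background maps to exactly zero.

**Segmentation.** Per frame: global Otsu threshold on the enhanced volume;
Euclidean distance transform with physical sampling; Gaussian smoothing of
the distance map (1 voxel) to remove digitization bumps; h-maxima seeds with
h equal to 10–30% (default 30%) of *each foreground component's own*
distance maximum — relative-per-component h keeps one seed per convex cell,
preserves the deep dip between two touching cells, and still seeds small
debris components that a global h would silence; watershed on the negative
smoothed distance map. Optionally seeds closer than `min_seed_dist_um` are
thinned (keeping the deeper one). Finally each segment is shrunk to the
voxels above half its peak *raw* intensity: for a PSF-blurred object the
half-peak contour approximates the true boundary, which removes the
band-pass halo and makes measured volumes quantitatively comparable to the
debris-filter threshold. All steps are deterministic.

**Morphometrics.** Volume is voxel count × voxel volume. Surface area comes
from a marching-cubes isosurface (level 0.5, physical spacing) of the mask
after half-voxel Gaussian pre-smoothing, which suppresses the ~1.5×
staircase-area bias of voxel-face counting. Sphericity is evaluated with
the *mesh-enclosed* volume (divergence theorem over triangles) rather than
the voxel-count volume: for any closed mesh the isoperimetric inequality
then guarantees ψ ≤ 1, removing the small-object overshoot that mixing
voxel volume with mesh area produces. On digitized solids this measures a
ball (r = 8 voxels) at ψ ≈ 0.96 and a 16-voxel cube at 0.84 vs the 0.806
closed form — a systematic ≈ 0.03–0.05 voxelization bias, inside the
documented ±0.05 mesh tolerance and common to all segments of a movie, so
group contrasts are unaffected. Segments too small to mesh fall back to
voxel-face area and are flagged `degenerate`.

**Drift correction.** Between consecutive frames, mutually-nearest-neighbor
centroid pairs vote; the per-frame drift increment is the component-wise
median of their displacements, robust to the cells' own Brownian motion.
Frames without pairs carry drift forward. The cumulative drift is
subtracted from all centroids before linking. With ~100 cells the residual
error in speed and MSD slope after correcting a constant stage drift is
below 1% (the acceptance report computes it); with very few cells the
median absorbs part of the shared Brownian displacement and biases speeds
slightly downward.

**Linking.** Frame-to-frame optimal one-to-one assignment
(`linear_sum_assignment`) on centroid distance with a hard gate (default
15 µm/frame, configurable; greedy nearest-neighbor available as a flag). A
single excluded timepoint (e.g. a residual heart-beat frame) may be
bridged with the gate doubled; longer gaps close the track — unlimited
bridging would fabricate tracks. Tracks shorter than five observations are
dropped. Unmatched observations always start new tracks.

**Statistics.** Speed divides each displacement by the actual elapsed time
(bridged gaps span two frame intervals). MSD is time-averaged per track,
MSD(τ) = mean over t of |r(t+τ) − r(t)|²; lags with no valid pair are
omitted, never padded. The MSD slope is fit through the origin over lags
1–5 and equals 6D for 3D Brownian motion; the per-heart reference-lag MSD
defaults to lag 5 (10 min at 2-min frames) — the lag is configurable since
a single number per heart requires choosing one. Group comparisons run on
per-heart means (hearts are the replicates); Welch's t or the Wilcoxon
rank-sum (Mann-Whitney, exact method at small n without ties) are
two-sided. Pooled per-cell comparisons are available as a secondary view
via the same two-sample helper.

## DEG set comparisons

Significance is strict `padj < alpha` (default 0.05): a gene at exactly
0.05 is not significant. Gene identity is an exact string match on
Ensembl-style ids with trailing `.N` version suffixes stripped by default.
Shared significant genes with a zero log2 fold change in either table are
excluded from the concordance denominator and counted separately, so
concordance is always a fraction of genes with a definite direction in
both studies. Marker-panel genes absent from a table are emitted as
explicit NA rows, never dropped. Unique-marker intersection removes any
marker listed for more than one population before intersecting (a
non-unique marker identifies no population), then rolls counts up by
lineage. Upstream DEG calling (count models, shrinkage, multiple-testing
correction) is deliberately out of scope: tables are consumed as produced
by the standard tools.

## Synthetic data

The generators define the study conditions the tests run under; all
randomness flows through one seeded `numpy` Generator per call, and equal
seeds give bit-identical outputs.

**AFOG sections.** An annular "ventricle" of muscle on a pale background
holds a wedge-shaped wound (fibrin core, collagen rim along the wound
border and the outer edge). Wound pixels are allocated in angular order and
collagen pixels by distance to the wound border, so the ground-truth label
map matches the configured wound fraction and collagen share exactly at
the pixel level — the truth map is an exact oracle for the area metrics.
Class colors default to a caricature palette (muscle (200,130,50), fibrin
(200,40,40), collagen (50,70,200), background (245,245,245)) with Gaussian
color noise; configuration enforces pairwise color-mean separation of at
least 3× the noise SD so classes remain learnable by construction. Not
modeled: real AFOG chemistry, staining gradients, section deformation.

**Movies.** Cells are prolate spheroids (a, a, ka); k is solved numerically
(Brent) so the analytic sphericity — with the Knud Thomsen surface-area
approximation, p = 1.6075, error < 1.1% — equals a per-cell target sampled
from a truncated normal. The truncation floor (default ψ ≥ 0.55, already a
~13:1 spheroid) keeps shapes renderable; volumes are truncated ≥ 1.8× the
intended debris-filter threshold so filtering separates cells from debris
with margin even under the residual ≤ ~20% volume-measurement error of the
rendered pipeline. Centroids follow reflected Brownian motion (per-axis
step SD √(2DΔt)) in the specimen frame; constant stage drift is added
afterward in the lab frame, because a drifting specimen translates cells
*and* boundaries together — this is what makes drift exactly removable.
Initial positions are rejection-sampled for pairwise separation
(volume-equivalent radii plus an elongation-scaled margin); dense
configurations fall back to the most isolated candidate, so cells may then
start in contact (only relevant when rendering). Defaults mirror the
imaging protocol the pipeline targets: 2-min frame interval, 90 cycles,
with plausible macrophage scales (mean volume 500 µm³, D ≈ 1 µm²/min) —
the physical cell scales are configuration, not claims. Images are binary
masks convolved with a Gaussian PSF plus Gaussian and/or Poisson noise;
the emitted truth table (pre-noise) is exact. Not modeled: beating-heart
deformation (excluded timepoints are simply dropped frames), intensity
heterogeneity within cells, photobleaching.

**DEG tables.** Two tables over one gene universe with exact counts of
significant genes, exactly `overlap_count` shared significant ids, and
`round(concordant_fraction · overlap_count)` of those same-signed in both.
Significant genes draw padj uniformly below alpha, others at or above it;
log2 fold changes are sign-controlled with magnitudes bounded away from
zero so every shared gene has a definite direction.

**What passing these tests does and does not show.** The synthetic data
exercise the full numerical chain under known truth — segmentation
fidelity, filter soundness, linking identity, estimator bias, set
arithmetic — but they are caricatures: real histology has stain variation
and out-of-class pixels, real movies have heterogeneous intensities,
deformable tissue and photobleaching, and real DEG tables carry correlated
noise. Performance on the synthetic benchmark bounds algorithmic
correctness, not real-data accuracy.

## Problem sizes used in the bundled checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which the statistical tolerances are comfortably
resolvable: 384–512 px sections, movies of 5–10 cells × 8–30 frames for
rendered checks, 100–200 simulated tracks × 90 frames for estimator
recovery, and 100 cohort repeats (6 hearts × 100 cells per group) for the
group-comparison power estimate.
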