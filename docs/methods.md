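# Methods

This note documents the models, estimators and numerical choices behind
`olfrecon`, and what the synthetic specimen does and does not emulate.

## The virtual specimen

Real data for this kind of workflow is a series of ~10 µm coronal sections
of an *en-bloc* olfactory specimen, scanned at 1.097 µm/px in four
fluorescence channels, with roughly a third of the cut sections unusable.
No such dataset ships with the package; instead `phantom.make_phantom`
builds a geometrically condensed scene in which all six structures of
interest co-exist inside a ~140 µm field of view (default grid
60 × 128 × 128 at the real pixel size):

- a **nasal-epithelium band** whose apical surface undulates smoothly in
  x and z; its thickness defaults to the measured 67.23 µm;
- discrete **OSN somata** placed per section along the epithelium as a
  hard-core Poisson process (nuclei do not interpenetrate, so connected
  components equal the placed cell count) with linear density defaulting
  to the measured 78.31 per mm; the patch indicator controlling which
  columns carry OSNs is a thresholded smooth random field
  (`osn_patch_density` sets its coverage);
- **arterial tubes** running through the lamina propria (never inside the
  epithelium), a **bone plate**, an **olfactory-bulb ellipsoid** beyond it,
  and **glomerular blobs** confined to the bulb's outer shell;
- channels as per-structure emission intensities (OMP OSN-specific, VGLUT2
  glomerulus-dominant, UEA1 broad, Hoechst generic; bone unstained) plus
  clipped additive Gaussian noise (σ = 0.02).

Section rendering degrades the slices with (i) a rigid lateral shift
quadratic in the 1-based section index (`banana_curvature · i²` px) — the
minimal model of the curvature a pairwise-chained registration would
straighten; (ii) a per-section smooth random displacement field of bounded
amplitude (Gaussian-smoothed noise, normalised to `deform_amplitude`);
(iii) i.i.d. Bernoulli dropout with default rate 0.358, matching the
fraction of sections a real series loses.  Truth masks are warped with the
identical transform (nearest-neighbour; channels bilinear).  Everything is
bit-reproducible under a fixed seed.

What the phantom does **not** emulate: staining chemistry and its spatial
variation, tissue folds and bright-stripe artifacts, anatomically realistic
structure scales (the scene is a miniature), clustered dropout (real
exclusions concentrate anteriorly/posteriorly), and section-to-section
deformation statistics of real paraffin sections (amplitudes are chosen for
testability).  Passing tests therefore demonstrate correctness of the
algorithms under known truth, not segmentation or registration performance
on cadaveric tissue.

## Segmentation

One independent 2D U-Net per structure: three encoder blocks of two 3×3
convolutions (8/16/32 features) with batch normalisation, dropout 0.2
before each 2×2 max pooling; a 64-feature bottleneck with a 2×2 transpose
convolution; a mirrored decoder with skip concatenations; a 3×3 output
convolution to 2 classes under softmax; ReLU throughout.  The network,
its backpropagation and the Adam optimizer are implemented directly on
NumPy (im2col convolutions), which keeps the package free of framework
dependencies and fully deterministic single-threaded; it is sized for
~128 px tiles, not the 20k-px originals.

Training follows the staged schedule (defaults 1e-4, 5e-5, 1e-5 for ~35
epochs each; the olfactory-bulb variant trains two stages of 200 epochs at
1e-4 and 1e-5 on fourfold-downsampled input): at each stage's end the
weights with the best validation DSC seed the next stage.  Epochs draw
random crops from the training sections (uniform over valid origins);
each crop receives one uniform offset in [−0.01, +0.01] per channel,
clipped to [0, 1], so the network learns that absolute channel brightness
is irrelevant.  The centre-pixels rule is applied at inference: tiles
overlap by twice the margin and each tile contributes only its centre
region (border tiles also their outer border), partitioning the image so
every pixel is predicted exactly once.  The binarisation threshold is the
DSC-maximising cut-off on a 99-point grid 0.01…0.99 (ties to the smallest
value); DSC of two empty masks is defined as 1.0 (perfect agreement on
absence).  The bootstrap loop of manually correcting poor sections is a
human act and is exposed only as the `add_sections_and_retrain` hook.

## Registration

Included sections are partitioned into blocks of five; the reference of a
block maximises the summed pairwise DSC of the combined
vasculature-OR-epithelium masks (self-term included; ties to the lowest
index).  Every other section is registered to the reference in two steps:

1. **intensity**: rigid (Euler2D, moments-initialised) followed by
   B-spline, on the channel-mean image, with Mattes mutual information,
   linear interpolation, seeded random coordinate sampling and a
   multiresolution pyramid (SimpleITK).  The mean image is used because
   the registration framework is scalar-valued; with a single shared
   geometry across channels, MI on the mean is an adequate stand-in for a
   per-channel combination.
2. **mask**: a shallow (3-level) B-spline refinement driven only by the
   lightly blurred combined masks, initialised with the intensity field;
   the shallow pyramid keeps the step focused on small structures so it
   cannot undo the intensity alignment.  Mean-squares is the default mask
   similarity (well-behaved on near-binary images); MI is a config option.
   Sections with an empty combined mask skip the refinement.

Pyramid depths default to 4/3/3 levels for 128-px images — levels beyond
log2 of the image size are meaningless — while the 16/13-level settings
used on 20k-px sections remain valid configuration.

**Interfaces.** For consecutive blocks the cross pair with the highest
combined-mask DSC (lexicographic ties) is registered, yielding φ.  The
field is applied only as an interface smoother: the posterior block's
sections anterior to the pair receive ((i−1)/N)·φ, ramping from ≈φ at the
block boundary (continuous with the anterior block's frame) to zero
beside the pair's posterior member; block frames themselves are never
replaced.  The alternative — warping the posterior pair member and its
block-mates with the full φ — was implemented and measured on the banana
phantom: sequential full-field propagation collapses every block into the
first block's frame and straightens the curved anatomy as badly as naive
section-to-section chaining, which is precisely the artifact the
block-wise scheme exists to avoid.  With the smoothing-only form the
reconstructed centerline of a curved tube stays within ~2 px RMS of
truth while pairwise chaining drifts 3–5 px.

Fields are (2, H, W) arrays of (row, col) pixel offsets; warping samples
the moving image at x + φ(x) (bilinear for channels, nearest for masks),
and each section is warped exactly once with its composed field.  Blocks
are processed independently with per-pair seeding, so results are
bit-identical regardless of processing order (single-threaded ITK).

## Stereology

**Volumes.** A structure's volume is its per-section positive-pixel area
times 1.097² × 10 µm³, summed over sections; areas of non-included
sections are linearly interpolated between the nearest included
neighbours (constant extrapolation at the series boundaries).  This is
exact for constant and linear area profiles, which is why interleaved
sampling (keeping every 4th/16th/32nd included section) incurs zero error
on such phantoms and small errors on smooth ones.

**Envelope.** Per section, OSN ∩ epithelium is expanded to the
epithelium's full thickness (within each epithelium connected component,
apical–basal columns carrying any OSN pixel are filled), then closed with
a disk of diameter 80 µm — gaps smaller than the element close, larger
ones persist, and the erosion leaves the characteristic semi-circular
bites at stretch ends.  The closing is computed by thresholding Euclidean
distance transforms (dilation ≡ EDT ≤ r on the padded image), which is
exactly the disk-footprint closing in free space and orders of magnitude
faster; it is idempotent and extensive by construction.

**Counting.** The virtual anatomist counts somata as connected components
of OSN ∩ envelope on a few sections and measures the OSN-bearing length
as envelope area over mean thickness — the same length definition the
envelope-volume extrapolation implies, which keeps the chain internally
consistent.  The linear density is the pooled ratio estimator Σn/ΣL with
the standard ratio-estimator SEM over sections; averaging per-section
ratios instead carries an O(1/n) small-sample bias at ~10 cells per
section.  Raw counts are Abercrombie-corrected by T/(T+D); the nucleus
diameter D is a required user parameter (0 for the phantom, whose cells
live in single sections).

**Density and totals.** ρ = λ/(t·T) is a ratio of two estimates; its
90 % limits come from Fieller's theorem, using the Student-t quantile at
n_sections − 1 degrees of freedom when the section count is known (the
theorem's classical form) and 1.645 otherwise, with the SEM reported as
the interval width over 2 × 1.645.  A first-order Delta-method SEM is the
labelled alternative; the two agree as input SEMs shrink.  The total
N = ρ·V treats the envelope volume as fixed, so SEM scales linearly and
the 90 % CI is mean ± 1.645·SEM.  Surface area is V/t with a Delta SEM
from the thickness.  Sphere-model glomerulus counts divide a glomerular
volume by (4/3)π(d/2)³.  End-to-end, the chain telescopes: with the
area-based length, density × envelope volume equals counted cells scaled
by the envelope area ratio, making the estimator unbiased for the
phantom's true counts (verified: estimate/truth = 1.000 without
measurement subsampling; 90 % CI covers the true ρ·V in ~90 % of seeded
replicates at 40 × 128 × 128 scale).

**Splits.** Left/right and septal/lateral divisions are accepted as
user-supplied label images; drawing them is a manual act.

## Numerical and interface choices

- Sections are 1-based anterior→posterior; pixels 0-based (row, col).
- Series round-trip as one multi-page TIFF per section (4 float32 channel
  pages, 6 mask pages) plus a JSON manifest; excluded sections may omit
  their file.  NIfTI exports record 1.097 × 1.097 × 10 µm voxels; the
  16-fold viewing downsample uses block means for channels and block
  majority for masks (ties to background) and scales the recorded pixel
  size by the factor.
- All randomness flows through `numpy.random.Generator` seeds carried in
  the configs; registration sampling is seeded through SimpleITK.
- Problem sizes throughout the examples and tests (6–40 sections at
  128 × 128, minutes on one CPU) are the package's chosen desk scale; the
  algorithms are size-agnostic.

## Known limitations

- The NumPy U-Net is CPU-bound and impractical beyond small tiles and
  short schedules; it demonstrates the architecture and training scheme,
  not production segmentation throughput.
- The mask-refinement step registers mask images under a generic
  optimizer; explicit overlap losses (e.g. Dice) are not implemented.
- The phantom's per-section deformations are smooth and small; tearing,
  folding and missing tissue are not modelled, so registration robustness
  to gross artifacts is untested.
- Fieller limits assume independent numerator and denominator estimates;
  counts and thickness are measured on overlapping section sets, where
  any dependence is ignored.
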