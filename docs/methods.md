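# Methods

This note documents the models and procedures implemented in `neuralign`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open.

## Coordinate and data conventions

All numerical code uses one array convention: volumes are indexed
`(x, y, z)` (multi-channel: `(x, y, z, c)`), 0-based voxel coordinates.
The annotation stack additionally uses the label-stack layout
`(K, Z, Y, X)` that labeled volumes are conventionally stored in; the
adapters `labeler.to_zyx` / `from_zyx` convert at that boundary only.
Rotations are counter-clockwise in the x-y plane viewed from +z; only
internal consistency matters, and the rigid-DDF unit test pins the
handedness.

A dense displacement field (DDF) is an `(X, Y, Z, 3)` array mapping
fixed-image coordinates to moving-image coordinates: fixed voxel `p`
corresponds to moving position `p + D[p]`.  Warping an image samples the
moving image there with trilinear interpolation; samples outside
`[0, S-1]` in any axis evaluate to 0 (label volumes use nearest-neighbor).
Centroid lists are fixed-capacity `(200, 3)` arrays padded with
`(-1, -1, -1)`; matched fixed/moving lists share row order, so row *i* of
both is the same neuron.

## Preprocessing

`preprocess_to_shape` subtracts the image median, clips negatives, and
crops/zero-pads so the intensity center of mass (computed after
subtraction, rounded half-up) lands on the geometric center of the target
grid, default `(284, 120, 64)`.  A volume that is all-zero after median
subtraction has no center of mass and raises a degenerate-input error.
Centroids are unweighted means of ROI voxel coordinates; only ROI indices
present in both images of a pair are kept.

## Euler pre-alignment

Learned non-rigid registration struggles when large rotations and
translations are entangled with small deformations, so a brute-force grid
search removes rigid motion first.  The in-plane stage maximizes global
zero-normalized cross-correlation (NCC) of z-maximum-intensity projections
downsampled 4× by block mean (block mean, not striding, to suppress
aliasing); the axial stage then maximizes full-3D NCC over an integer z
shift.  Default grid: θ ∈ [−180°, 180°) step 2°, in-plane shifts ±quarter
of each downsampled dimension step 2, dz ∈ [−8, 8] step 1 — all
configurable; results are deterministic with ties broken toward the
earlier grid point.  The axial objective is read as maximization of NCC
(higher NCC = better alignment), consistent with the in-plane stage.
Rotation is about the geometric grid center; exposed regions fill with 0.

## Registration network

The LocalNet is a 3-level 3-D U-Net with `base_channels · 2^i` features at
level *i* (default 16) and a multi-level output head.  Encoder block =
conv(k=3, to the level width) + batch-norm + ReLU, a residual conv block
(input added before the second ReLU), and 2³ max-pool; bottom block = one
conv block without pooling.  Decoder block = transposed conv (k=3, stride
2, halving channels) added to a resize-split-sum branch (bilinear resize
to double dims, split channels in two, sum), skip concatenation with the
spatially matching pre-pool encoder output, then conv + residual blocks
with the conv halving the concatenated width.  Where halving yields an odd
channel count it is rounded up to the next even number so the following
split-sum branch can split; this keeps the architecture valid at any base
width.  The output layer applies a 3-channel conv plus trilinear
upsampling to the bottom block and every decoder output and averages them.
Output convolutions are zero-initialized so the initial DDF is the
identity map, which stabilizes early training; other weights use fan-in
scaled Gaussian init from a seeded generator.

Normalization uses the current volume's own spatial statistics (batch size
is 1 throughout), making inference deterministic.  The jellyfish variant
zeroes the z-displacement after the output layer — masking, rather than a
huge axis-difference weight, because even small out-of-plane shifts
degrade interpolated intensities — and its gradient norm ignores
z-derivatives.  The cross-animal variant concatenates two 4-channel images
into an 8-channel stem and warps each channel with the same DDF.

### Losses

* **Image loss (single-channel):** negative mean local squared
  zero-normalized cross-correlation over a sliding cube of side n = 16
  (n = 8 in reduced-scale tests).  Windows are anchored at each voxel and
  clipped at the far border; the independent loop oracle in the tests uses
  the same convention.  The variance product is guarded by ε = 1e-7.
* **Image loss (multi-channel):** negative squared channel-averaged global
  NCC, in [−1, 0]; invariant to per-channel affine intensity rescaling.
* **Centroid loss:** the mean Euclidean distance between true and
  predicted moving centroids over valid rows (the positive quantity that
  minimization shrinks), with 1e-12 inside the square root for a finite
  gradient at exact coincidence.  Pad rows never contribute.
* **Regularizers:** gradient norm (mean squared central differences over
  interior voxels, normalized by `3(X−2)(Y−2)(Z−2)`; the 2-D variant pools
  interior voxels of all z-slices and normalizes by `3(X−2)(Y−2)Z`),
  difference norm (`ΣD²/3XYZ`), axis difference norm (mean squared
  z-component), and the nonrigid penalty: with `D_ref[p] = −p` and
  `M[p, m]` the summed squared central differences of component *m* of
  `D − D_ref`, the penalty is `mean(M + 1/M − 2)`.  `M = 1` identically
  under rigid-body maps, so the penalty vanishes exactly there; `M` is
  floored at 1e-8 before inversion.
* **Weights:** worm preset `w_I, w_C, w_R = 1, 0.1, 1` with sub-weights
  `0.02, 0.005, 0.001, 0.02` (grad, diff, axis, nonrigid); jellyfish
  preset drops the centroid term and uses the 2-D gradient norm; the
  cross-animal preset uses `0.05, 0.0025, 0, 0.05`.

Training uses Adam at learning rate 1e-4 (package default), batch size 1,
with the affine pair augmentation (below) applied per iteration when
enabled.  Losses are built from the same differentiable primitives that
the reference numpy implementations use, and a test pins the two paths to
agree to 1e-8 on a nontrivial model.

### Augmentation

The registration augmentation draws one random affine per iteration by
perturbing the eight corner points of the volume by a bounded fraction of
each dimension and least-squares-fitting the affine through those
correspondences (degenerate draws are resampled).  The same transform is
applied to both images, all channels, and both centroid lists; images are
resampled linearly with median fill, centroids mapped analytically.  The
jellyfish pipeline additionally rotates both images of a pair by a
uniformly drawn multiple of 90°.

## Identity linking

Registered ROI pairs score
`M_ij = R · 1/(1+w1·d_i) · q^w2 · r_ij^w3 · exp(−(w4·a_ij + w5·c_ij + w6·n))`,
zero when the contexts were not registered or the warped ROIs do not
overlap.  The exponential groups all three penalty terms (brightness/color
mismatch, warped centroid distance, nonrigid penalty) under one negative
sign — the reading under which every factor rewards agreement.  In
temporal mode `a` is the absolute difference of marker brightness, each
normalized by its timepoint's mean ROI brightness; in cross-animal mode
`a = Σ_k |C_ik − C_jk|` with `C` the per-ROI channel-brightness 4-vector
normalized by its own channel mean, and `w4 = 7`, `w8 = 0`, `w7 = 1e-9`.
Temporal defaults: `w1..w8 = 2, 25, 1, 3, 1, 1, 1e-4, 0.05`.  The matrix
is symmetrized by copying each entry to its empty transpose slot.

Clustering is agglomerative with average linkage computed over the nonzero
pairwise entries between two clusters, merging in descending linkage
order.  `w7` is the merge floor; a merge is rejected (and that cluster
pair permanently excluded) when the merged cluster's collision fraction —
members sharing a context, divided by cluster size — exceeds `w8`.  With
`w8 = 0` no cluster ever contains two ROIs from one context.  Ties break
on the smaller cluster ids, so the output is independent of ROI
enumeration order.  A higher floor stops agglomeration earlier and
therefore weakly *increases* the number of raw clusters (the property the
tests assert); counting only clusters that span most contexts, as a
detection criterion would, instead shrinks with the floor.

The temporal registration graph is pluggable; the default pairs each
timepoint with its k nearest neighbors under z-MIP NCC (posture-based
pair selection belongs to upstream tooling and is out of scope).  Traces
are per-cluster, per-timepoint ratios of mean green to mean marker
intensity over the ROI's voxels; the sparse-GFP error rate calls a trace
positive when its median exceeds 1.5, counts timepoints that differ from
the trace median by more than 1.5 with exactly one of the two above
threshold, and divides by `total timepoints · 2·FracGFP·(1−FracGFP)` to
correct for undetectable same-class mis-links.  Cross-animal cluster
accuracy scores, over clusters with more than two labeled members, the
fraction matching the cluster's most frequent label, ignoring the L/R
subclass.

## Cell annotation

Training targets pair a one-hot label stack (background = 1 where all
other channels are 0; confidence-1 human labels are excluded and treated
as background) with a per-voxel weight volume: background 1, labeled ROI
voxels `(130/N_l)·f(c)` with `f(2..5) = 50, 600, 900, 1000`, where `N_l`
is the corpus-wide count of label `l` and 130 the maximum count of any
neuronal label — rare and confidently labeled neurons weigh most.  The
loss is pixel-weighted cross-entropy normalized by `XYZ·K`; the evaluation
metric is the weighted mean IoU of the argmax prediction against the
labels.  Channels whose union is empty (label absent and never predicted)
are excluded from the IoU average, so a perfect prediction scores exactly
1 even when some catalog classes are unused; argmax ties break toward the
lower label index.

The annotation U-Net has 4 levels with `64·2^i` channels (reduced in
tests), encoder blocks of two GroupNorm→conv(k=3)→ReLU units with 2³
max-pooling between levels, interpolation upsampling with skip
concatenation in the decoder, and a final 1×1 conv to K classes.
GroupNorm group size is 16, except group 1 for the first convolution; for
reduced channel counts the group size shrinks to the largest divisor not
exceeding the configured value.

ROI labels: each ROI's mask weighs interior voxels 1 and voxels
face-adjacent to the exterior 0.01, so central voxels dominate the vote;
the resulting prediction rows `D[i, ·]` are normalized softmax averages
and sum to 1.  Postprocessing runs, in order: (1) descending-confidence
duplicate resolution — duplicates with centroid distance at most 4 voxels
(configurable; unspecified upstream) are treated as over-segmentation and
share the label, otherwise the lower-confidence copy is deleted; (2)
under-segmentation — at least 10 voxels, or 20% of the ROI, confidently
(P > 0.75) claiming a different label deletes the label; (3) L/R merge —
when both subclasses of a bilateral class carry over 10% mass, the
class-level label is emitted with the summed mass (never for D/V, which
are functionally distinct); (4) deletion of the rare-class list and of
"glia"/"granule"; (5) deletion below 75% confidence.  Every deletion
records its rule; confidences never increase except by the L/R sum.  The
catalog carries an explicit subclass table (inferred from trailing L/R
pairs or supplied directly) so names like "RMH?" are never string-parsed.

The labeled-volume augmentation composes, in order: B-spline control-point
noise plus a "worm-bend" arc along x (y-displacements with compensating
x-shifts that preserve inter-point spacing), rotations (large xy/yz
ranges, small xz), translation, scaling, shearing, a 180° rotation about a
random axis, per-channel contrast, Gaussian blur in a gradient along z
(mimicking optics blurring away from the objective), Gaussian noise, and
Poisson noise.  Geometric operations apply identically to image, labels,
and weights — labels travel as an argmax index volume resampled
nearest-neighbor and re-one-hot-encoded, which preserves the one-hot sum
exactly (missing voxels become background); intensity operations touch
only the image.  All-zero strengths give the exact identity.

## Synthetic data

The generator emulates the features the pipeline actually consumes:

* **Nuclei volumes:** `n_cells` isotropic Gaussian nuclei (σ = 1.5 voxels;
  anisotropy is a knob, default 1) placed by rejection sampling with a
  minimum separation, log-normal peak intensities; ROIs are voxels above
  half the weakest peak assigned to the nearest center; centroids are the
  planted centers.
* **Deformations:** a random affine (identity ± `affine_strength`, same
  scale for the translation as a fraction of each dimension) composed with
  a sinusoidal y-bend of configurable amplitude and period — smooth,
  analytically invertible, with exact point maps, so the moving image,
  matched centroids, and ground-truth DDF are all consistent by
  construction.  Cross-animal registration pairs get exact DDFs by
  composing one animal's forward map with the other's inverse.
* **Trace populations:** constant baselines (positive ≈ 3.0, negative ≈
  0.2, Gaussian noise 0.05) with identity swaps planted independently per
  (trace, timepoint) at a configurable rate; the swap mask is returned.
* **Cohorts:** one canonical layout shared by all animals, per-animal
  smooth deformations, per-cell-type channel signatures drawn once from a
  Dirichlet (or supplied explicitly) and conserved across animals with
  multiplicative jitter — mirroring genetically fixed multi-spectral
  colors.

What this does *not* emulate: realistic PSFs and optical sectioning,
segmentation errors (ROIs are consistent with the planted cells by
construction), background autofluorescence structure, bleaching, or
motion blur.  Passing tests therefore demonstrate correctness of the
algorithms and their implementations under controlled conditions, not
performance on real microscope data.

## Desk-scale study conditions

The full-scale reference configuration (284×120×64 volumes, base 16 / 64
channels, Adam 1e-4, hundreds of epochs) remains the package default.
The test suite and worked example exercise the same code at reduced sizes
chosen once for the synthetic substrate: 32×16×8 volumes, LocalNet base 4,
LNCC cube 8, learning rate 2e-3 for 150 epochs on the single-pair overfit
(≈15 s); the annotation U-Net at base 4 with 150 epochs at 3e-3; linking
on 4–5 cells over 4 contexts.  The labeler fixture sets the corpus label
counts to 130 (each label as common as the rarity normalizer), keeping the
neuron-to-background weight ratio near the realistic ~1000:1 rather than
the 130000:1 that singleton counts would give.

## Numerical choices and degenerate inputs

* NCC raises a degenerate-input error on zero-variance inputs; the grid
  search skips constant-overlap candidates.
* LNCC windows clip at the far border; ε = 1e-7 in the denominator.
* `M` in the nonrigid penalty is floored at 1e-8; sliding variances are
  clipped at 0 before the product.
* Out-of-grid centroids clamp their DDF sample to the border and log a
  warning; out-of-bounds image samples are 0 (augmentation instead fills
  with the image median, following the different role of missing data
  there).
* Fractional centers of mass round half-up; argmax ties break toward the
  lower index; clustering ties break toward smaller cluster ids.
* The trainable stack runs on the package's own reverse-mode autodiff
  (`neuralign.nn`): numpy forward math with analytic backward passes,
  im2col convolutions, and differentiable trilinear warping of images and
  point sets with respect to the DDF.  Every primitive is verified against
  central-difference numerics in the test suite.

## Known limitations

* Training at full recording scale (thousands of pairs, hundreds of
  epochs, full resolution) is out of scope; the architecture is the same
  but throughput is CPU-bound.
* DDFs are not guaranteed diffeomorphic and are never inverted.
* The similarity matrix is O(pairs × ROIs) dense in compute (not memory);
  registration graphs should stay sparse for long recordings.
* The posture-similarity pair selection of the upstream tracking system is
  replaced by a z-MIP NCC nearest-neighbor graph.
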