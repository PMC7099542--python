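# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `sinocad`, in the spirit of a model
documentation page: what each stage computes, which knobs matter, what
the synthetic data does and does not emulate, and where the design was
genuinely open.

## Synthetic phantoms

The volume generator produces the statistical structure the candidate
detector assumes, with deliberately minimal geometry:

- an elliptic-cylinder soft-tissue body in an air background;
- two ellipsoidal lungs of low-intensity parenchyma;
- vessels as random-walk tubes (radius ≈ 0.9–1.5 voxels) inside the lungs;
- a configurable number of dense ("high-intensity") parenchyma blobs;
- nodules as randomly oriented spheroids, radius 2.5–4.5 voxels by
  default, of which `n_juxtapleural` sit on the pleural boundary.

Voxel intensities are drawn from a four-class Gaussian mixture plus
optional additive noise. Defaults mimic HU contrast — lung parenchyma
≈ −850, soft tissue/wall ≈ −50, vessels ≈ +50, nodules ≈ +30, with
standard deviations 30–40 — and are fully configurable, since absolute
intensities are not essential to the method: only the four-population
structure is.

Two geometric choices deserve mention. Juxtapleural nodules are centred
at a depth of 0.6–0.9 of their radius below the pleural surface, so they
bulge into the lung while still crossing the boundary; this is the
configuration morphological closing can realistically recover, and the
carved indentation is what makes them hard for intensity-based lung
masking. Vessel walks terminate when they approach a nodule: a vessel
fused through a nodule has no unambiguous ground-truth label, and an
evaluation mask must be interpretable.

The patch generator supplies the classifier directly, in two codings.
The default *shape* coding models the candidate stage's output: positives
are compact soft-edged blobs of varied radius and eccentricity with
coarse gentle texture; negatives are elongated ellipses or bent tubes
with fine speckle, modelled on the vessel fragments and dense-parenchyma
pieces the detector actually produces as false positives. The
*size_texture* coding, used by the experiment harness, couples the label
jointly to object size and texture: positives are large AND smooth,
negatives draw uniformly from the other three (size, texture)
combinations, so neither cue alone separates the classes; under pixel
noise the object boundary — hence its size — is far better read from
line integrals (which average ~40 pixels of noise) than from the image,
which is exactly the regime where the projection representation should
help. A single `difficulty` parameter (0–1) widens distribution overlap
and raises pixel noise (σ up to 0.35 of the intensity range in the shape
coding, 0.30 in the size/texture coding); 0 gives a cleanly separable
set. Every patch is centred on its mass centroid, zero outside its
support, and min–max normalised to [0, 1] (the network needs a fixed
input scale; patch-relative normalisation also removes absolute
brightness as a confound).

What the phantoms do **not** emulate: reconstruction artefacts, scanner
noise spectra, anatomical variability of real lungs, partial-volume
effects at real slice thicknesses, or the correlation structure of real
nodule/vessel appearance. Green tests therefore certify the pipeline's
mechanics and its internal orderings, not clinical performance.

## Candidate detection (hierarchical VQ)

Every voxel in the region of interest contributes a 7-element local
intensity vector: itself plus its six face neighbours, in the fixed order
(centre, z−, z+, y−, y+, x−, x+), with replicate-edge padding at volume
borders (this keeps exactly one vector per voxel). The Karhunen–Loève
step projects these onto the smallest leading set of principal components
holding ≥ 95 % of the variance (typically 1–2 dimensions on smooth
volumes, since neighbouring intensities are strongly correlated); a zero
variance region degenerates to one dimension by convention.

The online VQ is competitive learning: codebook vectors start at
quantiles of the first principal component, and each sample moves its
nearest centroid by a decaying step η_t = η₀ / (1 + t/τ) with η₀ = 0.2
and τ = n/2 samples. Samples are processed in aggregation chunks of 1024
so the winner search is vectorised; passes repeat (max 8) until the
codebook moves < 1e-4. Classes are relabelled ascending by intensity, so
"class 0" is always the darkest tissue. On well-separated clusters this
agrees with converged Lloyd k-means on ≥ 99 % of points (asserted in the
tests); k-means is used only as an independent oracle there, never as the
implementation.

Lung extraction runs the 2-class VQ inside the largest above-Otsu
connected component, takes the low class, requires the two class means to
differ by ≥ 3 pooled within-class standard deviations (otherwise "no lung
found" — a uniform volume must not yield a lung), fills internal holes,
applies morphological closing with a ball of radius 3 (configurable) to
re-attach juxtapleural indentations, and keeps the two largest
components. On default phantoms this achieves Dice ≥ 0.99 against truth.

INC detection runs the 4-class VQ inside the lung mask. A class is a
candidate source only if its mean intensity exceeds the background
(darkest) class by ≥ 2 background standard deviations. Each source class
is opened with a 6-connected cross element — this severs one-voxel-thin
pleural rim sheets and sub-voxel bridges that would otherwise merge a
nodule into one sprawling component — then 26-connected components are
filtered by size (3–4000 voxels) and by elongation: the component's
voxel-coordinate covariance is eigendecomposed and components with
√(λ_max/λ_min) ≥ 3 are attributed to vessels and dropped. Survivors
become candidates (capped at 100, largest first). The design aims at the
stage-1 contract: sensitivity near 1 with a bounded, nonzero
false-positive load for stage 2 to remove.

ROI extraction takes the candidate's central axial slice, zeroes
everything outside the candidate mask, re-centres the mask centroid by
bilinear resampling, crops the bounding box plus a 2-pixel margin into a
square canvas, resizes bilinearly to 40 × 40 (aspect ratio of the box is
not preserved — the projection representation is what retains shape), and
min–max normalises.

## Sinogram projection and channelization

The projector evaluates the parallel-beam line integrals directly: for
each (view φ, bin s) the line is sampled every 0.5 px over the full patch
diagonal, sample values are taken by bilinear interpolation (zero outside
the patch), and the quadrature is assembled once per geometry into a
sparse matrix mapping flattened patches to flattened sinograms — so
projecting a batch is one sparse matmul, and linearity holds to float
precision. Views cover [0, π) uniformly (a 2π span would duplicate every
line); the 40 detector bins span the patch width, centred on the patch
centre, with no circular masking: lines near the edge bins pick up corner
mass exactly as the integral dictates. Against an independently coded
dense line-sampling oracle (step 0.1 px) the relative RMS error on random
patches is ≈ 0.1 %, far inside the 2 % tolerance used in the tests, and
per-view bin sums conserve patch mass to < 0.3 %.

Direct-cut reshapes a `40 × V` sinogram into C contiguous blocks of
V/C views. Interleave-cut assigns channel c the views
(c + j·C·step) mod V, j = 0 … V/C−1: with step 1 (the default) channel c
is the classic sparse-view comb {c, c+C, c+2C, …} covering the whole
angular range. The assignment partitions the views iff
gcd(step, V/C) = 1, which is validated up front; the step-3 variant on
640 views → 16 channels satisfies it. Both cuts are pure index
operations, so reassembly through the recorded view map is bit-exact.
Sinograms are min–max normalised per item before entering the network,
matching the image-patch convention.

## Classifier

The single-input network is conv 7×7×32 → maxpool 2×2/s2 → conv 5×5×64 →
maxpool 2×2/s2 → FC 1000 → FC 2 softmax, LeakyReLU (slope 0.01)
throughout; convolutions are stride 1 with same padding, giving the clean
40 → 20 → 10 spatial schedule and 6,455,866 parameters at 40×40×1 input.
The first convolution's channel depth follows the input, so image
patches, wide sinograms and 16-channel stacks share one topology. The
dual-input network keeps that sinogram branch, gives the image branch 64
filters in its first convolution, and fuses the two flattened conv
outputs by concatenation into the shared FC 1000 head (fusion before the
first FC layer is the only arrangement consistent with a single shared
FC block).

The network runs on a small numpy engine written for this package:
im2col convolutions backed by BLAS matmuls, float32 throughout, a fused
Adam update (numba-compiled when available, pure numpy otherwise), and
deterministic seeded initialisation (He-scaled). Training follows the
fixed protocol — Adam, lr 1e-4, β₁ 0.9, β₂ 0.999, batch 30, up to 25
epochs — with early stopping: 10 % of the training split is held out,
validation loss is monitored, and training stops after `patience` epochs
without improvement, restoring the best weights. The harness uses
patience 3 with a minimum improvement of 1e-3 (improvements below that
are noise at these dataset sizes); the estimator default is patience 5
with no minimum delta. Loss is 2-class cross-entropy, implied by the
softmax head.

Datasets are always split 80/20 over distinct ROI identifiers, stratified
by label, so that a ROI's image patch and all of its sinogram-derived
representations land on the same side; a leakage assertion in the tests
enforces this.

## Evaluation harness

AUC is computed by the rank method with average ranks for ties (equal to
the normalised Mann–Whitney U, and to exhaustive positive–negative pair
comparison, which the tests assert for all n ≤ 50). Conditions are run
`n_runs = 5` times with derived seeds; each run regenerates the dataset,
the ROI split and the training, and results are reported as mean ± sample
standard deviation over runs with full seed provenance. What the spread
is taken over is thus explicit: repeated end-to-end runs, not repeated
scoring of one model.

Within a suite all conditions are paired: each run's dataset and its
dense base sinogram are computed once, and every condition derives its
input from them (a V-view geometry's angles are an exact subset of the
base geometry's when V divides the base view count, so view subsetting
reproduces the V-view projection). The view sweep feeds V ∈ {40, 160,
640} as interleave stacks of V/40 channels of 40 views — the network
input stays 40 × 40 × C while angular information grows with V, which is
how the pipeline is designed to consume large view counts; the cut
comparison contrasts direct vs interleave at 640 views / 16 channels; the
domain comparison contrasts image-only, sinogram-only (640 → 16
interleave channels) and the combined dual-branch input.

Desk-scale problem sizes: each run trains on 50 + 50 size/texture-coded
ROIs at difficulty 1.0 (80/20 ROI-level split) and is scored on the
held-out side plus 75 + 75 freshly drawn evaluation-only ROIs — synthetic
data is unlimited, and the wider evaluation pool narrows AUC measurement
noise to ≈ ±0.02 without touching the training protocol. These sizes are
the smallest at which the directional comparisons (more views ≥ fewer;
interleave ≥ direct; combined ≥ each single input) operate away from the
AUC ceiling and with usable resolution. The comparisons are directional
by design: absolute AUC values on synthetic patches are not comparable
to clinical results. On shape-coded data (labels carried by elongation
alone, a cue both domains read easily) the cut and domain orderings are
statistical ties at this scale — the projection domain's advantage
specifically requires size information degraded by image-domain noise,
which is the regime the size/texture coding constructs.

## Known limitations

- The online VQ is one reasonable instantiation of self-adaptive
  competitive learning; its exact adaptive schedule, and the rule for
  picking the candidate class among the four tissue classes, are
  package design choices (flagged as such above), not uniquely determined
  by the problem.
- 2-D classification patches (the candidate's central axial slice) are
  used throughout; candidates are 3-D but their classification
  representation is planar by construction.
- The interleave view-to-channel assignment is the modular
  generalisation described above; other sparse-view orderings are
  possible and `step` exposes one family of them.
- Synthetic-data caveats listed under "Synthetic phantoms" apply to every
  quantitative result the tests and the acceptance script produce.
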