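# sinocad — sinogram-domain CADe for pulmonary nodules

`sinocad` implements a two-stage computer-aided detection (CADe) pipeline
for pulmonary nodules in chest CT that performs its false-positive
reduction in the **sinogram domain**. Most CADe systems classify candidate
patches in the reconstructed image domain; here each candidate's region of
interest (ROI) is additionally projected through the Radon transform

    Rd_f(φ, s) = ∫_{L(φ,s)} f(x, y) dl,      L(φ,s) = {(x,y) : x cos φ + y sin φ = s}

and a convolutional network learns nodule/non-nodule features directly
from the resulting `bins × views` sinogram, alone or fused with the image
patch. The projection-domain representation retains shape and size
information that is diluted when ROIs of very different sizes are all
resized to one patch size.

The pipeline has two stages:

1. **Initial nodule candidate (INC) detection** — hierarchical vector
   quantization (VQ): every voxel contributes a 7-element local intensity
   vector (itself + 6 face neighbours), reduced by a Karhunen–Loève
   transform keeping ≥ 95 % of the variance; a 2-class online VQ separates
   the lung from the chest body (followed by hole filling and morphological
   closing, which recovers juxtapleural nodules), and a 4-class VQ inside
   the lung separates parenchyma, vessels and nodule candidates. Compact
   bright components become candidates; elongated ones are attributed to
   vessels.
2. **False-positive reduction** — each candidate is centred, mask-isolated
   and resized to 40 × 40; projected to a 40-bin sinogram over 40–640
   uniformly spaced views in [0, π); wide sinograms are converted to
   multi-channel stacks either by contiguous blocks of views
   (*direct-cut*) or by strided sparse-view subsets (*interleave-cut*,
   e.g. 40 × 640 → 40 × 40 × 16); a small CNN
   (conv 7×7×32 → pool → conv 5×5×64 → pool → FC 1000 → softmax 2, LeakyReLU
   activations; a dual-branch variant fuses a sinogram branch and an image
   branch whose first convolution has 64 filters) outputs the nodule
   probability. Training uses Adam (lr 1e-4, β₁ 0.9, β₂ 0.999), batch
   size 30, up to 25 epochs with early stopping, and an 80/20 split at ROI
   level so no candidate's representations leak across the split.

Because clinical CT with radiologist annotations cannot ship with a code
repository, the package includes a first-class synthetic generator: chest
phantoms with the four-class Gaussian intensity structure the detector
assumes (low/high-intensity parenchyma, vessels, nodules, including
juxtapleural ones) and labelled 40×40 patch sets — shape-coded (compact
nodule-like blobs vs elongated vessel-like structures) for the detection
contracts, and size/texture-coded (labels depending jointly on object
size and texture under pixel noise) for the experiment harness, where
the projection domain's cleaner size readout matters. Real-data adapters
are intentionally out of scope.

## Worked example

```python
import numpy as np
import sinocad as sc

# stage 0: a synthetic chest volume with known truth
vol, truth = sc.generate_phantom(sc.PhantomConfig(seed=3))

# stage 1: lung extraction and candidate detection
lung = sc.segment_lung(vol, seed=0)
dice = 2 * (lung & truth.lung_mask).sum() / (lung.sum() + truth.lung_mask.sum())
records = sc.detect_incs(vol, lung, seed=0)
print(f"lung Dice {dice:.3f}, {len(records)} candidates")

# stage 2: sinogram projection and channelization of one candidate
sino = sc.radon_project(records[0].patch, sc.ProjectionGeometry(n_bins=40, n_views=640))
stack = sc.interleave_cut(sino, n_channels=16)
print(sino.values.shape, "->", stack.values.shape)

# classifier on a labelled synthetic patch set
patches = sc.generate_patch_dataset(60, 60, seed=1, difficulty=0.9)
train, test = sc.split_dataset(patches, fraction=0.8, seed=1)
x = lambda ps: np.stack([p.pixels for p in ps])
y = lambda ps: np.array([p.label for p in ps])
clf = sc.CNNClassifier(random_state=1).fit(x(train), y(train))
print("image-domain AUC", round(sc.roc_auc(clf.decision_scores(x(test)), y(test)), 3))
```

Output:

```
lung Dice 0.999, 5 candidates
(40, 640) -> (40, 40, 16)
image-domain AUC 0.958
```

`lung Dice` compares the VQ lung mask with the generator's truth; the
candidate count includes true nodules plus vessel/parenchyma false
positives (stage 2's input); the shapes show one 640-view sinogram being
converted to 16 sparse-view channels; the AUC is the held-out
nodule-vs-non-nodule discrimination of the image-domain CNN at the
default desk-scale conditions.

The experiment harness compares input representations over repeated
seeded runs (fresh dataset, ROI split and training each run):

```python
for r in sc.domain_comparison_suite(n_runs=5, base_seed=0):
    print(r)
```

A command-line interface mirrors the library:
`sinocad simulate|segment|detect|project|channelize|evaluate --help`.

## Layout

```
src/sinocad/
  core.py        shared containers (CTVolume, ROIPatch, CandidateRecord)
  phantom.py     synthetic volumes and labelled patch sets
  vq.py          7-neighbour features, KL reduction, online VQ
  candidates.py  lung segmentation, INC detection, ROI extraction
  sinogram.py    Radon projection, direct-/interleave-cut channelization
  nn.py          minimal CPU CNN engine (im2col conv, Adam, early stopping)
  classifier.py  network specs, ROI-level split, sklearn-style estimators
  evaluation.py  ROC/AUC, repeated-run aggregation, experiment suites
  io.py, cli.py  NIfTI/archive I/O and the command-line interface
docs/methods.md  modelling assumptions, parameters, numerical choices
```
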