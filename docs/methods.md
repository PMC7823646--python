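# Methods

This note documents the models, numerical choices and limitations of
`cowseg` in one place. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem and data model

The task is per-pixel multiclass classification of cow depth maps into
eight body parts (seven for the upper top-view camera 'U', from which
the udder is not visible). Inputs are 640×480 depth maps in integer
millimetres with background set to 0 and an aligned label mask. Real
barn recordings of this kind are not publicly distributable, so the
package generates synthetic scenes with the same structure; everything
downstream of the scene generator works unchanged on real depth/label
pairs read from 16-bit PGM files.

## Synthetic scene generator

**Cow geometry.** A cow is a union of labelled quadric primitives:
ellipsoids for back (torso), rump, head and udder, and capped cylinders
for the four legs. Vertical dimensions scale with the sacrum height
(default 1.46 m; the recorded herd spanned 1.43–1.49 m) and horizontal
ones with a nominal body length (default 2.4 m); a seeded ±2 % size
jitter differentiates individual cows. Two deliberately stylised
choices serve the camera geometry:

* the udder is tucked fully inside the torso's plan-view outline
  (semi-axes 0.05 L × 0.08 h × 0.13 h, centred under the rear belly), so
  overhead viewpoints cannot see it while side and shallow-diagonal
  viewpoints can;
* the legs splay outward by 25° (a wide stance), so the averted pair
  peeks beyond the body silhouette in top views, as the far legs of a
  real walking cow do.

**Cameras.** Pinhole intrinsics: 640×480, 57° horizontal field of view,
focal length = (width/2)/tan(fov/2) ≈ 589 px, square pixels, principal
point at the image centre. Three pose presets:

* **S** — side view: fixed by the recording-unit description at 0.6 m
  height with a horizontal optical axis across the passage. The standoff
  (default 3.2 m from the passage centre) is our choice, set so one
  whole cow fits a single frame; the physical unit instead stitched two
  cameras and many frames per pass.
* **N** — lower top view: 1.8 m height, shallow downward-inward axis
  (≈18° below horizontal). From here the udder is visible under the
  belly.
* **U** — upper top view, mounted upside down (the 180° roll is folded
  into the rotation matrix and the pose carries `flipped=True`): 3.6 m
  height, near-overhead axis. The exact top-view geometry of the
  original unit is not on record; this preset was chosen so that the
  torso geometrically occludes the udder (no label deletion — the
  occlusion logic itself enforces the 7-class structure) while head,
  rump, back and all four legs remain visible for every cow size in the
  herd range.

**Rendering.** Analytic ray–quadric intersection per pixel (no mesh or
z-buffer), taking the nearest hit; exact intersections make the
brute-force occlusion oracle in the test suite feasible. Depth is the
distance along the optical axis (z-depth) in mm — the Kinect depth-map
convention — plus Gaussian noise (default σ = 2 mm), rounded to integer
mm. The 2 mm default is small against the 500–4000 mm working range but
large enough to make the variance feature non-degenerate; returns
outside the working range become background. Scenes are stored as
16-bit binary PGM (depth) + 8-bit PGM (labels) + a JSON pose sidecar,
written and parsed through Pillow.

## Features

Gradient and Hessian of the depth surface are estimated by central
differences on the 3×3 neighbourhood with unit pixel spacing — the
simplest scheme fully determined by a nine-pixel square, and exact for
polynomial surfaces of degree ≤ 2 (a property test). Depth stays in raw
mm against the pixel grid; the mixed units are intentional (the
published example feature values are only reproducible with raw-unit
derivatives) and wash out in the MinMax standardisation. The curvature
score uses the convention m_curv = 0 where |g| = 0, since the formula
is 0/0 on locally flat patches.

Two properties of this curvature score discovered while building the
test oracles are worth recording:

* On any radially symmetric depth surface the score reduces exactly to
  −1/(2p) at pixel distance p from the cap — it is a level-set-type
  curvature, so on concentric level sets it measures ring radius, not
  surface bending. Spheres of different radii therefore give *equal*
  scores at matched pixels; the test suite checks the −1/(2p) closed
  form (0.5 % tolerance) and sign uniformity on analytic float samples.
* Integer-mm quantisation zeroes the gradient on most patches of a
  gently curved surface, so per-pixel curvature values on rendered
  scenes are heavily discretised near depth extrema. This mirrors real
  structured-light data, which quantises similarly.

Local variance uses the sample convention (denominator 8); this choice
reproduces the published worked values (126/648 ≈ 0.1944 and
72/648 ≈ 0.1111) where denominator 9 does not.

Pixels whose 3×3 patch touches background or the image border are
excluded from the feature table — the zeroed background would otherwise
contaminate curvature and variance. How the original pipeline treated
such pixels is not on record; this is a documented package choice.

Polygon labelling (the programmatic replacement for a manual
polygon-drawing tool) assigns each pixel strictly inside a polygon the
polygon's part index, later polygons winning on overlap, via shapely
point-in-polygon tests.

MinMax standardisation maps each feature to (x − min)/(max − min)
through scikit-learn's MinMaxScaler; constant features map to 0, and
out-of-range values on unseen data are not clipped. By default the
scaler is fitted on the 70 % training portion only; a
`scale_on_full` switch fits it on the full table before the split
instead, mirroring a fit-before-split reading of the original order of
operations. Both modes are supported; with five bounded features the
difference is negligible at this scale.

## Balancing

SMOTE is implemented in-package: per minority class, synthetic samples
x_i + λ(x_j − x_i) with x_j among the k = 5 nearest same-class
neighbours (scikit-learn neighbour search, exact brute force at these
sizes) and λ ~ U[0, 1], until every class reaches the majority count.
k = 5 is the canonical SMOTE default; the original study names the
technique but not k. Balancing is embedded *inside* the fold and
validation loops so that synthetic points can never leak into
evaluation rows. Tests verify exact count equality, the segment and
bounding-box properties, and k = 1 nearest-pair reconstruction against
a brute-force oracle.

## Classifiers

**kNN.** Training stores the standardised rows verbatim. Prediction is
majority vote among the k nearest Euclidean neighbours with fully
deterministic tie rules: neighbours are ordered by (distance,
stored-row index), and vote ties go to the class of the nearest
neighbour among the tied classes. Small problems use exact brute-force
distances; larger ones a cKDTree query re-sorted to the same ordering.
The tie rules are the reason kNN is implemented in-package;
scikit-learn's KNeighborsClassifier serves as an independent
cross-check at k = 1, where the rules coincide almost surely. Grid
search evaluates all k on each fold from a single neighbour query at
max(k).

**Dense network.** A numpy implementation of a plain dense stack:
Glorot-uniform seeded initialisation, ReLU hidden activations, softmax
output, categorical cross entropy, mini-batch Adam (β₁ = 0.9,
β₂ = 0.999). Defaults the original description leaves open, all
configurable: initial learning rate 0.001, batch size 256, at most 100
epochs. The learning rate decays linearly, lr(e) = lr₀·(1 − (e−1)/E),
floored at lr₀/100. Inverted dropout (rate 0.15) is applied after
hidden layers 2, 4, 6, … during training only. 30 % of the training
rows are split off for validation before SMOTE; early stopping halts
training `patience` (5) epochs after the last validation-loss
improvement and the best-epoch weights are returned. Architecture
search minimises the best observed validation loss per (layers,
neurons) cell, ties resolving to fewer layers, then fewer neurons;
diverged cells are recorded and excluded. Whether the original grid
search used early stopping per cell is unknown; this implementation
does, which only shortens hopeless cells.

## Evaluation

One-vs-rest confusion counts per class give precision, recall and F1
(zero-denominator cases return 0 so degenerate folds stay defined).
Hamming loss is the per-sample mean of mismatching one-hot indicators,
averaged over samples; for single-label data it equals
2(1 − accuracy)/N, the identity the acceptance checks exercise. Print
conventions: 3 decimals for accuracy/Hamming loss, 2 for per-class
metrics, halves rounded away from zero. Kruskal–Wallis tests (scipy,
tie-corrected, χ² approximation with df = groups − 1) compare pooled
per-class metrics between methods and between camera positions;
completely tied data returns H = 0, p = 1 rather than an error.

## Experiment scale and reproducibility

The default experiment renders 3 cows (sacrum heights 1.43/1.46/1.49 m)
from each of the 3 camera positions and subsamples 12 000 eligible
pixels per scene — 36 000 rows per position, ~10⁵ overall — which the
package treats as its standard desk-scale study size; the full
published-size tuning grids remain available (`full_grids` /
`--full`). A single master seed fans out to every stage by fixed
offsets (cow geometry: +100 + cow index; rendering: +1000 + 10·position
+ cow; subsampling: +5; hold-out split: +1; CV: +2; SMOTE: +3;
network: +4), so stages re-run in isolation bit-identically and
`run-all` is end-to-end deterministic.

## What the synthetic data does and does not show

The generator emulates the geometry the pipeline assumes: smooth
labelled surfaces, three calibrated viewpoints, integer-mm depth with
additive noise, zero background, udder invisibility from above, strong
class imbalance (back/rump dominate, legs and udder are small). It does
not emulate cow-to-cow shape variability beyond size scaling, gait or
articulation, structured-light artefacts (speckle dropout, edge
shadows, inter-camera interference), segmentation errors, or labelling
noise from hand-drawn polygons. Synthetic scenes are therefore *much*
easier than barn data: hold-out accuracies near 0.99 here say that the
implementation recovers a learnable structure from the five features,
not that the method reaches this accuracy on real herds, whose
published accuracies are lower. The method ordering observed on
synthetic data (kNN at or above the network) matches the published
finding, and is logged by the acceptance script rather than asserted as
a theorem.

## Known limitations

* The cow composite is stylised; part boundaries are primitive
  intersections, not anatomical landmarks.
* m_curv is the level-set-type score defined above, not the textbook
  graph mean curvature; see the closed-form discussion under Features.
* Quantisation makes per-pixel curvature nearly ternary on gently
  curved regions; the feature still separates parts in combination with
  position and depth.
* kNN prediction on very large stored sets uses a KD-tree whose
  behaviour under exact distance ties at the k-boundary is resolved by
  the post-sort, not by the tree itself; within-run determinism is
  unaffected.
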