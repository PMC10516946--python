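# Methods

## Problem

Alveolar bone defects in cleft lip/palate (CLP) patients are graded on a
four-level severity index from the morphology of the maxillary surface
model: **0** — a bone depression with at least one intact supporting wall;
**1** — a complete unilateral cleft of the alveolus; **2** — a projected
premaxilla with some palatal bone continuity; **3** — a projected premaxilla
with little or no palatal continuity.  `cleftgrade` implements an
interpretable classifier for this index that operates directly on triangle
surface meshes, together with **SurfGradCAM**, which renders the basis of
each decision as a per-vertex heatmap on the mesh.

## Classification pipeline

1. **Pose normalization** — the mesh is translated so its vertex centroid is
   at the origin and scaled so the maximum vertex radius is 1.  No rotational
   alignment is attempted: the surrounding spherical camera set makes the
   classifier tolerant to orientation, so clinical orientation conventions
   are not required.
2. **Fly-by rendering** — cameras are placed at the vertices of a subdivided
   icosahedron (level *L* gives `10·4^L + 2` viewpoints; default *L* = 0,
   12 views) at radius 3, each looking at the origin with a field of view
   that frames the unit sphere at ~90% of the image height.  Each view is
   rasterized by a software z-buffer into four channels — camera-space
   normal (x, y, z) mapped to [0, 1] and frustum-normalized depth — plus a
   per-pixel **face-ID buffer** recording which triangle produced each
   pixel.  Shading is two-sided because cleft meshes are open surfaces.
   Default training resolution is 64 px (128 px supported).
3. **Per-view encoding** — a small shared CNN (three 3×3 stride-2 conv +
   ReLU blocks with 16/32/64 channels) maps each view to K = 64 final conv
   maps at 8×8; global average pooling gives one 64-d descriptor per view.
4. **Attention aggregation** — a gated attention scorer
   `s_v = w·(tanh(U h_v) ⊙ σ(V h_v))` produces one scalar per view;
   softmax over views yields convex weights `a_v` and the shape descriptor
   `z = Σ_v a_v h_v`.  The aggregation is permutation-invariant in `z` and
   permutation-equivariant in the weights.
5. **Severity head** — a linear map to 4 logits and a softmax.  Severity is
   treated as nominal 4-class classification; the ordinal structure enters
   only through the within-±1 evaluation band.

### Training

Class-weighted cross-entropy (inverse-frequency weights, on by default
because the reference cohort supports are imbalanced 62/45/45/38), Adam at
1e-3 with cosine decay to one tenth, batch size 8 shapes (96 views),
default 220 epochs with early stopping on validation loss (patience 60) and
restoration of the best parameters.  Per-view augmentation — random integer
translations up to ±6 px with background fill — is applied during training
only.  It denies the network frame-layout shortcuts (where the arch sits in
the image) so the learned evidence is carried by translation-equivariant
local detectors.  Image flips are deliberately *not* used: cleft sidedness
is chiral information, the generator already mirrors arches between shapes,
and flip-augmented models were observed to paint class-1 heatmaps onto the
mirror-image position of the cleft.

The whole network, including backpropagation and the Adam loop, is
implemented directly on NumPy arrays (float32, im2col convolutions).  This
keeps the dependency set small and gives SurfGradCAM *exact* analytic
gradients of any logit with respect to the final conv maps.  Training is
deterministic for a fixed seed.

## SurfGradCAM

For a target class *c*:

1. the gradient of the pre-softmax logit *c* is backpropagated to the final
   conv feature maps `A^k` of every view.  The gradient flows through global
   average pooling **and** the attention weights, so a view's contribution
   reflects both its content and how much the model attends to it.  Gradients
   are taken with respect to the logit, not the softmax probability
   (standard GradCAM practice);
2. channel weights `α_k` are the spatial means of that gradient, and the
   per-view class activation map is `ReLU(Σ_k α_k A^k)`, bilinearly
   upsampled from 8×8 to the render resolution;
3. the maps are pooled with a **max** through the face-ID buffers: a face's
   score is the largest CAM value over every pixel it produced in any view,
   and a vertex takes the max over its incident faces (mean pooling over
   incident faces is available as a flag).  Vertices never visible in any
   view keep raw value exactly 0.

Both pooling stages use max deliberately: "pooled using a max function" can
be read as across-view pooling only or as both stages, and the second stage
is flagged so either reading is available.  A per-mesh, per-class [0, 1]
display normalization is attached alongside the raw values; heatmap color
scales are therefore relative within one mesh and class, matching how such
maps are inspected visually.

## Synthetic shape population

Patient meshes are not redistributable, so all training and testing uses a
parametric "cleft arch": an elliptical cross-section swept along a parabolic
midline (a horseshoe), with grade-specific deformations —

| grade | construction |
|---|---|
| 0 | partial-depth buccal depression carved over an angular window (depth fraction 0.30–0.65 of the cross-section, width 0.25–0.45 rad) |
| 1 | one full-thickness gap (width 0.30–0.50 rad); palatal continuity kept as a thin palatally-offset continuation of the tube (thickness factor 0.50–0.90) |
| 2 | bilateral gaps (0.40–0.60 rad) isolating a premaxilla displaced forward by 0.15–0.40 model units; palatal bridges 0.25–0.60 |
| 3 | wider bilateral gaps (0.50–0.75 rad), projection 0.30–0.55, bridges 0–0.05 (half the draws snap to exactly 0 — no continuity, and the mesh then separates into three connected components) |

Within-class parameters are drawn uniformly from these ranges, which overlap
slightly between neighbouring grades as the difficulty control.  Mean gap
width and mean projection are non-decreasing in grade.  Tube ends are capped
(segmented bone surfaces are closed; the cleft cut rims are the only
deliberate openings).  Every shape also receives nuisance variation — arch
width and depth ±12%, cross-section radii ±28%, random left/right mirroring,
per-shape defect *positions* along the arch (clefts arise at varying
positions in the lateral-incisor/canine region), and vertex noise
(σ = 0.004) — chosen large enough that overall size, thickness, silhouette
and frame position carry essentially no class information.  The
severity cues are then the local defect features themselves, as they are in
real anatomy; without this, a classifier can exploit pose-normalization
side effects (a projected premaxilla inflates the bounding radius, making
grade-3 arches render systematically thinner) and its heatmaps delocalize.

Each generated mesh records its **defect region** (vertices of the carved
depression, the gap rims and bridges, and the displaced premaxilla for
grades 2–3).  This ground-truth mask enables a quantitative localization
test of the heatmaps, something a patient cohort can only support visually.

What the generator does *not* emulate: tooth anatomy, segmentation noise and
artifacts, anatomical maxilla shape, and the real (unknown) overlap between
severity grades.  Passing the synthetic classification benchmark therefore
demonstrates that the pipeline recovers a severity signal present in surface
geometry — not that the reference patient-cohort metrics would be reproduced
on clinical data; and the heatmap-localization score quantifies where the
gradient evidence sits, with the caveats discussed under limitations.

## Evaluation protocol

Stratified 5-fold cross-validation: the five test folds partition the data
(each ≈20%); within each fold the remainder splits 7:1 into train and
validation — the 70/10/20 layout.  Reported metrics: per-class precision,
recall, F1 and one-vs-rest AUC (midrank ties); pooled totals are
**support-weighted** (`Σ m_c·s_c / Σ s_c`) — the convention verified to
reproduce the published pooled values from the per-class rows, and under
which total recall equals overall accuracy; a row-normalized confusion
matrix whose diagonal is asserted equal to per-class recall; and the
within-±k agreement read from the |i−j| ≤ k band (k = 1 by default).
Across-fold SDs are reported on metric scale.  Per-class F1 printed in the
reference report differs from the harmonic mean of its printed P/R by up to
one unit in the third decimal (it was evidently computed before rounding);
the identity tests therefore use a 1.5e-3 tolerance, while the pooled totals
reproduce exactly at three decimals.

## Numerical and design choices

- Rasterizer: pixel centers at half-integers, top-left origin; screen-space
  linear interpolation of 1/w for the z-test (perspective-exact for planar
  triangles); face-ID sentinel −1; background depth exactly 1.0; foreground
  depth clamped strictly below 1 so `face_id = −1 ⇔ depth = 1` holds.
- Degenerate faces (zero screen area) and faces behind the camera are
  skipped; a mesh fully outside the frustum renders as all-background with
  a warning rather than an error.
- Attention logits and CAMs are computed in float32; the finite-difference
  validation of the GradCAM gradients runs the head in float64, where
  agreement is at machine precision.
- Pose normalization rejects all-coincident-vertex meshes (zero scale).
- Empty confusion-matrix rows/columns yield 0 metrics with a warning rather
  than NaN; AUC for a class absent from the truth is NaN and flagged.
- VTK legacy and XML polydata I/O is ASCII; binary legacy VTK is rejected
  with a clear error.  OBJ cannot carry per-vertex scalars and drops them
  with a warning.

## Problem sizes

The shipped benchmarks use 12 views at 64 px, 200 shapes (160 train / 40
test) and the default 220-epoch schedule; the rasterizer oracle tests use
≤50-face convex meshes at 48 px.  These sizes were chosen so a complete
from-scratch run (generate, render, train, evaluate, explain) completes on
a single CPU core in minutes while leaving every algorithmic property
exercised at full fidelity.

## Known limitations

- GradCAM heatmaps inherit the 8×8 spatial granularity of the final conv
  maps; after bilinear upsampling and max pooling, importance bleeds a few
  pixels across silhouette boundaries.
- Which image evidence a small CNN uses for a class — hence where its CAM
  mass sits — depends on the training trajectory, and at this scale the
  quantitative localization of the heatmaps is markedly less stable than
  the classification itself.  In a 4-class softmax the one-vs-rest evidence
  for the lower and middle grades is substantially the *absence* of the
  more severe features (grade 0: no through-cleft anywhere; grade 1: no
  second gap, no projection), and a ReLU-rectified positive-evidence map
  cannot display absence at the defect site — the heat settles instead on
  the anatomy whose intactness is discriminative.  Empirically, grade 2
  (projected premaxilla *with* palatal bridges, both positive features)
  localizes to its defect region in 70–100% of test shapes across training
  seeds, while grades 0, 1 and 3 range from 10% to 90% depending on the
  seed; the pooled defect-localization rate of the default benchmark sits
  well below the classification accuracy and should be read as a property
  of gradient-based class evidence at this model and cohort scale, not as a
  measure of classifier quality.
- The attention layer may concentrate almost all weight on one or two views
  of a shape; faces visible only in ignored views then receive near-zero
  heatmap values even when geometrically salient.
- Severity is modeled as nominal; no ordinal regression head is provided.
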