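# Methods

This note records the models, conventions and numerical choices behind
`fioseg`, and what the synthetic experiments do and do not demonstrate.

## The intensification operator

Enhancement operates per 2-D plane. `Min` and `Max` are always the plane's
own extremes — never pooled over a batch or across channels — so a plane's
dynamic range is preserved exactly and the operator is invariant to which
other images happen to be processed alongside it.

The intensification map is `μ' = 2μ²` for `μ ≤ 0.5` and
`μ' = 1 − 2(1 − μ)²` above. This is the classic squared-parenthesis form:
it is the only reading of the operator that is continuous at the 0.5
crossover, maps [0, 1] onto itself, and fixes 0, 0.5 and 1; the
alternative placement of the square, `1 − 2(1 − μ²)`, evaluates to −0.5 at
μ = 0.5 and is rejected on those grounds. Because the map is monotone and
endpoint-fixing, enhanced planes preserve pixel ordering, keep every value
inside `[Min, Max]`, darken pixels below the plane midpoint and brighten
pixels above it; a plane containing only two values {Min, Max} is a fixed
point for any iteration count.

Tunable parameters (`EnhanceConfig`):

- `iterations` (default 1): extra passes polarise harder; one pass is the
  conventional use.
- `channel_policy` (default `per_channel`): grayscale content stored as
  three identical channels — the normal case for exported ultrasound
  frames — behaves identically under both policies; `luminance_first`
  exists for genuine colour input and applies the per-pixel luminance gain
  to all channels (Rec.601 weights).
- `rounding` (default nearest, ties away from zero) and `output_mode`
  (`integer` for the 8-bit path, `real` for comparisons against the
  per-pixel scalar reference). Constant planes are returned unchanged with
  a warning: a zero-contrast plane gives `Max = Min` and the fuzzification
  denominator vanishes; returning the input is the only value-preserving
  choice.

## Evaluation measures

Masks use the {1 = normal tissue, 2 = tumor} convention; tumor is the
positive class of the confusion table, and class-1 scores are obtained by
swapping the roles of TP/TN and FP/FN. Global accuracy, Jaccard IoU and
pixelwise F1 (Dice) follow their standard confusion-table definitions;
Dice and IoU satisfy `Dice = 2·IoU/(1+IoU)` exactly, which the tests
assert on random tables.

Two F1 variants exist deliberately. The pixelwise F1 is the literal
precision/recall harmonic mean over pixels and tracks IoU closely. The
"BF score" columns of all reports instead use the boundary-matching F1:
extract each mask's inner 4-connectivity boundary (a region pixel with a
4-neighbour of a different label, or a region pixel on the image border),
then score the fraction of boundary pixels of each mask lying within a
Euclidean distance tolerance of the other's boundary. Reported BF values
are systematically far below IoU for imperfect contours, which is the
behaviour the measure is designed to have. Choices made concrete here:

- boundary definition: inner 4-connectivity boundary — simple,
  orientation-free, and checkable against an all-pairs brute-force oracle
  (the implementation matches it exactly; distances come from an exact
  Euclidean distance transform);
- default tolerance: 0.75 % of the image diagonal, rounded up to a whole
  pixel (≈ 2 px at 128×128), exposed as a parameter;
- empty boundaries: both empty → the class is absent from the comparison
  (NaN, excluded from means); exactly one empty → 0.

Set-level semantics: GA accumulates confusion counts over all pixels of
all images; mean IoU and mean BF are the unweighted average over images
of the per-image class means, with classes absent from an image skipped
rather than scored 0 or 1 (so images that genuinely lack a class are not
penalised). A dataset-accumulated IoU mode is provided for comparison but
is not the default, since the class-then-image averaging is the
convention the shipped reference tables follow.

Tables of percentages are aggregated in exact decimal arithmetic: cells
are averaged across tables and quantised to 2 decimals with half-up
rounding, and the appended average row is the column mean of the rounded
model rows, rounded the same way. Half-up (not banker's) rounding is
required to reproduce the shipped reference tables' printed cells.
Aggregating the two batch-mode subset tables reproduces every cell of the
shipped batch average table, including its average row; on the one-by-one
pair the same procedure reproduces all 48 model cells but lands 0.01
higher on two average-row cells (95.45 vs 95.44, 68.08 vs 68.07). Those
two published cells sit on half-cent ties and are consistent only with
averaging performed before rounding, which in turn would misreproduce one
batch-table cell — no single rounding scheme matches both printed average
rows, so the documented procedure is applied uniformly and the 0.01
discrepancy is accepted.

## The phantom generator

Phantoms emulate the statistical features of B-mode breast imaging that
enhancement and thresholding interact with — speckle texture, a single
darker lesion, limited contrast — not ultrasound physics (no wave
propagation, transducer point-spread function, or malignancy morphology).

A lesion support is sampled as an ellipse with random centre, semi-axes
(aspect ratio 0.5–1) and orientation, its radius modulated by a smooth
periodic perturbation built from harmonics 2–4 with amplitude
`boundary_irregularity` (default 0.15) so the contour is roughened but
stays star-convex, hence one connected component. Samples are redrawn
(cap: 100 attempts) until the rasterised area fraction lies inside
`lesion_area_fraction` (default 3–25 % of the image, the range typical of
single-tumor 128×128 BUS crops). Echogenicity is piecewise constant —
background 1, lesion `contrast` (default 0.35, a clearly hypoechoic
lesion; a hyperechoic flag inverts the ratio) — multiplied by mean-one
gamma speckle with shape `speckle_looks` (default 4; 1 is fully developed
speckle), optionally attenuated by `shadow_strength` in the band below
the lesion, then log-compressed, min-max rescaled to 8 bits and
replicated to three identical channels. Defaults are frozen as the
package's study conditions; all randomness flows through one seed, so
(parameters, seed) determine every output byte, which the tests verify at
file level.

What phantom results do not show: performance on clinical BUS images,
where attenuation with depth, heterogeneous tissue texture, acoustic
artifacts and annotation ambiguity all matter. The phantoms establish
correctness and reproducibility of the machinery, not clinical accuracy.

## Backends and invocation modes

The classical backend is a deterministic pipeline: channel collapse →
median smoothing (disk radius 2) → Otsu global threshold, dark side as
tumor candidate (hypoechoic assumption; a polarity flag flips it) →
morphological opening and closing (disk radius 2) → keep the largest
connected candidate of at least `min_area` pixels (default 30), else no
tumor. It is a pure function of (image, parameters).

The learned backend is a tiny per-pixel classifier: a small scikit-learn
MLP (hidden layers 32/16, a few thousand weights) over 11 per-pixel
features — intensity, Gaussian means and local standard deviations at
scales 1–8 px, and normalised image coordinates — trained on a balanced,
seeded subsample of pixels (400/image by default) from phantom pairs,
with the same morphological cleanup applied to its predictions. Training
is reproducible given (dataset, seed); a zero-epoch handle predicts all
normal tissue and is rejected by the built-in sanity check. At the
default study scale (200 training phantoms, 50 held-out) it reaches
held-out tumor IoU ≈ 0.96, far above the 0.6 floor asserted in the
acceptance suite.

Both invocation modes — batch (the whole collection as one datastore) and
one-by-one (one image per call) — route through the same per-image
function, so their outputs are identical by construction and the harness
asserts exactly that. Segmentation toolchains that normalise or batch
state across a datastore can behave differently between these modes; this
package deliberately forbids any batch-dependent state, making
mode-invariance a checkable invariant rather than an empirical accident.

A consequence worth stating: for the classical backend, FIO enhancement
is nearly neutral. A global threshold selects a partition of the
intensity order, and the FIO map is monotone, so the set of achievable
partitions is unchanged — only the variance-based threshold choice shifts
slightly. A pre-registered 20-seed pilot at contrast 0.5 and fully
developed speckle found per-run mean tumor IoU of ~0.834 before vs
~0.830 after enhancement (after ≥ before in 3/20 runs). Reported gains
from this kind of preprocessing therefore hinge on segmenters whose
decision surfaces are not monotone-invariant (e.g. trained CNNs); no test
in this package asserts an improvement direction for the threshold
backend.

## Pipeline and problem sizes

`run_experiment` evaluates every requested subset × backend × mode ×
condition cell, where "Before" uses raw images and "After" uses
FIO-enhanced images computed on the fly (a flag materialises the enhanced
images to `Fuzzy_*` folders to mirror the on-disk dataset convention).
Reports are written as one CSV per table plus a JSON twin validated
against the shipped pydantic schema; identical configuration and master
seed yield byte-identical report files. Per-subset phantom seeds derive
from the master seed through a CRC-based stream split, keeping subsets
independent but reproducible.

Default problem sizes keep the full test suite around a minute and the
acceptance script under half a minute on one CPU: 8×8 planes for the
1000-plane operator-oracle sweep, ≤12×12 masks for the 500-pair metric
oracles (brute-force all-pairs boundary matching is quadratic in boundary
size), 128×128 phantoms with 20-image experiment runs, and the 200/50
phantom split for the learned backend. These sizes are the package's
registered study conditions, not tunables.

## Known limitations

- The boundary-F1 depends on the boundary definition; other toolchains
  use morphological boundaries with other connectivities and will differ
  in the third decimal on coarse masks.
- The luminance-first channel policy rescales chroma multiplicatively and
  can clip saturated colour pixels; it is untested territory beyond shape
  and range contracts, as ultrasound exports are grayscale.
- The learned backend is a texture classifier, not an encoder–decoder; it
  has no shape prior beyond the morphological cleanup and will fragment
  on lesions far outside the phantom statistics it was trained on.
- Only two-class problems are supported; the {1,2} coding is load-bearing
  throughout.
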