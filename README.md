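# fioseg

Fuzzy intensification-operator (FIO) contrast enhancement and two-class
semantic-segmentation evaluation for breast-ultrasound-like images.

B-mode breast ultrasound (BUS) shows tumors as hypoechoic (darker)
regions embedded in speckled tissue with limited contrast. A common
preprocessing step before automatic tumor segmentation is fuzzy contrast
enhancement: map intensities into fuzzy memberships, polarise them away
from the midpoint, and map back. `fioseg` implements that operator, the
standard evaluation measures used to score two-class tumor/normal-tissue
segmentations, a seeded speckle-phantom generator that provides paired
images and ground truth without any clinical data, pluggable segmentation
backends invocable in batch or one-by-one mode, and an experiment pipeline
that produces before/after-enhancement comparison tables.

It is aimed at researchers who want a reproducible, dependency-light
harness for studying how intensity preprocessing interacts with
segmentation quality — on synthetic phantoms or on any dataset laid out as
`Original_*/Ground_Truth_*` folders of 8-bit images and {1 = normal,
2 = tumor} masks.

## The operator and the measures

For a 2-D intensity plane with minimum `Min` and maximum `Max`, the FIO
enhancement is the composition of three steps applied pixel-by-pixel:

1. fuzzification: `μ = (I − Min) / (Max − Min)`
2. intensification:
   `μ' = 2μ²` for `μ ≤ 0.5`, and `μ' = 1 − 2(1 − μ)²` for `μ > 0.5`
3. de-fuzzification: `O = Min + μ'·(Max − Min)`

The map fixes `Min`, `Max` and the midpoint, preserves pixel ordering, and
darkens everything below the midpoint while brightening everything above
it — a contrast stretch with no change in dynamic range.

Segmentations are scored with tumor (class 2) as the positive class:

- global accuracy `GA = (TP + TN) / (TP + TN + FP + FN)`
- per-class Jaccard index `IoU = TP / (TP + FP + FN)`
- boundary-F1 (`BF`): harmonic mean of boundary precision and recall,
  where a boundary pixel matches if a boundary pixel of the other mask
  lies within a Euclidean distance tolerance (default 0.75 % of the image
  diagonal, rounded up to a whole pixel)

"Mean" IoU/BF averages the per-image class means over all images of a
set; GA accumulates pixel counts over the set. Per-model results are
assembled into tables with Before/After sub-columns and averaged across
subsets with half-up rounding at two decimals, including an appended
column-average row.

## Worked example

```python
import numpy as np
import fioseg as fs

# the operator on a plane spanning the full 8-bit range
img = np.array([[0, 64, 128], [192, 230, 255]], dtype=np.uint8)
fs.enhance(img)
# array([[  0,  32, 128],
#        [224, 250, 255]], dtype=uint8)
```

Pixel 64 has membership 64/255 ≈ 0.251, is intensified to 2·0.251² ≈ 0.126
and mapped back to ≈ 32.1 → 32; pixel 192 (membership ≈ 0.753) brightens
to 224. The extremes and the midpoint 128 are unchanged.

A small end-to-end experiment on noisy phantoms (fully developed speckle,
lesion/background echogenicity ratio 0.5), scoring an Otsu-threshold
backend before and after enhancement in both invocation modes:

```python
config = fs.ExperimentConfig(
    subsets={"noisy": fs.PhantomSource(
        params=fs.PhantomParams(contrast=0.5, speckle_looks=1), n=20)},
    backends=[fs.SegmenterSpec(name="otsu")],
    modes=["batch", "one_by_one"],
    seed=42,
)
report = fs.run_experiment(config)
print(report.aggregated["batch"])
```

```
metric    Global Accuracy       Mean IoU       Mean BF
condition          Before After   Before After  Before After
model
otsu                97.98 97.97    89.02 89.37   80.58 81.31
Average             97.98 97.97    89.02 89.37   80.58 81.31
```

Each cell is a percentage over the 20 phantoms: the Otsu backend labels
~98 % of pixels correctly, overlaps the true lesion by ~89 % IoU, and
matches ~81 % of boundary pixels within the distance tolerance; on these
phantoms enhancement shifts a threshold-based segmenter only marginally.
The batch and one-by-one tables are identical because every shipped
backend is a pure function of the single image — the two invocation modes
cannot disagree by construction.

The same workflow is available from the shell:

```bash
fioseg simulate --n 20 --out ds/ --seed 1          # phantom dataset
fioseg enhance  --in ds/Original_Phantom --out enhanced/
fioseg segment  --in ds/Original_Phantom --out pred/ --backend classical
fioseg evaluate --pred pred/ --truth ds/Ground_Truth_Phantom --report scores.csv
fioseg run      --config experiment.yaml           # full before/after table
```

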