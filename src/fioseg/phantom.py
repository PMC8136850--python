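"""Synthetic B-mode-like breast ultrasound phantoms with ground truth.

Each phantom is a 128x128 image with three identical channels, containing
one hypoechoic (darker than background) lesion on a speckled background,
paired with a {1 = normal tissue, 2 = tumor} label mask.  The generator is
a statistical caricature of B-mode imaging, not an acoustic simulation:

* the lesion support is a randomly placed, oriented ellipse whose radius
  is perturbed by a smooth periodic function to roughen the contour;
* echogenicity is piecewise constant (background mean 1, lesion mean
  ``contrast``), multiplied by mean-one gamma speckle with shape
  ``speckle_looks`` (fully developed speckle for 1 look, smoother for
  more looks), optionally attenuated in a posterior-shadow band below the
  lesion, then log-compressed and min-max rescaled to 8 bits.

All randomness flows through a single seed, so (parameters, seed) fully
determine every output byte.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.typing import NDArray
from PIL import Image

from .metrics import NORMAL, TUMOR, write_mask

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomParams",
    "PhantomPair",
    "sample_lesion_mask",
    "render_phantom",
    "generate_pair",
    "generate_dataset",
]

_RETRY_CAP = 100


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings.

    Parameters
    ----------
    size:
        Image height and width in pixels; components must be >= 32.
    lesion_area_fraction:
        Inclusive (low, high) bounds on the lesion's share of the image
        area; lesions are resampled until the rasterised area lands in
        this window.
    boundary_irregularity:
        Amplitude of the smooth radial perturbation of the lesion contour,
        as a fraction of the local ellipse radius; 0 gives an exact
        ellipse.
    contrast:
        Lesion/background mean echogenicity ratio in (0, 1] — values below
        1 give the usual hypoechoic (dark) lesion; 1 makes the lesion
        invisible.
    hyperechoic:
        If true, invert the contrast so the lesion is brighter than the
        background (ratio 1/contrast); for robustness experiments.
    speckle_looks:
        Shape of the mean-one gamma speckle; 1 is fully developed
        (roughest) speckle, larger values average it down.
    shadow_strength:
        Multiplicative attenuation in [0, 1] of the band below the lesion
        (0 disables posterior shadowing).
    seed:
        Master seed for mask sampling and rendering.
    """

    size: tuple[int, int] = (128, 128)
    lesion_area_fraction: tuple[float, float] = (0.03, 0.25)
    boundary_irregularity: float = 0.15
    contrast: float = 0.35
    hyperechoic: bool = False
    speckle_looks: int = 4
    shadow_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError(f"size components must be >= 32, got {self.size}")
        lo, hi = self.lesion_area_fraction
        if not (0 < lo <= hi < 1):
            raise ValueError(f"lesion_area_fraction must lie within (0, 1), got {self.lesion_area_fraction}")
        if not (0 < self.contrast <= 1):
            raise ValueError(f"contrast must be in (0, 1], got {self.contrast}")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1")
        if not (0 <= self.shadow_strength <= 1):
            raise ValueError("shadow_strength must be in [0, 1]")


@dataclass(frozen=True)
class PhantomPair:
    """A rendered phantom: (H, W, 3) uint8 image with identical channels,
    its {1,2} mask, and the parameters/seed that produced it."""

    image: NDArray[np.uint8]
    mask: NDArray[np.int64]
    params: PhantomParams
    seed: int = field(default=0)


def _perturbed_radius(phi: NDArray, amplitude: float, rng: np.random.Generator) -> NDArray:
    """Smooth periodic radial modulation in [1-amplitude, 1+amplitude]."""
    if amplitude == 0:
        return np.ones_like(phi)
    mod = np.zeros_like(phi)
    # low harmonics only, so the contour stays smooth and star-convex
    for k in (2, 3, 4):
        a, b = rng.normal(size=2)
        mod += a * np.cos(k * phi) + b * np.sin(k * phi)
    peak = np.abs(mod).max()
    if peak > 0:
        mod = mod / peak * amplitude
    return 1.0 + mod


def sample_lesion_mask(params: PhantomParams, rng: np.random.Generator) -> NDArray[np.int64]:
    """Sample a single-lesion {1,2} mask meeting the area-fraction bounds.

    Draws an ellipse with random centre, axes and orientation, perturbs
    its radius by smooth noise scaled by ``boundary_irregularity``, and
    rasterises class 2 onto a class-1 background.  Resamples (up to a
    bounded retry budget) until the mask area fraction is inside the
    configured window and the lesion is a single connected component.
    """
    from scipy import ndimage

    h, w = params.size
    lo, hi = params.lesion_area_fraction
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(_RETRY_CAP):
        frac = rng.uniform(lo, hi)
        ratio = rng.uniform(0.5, 1.0)  # semi-axis aspect b/a
        a = np.sqrt(frac * h * w / (np.pi * ratio))
        b = ratio * a
        if 2 * a >= min(h, w) - 4:
            continue
        cy = rng.uniform(a + 2, h - a - 2)
        cx = rng.uniform(a + 2, w - a - 2)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
        phi = np.arctan2(yr / b, xr / a)
        inside = rho <= _perturbed_radius(phi, params.boundary_irregularity, rng)
        area_frac = inside.mean()
        if not (lo <= area_frac <= hi):
            continue
        labeled, ncomp = ndimage.label(inside)
        if ncomp != 1:
            continue
        return np.where(inside, TUMOR, NORMAL).astype(np.int64)
    raise RuntimeError(
        f"could not sample a lesion meeting area fraction {params.lesion_area_fraction} "
        f"at size {params.size} within {_RETRY_CAP} attempts"
    )


def render_phantom(
    mask: NDArray, params: PhantomParams, rng: np.random.Generator
) -> PhantomPair:
    """Render a speckled B-mode-like image for a given lesion mask."""
    mask = np.asarray(mask)
    h, w = mask.shape
    lesion = mask == TUMOR

    ratio = params.contrast if not params.hyperechoic else 1.0 / params.contrast
    echo = np.where(lesion, ratio, 1.0)

    if params.shadow_strength > 0 and lesion.any():
        rows, cols = np.nonzero(lesion)
        bottom, c0, c1 = rows.max(), cols.min(), cols.max()
        shade = np.ones((h, w))
        shade[bottom + 1 :, c0 : c1 + 1] = 1.0 - params.shadow_strength
        echo = echo * shade

    looks = params.speckle_looks
    speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=(h, w))
    intensity = echo * speckle

    # log compression, then min-max rescale to the 8-bit range
    compressed = np.log1p(50.0 * intensity)
    lo, hi = compressed.min(), compressed.max()
    if hi > lo:
        scaled = (compressed - lo) / (hi - lo) * 255.0
    else:
        scaled = np.zeros_like(compressed)
    plane = np.floor(scaled + 0.5).astype(np.uint8)
    image = np.repeat(plane[:, :, None], 3, axis=2)
    return PhantomPair(image=image, mask=mask.astype(np.int64), params=params, seed=params.seed)


def generate_pair(params: PhantomParams) -> PhantomPair:
    """Sample a lesion mask and render it, all from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    mask = sample_lesion_mask(params, rng)
    return render_phantom(mask, params, rng)


def generate_dataset(
    n: int,
    params: PhantomParams,
    out_dir: str | Path,
    seed: int | None = None,
    subset: str = "Phantom",
) -> Path:
    """Write ``n`` phantom pairs in the Original_*/Ground_Truth_* layout.

    Creates ``Original_<subset>/`` with 3-channel 8-bit PNG images and
    ``Ground_Truth_<subset>/`` with {1,2} 8-bit PNG masks, plus a
    ``manifest.csv`` recording filename, per-phantom seed and parameters.
    Deterministic for a fixed master seed.  Returns the manifest path.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    master = params.seed if seed is None else seed
    out_dir = Path(out_dir)
    img_dir = out_dir / f"Original_{subset}"
    gt_dir = out_dir / f"Ground_Truth_{subset}"
    img_dir.mkdir(parents=True, exist_ok=True)
    gt_dir.mkdir(parents=True, exist_ok=True)

    # independent child seeds, reproducible from the master seed
    child_seeds = np.random.SeedSequence(master).generate_state(n) % (2**31)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["filename", "subset", "seed", "height", "width", "area_fraction",
             "contrast", "boundary_irregularity", "speckle_looks", "shadow_strength"]
        )
        for i in range(n):
            p = replace(params, seed=int(child_seeds[i]))
            pair = generate_pair(p)
            name = f"{subset.lower()}_{i:04d}.png"
            Image.fromarray(pair.image, mode="RGB").save(img_dir / name)
            write_mask(gt_dir / name, pair.mask)
            writer.writerow(
                [name, subset, p.seed, p.size[0], p.size[1],
                 f"{(pair.mask == TUMOR).mean():.6f}",
                 p.contrast, p.boundary_irregularity, p.speckle_looks, p.shadow_strength]
            )
    logger.info("wrote %d phantom pairs to %s", n, out_dir)
    return manifest_path
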