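"""Fuzzy intensification-operator (FIO) contrast enhancement.

The operator stretches contrast in three steps applied per 2-D intensity
plane:

1. *Fuzzification* — min–max normalise intensities into a fuzzy membership
   map: ``mu = (I - Min) / (Max - Min)`` with ``Min``/``Max`` taken over the
   plane itself.
2. *Intensification* — push memberships away from the 0.5 crossover:
   ``mu' = 2 mu**2`` for ``mu <= 0.5`` and ``mu' = 1 - 2 (1 - mu)**2``
   above it.  The map is continuous, fixes 0, 0.5 and 1, and maps [0,1]
   onto itself, so it can be iterated.
3. *De-fuzzification* — rescale back onto the original intensity range:
   ``O = Min + mu' * (Max - Min)``.

Pixels darker than the plane midpoint get darker and brighter pixels get
brighter; the extremes and the exact midpoint are fixed, so the dynamic
range of the plane is preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import NDArray

logger = logging.getLogger(__name__)

__all__ = [
    "EnhanceConfig",
    "fuzzify",
    "intensify",
    "defuzzify",
    "enhance",
]


@dataclass(frozen=True)
class EnhanceConfig:
    """Settings for :func:`enhance`.

    Parameters
    ----------
    channel_policy:
        ``"per_channel"`` enhances each plane of a 3-channel stack
        independently (on grayscale content stored as three identical
        channels this is identical to enhancing the single plane);
        ``"luminance_first"`` enhances the Rec.601 luminance plane and
        rescales each channel by the per-pixel luminance gain.
    iterations:
        Number of intensification passes (>= 1).  The classic operator is
        applied once but is often iterated for stronger polarisation.
    rounding:
        ``"nearest"`` rounds half away from zero; ``"floor"`` truncates.
    output_mode:
        ``"integer"`` rounds and clamps to the source range (the normal
        8-bit image path); ``"real"`` returns unrounded float values, used
        when comparing against a scalar reference evaluation.
    """

    channel_policy: Literal["per_channel", "luminance_first"] = "per_channel"
    iterations: int = 1
    rounding: Literal["nearest", "floor"] = "nearest"
    output_mode: Literal["integer", "real"] = "integer"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.channel_policy not in ("per_channel", "luminance_first"):
            raise ValueError(f"unknown channel_policy {self.channel_policy!r}")
        if self.rounding not in ("nearest", "floor"):
            raise ValueError(f"unknown rounding {self.rounding!r}")
        if self.output_mode not in ("integer", "real"):
            raise ValueError(f"unknown output_mode {self.output_mode!r}")


def _as_plane(image: NDArray) -> NDArray[np.float64]:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D plane, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr


def fuzzify(image: NDArray) -> NDArray[np.float64]:
    """Min–max normalise a 2-D intensity plane into [0, 1] memberships.

    The plane minimum maps to 0 and the maximum to 1.  A constant plane has
    no contrast to normalise; it yields an all-zero map and a warning (the
    degenerate case is handled by :func:`enhance`, which returns such
    planes unchanged).
    """
    arr = _as_plane(image)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        logger.warning("constant plane (all pixels = %g): degenerate fuzzification", lo)
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def intensify(membership: NDArray, iterations: int = 1) -> NDArray[np.float64]:
    """Apply the intensification operator ``iterations`` times.

    One pass maps ``mu <= 0.5`` to ``2 mu**2`` and ``mu > 0.5`` to
    ``1 - 2 (1 - mu)**2``; both branches agree at the 0.5 crossover and the
    output stays in [0, 1].
    """
    mu = np.asarray(membership, dtype=np.float64)
    if mu.size == 0:
        raise ValueError("empty membership map")
    if mu.min() < 0 or mu.max() > 1:
        raise ValueError("memberships must lie in [0, 1]")
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    for _ in range(iterations):
        mu = np.where(mu <= 0.5, 2.0 * mu * mu, 1.0 - 2.0 * (1.0 - mu) ** 2)
    return np.clip(mu, 0.0, 1.0)


def defuzzify(
    membership: NDArray,
    min_val: float,
    max_val: float,
    config: EnhanceConfig | None = None,
) -> NDArray:
    """Map memberships back onto the intensity range ``[min_val, max_val]``.

    In integer output mode the result is rounded per ``config.rounding``
    (nearest: half away from zero) and clamped to the range; real mode
    returns the unrounded values.
    """
    config = config or EnhanceConfig()
    mu = np.asarray(membership, dtype=np.float64)
    if mu.size == 0:
        raise ValueError("empty membership map")
    if mu.min() < 0 or mu.max() > 1:
        raise ValueError("memberships must lie in [0, 1]")
    if min_val > max_val:
        raise ValueError(f"min_val {min_val} exceeds max_val {max_val}")
    out = min_val + mu * (max_val - min_val)
    if config.output_mode == "real":
        return out
    if config.rounding == "nearest":
        # round half away from zero (intensities are nonnegative)
        out = np.floor(out + 0.5)
    else:
        out = np.floor(out)
    return np.clip(out, min_val, max_val)


def _enhance_plane(plane: NDArray[np.float64], config: EnhanceConfig) -> NDArray:
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        logger.warning("constant plane (all pixels = %g): returned unchanged", lo)
        return plane.copy()
    mu = (plane - lo) / (hi - lo)
    mu = intensify(mu, config.iterations)
    return defuzzify(mu, lo, hi, config)


def enhance(image: NDArray, config: EnhanceConfig | None = None) -> NDArray:
    """Apply FIO contrast enhancement to a 2-D plane or an ``(H, W, C)`` stack.

    Min and Max are computed per plane per image, never across a batch or
    across channels.  Constant planes are returned unchanged.  Integer
    output mode preserves the input dtype for integer inputs.
    """
    config = config or EnhanceConfig()
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    in_dtype = arr.dtype
    work = arr.astype(np.float64)
    if work.min() < 0 or work.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")

    if work.ndim == 2:
        out = _enhance_plane(work, config)
    elif work.ndim == 3:
        if config.channel_policy == "per_channel":
            out = np.stack(
                [_enhance_plane(work[..., c], config) for c in range(work.shape[2])],
                axis=-1,
            )
        else:  # luminance_first
            if work.shape[2] != 3:
                raise ValueError("luminance_first policy requires 3 channels")
            lum = 0.299 * work[..., 0] + 0.587 * work[..., 1] + 0.114 * work[..., 2]
            real_cfg = EnhanceConfig(
                channel_policy=config.channel_policy,
                iterations=config.iterations,
                rounding=config.rounding,
                output_mode="real",
            )
            lum_out = _enhance_plane(lum, real_cfg)
            gain = np.where(lum > 0, np.asarray(lum_out, dtype=np.float64) / np.maximum(lum, 1e-12), 1.0)
            out = work * gain[..., None]
            if config.output_mode == "integer":
                rounded = np.floor(out + 0.5) if config.rounding == "nearest" else np.floor(out)
                out = np.clip(rounded, 0, 255)
    else:
        raise ValueError(f"expected 2-D or 3-D image, got shape {arr.shape}")

    if config.output_mode == "integer" and np.issubdtype(in_dtype, np.integer):
        return out.astype(in_dtype)
    return out
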