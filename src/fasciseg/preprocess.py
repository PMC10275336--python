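"""Preprocessing chain for microCT nerve slices.

The chain mirrors what the segmenter expects at train and test time:

1. drop slices whose epineurium is not fully inside the field of view;
2. center a fixed-size crop window on the epineurium centroid;
3. enhance contrast 16-bit -> 8-bit: zero staining-artifact pixels above a
   saturation threshold (default 18,000), pin the lowest/highest 0.1% of the
   remaining pixels to 1/255 and rescale linearly in between;
4. normalize to float32 by dividing by the slice mean (output mean 1);
5. Gaussian-smooth with sigma = 1 px.

Every step records itself in a provenance list carried alongside the pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from fasciseg.synthetic import NerveStack

__all__ = [
    "ContrastParams",
    "exclude_border_slices",
    "compute_centroid",
    "center_crop",
    "enhance_contrast",
    "normalize",
    "gaussian_smooth",
    "preprocess_stack",
]


@dataclass(frozen=True)
class ContrastParams:
    """Contrast-enhancement parameters.

    ``saturation_threshold`` is the 16-bit value above which pixels are
    treated as staining artifacts and zeroed; ``low_tail`` / ``high_tail``
    are the pixel fractions pinned to 1 and 255.
    """

    saturation_threshold: int = 18_000
    low_tail: float = 0.001
    high_tail: float = 0.001

    def validate(self) -> None:
        if not (0 < self.saturation_threshold <= 65535):
            raise ValueError(f"saturation_threshold must lie in (0, 65535], got {self.saturation_threshold}")
        for name, v in (("low_tail", self.low_tail), ("high_tail", self.high_tail)):
            if not (0 < v < 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5), got {v}")


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())


def exclude_border_slices(stack: NerveStack) -> tuple[NerveStack, list[int]]:
    """Drop slices whose epineurium touches the image border or is empty.

    Returns the filtered stack and the (0-based) indices of removed slices.
    """
    removed = [
        z
        for z in range(stack.n_slices)
        if not stack.epineurium_masks[z].any() or _touches_border(stack.epineurium_masks[z])
    ]
    if len(removed) == stack.n_slices:
        warnings.warn(f"nerve {stack.nerve_id!r}: all slices excluded by the border rule", stacklevel=2)
    keep = np.array([z for z in range(stack.n_slices) if z not in set(removed)], dtype=int)
    out = NerveStack(
        nerve_id=stack.nerve_id,
        images=stack.images[keep].copy() if len(keep) else stack.images[:0],
        fascicle_masks=stack.fascicle_masks[keep].copy() if len(keep) else stack.fascicle_masks[:0],
        epineurium_masks=stack.epineurium_masks[keep].copy() if len(keep) else stack.epineurium_masks[:0],
        pixel_spacing=stack.pixel_spacing,
        slice_spacing=stack.slice_spacing,
        meta={**stack.meta, "excluded_border_slices": removed},
    )
    return out, removed


def compute_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic-mean (row, col) of the true pixels of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot compute the centroid of an empty mask: slice unusable")
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def center_crop(
    image: np.ndarray,
    *masks: np.ndarray,
    centroid: tuple[float, float],
    size: int = 400,
) -> tuple[np.ndarray, ...]:
    """Crop ``image`` (and any masks) to ``size`` x ``size`` centered on ``centroid``.

    The window starts at ``round(centroid) - size // 2`` per axis (rounding
    half away from zero); parts of the window outside the image are
    zero-padded (false for masks). Returns ``(cropped_image, *cropped_masks)``.
    """
    if size < 1:
        raise ValueError(f"crop size must be positive, got {size}")
    H, W = image.shape
    r0 = _round_half_away(centroid[0]) - size // 2
    c0 = _round_half_away(centroid[1]) - size // 2

    def crop_one(arr: np.ndarray) -> np.ndarray:
        out = np.zeros((size, size), dtype=arr.dtype)
        rs, re = max(r0, 0), min(r0 + size, H)
        cs, ce = max(c0, 0), min(c0 + size, W)
        if rs < re and cs < ce:
            out[rs - r0 : re - r0, cs - c0 : ce - c0] = arr[rs:re, cs:ce]
        return out

    return tuple(crop_one(a) for a in (image, *masks))


def enhance_contrast(image: np.ndarray, params: ContrastParams | None = None) -> np.ndarray:
    """16-bit -> 8-bit contrast enhancement with artifact saturation.

    Pixels above ``saturation_threshold`` are set to 0. Tail percentiles are
    then computed over the remaining pixels: values at or below the low
    percentile map to 1, at or above the high percentile to 255, and the rest
    linearly in between (rounded to nearest, ties to even). Output values lie
    in {0} ∪ [1, 255].
    """
    params = params or ContrastParams()
    params.validate()
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot enhance an empty image")
    out = np.zeros(image.shape, dtype=np.uint8)
    keep = image <= params.saturation_threshold
    vals = image[keep].astype(np.float64)
    if vals.size == 0:
        warnings.warn("all pixels saturated; output is all zero", stacklevel=2)
        return out
    lo = np.quantile(vals, params.low_tail)
    hi = np.quantile(vals, 1.0 - params.high_tail)
    if hi <= lo:
        warnings.warn("degenerate contrast (low and high percentiles coincide); mapping to 255", stacklevel=2)
        out[keep] = 255
        return out
    scaled = (image.astype(np.float64) - lo) / (hi - lo) * 254.0 + 1.0
    mapped = np.rint(np.clip(scaled, 1.0, 255.0)).astype(np.uint8)
    out[keep] = mapped[keep]
    return out


def normalize(image: np.ndarray) -> np.ndarray:
    """Divide by the slice mean; float32 output with mean 1 (within 1e-6)."""
    image = np.asarray(image, dtype=np.float32)
    m = float(image.mean(dtype=np.float64))
    if m <= 0:
        raise ValueError("cannot normalize a slice with nonpositive mean (all-zero image?)")
    out = (image.astype(np.float64) / m).astype(np.float32)
    return out


def gaussian_smooth(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """2D Gaussian smoothing with reflective boundaries."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return gaussian_filter(np.asarray(image, dtype=np.float32), sigma=sigma, mode="reflect").astype(np.float32)


def preprocess_stack(
    stack: NerveStack,
    crop_size: int = 400,
    contrast: ContrastParams | None = None,
    sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Run the full chain on every slice of a stack.

    Border slices are excluded first; each surviving slice is cropped around
    its epineurium centroid, contrast-enhanced, normalized and smoothed.
    Returns ``(inputs, targets, provenance)`` where ``inputs`` is
    ``(n, crop_size, crop_size)`` float32, ``targets`` the matching cropped
    fascicle masks (bool), and ``provenance`` one record per surviving slice.
    """
    contrast = contrast or ContrastParams()
    filtered, removed = exclude_border_slices(stack)
    inputs, targets, prov = [], [], []
    for z in range(filtered.n_slices):
        centroid = compute_centroid(filtered.epineurium_masks[z])
        img, fasc = center_crop(
            filtered.images[z], filtered.fascicle_masks[z], centroid=centroid, size=crop_size
        )
        enhanced = enhance_contrast(img, contrast)
        norm = normalize(enhanced)
        smooth = gaussian_smooth(norm, sigma=sigma)
        inputs.append(smooth)
        targets.append(fasc)
        prov.append(
            {
                "nerve_id": stack.nerve_id,
                "slice": z,
                "centroid": [round(centroid[0], 3), round(centroid[1], 3)],
                "crop_size": crop_size,
                "saturation_threshold": contrast.saturation_threshold,
                "tails": [contrast.low_tail, contrast.high_tail],
                "normalized": True,
                "smooth_sigma": sigma,
                "excluded_border_slices": removed,
            }
        )
    if inputs:
        return np.stack(inputs), np.stack(targets), prov
    shape = (0, crop_size, crop_size)
    return np.zeros(shape, np.float32), np.zeros(shape, bool), prov
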