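"""On-the-fly augmentation of image/mask pairs during training.

Each pair passes through an independent Bernoulli gate per transform, in the
fixed order rotation -> flips -> scale -> additive noise -> multiplicative
intensity field. Geometric transforms share one parameter draw between image
and mask (bilinear for the image, nearest-neighbor for the mask) so the
ground truth never moves relative to its image. Defaults follow the training
recipe for osmium-stained microCT: rotation 0-270 degrees on half the
images, vertical/horizontal flips on a third each, scaling 0.9-1.2x on two
thirds, zero-mean Gaussian noise with sigma drawn in [0.001, 0.003] on every
image (intensities are on the mean-1 normalized scale), and a low-frequency
intensity field f(x, y) = A sin(a x) + B sin(b y) + 1 on half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentationConfig",
    "apply_rotation",
    "apply_flip",
    "apply_scale",
    "apply_noise",
    "apply_intensity_field",
    "augment_pair",
]


@dataclass(frozen=True)
class AugmentationConfig:
    p_rotation: float = 0.5
    rotation_range: tuple[float, float] = (0.0, 270.0)
    p_flip_vertical: float = 1.0 / 3.0
    p_flip_horizontal: float = 1.0 / 3.0
    p_scale: float = 2.0 / 3.0
    scale_range: tuple[float, float] = (0.9, 1.2)
    noise_std_range: tuple[float, float] = (0.001, 0.003)
    p_intensity_field: float = 0.5
    field_param_range: tuple[float, float] = (0.001, 0.3)
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_rotation", "p_flip_vertical", "p_flip_horizontal", "p_scale", "p_intensity_field"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("rotation_range", "scale_range", "noise_std_range", "field_param_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")


def apply_rotation(image: np.ndarray, mask: np.ndarray, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image (bilinear) and mask (nearest) about the center.

    Angles that are exact multiples of 90 degrees are lossless pixel
    permutations; other angles interpolate, filling out-of-frame regions
    with 0/false. Output dimensions are unchanged.
    """
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        return np.rot90(image, k).copy(), np.rot90(mask, k).copy()
    img = ndimage.rotate(image, angle, reshape=False, order=1, mode="constant", cval=0.0)
    msk = ndimage.rotate(mask.astype(np.uint8), angle, reshape=False, order=0, mode="constant", cval=0)
    return img, msk.astype(bool)


def apply_flip(image: np.ndarray, mask: np.ndarray, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Mirror both layers; ``axis`` is ``"vertical"`` (flip rows) or ``"horizontal"``."""
    if axis == "vertical":
        return image[::-1].copy(), mask[::-1].copy()
    if axis == "horizontal":
        return image[:, ::-1].copy(), mask[:, ::-1].copy()
    raise ValueError(f"unknown flip axis {axis!r}; expected 'vertical' or 'horizontal'")


def apply_scale(image: np.ndarray, mask: np.ndarray, factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Rescale content about the center by ``factor``, back to original size.

    Upscaled content is center-cropped; downscaled content is zero-padded.
    """
    if factor == 1.0:
        return image.copy(), mask.copy()
    H, W = image.shape
    img = ndimage.zoom(image, factor, order=1, mode="constant", cval=0.0)
    msk = ndimage.zoom(mask.astype(np.uint8), factor, order=0, mode="constant", cval=0).astype(bool)

    def fit(arr: np.ndarray, fill) -> np.ndarray:
        h, w = arr.shape
        out = np.full((H, W), fill, dtype=arr.dtype)
        r0 = (h - H) // 2
        c0 = (w - W) // 2
        rs, cs = max(r0, 0), max(c0, 0)
        rd, cd = max(-r0, 0), max(-c0, 0)
        rows = min(h, H)
        cols = min(w, W)
        out[rd : rd + rows, cd : cd + cols] = arr[rs : rs + rows, cs : cs + cols]
        return out

    return fit(img, 0.0 if img.dtype.kind == "f" else 0), fit(msk, False)


def apply_noise(image: np.ndarray, std: float, rng: np.random.Generator) -> np.ndarray:
    """Add pixelwise zero-mean Gaussian noise with standard deviation ``std``."""
    if std < 0:
        raise ValueError(f"noise std must be nonnegative, got {std}")
    if std == 0:
        return image.copy()
    return image + rng.normal(0.0, std, size=image.shape).astype(image.dtype, copy=False)


def apply_intensity_field(image: np.ndarray, A: float, B: float, a: float, b: float) -> np.ndarray:
    """Multiply by the low-frequency field f(x, y) = A sin(a x) + B sin(b y) + 1.

    ``x`` is the column index and ``y`` the row index, in pixels. With the
    default parameter range [0.001, 0.3] the field stays within [0.4, 1.6],
    a gentle multiplicative shading of a mean-1 image.
    """
    rows, cols = image.shape
    y = np.arange(rows, dtype=np.float64)[:, None]
    x = np.arange(cols, dtype=np.float64)[None, :]
    f = A * np.sin(a * x) + B * np.sin(b * y) + 1.0
    return (image * f).astype(image.dtype, copy=False)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Apply the compound augmentation to one image/mask pair.

    Each sub-transform fires independently with its configured probability,
    in the fixed order rotation -> vertical flip -> horizontal flip -> scale
    -> noise -> intensity field. Returns the transformed pair and a record of
    every applied transform with its sampled parameters. Deterministic given
    the state of ``rng``.
    """
    config.validate()
    applied: list[dict] = []
    img = image
    msk = mask

    if rng.random() < config.p_rotation:
        angle = float(rng.uniform(*config.rotation_range))
        img, msk = apply_rotation(img, msk, angle)
        applied.append({"transform": "rotation", "angle_deg": angle})
    if rng.random() < config.p_flip_vertical:
        img, msk = apply_flip(img, msk, "vertical")
        applied.append({"transform": "flip", "axis": "vertical"})
    if rng.random() < config.p_flip_horizontal:
        img, msk = apply_flip(img, msk, "horizontal")
        applied.append({"transform": "flip", "axis": "horizontal"})
    if rng.random() < config.p_scale:
        factor = float(rng.uniform(*config.scale_range))
        img, msk = apply_scale(img, msk, factor)
        applied.append({"transform": "scale", "factor": factor})
    std = float(rng.uniform(*config.noise_std_range))
    if std > 0:
        img = apply_noise(img, std, rng)
        applied.append({"transform": "noise", "std": std})
    if rng.random() < config.p_intensity_field:
        A, B, a, b = (float(rng.uniform(*config.field_param_range)) for _ in range(4))
        img = apply_intensity_field(img, A, B, a, b)
        applied.append({"transform": "intensity_field", "A": A, "B": B, "a": a, "b": b})

    if img is image:
        img = image.copy()
    if msk is mask:
        msk = mask.copy()
    return img, np.asarray(msk, dtype=bool), applied
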