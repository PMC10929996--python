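"""Training-time augmentation: nine composable stochastic transforms.

The catalog (in order) is: rotation, scaling, flipping, additive white
Gaussian noise, Gaussian blurring, brightness adjustment, contrast
adjustment, simulation of low resolution, and gamma transformation.

Spatial transforms (rotation, scaling, flipping, low-resolution) are applied
identically to image and mask — the mask via nearest-neighbor interpolation
so it stays binary; intensity transforms touch the image only.  Spatial
transforms run before intensity transforms so injected noise is never
interpolated.  Out-of-frame regions are filled with 0 (air) in both image
and mask.  All randomness comes from the caller's generator, so a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import Patch


@dataclass
class TransformConfig:
    enabled: bool = True
    p: float = 0.2
    lo: float = 0.0
    hi: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"probability must be in [0,1], got {self.p}")
        if self.enabled and self.hi < self.lo:
            raise ValueError(f"degenerate parameter range ({self.lo}, {self.hi})")


@dataclass
class AugmentConfig:
    """One entry per catalog transform; ranges follow common practice for
    patch-based 3D segmentation (the magnitudes are fully configurable)."""

    rotation: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.2, lo=-30.0, hi=30.0))
    scaling: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.2, lo=0.85, hi=1.25))
    flipping: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.5))
    gaussian_noise: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.1, lo=0.01, hi=0.1))
    gaussian_blur: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.2, lo=0.5, hi=1.5))
    brightness: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.15, lo=-0.2, hi=0.2))
    contrast: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.15, lo=0.75, hi=1.25))
    low_resolution: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.25, lo=1.0, hi=2.0))
    gamma: TransformConfig = field(default_factory=lambda: TransformConfig(p=0.3, lo=0.7, hi=1.5))

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        cfg = cls()
        for name in _CATALOG:
            getattr(cfg, name).p = 0.0
        return cfg


_CATALOG = (
    "rotation",
    "scaling",
    "flipping",
    "gaussian_noise",
    "gaussian_blur",
    "brightness",
    "contrast",
    "low_resolution",
    "gamma",
)

# spatial transforms run first (mask follows the image), then intensity-only
_SPATIAL = ("rotation", "scaling", "flipping", "low_resolution")
_ORDER = ("rotation", "scaling", "flipping", "low_resolution",
          "gaussian_noise", "gaussian_blur", "brightness", "contrast", "gamma")


def transform_catalog() -> list[dict]:
    """The nine augmentations, named and in canonical order."""
    return [{"name": name, "kind": "spatial" if name in _SPATIAL else "intensity"}
            for name in _CATALOG]


def _fit_shape(arr: np.ndarray, shape, cval=0.0) -> np.ndarray:
    """Center-crop / center-pad to an exact target shape."""
    out = arr
    for ax, (n, target) in enumerate(zip(arr.shape, shape)):
        if n > target:
            start = (n - target) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(start, start + target)
            out = out[tuple(sl)]
        elif n < target:
            pad = [(0, 0)] * out.ndim
            short = target - n
            pad[ax] = (short // 2, short - short // 2)
            out = np.pad(out, pad, constant_values=cval)
    return out


def _rotate(img, msk, angle, axes):
    img = ndimage.rotate(img, angle, axes=axes, reshape=False, order=1, cval=0.0)
    msk = ndimage.rotate(msk.astype(np.float32), angle, axes=axes, reshape=False, order=0, cval=0.0)
    return img, msk


def _zoom(img, msk, factor):
    shape = img.shape
    img = _fit_shape(ndimage.zoom(img, factor, order=1, cval=0.0), shape)
    msk = _fit_shape(ndimage.zoom(msk.astype(np.float32), factor, order=0, cval=0.0), shape)
    return img, msk


def _low_res(img, msk, factor):
    shape = img.shape
    small = ndimage.zoom(img, 1.0 / factor, order=1)
    img = _fit_shape(ndimage.zoom(small, np.array(shape) / np.array(small.shape), order=1), shape)
    msmall = ndimage.zoom(msk.astype(np.float32), 1.0 / factor, order=0)
    msk = _fit_shape(ndimage.zoom(msmall, np.array(shape) / np.array(msmall.shape), order=0), shape)
    return img, msk


def apply_augmentations(patch: Patch, cfg: AugmentConfig,
                        rng: np.random.Generator) -> Patch:
    """Apply the enabled transforms to an image/mask patch pair.

    The image must be normalized to [0, 1]; output intensities are clipped
    back into [0, 1] and the mask stays exactly binary.
    """
    img = np.asarray(patch.image, dtype=np.float32)
    if img.min() < -1e-6 or img.max() > 1 + 1e-6:
        raise ValueError("apply_augmentations expects a [0,1]-normalized image patch")
    msk = np.asarray(patch.mask)
    img = img.copy()
    msk = msk.astype(np.float32, copy=True)

    for name in _ORDER:
        tc: TransformConfig = getattr(cfg, name)
        if not tc.enabled or rng.random() >= tc.p:
            continue
        if name == "rotation":
            angle = rng.uniform(tc.lo, tc.hi)
            plane = [(0, 1), (0, 2), (1, 2)][rng.integers(3)]
            img, msk = _rotate(img, msk, angle, plane)
        elif name == "scaling":
            img, msk = _zoom(img, msk, rng.uniform(tc.lo, tc.hi))
        elif name == "flipping":
            axes = [ax for ax in range(3) if rng.random() < 0.5]
            if axes:
                img = np.flip(img, axis=axes)
                msk = np.flip(msk, axis=axes)
        elif name == "low_resolution":
            img, msk = _low_res(img, msk, rng.uniform(max(tc.lo, 1.0), tc.hi))
        elif name == "gaussian_noise":
            img = img + rng.normal(0.0, rng.uniform(tc.lo, tc.hi), size=img.shape)
        elif name == "gaussian_blur":
            img = ndimage.gaussian_filter(img, sigma=rng.uniform(tc.lo, tc.hi))
        elif name == "brightness":
            img = img + rng.uniform(tc.lo, tc.hi)
        elif name == "contrast":
            m = img.mean()
            img = (img - m) * rng.uniform(tc.lo, tc.hi) + m
        elif name == "gamma":
            img = np.clip(img, 0.0, 1.0) ** rng.uniform(tc.lo, tc.hi)

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    msk = (msk > 0.5).astype(np.uint8)
    return Patch(image=np.ascontiguousarray(img), mask=np.ascontiguousarray(msk),
                 volume_id=patch.volume_id, corner=patch.corner, padded=patch.padded)
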