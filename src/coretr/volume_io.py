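"""CT volume I/O and the preprocessing chain.

Volumes are held as ``(H, W, D)`` float arrays in Hounsfield units (HU), with
``H``/``W`` the in-plane axes and ``D`` the through-plane (slice) axis.  The
preprocessing chain applied before training/inference is: clip intensities to
a fixed HU window, min-max normalize with that same fixed window (so intensity
meaning is comparable across scans), resample to uniform voxel spacing, and
crop fixed-size cubic patches.

NIfTI (.nii / .nii.gz) is the interchange format; files are reoriented to a
canonical anatomical orientation (LPS) at read time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import SimpleITK as sitk

DEFAULT_CLIP_LO = -1024.0
DEFAULT_CLIP_HI = 3068.0
DEFAULT_PATCH_SIZE = 96
DEFAULT_PATCHES_PER_VOLUME = 4


class VolumeIOError(Exception):
    """Base error for volume reading problems."""


class MissingFileError(VolumeIOError):
    pass


class NotA3DImageError(VolumeIOError):
    pass


class UnreadableHeaderError(VolumeIOError):
    pass


@dataclass
class CTVolume:
    """A 3D scalar grid with physical geometry.

    ``voxels`` is (H, W, D); ``spacing`` is mm per voxel along (H, W, D);
    ``origin`` is the scanner-space coordinate of voxel (0, 0, 0).
    ``normalized`` is False while values are in HU and True after min-max
    normalization to [0, 1].
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normalized: bool = False

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise NotA3DImageError(f"expected 3D volume, got {self.voxels.ndim}D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if min(self.voxels.shape) < 1:
            raise ValueError("volume dimensions must each be >= 1")
        if self.normalized:
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(f"normalized volume has values outside [0,1]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SegMask:
    """Binary mask geometrically aligned to a CTVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise NotA3DImageError(f"expected 3D mask, got {v.ndim}D")
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be exactly 0/1, found {uniq[:10]}")
        self.voxels = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class Patch:
    """A cubic image/mask crop with provenance back to its source volume."""

    image: np.ndarray
    mask: np.ndarray
    volume_id: str = ""
    corner: tuple[int, int, int] = (0, 0, 0)  # 0-based corner in the (padded) source
    padded: bool = False

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(f"patch image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img)  # (D, H, W) = (z, y, x)
    voxels = np.ascontiguousarray(np.transpose(arr, (1, 2, 0)))  # (H, W, D)
    sx, sy, sz = img.GetSpacing()
    spacing = (float(sy), float(sx), float(sz))
    origin = tuple(float(o) for o in img.GetOrigin())
    return voxels, spacing, origin


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    arr = np.ascontiguousarray(np.transpose(voxels, (2, 0, 1)))  # (D, H, W)
    img = sitk.GetImageFromArray(arr.astype(np.float32))
    img.SetSpacing((float(spacing[1]), float(spacing[0]), float(spacing[2])))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def read_volume(path: str | os.PathLike) -> CTVolume:
    """Read a 3D NIfTI volume, reorienting to canonical (LPS) orientation."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise MissingFileError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as e:  # noqa: BLE001 - SimpleITK raises RuntimeError
        raise UnreadableHeaderError(f"cannot read image header of {path}: {e}") from e
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise NotA3DImageError(
            f"expected 3D scalar volume, got {img.GetDimension()}D with "
            f"{img.GetNumberOfComponentsPerPixel()} component(s) in {path}")
    img = sitk.DICOMOrient(img, "LPS")
    voxels, spacing, origin = _from_sitk(img)
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin, normalized=False)


def read_mask(path: str | os.PathLike) -> SegMask:
    vol = read_volume(path)
    return SegMask(voxels=(vol.voxels > 0.5).astype(np.uint8),
                   spacing=vol.spacing, origin=vol.origin)


def write_volume(vol: CTVolume | SegMask, path: str | os.PathLike):
    img = _to_sitk(np.asarray(vol.voxels, dtype=np.float32), vol.spacing, vol.origin)
    sitk.WriteImage(img, os.fspath(path))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def truncate_hu(vol: CTVolume, lo: float = DEFAULT_CLIP_LO, hi: float = DEFAULT_CLIP_HI) -> CTVolume:
    """Clip HU values into [lo, hi] (default [-1024, 3068])."""
    if lo >= hi:
        raise ValueError(f"truncate_hu: lo ({lo}) must be < hi ({hi})")
    if vol.normalized:
        raise ValueError("truncate_hu expects an unnormalized (HU) volume")
    return replace(vol, voxels=np.clip(vol.voxels, lo, hi))


def minmax_normalize(vol: CTVolume, lo: float = DEFAULT_CLIP_LO, hi: float = DEFAULT_CLIP_HI) -> CTVolume:
    """Map [lo, hi] linearly onto [0, 1] using the fixed clip window.

    The window is fixed (not the per-volume min/max) so a given HU value maps
    to the same normalized intensity in every scan.
    """
    if vol.normalized:
        raise ValueError("volume is already normalized")
    v = (vol.voxels - lo) / (hi - lo)
    if v.min() < -1e-6 or v.max() > 1 + 1e-6:
        raise ValueError("minmax_normalize expects a volume already truncated to [lo, hi]")
    return replace(vol, voxels=np.clip(v, 0.0, 1.0), normalized=True)


def preprocess(vol: CTVolume, lo: float = DEFAULT_CLIP_LO, hi: float = DEFAULT_CLIP_HI) -> CTVolume:
    """Truncate + min-max normalize."""
    return minmax_normalize(truncate_hu(vol, lo, hi), lo, hi)


_SITK_INTERP = {
    "windowed-sinc": sitk.sitkHammingWindowedSinc,
    "linear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
}


def resample_uniform(vol: CTVolume | SegMask,
                     target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     method: str = "windowed-sinc"):
    """Resample to uniform spacing; output dims = round(dim * in_sp / out_sp).

    Images default to windowed-sinc interpolation; masks must use ``nearest``
    (which preserves binarity exactly).
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if method not in _SITK_INTERP:
        raise ValueError(f"unknown interpolation {method!r}; choose from {sorted(_SITK_INTERP)}")
    is_mask = isinstance(vol, SegMask)
    if is_mask and method != "nearest":
        raise ValueError("masks must be resampled with method='nearest'")
    in_shape = vol.voxels.shape
    in_sp = vol.spacing
    out_shape = tuple(max(1, int(round(n * s / t)))
                      for n, s, t in zip(in_shape, in_sp, target_spacing))
    if out_shape == in_shape and tuple(in_sp) == tuple(target_spacing):
        return replace(vol, voxels=vol.voxels.copy())
    img = _to_sitk(np.asarray(vol.voxels, dtype=np.float32), in_sp, vol.origin)
    res = sitk.ResampleImageFilter()
    res.SetInterpolator(_SITK_INTERP[method])
    res.SetOutputSpacing((float(target_spacing[1]), float(target_spacing[0]), float(target_spacing[2])))
    res.SetSize((int(out_shape[1]), int(out_shape[0]), int(out_shape[2])))  # sitk (x, y, z)
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetDefaultPixelValue(float(np.asarray(vol.voxels).min()))
    out = res.Execute(img)
    voxels, spacing, origin = _from_sitk(out)
    if is_mask:
        return SegMask(voxels=(voxels > 0.5).astype(np.uint8), spacing=spacing, origin=origin)
    if vol.normalized:
        voxels = np.clip(voxels, 0.0, 1.0)  # sinc ringing can leave [0,1]
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin, normalized=vol.normalized)


def _pad_to_size(arr: np.ndarray, size: int, value: float):
    """Symmetric padding so every axis is at least ``size`` long."""
    pads = []
    for n in arr.shape:
        short = max(size - n, 0)
        pads.append((short // 2, short - short // 2))
    if not any(p != (0, 0) for p in pads):
        return arr, False
    return np.pad(arr, pads, constant_values=value), True


def crop_random_patches(vol: CTVolume, mask: SegMask, size: int = DEFAULT_PATCH_SIZE,
                        n: int = DEFAULT_PATCHES_PER_VOLUME, fg_fraction: float = 0.5,
                        rng: np.random.Generator | None = None,
                        volume_id: str = "") -> list[Patch]:
    """Randomly crop ``n`` aligned image/mask patches of shape size^3.

    With probability ``fg_fraction`` the patch is centered on a randomly
    chosen foreground (tumor) voxel; otherwise the corner is uniform.  Volumes
    smaller than the patch are first zero-padded symmetrically (zero = air
    after normalization).  Deterministic for a fixed ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if vol.voxels.size == 0:
        raise ValueError("empty volume")
    if vol.voxels.shape != mask.voxels.shape:
        raise ValueError(f"volume/mask shape mismatch: {vol.voxels.shape} vs {mask.voxels.shape}")
    img, padded = _pad_to_size(vol.voxels, size, 0.0)
    msk, _ = _pad_to_size(mask.voxels, size, 0)
    dims = img.shape
    fg = np.argwhere(msk > 0)
    patches = []
    for _ in range(int(n)):
        if fg.size and rng.random() < fg_fraction:
            center = fg[rng.integers(len(fg))]
            corner = [int(np.clip(c - size // 2, 0, d - size)) for c, d in zip(center, dims)]
        else:
            corner = [int(rng.integers(0, d - size + 1)) for d in dims]
        sl = tuple(slice(c, c + size) for c in corner)
        patches.append(Patch(image=img[sl].copy(), mask=msk[sl].copy(),
                             volume_id=volume_id, corner=tuple(corner), padded=padded))
    return patches
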