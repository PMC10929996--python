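"""Synthetic lung-CT phantoms with ground-truth ellipsoidal tumors.

Each phantom is an HU-valued volume containing a soft-tissue body ellipsoid
(~40 HU) on an air background (-1000 HU), two low-density lung regions
(~-800 HU), and 1-3 tumor ellipsoids of soft-tissue density placed fully
inside a lung, plus optional additive Gaussian noise.  The mask is the exact
geometric union of the tumor ellipsoids, so its volume has a closed form
(4/3 pi abc) usable as an oracle, and it is untouched by the noise field.

The generator is the test-data source for the whole package: tumor radii
span the sub-1 cc to >50 cc range seen in clinical NSCLC cohorts, and voxel
spacing can be anisotropic (slice thickness coarser than in-plane).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, SegMask, write_volume

HU_AIR = -1000.0
HU_LUNG = -800.0
HU_BODY = 40.0


class PhantomFitError(ValueError):
    """Raised when the requested tumors cannot fit inside the lung regions."""


@dataclass
class PhantomSpec:
    dims: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (1.5, 1.5, 2.5)
    n_tumors: int = 1
    tumor_radii_mm: tuple[float, float] = (5.0, 15.0)
    tumor_hu: tuple[float, float] = (0.0, 100.0)
    background_hu: float = HU_LUNG
    body_hu: float = HU_BODY
    noise_sd: float = 20.0
    seed: int = 0
    rotated: bool = False  # random tumor orientation; axis-aligned keeps the analytic oracle
    anisotropy: float = 1.0  # max ratio between tumor semi-axes

    def __post_init__(self):
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        if self.tumor_radii_mm[0] <= 0:
            raise ValueError("tumor radii must be strictly positive")
        if any(d < 1 for d in self.dims) or any(s <= 0 for s in self.spacing):
            raise ValueError("invalid dims/spacing")


def _ellipsoid_mask(dims, spacing, center_mm, semi_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(dims, spacing)],
                        indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, semi_mm))
    return q <= 1.0


def _lung_geometry(extent):
    """Body and lung ellipsoids (center, semi-axes) in mm for a given physical extent."""
    ex = np.asarray(extent, dtype=float)
    c = ex / 2.0
    body = (c, ex * np.array([0.46, 0.42, 0.48]))
    lungs = []
    for side in (-1.0, 1.0):
        center = c + side * np.array([0.22 * ex[0], 0.0, 0.0])
        semi = ex * np.array([0.18, 0.30, 0.42])
        lungs.append((center, semi))
    return body, lungs


def max_tumor_radius(dims, spacing) -> float:
    """Largest spherical tumor radius (mm) that can fit inside a lung region
    of a phantom with the given grid, including the placement margin."""
    extent = [n * s for n, s in zip(dims, spacing)]
    _, lungs = _lung_geometry(extent)
    margin = float(max(spacing))
    return max(min(semi.min() for _, semi in lungs) - margin, 0.0)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, SegMask]:
    """Build one phantom volume + tumor mask, deterministic per ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    dims, spacing = spec.dims, spec.spacing
    extent = [n * s for n, s in zip(dims, spacing)]
    body, lungs = _lung_geometry(extent)

    hu = np.full(dims, HU_AIR, dtype=np.float32)
    hu[_ellipsoid_mask(dims, spacing, *body)] = spec.body_hu
    lung_union = np.zeros(dims, dtype=bool)
    for center, semi in lungs:
        lm = _ellipsoid_mask(dims, spacing, center, semi)
        hu[lm] = spec.background_hu
        lung_union |= lm

    mask = np.zeros(dims, dtype=np.uint8)
    placed: list[tuple[np.ndarray, float]] = []  # (center_mm, bounding radius)
    margin = float(max(spacing))
    # one-voxel 26-connected halo keeps tumors as distinct 6-connected components
    halo = np.ones((3, 3, 3), dtype=bool)
    for _ in range(spec.n_tumors):
        tm = None
        for _attempt in range(500):
            r = rng.uniform(*spec.tumor_radii_mm)
            if spec.anisotropy > 1.0:
                semi = r * rng.uniform(1.0, spec.anisotropy, size=3)
                semi *= r / semi.max()
            else:
                semi = np.full(3, r)
            rmax = float(semi.max())
            lc, ls = lungs[rng.integers(2)]
            shrunk = ls - (rmax + margin)  # per-axis proposal region
            if shrunk.min() <= 0:
                continue
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            center = lc + (u * rng.uniform() ** (1 / 3)) * shrunk
            if any(np.linalg.norm(center - pc) <= rmax + pr + 2 * margin
                   for pc, pr in placed):
                continue
            cand = _ellipsoid_mask(dims, spacing, center, semi)
            if not cand.any() or np.any(cand & ~lung_union):
                continue  # not fully inside the lung on the voxel grid
            if mask.any() and np.any(ndimage.binary_dilation(cand, halo) & (mask > 0)):
                continue
            tm = cand
            break
        if tm is None:
            raise PhantomFitError(
                f"cannot place {spec.n_tumors} tumors of radius {spec.tumor_radii_mm} mm "
                f"inside lungs of a {extent} mm phantom")
        hu[tm] = rng.uniform(*spec.tumor_hu)
        mask |= tm.astype(np.uint8)
        placed.append((center, float(np.max(semi))))

    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, size=dims).astype(np.float32)

    vol = CTVolume(voxels=hu, spacing=spacing, normalized=False)
    seg = SegMask(voxels=mask, spacing=spacing)
    return vol, seg


def phantom_dataset(n_cases: int, spec_ranges: dict | None = None,
                    seed: int = 0) -> list[tuple[CTVolume, SegMask, PhantomSpec]]:
    """Draw ``n_cases`` phantoms with per-case specs sampled from ranges.

    ``spec_ranges`` may override: ``dims``, ``spacing_choices`` (list of
    spacing triples), ``radius_mm`` (lo, hi), ``n_tumors_choices``,
    ``noise_sd``, ``tumor_hu``.  Cases alternate deterministically between
    single- and multiple-tumor so both evaluation strata are present.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    ranges = dict(spec_ranges or {})
    dims = tuple(ranges.get("dims", (96, 96, 64)))
    spacing_choices = ranges.get("spacing_choices",
                                 [(1.5, 1.5, 1.5), (1.5, 1.5, 2.5), (1.0, 1.0, 3.0)])
    r_lo, r_hi = ranges.get("radius_mm", (4.0, 18.0))
    n_tumors_choices = list(ranges.get("n_tumors_choices", (1, 2, 3)))
    noise_sd = float(ranges.get("noise_sd", 20.0))
    tumor_hu = tuple(ranges.get("tumor_hu", (0.0, 100.0)))

    rng = np.random.default_rng(seed)
    multi_choices = [n for n in n_tumors_choices if n > 1] or [1]
    strata = [1 if (i % 2 == 0 or len(n_tumors_choices) == 1) and 1 in n_tumors_choices
              else int(rng.choice(multi_choices)) for i in range(n_cases)]
    n_single = max(sum(1 for n in strata if n == 1), 1)
    out = []
    single_rank = 0
    for i, n_tum in enumerate(strata):
        spacing = tuple(spacing_choices[int(rng.integers(len(spacing_choices)))])
        # cap by what physically fits inside the lung regions
        cap = 0.9 * max_tumor_radius(dims, spacing)
        hi_eff = min(r_hi, cap)
        lo_eff = min(r_lo, hi_eff)
        if n_tum == 1:
            # single-tumor cases sweep the radius range end to end, so the
            # dataset spans the full sub-cc to tens-of-cc tumor-volume range
            frac = single_rank / max(n_single - 1, 1)
            single_rank += 1
            mid = lo_eff + (hi_eff - lo_eff) * frac
            lo = max(lo_eff, mid * 0.9)
            hi = min(hi_eff, max(mid * 1.1, lo + 1e-6))
        else:
            # several tumors must pack without touching: stay in the lower range
            hi = lo_eff + 0.4 * (hi_eff - lo_eff)
            lo = lo_eff
        spec = PhantomSpec(
            dims=dims,
            spacing=spacing,
            n_tumors=n_tum,
            tumor_radii_mm=(lo, hi),
            tumor_hu=tumor_hu,
            noise_sd=noise_sd,
            seed=int(rng.integers(2 ** 31 - 1)),
        )
        vol, seg = generate_phantom(spec)
        out.append((vol, seg, spec))
    return out


def write_phantom_dataset(cases, out_dir: str | os.PathLike) -> str:
    """Write paired NIfTI files and a JSON manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    for i, (vol, seg, spec) in enumerate(cases):
        cid = f"case_{i:03d}"
        img_path = os.path.join(out_dir, f"{cid}_ct.nii.gz")
        msk_path = os.path.join(out_dir, f"{cid}_gtv.nii.gz")
        write_volume(vol, img_path)
        write_volume(seg, msk_path)
        voxel_cc = float(np.prod(spec.spacing)) / 1000.0
        manifest.append({
            "case_id": cid,
            "image": os.path.basename(img_path),
            "mask": os.path.basename(msk_path),
            "seed": spec.seed,
            "n_tumors": spec.n_tumors,
            "tumor_volume_cc": float(seg.voxels.sum()) * voxel_cc,
            "spacing_mm": list(spec.spacing),
            "spec": dataclasses.asdict(spec),
        })
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
    return path
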