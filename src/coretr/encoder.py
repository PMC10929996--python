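"""Dual-resolution CNN encoder with multi-scale feature pyramid fusion.

Two convolutional backbones share one design: a stem of Conv-IN-ReLU layers
(a 1x1x1 filter then 3x3x3 filters raising the channel count), followed by
residual stages that downsample by strided convolution while doubling
channels.  The *shallow* branch runs on the 2x-upsampled patch to preserve
positional detail; the *deep* branch runs on the 2x-downsampled patch with
more residual blocks to extract semantic context.

The multi-scale feature pyramid (Ms-FPN) projects every map to a common
channel width with 1x1x1 convolutions and fuses additively: within each
branch from coarse to fine (top-down), and across branches from the deep
(low-resolution) branch into the shallow one, each term trilinearly
upsampled by 2 where resolutions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import BackboneConfig, ModelConfig
from .nn import Conv3d, InstanceNorm, Module


@dataclass
class FeatureMap:
    """A (C, H, W, D) feature grid tagged with backbone level and scale."""

    tensor: Tensor
    level: int  # 0 = shallow (high-res) branch, 1 = deep (low-res) branch
    scale: int  # stage index within the branch, 0 = finest
    stride: float  # voxels per feature cell relative to the network input patch

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("feature map needs >= 1 channel")
        s = self.stride
        while s < 1:
            s *= 2
        if abs(np.log2(s) - round(np.log2(s))) > 1e-9:
            raise ValueError(f"stride must be a power of 2 (or 1/2), got {self.stride}")

    @property
    def channels(self) -> int:
        return self.tensor.data.shape[0]

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.tensor.data.shape[1:])


@dataclass
class FeaturePyramid:
    maps: list[FeatureMap] = field(default_factory=list)
    fused: bool = False

    def __post_init__(self):
        keys = [(m.level, m.scale) for m in self.maps]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (level, scale) in pyramid")
        if self.fused and len({m.channels for m in self.maps}) > 1:
            raise ValueError("fused pyramid must have a uniform channel count")

    def level_maps(self, level: int) -> list[FeatureMap]:
        return sorted((m for m in self.maps if m.level == level), key=lambda m: m.scale)


class ConvINReLU(Module):
    """Convolution -> instance normalization -> ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1, *,
                 rng: np.random.Generator):
        self.conv = Conv3d(in_ch, out_ch, kernel, stride, rng=rng)
        self.norm = InstanceNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(self.norm(self.conv(x)))


class ResidualBlock(Module):
    """Conv-IN-ReLU -> Conv-IN plus an identity shortcut (1x1x1 projection
    when the channel count or resolution changes), then ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 5, stride: int = 1, *,
                 rng: np.random.Generator):
        self.unit = ConvINReLU(in_ch, out_ch, kernel, stride, rng=rng)
        self.conv2 = Conv3d(out_ch, out_ch, kernel, 1, rng=rng)
        self.norm2 = InstanceNorm(out_ch)
        if in_ch != out_ch or stride != 1:
            self.shortcut = Conv3d(in_ch, out_ch, 1, stride, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm2(self.conv2(self.unit(x)))
        s = self.shortcut(x) if self.shortcut is not None else x
        return ad.relu(y + s)


class Stem(Module):
    """Conv-IN-ReLU stack raising a 1-channel image to ``base_channels``:
    a 3^3 layer, a 1^3 layer, then 3^3 layers up to ``n_blocks`` total."""

    def __init__(self, base_channels: int, n_blocks: int = 5, *, rng: np.random.Generator):
        if n_blocks < 3:
            raise ValueError("stem needs at least 3 Conv-IN-ReLU blocks")
        kernels = [3, 1] + [3] * (n_blocks - 2)
        chans = [1] + [base_channels] * n_blocks
        self.blocks = [ConvINReLU(chans[i], chans[i + 1], kernels[i], rng=rng)
                       for i in range(n_blocks)]

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class Backbone(Module):
    """Stem + residual stages; emits one feature map per stage."""

    def __init__(self, cfg: BackboneConfig, level: int, *, rng: np.random.Generator):
        self.level = level
        self.stem = Stem(cfg.base_channels, cfg.shallow_conv_blocks, rng=rng)
        if level == 0:
            strides = [1] + [2] * (cfg.shallow_res_stages - 1)
            blocks_per_scale = [1] * cfg.shallow_res_stages
        else:
            strides = cfg.deep_stage_strides()
            blocks_per_scale = cfg.deep_blocks_per_scale()
        self.stage_strides = strides
        self.stages: list[list[ResidualBlock]] = []
        in_ch = cfg.base_channels
        self._out_channels = []
        for j, (stride, n_blocks) in enumerate(zip(strides, blocks_per_scale)):
            out_ch = cfg.stage_channels(sum(1 for s in strides[:j + 1] if s == 2))
            stage = [ResidualBlock(in_ch, out_ch, cfg.res_kernel, stride, rng=rng)]
            for _ in range(n_blocks - 1):
                stage.append(ResidualBlock(out_ch, out_ch, cfg.res_kernel, 1, rng=rng))
            self.stages.append(stage)
            self._out_channels.append(out_ch)
            in_ch = out_ch

    @property
    def out_channels(self) -> list[int]:
        return list(self._out_channels)

    def forward(self, image: Tensor, input_stride: float) -> list[FeatureMap]:
        """``input_stride``: resolution of ``image`` relative to the patch
        (0.5 for the upsampled shallow input, 2 for the pooled deep input)."""
        if min(image.data.shape[1:]) < 2 ** sum(1 for s in self.stage_strides if s == 2):
            raise ValueError(f"input {image.data.shape[1:]} too small for this backbone depth")
        x = self.stem(image)
        maps = []
        stride = input_stride
        for j, stage in enumerate(self.stages):
            stride *= self.stage_strides[j]
            for block in stage:
                x = block(x)
            maps.append(FeatureMap(tensor=x, level=self.level, scale=j, stride=stride))
        return maps


def _upsample(x: Tensor, gain: float) -> Tensor:
    y = ad.upsample2_trilinear(x)
    return ad.mul(y, gain) if gain != 1.0 else y


class MsFPN(Module):
    """Multi-scale feature pyramid fusion over both backbones' maps."""

    def __init__(self, shallow_channels: list[int], deep_channels: list[int],
                 fpn_channels: int, upsample_gain: float = 1.0, *, rng: np.random.Generator):
        self.lateral = {
            0: [Conv3d(c, fpn_channels, 1, rng=rng) for c in shallow_channels],
            1: [Conv3d(c, fpn_channels, 1, rng=rng) for c in deep_channels],
        }
        self.gain = upsample_gain

    def _fuse_branch(self, maps: list[FeatureMap], cross: dict | None) -> list[FeatureMap]:
        """Top-down additive fusion within one branch; ``cross`` maps spatial
        dims to an already-fused map from the other (coarser) branch."""
        fused: list[FeatureMap] = [None] * len(maps)
        prev: FeatureMap | None = None
        for m in sorted(maps, key=lambda m: -m.scale):  # coarsest first
            t = self.lateral[m.level][m.scale](m.tensor)
            if prev is not None:
                if prev.dims == tuple(d // 2 for d in m.dims):
                    t = t + _upsample(prev.tensor, self.gain)
                elif prev.dims == m.dims:
                    t = t + prev.tensor
            if cross:
                half = tuple(d // 2 for d in m.dims)
                other = cross.get(half)
                if other is not None:
                    t = t + _upsample(other.tensor, self.gain)
            prev = FeatureMap(tensor=t, level=m.level, scale=m.scale, stride=m.stride)
            fused[m.scale] = prev
        return fused

    def forward(self, shallow: list[FeatureMap], deep: list[FeatureMap]) -> FeaturePyramid:
        if not shallow and not deep:
            raise ValueError("empty pyramid")
        deep_fused = self._fuse_branch(deep, None) if deep else []
        by_dims: dict[tuple, FeatureMap] = {}
        for m in sorted(deep_fused, key=lambda m: -m.scale):
            by_dims[m.dims] = m  # finer scales overwrite equal-dims coarser ones
        shallow_fused = self._fuse_branch(shallow, by_dims) if shallow else []
        return FeaturePyramid(maps=shallow_fused + deep_fused, fused=True)


class CoReTrEncoder(Module):
    """Multi-resolution branch preparation + both backbones + Ms-FPN."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        self.cfg = cfg
        self.shallow = Backbone(cfg.backbone, level=0, rng=rng)
        self.deep = Backbone(cfg.backbone, level=1, rng=rng)
        self.fpn = MsFPN(self.shallow.out_channels, self.deep.out_channels,
                         cfg.fpn_channels, cfg.fpn_upsample_gain, rng=rng)

    def forward(self, patch: Tensor) -> FeaturePyramid:
        """``patch``: (1, H, W, D) normalized image at native resolution."""
        if self.cfg.multi_resolution_input:
            hi = ad.upsample2_trilinear(patch)
            lo = ad.avg_pool2(patch)
            hi_stride, lo_stride = 0.5, 2.0
        else:
            hi = lo = patch
            hi_stride = lo_stride = 1.0
        smaps = self.shallow(hi, hi_stride)
        dmaps = self.deep(lo, lo_stride)
        return self.fpn(smaps, dmaps)
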