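"""Decoder and full network assembly.

The decoder reshapes transformer tokens back into 3D feature grids, then
progressively upsamples with kernel-2/stride-2 transpose convolutions,
merging the encoder's fused skip maps at every scale (channel concatenation
followed by a 1x1x1 projection) and refining with a residual block, until the
native patch resolution is reached; a 1x1x1 convolution produces voxel-wise
logits.  When the multi-resolution input is enabled, the shallow branch's
finer-than-native map is average-pooled by 2 and merged as an extra skip at
the final (native-resolution) stage, so the output always lives at the
patch's own resolution.

``CoReTr`` wires the three components together: encoder -> Ms-FPN ->
(optional) deformable transformer -> decoder, with configuration switches to
bypass the transformer or feed both backbones the native-resolution patch
(the two ablation arms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import ModelConfig
from .encoder import ConvINReLU, CoReTrEncoder, FeatureMap, FeaturePyramid, ResidualBlock
from .nn import Conv3d, ConvTranspose3d2x, Module
from .transformer import DeformableTransformer, TokenSequence, flatten_with_pos


@dataclass
class LogitVolume:
    """Single-channel voxel-wise scores at network-input resolution."""

    grid: Tensor  # (H, W, D)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.grid.data.shape)


def reshape_to_volume(seq: TokenSequence, level_index: int = 0) -> FeatureMap:
    """Invert the flatten raster order for one scale of a token sequence."""
    info = seq.levels[level_index]
    n = info.stop - info.start
    h, w, d = info.dims
    if n != h * w * d:
        raise ValueError(f"token count {n} does not match dims {info.dims}")
    rows = seq.tokens[info.start:info.stop, :]
    C = rows.data.shape[1]
    grid = ad.reshape(ad.transpose(rows), (C, h, w, d))
    return FeatureMap(tensor=grid, level=info.level, scale=info.scale, stride=info.stride)


class UpsampleBlock(Module):
    """Transpose-conv x2 -> concatenate skip(s) -> 1x1x1 projection ->
    residual refinement."""

    def __init__(self, channels: int, n_skips: int = 1, kernel: int = 3, *,
                 rng: np.random.Generator):
        self.up = ConvTranspose3d2x(channels, channels, rng=rng)
        self.proj = ConvINReLU(channels * (1 + n_skips), channels, 1, rng=rng)
        self.refine = ResidualBlock(channels, channels, kernel, 1, rng=rng)

    def forward(self, x: Tensor, skips: list[Tensor]) -> Tensor:
        y = self.up(x)
        for s in skips:
            if s.data.shape[1:] != y.data.shape[1:]:
                raise ValueError(
                    f"skip resolution {s.data.shape[1:]} does not match upsampled {y.data.shape[1:]}")
        y = self.proj(ad.concat([y] + skips, axis=0))
        return self.refine(y)


class SegmentationHead(Module):
    def __init__(self, channels: int, *, rng: np.random.Generator):
        self.conv = Conv3d(channels, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> LogitVolume:
        logits = self.conv(x)
        return LogitVolume(grid=ad.reshape(logits, logits.data.shape[1:]))


class Decoder(Module):
    """Decode a fused pyramid (tokens already folded back in) to logits."""

    def __init__(self, cfg: ModelConfig, *, rng: np.random.Generator):
        self.cfg = cfg
        C = cfg.fpn_channels
        n_scales = cfg.backbone.shallow_res_stages
        # shallow strides relative to the patch: 0.5,1,2,... (multi-res) or 1,2,4,...
        finest = 0.5 if cfg.multi_resolution_input else 1.0
        self.strides = [finest * 2 ** j for j in range(n_scales)]
        up_path = [s for s in self.strides if s >= 1.0]  # native and coarser
        self.blocks = []
        for step, stride in enumerate(sorted(up_path)[:-1]):  # target strides, fine last
            extra = 1 if (stride == 1.0 and cfg.multi_resolution_input) else 0
            self.blocks.append(UpsampleBlock(C, n_skips=1 + extra,
                                             kernel=cfg.decoder_kernel, rng=rng))
        self.blocks = self.blocks[::-1]  # coarse-to-fine application order
        self.head = SegmentationHead(C, rng=rng)

    def forward(self, pyramid: FeaturePyramid) -> LogitVolume:
        smaps = {m.stride: m for m in pyramid.level_maps(0)}
        path = sorted(s for s in smaps if s >= 1.0)[::-1]  # coarse -> fine, ends at 1.0
        x = smaps[path[0]].tensor
        for block, target in zip(self.blocks, path[1:]):
            skips = [smaps[target].tensor]
            if target == 1.0 and 0.5 in smaps:
                skips.append(ad.avg_pool2(smaps[0.5].tensor))
            x = block(x, skips)
        return self.head(x)


class CoReTr(Module):
    """Encoder + deformable transformer + decoder for binary GTV segmentation.

    Logits are returned at the patch's native resolution; the sigmoid is
    applied outside the network (by the loss and by inference thresholding).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.encoder = CoReTrEncoder(cfg, rng=rng)
        if cfg.use_transformer:
            self.transformer = DeformableTransformer(
                cfg.fpn_channels, cfg.transformer, n_levels=cfg.token_scales, rng=rng)
        else:
            self.transformer = None
        self.decoder = Decoder(cfg, rng=rng)

    def forward(self, patch) -> LogitVolume:
        """``patch``: (H, W, D) normalized image (numpy array or Tensor)."""
        if isinstance(patch, Tensor):
            x = ad.reshape(patch, (1,) + patch.data.shape) if patch.ndim == 3 else patch
        else:
            arr = np.asarray(patch, dtype=np.float32)
            if arr.ndim != 3:
                raise ValueError(f"expected a 3D patch, got {arr.ndim}D")
            x = Tensor(arr[None])
        dims = x.data.shape[1:]
        div = self.cfg.total_stride()
        if any(d % div for d in dims):
            raise ValueError(f"patch dims {dims} must be divisible by {div}")
        pyramid = self.encoder(x)
        if self.transformer is not None:
            seq = flatten_with_pos(pyramid, self.cfg.token_scales)
            seq = self.transformer(seq)
            folded = {(info.level, info.scale): reshape_to_volume(seq, i)
                      for i, info in enumerate(seq.levels)}
            maps = [folded.get((m.level, m.scale), m) for m in pyramid.maps]
            pyramid = FeaturePyramid(maps=maps, fused=True)
        return self.decoder(pyramid)


def coretr_forward(patch, cfg: ModelConfig, model: CoReTr | None = None,
                   rng: np.random.Generator | int = 0) -> LogitVolume:
    """Functional wrapper: run the full pipeline on one patch."""
    if model is None:
        model = CoReTr(cfg, rng)
    return model(patch)
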