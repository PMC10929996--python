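"""Architecture and training hyperparameter containers."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class BackboneConfig:
    """Dual-branch CNN encoder hyperparameters.

    The shallow branch sees the 2x-upsampled (high-resolution) patch through
    ``shallow_conv_blocks`` Conv-IN-ReLU layers and ``shallow_res_stages``
    residual stages; the deep branch sees the 2x-downsampled patch through the
    same stem and ``deep_res_stages`` residual blocks grouped over the same
    number of resolution scales.  Channels double at each downsampling stage,
    capped at ``channel_cap``.
    """

    base_channels: int = 32
    channel_cap: int = 320
    shallow_conv_blocks: int = 5
    shallow_res_stages: int = 6
    deep_res_stages: int = 9
    res_kernel: int = 5

    def __post_init__(self):
        if self.res_kernel % 2 == 0:
            raise ValueError("res_kernel must be odd")
        if self.shallow_res_stages < 2 or self.deep_res_stages < self.shallow_res_stages:
            raise ValueError("need >=2 shallow stages and deep_res_stages >= shallow_res_stages")

    def stage_channels(self, j: int) -> int:
        return min(self.base_channels * 2 ** j, self.channel_cap)

    def deep_blocks_per_scale(self) -> list[int]:
        """Distribute the deep branch's residual blocks over the shallow
        branch's number of scales (9 over 6 -> 2-2-2-1-1-1)."""
        s = self.shallow_res_stages
        base, rem = divmod(self.deep_res_stages, s)
        return [base + (1 if i < rem else 0) for i in range(s)]

    def deep_stage_strides(self) -> list[int]:
        """Per-scale entry stride of the deep branch: 1,2,2,...,2,1.

        The deep branch already starts from a 2x-downsampled input, so its
        last stage does not downsample again; this keeps the coarsest deep
        map at a usable spatial extent (>= 3^3 for a 96^3 patch).
        """
        s = self.shallow_res_stages
        return [1] + [2] * (s - 2) + [1]


@dataclass
class DeTransConfig:
    """Deformable-transformer stack hyperparameters."""

    n_layers: int = 4
    n_heads: int = 6
    n_sampling_points: int = 4
    ffn_mult: int = 4
    dropout: float = 0.0  # retained for config compatibility; 0 = unused

    def __post_init__(self):
        if self.n_layers < 1 or self.n_sampling_points < 1 or self.n_heads < 1:
            raise ValueError("n_layers, n_heads and n_sampling_points must be >= 1")


@dataclass
class ModelConfig:
    patch_size: int = 96
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fpn_channels: int = 48
    token_scales: int = 3  # how many of the coarsest pyramid scales feed the transformer
    transformer: DeTransConfig = field(default_factory=DeTransConfig)
    use_transformer: bool = True
    multi_resolution_input: bool = True
    # reading of the "2x Upsample" notation: trilinear upsampling, optionally
    # also multiplying values by 2 (gain=2.0) for the literal-scalar reading
    fpn_upsample_gain: float = 1.0
    decoder_kernel: int = 3

    def __post_init__(self):
        if self.fpn_channels % self.transformer.n_heads:
            raise ValueError("fpn_channels must be divisible by n_heads")
        div = self.total_stride()
        if self.patch_size % div:
            raise ValueError(f"patch_size must be divisible by {div}")

    def total_stride(self) -> int:
        return 2 ** (self.backbone.shallow_res_stages - 1)

    @classmethod
    def tiny(cls, patch_size: int = 16, base_channels: int = 8, n_layers: int = 2,
             **overrides) -> "ModelConfig":
        """A desk-scale configuration used by the test suite and examples."""
        kw = dict(
            patch_size=patch_size,
            backbone=BackboneConfig(base_channels=base_channels, channel_cap=64,
                                    shallow_conv_blocks=3, shallow_res_stages=4,
                                    deep_res_stages=6, res_kernel=3),
            fpn_channels=12,
            token_scales=2,
            transformer=DeTransConfig(n_layers=n_layers, n_heads=3, n_sampling_points=4,
                                      ffn_mult=2),
        )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if isinstance(d.get("backbone"), dict):
            d["backbone"] = BackboneConfig(**d["backbone"])
        if isinstance(d.get("transformer"), dict):
            d["transformer"] = DeTransConfig(**d["transformer"])
        return cls(**d)


@dataclass
class TrainConfig:
    optimizer: str = "sgd"
    initial_lr: float = 1e-3
    momentum: float = 0.99
    nesterov: bool = True
    weight_decay: float = 3e-5
    clip_norm: float = 12.0
    batch_size: int = 1
    epochs: int = 1000
    patches_per_volume: int = 4
    fg_fraction: float = 0.5
    loss: str = "dice_bce"
    lr_schedule: str = "poly"
    lr_power: float = 0.9
    val_fraction: float = 0.1
    val_interval: int = 10
    augment: bool = True
    seed: int = 0
    # optional early stop: end training once the mean training-set Dice
    # (checked every val_interval epochs by sliding-window inference) reaches this
    train_dice_stop: float | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 0 or self.initial_lr <= 0:
            raise ValueError("invalid training configuration")
        if self.optimizer != "sgd":
            raise ValueError("only SGD is supported")
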