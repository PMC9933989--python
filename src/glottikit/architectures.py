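"""Model builders: dual-task U-Nets for glottis segmentation + midline keypoints.

All models share a 4-level U-Net encoder with a latent bottleneck.  The 2-D
variants differ in *where* the segmentation task and the anterior/posterior
keypoint task separate on the decoding path:

=========  ====================================================================
variant    split point
=========  ====================================================================
v2a        shared decoder; only the final 1x1 output convolutions differ
v2b        shared decoder up to the last decoding step; split before its
           second convolution
v2c        shared decoder; three 1x1 heads (segmentation, AP map, PP map)
v2d        the whole last decoder step (upsampling + convolutions) is
           duplicated per task
v2e        two complete decoders, both originating in the latent bottleneck
           and both receiving skip connections from the shared encoder
v1_regression  segmentation decoder plus direct point regression from the
           bottleneck via global average pooling and a dense layer (baseline)
=========  ====================================================================

Temporal variants extend the dual-decoder topology to clips: ``channels``
stacks frames in the input channel dimension (predicting the center frame),
``conv3d`` replaces 2-D with 3-D convolutions (per-frame outputs), and
``convlstm`` replaces each double convolution by a single ConvLSTM2D layer,
with the final decoder step using 3-D convolutions (per-frame outputs).

Segmentation and keypoint heads end in a sigmoid, matching {0,1} mask and
binary-disk targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn


__all__ = [
    "ModelConfig",
    "ConfigurationError",
    "build_model",
    "build_temporal_model",
    "count_parameters",
    "save_model",
    "load_model",
    "VARIANTS",
    "TEMPORAL_MODES",
]

VARIANTS = ("v2a", "v2b", "v2c", "v2d", "v2e", "v1_regression")
TEMPORAL_MODES = ("none", "channels", "conv3d", "convlstm")
ALLOWED_FILTERS = (8, 16, 32, 64)
DEPTH = 4  # fixed U-Net depth for every member of the family


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "v2e"
    temporal_mode: str = "none"
    base_filters: int = 16
    normalization: str = "instance"
    n_frames: int = 1
    input_size: tuple[int, int] = (512, 256)
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.temporal_mode not in TEMPORAL_MODES:
            raise ConfigurationError(
                f"unknown temporal_mode {self.temporal_mode!r}; "
                f"choose from {TEMPORAL_MODES}")
        if self.base_filters not in ALLOWED_FILTERS:
            raise ConfigurationError(
                f"base_filters must be one of {ALLOWED_FILTERS}, "
                f"got {self.base_filters}")
        if self.normalization not in ("batch", "instance"):
            raise ConfigurationError(
                f"normalization must be 'batch' or 'instance', "
                f"got {self.normalization!r}")
        if self.temporal_mode != "none" and self.n_frames < 2:
            raise ConfigurationError(
                "temporal modes require n_frames >= 2")
        h, w = self.input_size
        factor = 2 ** DEPTH
        if h % factor or w % factor or h < factor or w < factor:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by "
                f"{factor} in both dimensions (minimum {factor}x{factor}) "
                f"for {DEPTH} pooling levels")
        if self.temporal_mode in ("conv3d", "convlstm") and \
                self.variant != "v2e":
            raise ConfigurationError(
                f"temporal_mode {self.temporal_mode!r} is built on the "
                "dual-decoder topology; set variant='v2e'")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "ModelConfig":
        d = json.loads(text)
        d["input_size"] = tuple(d["input_size"])
        return ModelConfig(**d)


# ---------------------------------------------------------------------------
# 2-D building blocks
# ---------------------------------------------------------------------------


class DoubleConv(nn.Module):
    """(conv 3x3 -> norm -> ReLU) x 2."""

    def __init__(self, cin, cout, norm, rng):
        self.c1 = nn.Conv2D(cin, cout, rng=rng)
        self.n1 = nn.make_norm(norm, cout)
        self.c2 = nn.Conv2D(cout, cout, rng=rng)
        self.n2 = nn.make_norm(norm, cout)

    def forward(self, x, training=False):
        x = nn.relu(self.n1(self.c1(x), training))
        return nn.relu(self.n2(self.c2(x), training))


class ConvNormRelu(nn.Module):
    def __init__(self, cin, cout, norm, rng):
        self.c = nn.Conv2D(cin, cout, rng=rng)
        self.n = nn.make_norm(norm, cout)

    def forward(self, x, training=False):
        return nn.relu(self.n(self.c(x), training))


class Head(nn.Module):
    """1x1 convolution + sigmoid."""

    def __init__(self, cin, cout, rng):
        self.c = nn.Conv2D(cin, cout, k=1, init="glorot", rng=rng)

    def forward(self, x, training=False):
        return nn.sigmoid(self.c(x))


class Encoder(nn.Module):
    """4 down-levels of double convs + max pooling, then the bottleneck."""

    def __init__(self, cin, f, norm, rng):
        chans = [f * 2 ** i for i in range(DEPTH)]
        self.blocks = []
        c = cin
        for co in chans:
            self.blocks.append(DoubleConv(c, co, norm, rng))
            c = co
        self.bottleneck = DoubleConv(c, f * 2 ** DEPTH, norm, rng)

    def forward(self, x, training=False):
        skips = []
        for block in self.blocks:
            x = block(x, training)
            skips.append(x)
            x = nn.max_pool2x2(x)
        return self.bottleneck(x, training), skips


class UpBlock(nn.Module):
    def __init__(self, cin, cout, norm, rng):
        self.up = nn.ConvTranspose2x2(cin, cout, rng=rng)
        self.conv = DoubleConv(2 * cout, cout, norm, rng)

    def forward(self, x, skip, training=False):
        x = self.up(x)
        x = nn.concat([x, skip], axis=-1)
        return self.conv(x, training)


class Decoder(nn.Module):
    """Full 4-level decoder consuming the bottleneck and encoder skips."""

    def __init__(self, f, norm, rng, levels=DEPTH):
        self.blocks = []
        c = f * 2 ** DEPTH
        for i in reversed(range(DEPTH - levels, DEPTH)):
            co = f * 2 ** i
            self.blocks.append(UpBlock(c, co, norm, rng))
            c = co

    def forward(self, x, skips, training=False):
        for block, skip in zip(self.blocks, reversed(skips[-len(self.blocks):])):
            x = block(x, skip, training)
        return x


# ---------------------------------------------------------------------------
# 2-D model family
# ---------------------------------------------------------------------------


class SegKeypointNet2D(nn.Module):
    """All 2-D variants; ``forward`` returns a dict of output tensors."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        f = config.base_filters
        norm = config.normalization
        rng = np.random.default_rng(config.seed)
        cin = config.n_frames if config.temporal_mode == "channels" else 1
        self.encoder = Encoder(cin, f, norm, rng)
        v = config.variant
        if v in ("v2a", "v2c"):
            self.decoder = Decoder(f, norm, rng)
            if v == "v2a":
                self.head_seg = Head(f, 1, rng)
                self.head_kp = Head(f, 2, rng)
            else:
                self.head_seg = Head(f, 1, rng)
                self.head_ap = Head(f, 1, rng)
                self.head_pp = Head(f, 1, rng)
        elif v == "v2b":
            self.decoder = Decoder(f, norm, rng, levels=DEPTH - 1)
            self.up_last = nn.ConvTranspose2x2(2 * f, f, rng=rng)
            self.conv_shared = ConvNormRelu(2 * f, f, norm, rng)
            self.conv_seg = ConvNormRelu(f, f, norm, rng)
            self.conv_kp = ConvNormRelu(f, f, norm, rng)
            self.head_seg = Head(f, 1, rng)
            self.head_kp = Head(f, 2, rng)
        elif v == "v2d":
            self.decoder = Decoder(f, norm, rng, levels=DEPTH - 1)
            self.last_seg = UpBlock(2 * f, f, norm, rng)
            self.last_kp = UpBlock(2 * f, f, norm, rng)
            self.head_seg = Head(f, 1, rng)
            self.head_kp = Head(f, 2, rng)
        elif v == "v2e":
            self.decoder_seg = Decoder(f, norm, rng)
            self.decoder_kp = Decoder(f, norm, rng)
            self.head_seg = Head(f, 1, rng)
            self.head_kp = Head(f, 2, rng)
        elif v == "v1_regression":
            self.decoder = Decoder(f, norm, rng)
            self.head_seg = Head(f, 1, rng)
            self.dense_pts = nn.Dense(f * 2 ** DEPTH, 4, rng=rng)

    @property
    def n_heads(self) -> int:
        return 3 if self.config.variant == "v2c" else 2

    def forward(self, x, training=False):
        """x: (N, H, W, Cin) -> dict with 'seg' and 'keypoints' (or 'points')."""
        x = nn.as_tensor(x)
        latent, skips = self.encoder(x, training)
        v = self.config.variant
        if v == "v2a":
            feat = self.decoder(latent, skips, training)
            return {"seg": self.head_seg(feat), "keypoints": self.head_kp(feat)}
        if v == "v2c":
            feat = self.decoder(latent, skips, training)
            ap = self.head_ap(feat)
            pp = self.head_pp(feat)
            return {"seg": self.head_seg(feat),
                    "keypoints": nn.concat([ap, pp], axis=-1),
                    "ap_map": ap, "pp_map": pp}
        if v == "v2b":
            feat = self.decoder(latent, skips, training)
            feat = self.up_last(feat)
            feat = nn.concat([feat, skips[0]], axis=-1)
            feat = self.conv_shared(feat, training)
            return {
                "seg": self.head_seg(self.conv_seg(feat, training)),
                "keypoints": self.head_kp(self.conv_kp(feat, training)),
            }
        if v == "v2d":
            feat = self.decoder(latent, skips, training)
            return {
                "seg": self.head_seg(self.last_seg(feat, skips[0], training)),
                "keypoints": self.head_kp(
                    self.last_kp(feat, skips[0], training)),
            }
        if v == "v2e":
            return {
                "seg": self.head_seg(
                    self.decoder_seg(latent, skips, training)),
                "keypoints": self.head_kp(
                    self.decoder_kp(latent, skips, training)),
            }
        # v1_regression: GAP on the latent bottleneck + dense layer
        feat = self.decoder(latent, skips, training)
        pooled = latent.mean(axis=(1, 2))
        pts = nn.sigmoid(self.dense_pts(pooled))
        return {"seg": self.head_seg(feat), "points": pts}


# ---------------------------------------------------------------------------
# temporal (3-D) variants — dual-decoder topology
# ---------------------------------------------------------------------------


def _fold(x, fn):
    """Apply a per-frame op to (N, T, H, W, C) by folding time into batch."""
    n, t, h, w, c = x.shape
    y = fn(x.reshape(n * t, h, w, c))
    nh, nw, nc = y.shape[1], y.shape[2], y.shape[3]
    return y.reshape(n, t, nh, nw, nc)


class DoubleConv3D(nn.Module):
    def __init__(self, cin, cout, norm, rng):
        self.c1 = nn.Conv3D(cin, cout, rng=rng)
        self.n1 = nn.make_norm(norm, cout)
        self.c2 = nn.Conv3D(cout, cout, rng=rng)
        self.n2 = nn.make_norm(norm, cout)

    def forward(self, x, training=False):
        x = nn.relu(self.n1(self.c1(x), training))
        return nn.relu(self.n2(self.c2(x), training))


class Head3D(nn.Module):
    """Per-frame 1x1 head over clips."""

    def __init__(self, cin, cout, rng):
        self.c = nn.Conv2D(cin, cout, k=1, init="glorot", rng=rng)

    def forward(self, x, training=False):
        return _fold(x, lambda fr: nn.sigmoid(self.c(fr)))


class Decoder3D(nn.Module):
    def __init__(self, f, norm, rng, block_cls):
        self.ups = []
        self.convs = []
        c = f * 2 ** DEPTH
        for i in reversed(range(DEPTH)):
            co = f * 2 ** i
            self.ups.append(nn.ConvTranspose2x2(c, co, rng=rng))
            self.convs.append(block_cls(2 * co, co, norm, rng))
            c = co

    def forward(self, x, skips, training=False):
        for up, conv, skip in zip(self.ups, self.convs, reversed(skips)):
            x = _fold(x, up)
            x = nn.concat([x, skip], axis=-1)
            x = conv(x, training)
        return x


class SegKeypointNet3D(nn.Module):
    """conv3d temporal mode: every convolution includes the time axis.

    Input (N, T, H, W, 1); outputs one segmentation map and one keypoint-map
    pair per frame.
    """

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        f = config.base_filters
        norm = config.normalization
        rng = np.random.default_rng(config.seed)
        chans = [f * 2 ** i for i in range(DEPTH)]
        self.enc_blocks = []
        c = 1
        for co in chans:
            self.enc_blocks.append(DoubleConv3D(c, co, norm, rng))
            c = co
        self.bottleneck = DoubleConv3D(c, f * 2 ** DEPTH, norm, rng)
        self.decoder_seg = Decoder3D(f, norm, rng, DoubleConv3D)
        self.decoder_kp = Decoder3D(f, norm, rng, DoubleConv3D)
        self.head_seg = Head3D(f, 1, rng)
        self.head_kp = Head3D(f, 2, rng)

    @property
    def n_heads(self) -> int:
        return 2

    def forward(self, x, training=False):
        x = nn.as_tensor(x)
        skips = []
        for block in self.enc_blocks:
            x = block(x, training)
            skips.append(x)
            x = _fold(x, nn.max_pool2x2)
        latent = self.bottleneck(x, training)
        return {
            "seg": self.head_seg(
                self.decoder_seg(latent, skips, training)),
            "keypoints": self.head_kp(
                self.decoder_kp(latent, skips, training)),
        }


class LSTMDecoder(nn.Module):
    """Dual-decoder side for the ConvLSTM variant.

    Levels 3..1 use one ConvLSTM2D in place of the double convolution; the
    last decoder level uses two 3-D convolutions.
    """

    def __init__(self, f, norm, rng):
        self.ups = []
        self.lstms = []
        c = f * 2 ** DEPTH
        for i in reversed(range(1, DEPTH)):
            co = f * 2 ** i
            self.ups.append(nn.ConvTranspose2x2(c, co, rng=rng))
            self.lstms.append(nn.ConvLSTM2D(2 * co, co, rng=rng))
            c = co
        self.up_last = nn.ConvTranspose2x2(c, f, rng=rng)
        self.last = DoubleConv3D(2 * f, f, norm, rng)

    def forward(self, x, skips, training=False):
        for up, lstm, skip in zip(self.ups, self.lstms,
                                  list(reversed(skips))[:-1]):
            x = _fold(x, up)
            x = nn.concat([x, skip], axis=-1)
            x = lstm(x, training)
        x = _fold(x, self.up_last)
        x = nn.concat([x, skips[0]], axis=-1)
        return self.last(x, training)


class SegKeypointNetLSTM(nn.Module):
    """convlstm temporal mode: one ConvLSTM2D replaces each double conv."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        f = config.base_filters
        norm = config.normalization
        rng = np.random.default_rng(config.seed)
        chans = [f * 2 ** i for i in range(DEPTH)]
        self.enc_blocks = []
        c = 1
        for co in chans:
            self.enc_blocks.append(nn.ConvLSTM2D(c, co, rng=rng))
            c = co
        self.bottleneck = nn.ConvLSTM2D(c, f * 2 ** DEPTH, rng=rng)
        self.decoder_seg = LSTMDecoder(f, norm, rng)
        self.decoder_kp = LSTMDecoder(f, norm, rng)
        self.head_seg = Head3D(f, 1, rng)
        self.head_kp = Head3D(f, 2, rng)

    @property
    def n_heads(self) -> int:
        return 2

    def forward(self, x, training=False):
        x = nn.as_tensor(x)
        skips = []
        for block in self.enc_blocks:
            x = block(x, training)
            skips.append(x)
            x = _fold(x, nn.max_pool2x2)
        latent = self.bottleneck(x, training)
        return {
            "seg": self.head_seg(
                self.decoder_seg(latent, skips, training)),
            "keypoints": self.head_kp(
                self.decoder_kp(latent, skips, training)),
        }


# ---------------------------------------------------------------------------
# public builders
# ---------------------------------------------------------------------------


def build_model(config: ModelConfig) -> nn.Module:
    """Build a 2-D model (temporal_mode 'none' or 'channels')."""
    config.validate()
    if config.temporal_mode in ("conv3d", "convlstm"):
        return build_temporal_model(config)
    return SegKeypointNet2D(config)


def build_temporal_model(config: ModelConfig) -> nn.Module:
    """Build a temporal model; requires ``temporal_mode != 'none'``."""
    config.validate()
    if config.temporal_mode == "none":
        raise ConfigurationError(
            "build_temporal_model requires a temporal mode")
    if config.temporal_mode == "channels":
        return SegKeypointNet2D(config)
    if config.temporal_mode == "conv3d":
        return SegKeypointNet3D(config)
    return SegKeypointNetLSTM(config)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalars in the model."""
    return int(sum(p.data.size for p in model.parameters()))


def save_model(model: nn.Module, directory) -> None:
    """Checkpoint weights (.npz) + config (JSON) into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = model.state_arrays()
    np.savez(directory / "weights.npz",
             **{f"arr_{i:04d}": a for i, a in enumerate(arrays)})
    (directory / "model_config.json").write_text(model.config.to_json())


def load_model(directory) -> nn.Module:
    directory = Path(directory)
    config = ModelConfig.from_json(
        (directory / "model_config.json").read_text())
    model = build_model(config)
    with np.load(directory / "weights.npz") as data:
        arrays = [data[k] for k in sorted(data.files)]
    model.load_state_arrays(arrays)
    return model
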