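"""The one-shot Siamese volume network.

Two weight-shared streams process the support set and the target subtomogram:
a three-level 3D convolutional volume encoder (with a DuSE recalibration block
per level) produces a latent representation, from which (a) a mirrored volume
decoder emits a per-voxel foreground probability map and (b) a feature encoder
(global average pool, an adapter projection and a 512x512 fully connected
layer) emits a 512-dim embedding. Class matching scores the elementwise L1
distance between embeddings through a single fully connected head: sigmoid
per pair during training, softmax across the n support classes at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import Conv3d, DuSE, GroupNorm, Linear, Module, global_avg_pool

__all__ = ["ModelConfig", "OneShotNet", "save_checkpoint", "load_checkpoint",
           "normalize_volume"]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    channels: tuple[int, int, int] = (32, 64, 128)
    duse_reduction: int = 2          # bottleneck C -> C/2 -> C
    embedding_dim: int = 512
    input_size: int = 32
    duse_enabled: bool = True
    decoder_enabled: bool = True
    head_mode: str = "pairwise-sigmoid"   # or "softmax-over-support"
    pre_embedding: str = "flatten"        # or "gap"
    n_pools: int = 3                      # 2x max-pools across the 3 levels
    decoder_skips: bool = False           # concat encoder features per level
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_pools <= 3:
            raise ValueError("n_pools must be 1..3")
        if self.input_size % (2**self.n_pools):
            raise ValueError(
                f"input_size must be divisible by {2**self.n_pools}")
        for c in self.channels:
            if self.duse_enabled and c % self.duse_reduction:
                raise ValueError("duse_reduction must divide every channel count")

    @property
    def latent_size(self) -> int:
        return self.input_size // 2**self.n_pools

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "duse_reduction": self.duse_reduction,
            "embedding_dim": self.embedding_dim,
            "input_size": self.input_size,
            "duse_enabled": self.duse_enabled,
            "decoder_enabled": self.decoder_enabled,
            "head_mode": self.head_mode,
            "pre_embedding": self.pre_embedding,
            "n_pools": self.n_pools,
            "decoder_skips": self.decoder_skips,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return ModelConfig(**d)


class _EncoderLevel(Module):
    def __init__(self, c_in, c_out, cfg: ModelConfig, rng, pool: bool):
        self.conv1 = Conv3d(c_in, c_out, 3, rng)
        self.norm1 = GroupNorm(c_out)
        self.conv2 = Conv3d(c_out, c_out, 3, rng)
        self.norm2 = GroupNorm(c_out)
        self.duse = DuSE(c_out, cfg.duse_reduction, rng) if cfg.duse_enabled else None
        self.pool = pool

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_with_pre(x)[0]

    def forward_with_pre(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (level output, pre-pooling feature map)."""
        x = self.norm1(self.conv1(x)).relu()
        x = self.norm2(self.conv2(x)).relu()
        if self.duse is not None:
            x = self.duse(x)
        return (x.maxpool3d() if self.pool else x), x


class _DecoderLevel(Module):
    def __init__(self, c_in, c_out, cfg: ModelConfig, rng, upsample: bool):
        self.conv = Conv3d(c_in, c_out, 3, rng)
        self.norm = GroupNorm(c_out)
        self.duse = DuSE(c_out, cfg.duse_reduction, rng) if cfg.duse_enabled else None
        self.upsample = upsample

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        if self.upsample:
            x = x.upsample3d()
        if skip is not None:
            x = concat([x, skip], axis=1)
        x = self.norm(self.conv(x)).relu()
        if self.duse is not None:
            x = self.duse(x)
        return x


class OneShotNet(Module):
    """Weight-shared encoder/decoder/feature-encoder with an L1 matching head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        c1, c2, c3 = config.channels
        np_ = config.n_pools  # the first n_pools levels downsample
        self.enc_levels = [
            _EncoderLevel(1, c1, config, rng, pool=np_ >= 1),
            _EncoderLevel(c1, c2, config, rng, pool=np_ >= 2),
            _EncoderLevel(c2, c3, config, rng, pool=np_ >= 3),
        ]
        if config.decoder_enabled:
            # with skips, each level also sees the encoder's pre-pooling
            # feature map at the matching resolution
            s3, s2, s1 = (c3, c2, c1) if config.decoder_skips else (0, 0, 0)
            self.dec_levels = [
                _DecoderLevel(c3 + s3, c2, config, rng, upsample=np_ >= 3),
                _DecoderLevel(c2 + s2, c1, config, rng, upsample=np_ >= 2),
                _DecoderLevel(c1 + s1, c1, config, rng, upsample=np_ >= 1),
            ]
            self.dec_out = Conv3d(c1, 1, 1, rng)
            # start the foreground probability near a realistic prior so the
            # class-imbalanced Dice gradient cannot saturate the output early
            self.dec_out.bias.data[:] = -2.0
        else:
            self.dec_levels = []
            self.dec_out = None
        e = config.embedding_dim
        if config.pre_embedding == "flatten":
            n_pre = c3 * config.latent_size**3
        elif config.pre_embedding == "gap":
            n_pre = c3
        else:
            raise ValueError(f"unknown pre_embedding {config.pre_embedding!r}")
        self.fe_adapter = Linear(n_pre, e, rng)
        self.fe_fc = Linear(e, e, rng)          # the 512x512 feature encoder
        self.head = Linear(e, 1, rng)

    # ---- streams ---------------------------------------------------------
    def volume_encode(self, volumes: np.ndarray | Tensor) -> Tensor:
        """(B, s, s, s) batch (or a single cube) -> latent (B, C3, ...)."""
        return self.encode_with_features(volumes)[0]

    def encode_with_features(self, volumes: np.ndarray | Tensor):
        """Returns (latent, per-level pre-pooling features, deepest first)."""
        if not isinstance(volumes, Tensor):
            volumes = Tensor(np.asarray(volumes, dtype=np.float32))
        x = volumes
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        s = self.config.input_size
        if x.shape[1:] != (s, s, s):
            raise ValueError(f"expected ({s},{s},{s}) cubes, got {x.shape[1:]}")
        x = x.reshape(x.shape[0], 1, s, s, s)
        pres = []
        for level in self.enc_levels:
            x, pre = level.forward_with_pre(x)
            pres.append(pre)
        return x, pres[::-1]

    def volume_decode(self, latent: Tensor,
                      skips: list[Tensor] | None = None) -> Tensor:
        """Latent -> per-voxel foreground probability map (B, s, s, s).

        `skips` (deepest first) are required when the model was built with
        decoder_skips; without skips the map is decoded from the latent
        alone.
        """
        if self.dec_out is None:
            raise RuntimeError("decoder disabled in this model configuration")
        if self.config.decoder_skips and skips is None:
            raise ValueError("this model decodes with encoder skips; pass "
                             "the feature maps from encode_with_features")
        x = latent
        for i, level in enumerate(self.dec_levels):
            x = level(x, skips[i] if skips is not None else None)
        x = self.dec_out(x).sigmoid()
        b = x.shape[0]
        s = self.config.input_size
        return x.reshape(b, s, s, s)

    def feature_encode(self, latent: Tensor) -> Tensor:
        """Latent -> 512-dim embedding per batch element."""
        if self.config.pre_embedding == "gap":
            v = global_avg_pool(latent)
        else:
            v = latent.reshape(latent.shape[0], -1)
        return self.fe_fc(self.fe_adapter(v).relu())

    def embed(self, volumes: np.ndarray) -> Tensor:
        return self.feature_encode(self.volume_encode(volumes))

    def predict_probability(self, volumes: np.ndarray) -> Tensor:
        """Full segmentation forward pass: encode then decode (with skips
        when the model uses them)."""
        latent, feats = self.encode_with_features(volumes)
        return self.volume_decode(
            latent, feats if self.config.decoder_skips else None)

    # ---- matching --------------------------------------------------------
    @staticmethod
    def pairwise_distance(a: Tensor, b: Tensor) -> Tensor:
        if a.shape[-1] != b.shape[-1]:
            raise ValueError("embedding length mismatch")
        return (a - b).abs()

    def match_logit(self, distance: Tensor) -> Tensor:
        """One scalar matching logit per distance vector."""
        return self.head(distance)

    def match_scores(self, distances: list[Tensor] | Tensor,
                     mode: str | None = None) -> np.ndarray:
        """Scores for a set of support-class distance vectors.

        pairwise-sigmoid: independent match probability per pair.
        softmax-over-support: normalized scores over the n support classes.
        """
        mode = mode or self.config.head_mode
        if isinstance(distances, list):
            if not distances:
                raise ValueError("need at least one distance vector")
            stacked = np.stack([np.atleast_1d(d.data.squeeze()) for d in distances])
        else:
            stacked = np.atleast_2d(distances.data)
        logits = self.match_logit(Tensor(stacked)).data.ravel()
        if mode == "pairwise-sigmoid":
            return 1.0 / (1.0 + np.exp(-logits))
        if mode == "softmax-over-support":
            e = np.exp(logits - logits.max())
            return e / e.sum()
        raise ValueError(f"unknown head mode {mode!r}")

    @staticmethod
    def predict_class(scores: np.ndarray) -> int:
        """Argmax with lowest-index tie-break."""
        return int(np.argmax(scores))


def normalize_volume(v: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization used for all network inputs."""
    v = np.asarray(v, dtype=np.float32)
    std = v.std()
    return (v - v.mean()) / (std if std > 1e-12 else 1.0)


def save_checkpoint(model: OneShotNet, path: str) -> None:
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "config": model.config.to_dict()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> OneShotNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError("unsupported checkpoint format version")
        model = OneShotNet(ModelConfig.from_dict(meta["config"]))
        n = len(model.parameters())
        model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    return model
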