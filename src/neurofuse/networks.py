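"""Volumetric encoders, projection heads and decoders.

The encoder is a DCGAN-style stack of stride-2 kernel-4 volumetric
convolutions that halves the spatial extent per block while doubling the
channel count, followed by a full-extent convolution to the d-dimensional
global representation z.  For a 64³ input with the default base of 32
channels the layer-3 feature map is 128×8×8×8; that intermediate map is the
"local" representation.  A residual 1×1×1 projection head maps local
features into the global d-dimensional space for score computation, and a
SimCLR-style head (0–3 hidden layers) projects z.  The decoder mirrors the
encoder with transposed convolutions and a final sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .losses import LocalFeatureMap, RepresentationSet
from .nn.autograd import Tensor

__all__ = [
    "EncoderConfig", "HeadConfig", "FeatureBundle", "VolumetricEncoder",
    "LocalProjectionHead", "GlobalProjectionHead", "VolumetricDecoder",
    "ModalityModel", "build_encoder", "build_decoder", "project_local",
    "project_global", "build_modality_model",
]


@dataclass
class EncoderConfig:
    input_shape: tuple = (64, 64, 64)
    base_channels: int = 32
    latent_dim: int = 64
    local_layer: int = 3
    activation: str = "leaky_relu"
    norm: str = "batch"  # or "none"

    def __post_init__(self):
        edge = self.input_shape[0]
        if len(set(self.input_shape)) != 1:
            raise ValueError("input volumes must be cubic")
        if edge < 16 or edge & (edge - 1):
            raise ValueError("edge must be a power of two >= 16")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if edge // 2**self.local_layer < 2:
            raise ValueError(
                f"input {edge}³ too small for local_layer={self.local_layer}")

    @classmethod
    def desk(cls, edge: int = 16, latent_dim: int = 16) -> "EncoderConfig":
        """Desk-scale configuration: small volumes, narrow channels, no norm.

        Batch normalization is the default at full scale; at desk scale its
        cross-sample coupling slows the contrastive objectives down, so the
        small configuration omits it.
        """
        return cls(input_shape=(edge,) * 3, base_channels=8,
                   latent_dim=latent_dim, norm="none")

    @property
    def n_blocks(self) -> int:
        edge = self.input_shape[0]
        return max(self.local_layer, int(np.log2(edge)) - 2)

    def block_channels(self, i: int) -> int:
        return self.base_channels * 2**i


@dataclass
class HeadConfig:
    """Global projection head: −1 none, 0 linear, k ≥ 1 hidden layers."""

    global_depth: int = 1
    head_dim: int = 64

    def __post_init__(self):
        if self.global_depth not in (-1, 0, 1, 2, 3):
            raise ValueError("global_depth must be in {-1, 0, 1, 2, 3}")


@dataclass
class FeatureBundle:
    """All representations of one modality batch from a single forward pass."""

    local: LocalFeatureMap
    local_projected: LocalFeatureMap
    global_raw: RepresentationSet
    global_projected: RepresentationSet


class VolumetricEncoder(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        gain = nn.calculate_gain(cfg.activation)
        blocks = []
        c_in = 1
        for i in range(cfg.n_blocks):
            c_out = cfg.block_channels(i)
            layer = [nn.Conv3d(c_in, c_out, 4, 2, 1, rng, gain=gain)]
            if cfg.norm == "batch":
                layer.append(nn.BatchNorm3d(c_out))
            layer.append(nn.LeakyReLU(0.2) if cfg.activation == "leaky_relu"
                         else nn.ReLU())
            blocks.append(nn.Sequential(*layer))
            c_in = c_out
        self.blocks = blocks
        final_extent = cfg.input_shape[0] // 2**cfg.n_blocks
        self.final = nn.Conv3d(c_in, cfg.latent_dim, final_extent, 1, 0, rng, gain=1.0)

    def forward(self, x: Tensor, return_layers: bool = False):
        """x: (N, 1, s, s, s) -> z (N, d); optionally all block activations."""
        acts = []
        h = x
        for b in self.blocks:
            h = b(h)
            acts.append(h)
        z = self.final(h)
        n, d = z.shape[0], z.shape[1]
        z = z.reshape(n, d)
        if return_layers:
            return z, acts
        return z

    def local_map(self, x: Tensor) -> tuple:
        """Returns (z, local) where local is the layer-l map as (N, C, S)."""
        z, acts = self.forward(x, return_layers=True)
        a = acts[self.cfg.local_layer - 1]
        n, c = a.shape[0], a.shape[1]
        local = a.reshape(n, c, int(np.prod(a.shape[2:])))
        return z, local


class LocalProjectionHead(nn.Module):
    """Residual block of 1×1×1 convolutions mapping C channels to d.

    Path A: two 1×1×1 convolutions (hidden and output width d, Xavier init).
    Path B: one 1×1×1 convolution initialized to (truncated) identity.
    Operates on flattened (N, C, S) maps, so the convolutions reduce to
    per-location linear maps.
    """

    def __init__(self, c_in: int, d: int, rng: np.random.Generator):
        super().__init__()
        gain = nn.calculate_gain("relu")
        self.w1 = nn.Parameter(nn.xavier_uniform((d, c_in), c_in, d, gain, rng))
        self.b1 = nn.Parameter(np.zeros(d))
        self.w2 = nn.Parameter(nn.xavier_uniform((d, d), d, d, 1.0, rng))
        self.b2 = nn.Parameter(np.zeros(d))
        eye = np.zeros((d, c_in))
        m = min(d, c_in)
        eye[np.arange(m), np.arange(m)] = 1.0
        self.w_skip = nn.Parameter(eye)

    def forward(self, local: Tensor) -> Tensor:
        n, c, s = local.shape
        flat = local.transpose(0, 2, 1).reshape(n * s, c)
        a = (flat @ self.w1.T + self.b1).relu() @ self.w2.T + self.b2
        b = flat @ self.w_skip.T
        out = a + b
        d = out.shape[1]
        return out.reshape(n, s, d).transpose(0, 2, 1)


class GlobalProjectionHead(nn.Module):
    def __init__(self, d_in: int, cfg: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        if cfg.global_depth == -1:
            if cfg.head_dim != d_in:
                raise ValueError("head_dim must equal latent_dim with no head")
            self.net = nn.Identity()
        elif cfg.global_depth == 0:
            self.net = nn.Linear(d_in, cfg.head_dim, rng)
        else:
            gain = nn.calculate_gain("relu")
            layers = []
            cur = d_in
            for _ in range(cfg.global_depth):
                layers += [nn.Linear(cur, cfg.head_dim, rng, gain=gain), nn.ReLU()]
                cur = cfg.head_dim
            layers.append(nn.Linear(cur, cfg.head_dim, rng))
            self.net = nn.Sequential(*layers)

    def forward(self, z: Tensor) -> Tensor:
        return self.net(z)


class VolumetricDecoder(nn.Module):
    """Transposed-convolution mirror of the encoder; final sigmoid to [0, 1]."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        gain = nn.calculate_gain("relu")
        final_extent = cfg.input_shape[0] // 2**cfg.n_blocks
        c_top = cfg.block_channels(cfg.n_blocks - 1)
        self.expand = nn.ConvTranspose3d(cfg.latent_dim, c_top, final_extent, 1, 0,
                                         rng, gain=gain)
        blocks = []
        for i in reversed(range(cfg.n_blocks)):
            c_in = cfg.block_channels(i)
            c_out = cfg.block_channels(i - 1) if i > 0 else 1
            layer = [nn.ConvTranspose3d(c_in, c_out, 4, 2, 1, rng, gain=gain)]
            if i > 0:
                if cfg.norm == "batch":
                    layer.append(nn.BatchNorm3d(c_out))
                layer.append(nn.ReLU())
            else:
                layer.append(nn.Sigmoid())
            blocks.append(nn.Sequential(*layer))
        self.blocks = blocks

    def forward(self, z: Tensor) -> Tensor:
        n, d = z.shape
        h = z.reshape(n, d, 1, 1, 1)
        h = self.expand(h)
        for b in self.blocks:
            h = b(h)
        return h


class ModalityModel(nn.Module):
    """Encoder plus the heads (and optionally decoder) of one modality."""

    def __init__(self, encoder: VolumetricEncoder,
                 local_head: LocalProjectionHead | None,
                 global_head: GlobalProjectionHead,
                 decoder: VolumetricDecoder | None = None,
                 modality_id: int = 1):
        super().__init__()
        self.encoder = encoder
        self.local_head = local_head
        self.global_head = global_head
        self.decoder = decoder
        self.modality_id = modality_id

    def forward(self, x: Tensor) -> FeatureBundle:
        z, local = self.encoder.local_map(x)
        g = self.global_head(z)
        lp = self.local_head(local) if self.local_head is not None else local
        layer = self.encoder.cfg.local_layer
        return FeatureBundle(
            local=LocalFeatureMap(local, layer, self.modality_id),
            local_projected=LocalFeatureMap(lp, layer, self.modality_id),
            global_raw=RepresentationSet(z, "global", self.modality_id),
            global_projected=RepresentationSet(g, "global", self.modality_id),
        )

    def encode(self, x: Tensor) -> Tensor:
        """Global z only (the probe/CKA representation)."""
        return self.encoder(x)

    def reconstruct(self, x: Tensor) -> Tensor:
        if self.decoder is None:
            raise ValueError("model has no decoder")
        return self.decoder(self.encoder(x))


def build_encoder(cfg: EncoderConfig, rng) -> VolumetricEncoder:
    return VolumetricEncoder(cfg, _as_rng(rng))


def build_decoder(cfg: EncoderConfig, rng) -> VolumetricDecoder:
    return VolumetricDecoder(cfg, _as_rng(rng))


def project_local(local, head: LocalProjectionHead):
    """Apply the residual local head to a LocalFeatureMap (or raw array)."""
    if isinstance(local, LocalFeatureMap):
        out = head(local.values)
        return LocalFeatureMap(out, local.layer_index, local.modality_id)
    return head(local if isinstance(local, Tensor) else Tensor(local))


def project_global(z, head: GlobalProjectionHead):
    if isinstance(z, RepresentationSet):
        return RepresentationSet(head(z.vectors), "global", z.modality_id)
    return head(z if isinstance(z, Tensor) else Tensor(z))


def build_modality_model(cfg: EncoderConfig, head_cfg: HeadConfig, rng,
                         with_local_head: bool = True,
                         with_decoder: bool = False,
                         modality_id: int = 1) -> ModalityModel:
    rng = _as_rng(rng)
    enc = VolumetricEncoder(cfg, rng)
    c_local = cfg.block_channels(cfg.local_layer - 1)
    lh = LocalProjectionHead(c_local, head_cfg.head_dim, rng) if with_local_head else None
    gh = GlobalProjectionHead(cfg.latent_dim, head_cfg, rng)
    dec = VolumetricDecoder(cfg, rng) if with_decoder else None
    return ModalityModel(enc, lh, gh, dec, modality_id)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
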