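"""The 3-D U-Net style transformer that maps a density block to an enhanced block.

Four encoder stages (strided conv + batch norm + three transformer blocks)
halve the spatial edge and widen the channels; a residual-convolution
bottleneck sits at the bottom; four decoder stages fuse the matching
encoder's features through skip connections, upsample by transposed
convolution, and run three more transformer blocks.  Transformer blocks
combine a learned positional embedding, paired spatial/channel attention
(EPA) and a convolutional feed-forward path, each with a residual
connection.  A 1x1x1 head projects back to one channel.

The network accepts any cubic input whose edge is divisible by
2**n_levels; positional embeddings and the spatial-attention projection are
stored at the configured base edge and linearly regridded when a different
edge arrives, so one trained model serves several block sizes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autodiff import resample3d, softmax

__all__ = [
    "ArchitectureConfig",
    "EPAAttention",
    "TransformerBlock",
    "ConvResBlock",
    "EncoderStage",
    "DecoderStage",
    "EnhancerNetwork",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ArchitectureConfig:
    """Hyperparameters that fully determine the network's shape."""

    in_channels: int = 1
    base_channels: int = 32
    channel_multipliers: tuple[int, ...] = (1, 2, 4, 8)
    blocks_per_stage: int = 3
    epa_heads: int = 4
    epa_spatial_proj: int = 64
    dropout_rate: float = 0.1
    negative_slope: float = 0.01
    input_edge: int = 48

    def __post_init__(self):
        self.channel_multipliers = tuple(self.channel_multipliers)
        n_levels = len(self.channel_multipliers)
        if self.input_edge % (2**n_levels) != 0:
            raise ValueError(
                f"input_edge {self.input_edge} must be divisible by 2^{n_levels}"
            )
        for m in self.channel_multipliers:
            if (self.base_channels * m) % self.epa_heads != 0:
                raise ValueError(
                    "channel count at every level must be divisible by epa_heads"
                )

    @property
    def n_levels(self) -> int:
        return len(self.channel_multipliers)

    def channels_at(self, level: int) -> int:
        return self.base_channels * self.channel_multipliers[level]

    def edge_at(self, level: int) -> int:
        """Spatial edge of the *output* of encoder `level` at the base input edge."""
        return self.input_edge // (2 ** (level + 1))


def _interp_matrix(new_len: int, old_len: int) -> np.ndarray:
    """Linear interpolation matrix mapping old_len samples to new_len samples."""
    if new_len == old_len:
        return np.eye(new_len, dtype=np.float32)
    m = np.zeros((new_len, old_len), dtype=np.float32)
    if old_len == 1:
        m[:, 0] = 1.0
        return m
    x = np.linspace(0.0, old_len - 1.0, new_len)
    lo = np.floor(x).astype(int)
    hi = np.minimum(lo + 1, old_len - 1)
    frac = x - lo
    m[np.arange(new_len), lo] += 1.0 - frac
    m[np.arange(new_len), hi] += frac
    return m


def _regrid(param: Tensor, base_edge: int, edge: int) -> Tensor:
    """Resample a (1, C, E0, E0, E0) parameter volume to edge E (identity if equal)."""
    if edge == base_edge:
        return param
    m = _interp_matrix(edge, base_edge)
    return resample3d(param, (m, m, m))


class EPAAttention(nn.Module):
    """Efficient Paired Attention: parallel spatial and channel branches.

    Queries and keys are shared between the branches.  The spatial branch
    attends from every position to a learned low-rank projection of the
    positions (cost O(N*p) instead of O(N^2)); the channel branch computes a
    per-head channel-by-channel affinity with a learned temperature.  The two
    branch outputs are concatenated and fused back to C channels.
    """

    PROJ_LATTICE = 4  # edge of the coarse lattice the projection patterns live on

    def __init__(self, channels: int, heads: int, spatial_proj: int,
                 base_edge: int, rng: np.random.Generator):
        super().__init__()
        if channels % heads != 0:
            raise ValueError("channels must be divisible by heads")
        self.channels = channels
        self.heads = heads
        self.base_edge = base_edge
        n_base = base_edge**3
        self.p = min(spatial_proj, n_base)
        self.wq = nn.Linear(channels, channels, rng)
        self.wk = nn.Linear(channels, channels, rng)
        self.wv_spatial = nn.Linear(channels, channels, rng)
        self.wv_channel = nn.Linear(channels, channels, rng)
        # learned projection patterns: one smooth volume per projected token,
        # stored on a small lattice and regridded to the working edge, so the
        # parameter cost is independent of the block size
        self.proj_edge = min(self.PROJ_LATTICE, base_edge)
        self.proj = nn.Parameter(
            rng.standard_normal((1, self.p) + (self.proj_edge,) * 3)
            .astype(np.float32) / np.sqrt(n_base)
        )
        self.temperature = nn.Parameter(np.ones((1, heads, 1, 1), dtype=np.float32))
        self.fuse = nn.Linear(2 * channels, channels, rng)
        # small output gain so the attention residual starts near-identity;
        # without it the residual stack amplifies activations multiplicatively
        self.fuse.weight.data *= 0.1

    def _split_heads(self, t: Tensor, n: int) -> Tensor:
        b = t.shape[0]
        d = self.channels // self.heads
        return t.reshape(b, n, self.heads, d).transpose(0, 2, 1, 3)

    def attention_weights(self, x: Tensor, edge: int) -> tuple[Tensor, Tensor]:
        """(spatial, channel) attention weight tensors, rows summing to 1."""
        return self._forward(x, edge, return_weights=True)

    def _forward(self, x: Tensor, edge: int, return_weights: bool = False):
        b = x.shape[0]
        n = edge**3
        d = self.channels // self.heads
        q = self._split_heads(self.wq(x), n)          # (B, H, N, d)
        k = self._split_heads(self.wk(x), n)
        vs = self._split_heads(self.wv_spatial(x), n)
        vc = self._split_heads(self.wv_channel(x), n)

        # spatial branch: project keys/values over positions to p tokens,
        # flattening the head dim into the batch for the projection matmul
        proj = _regrid(self.proj, self.proj_edge, edge).reshape(1, self.p, n)
        k_flat = k.reshape(b * self.heads, n, d)
        vs_flat = vs.reshape(b * self.heads, n, d)
        kp = (proj @ k_flat).reshape(b, self.heads, self.p, d)
        vp = (proj @ vs_flat).reshape(b, self.heads, self.p, d)
        a_spatial = softmax(q @ kp.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(d)), axis=-1)
        out_s = a_spatial @ vp                        # (B, H, N, d)

        # channel branch: d x d affinity per head from the shared Q/K
        a_channel = softmax(
            (q.transpose(0, 1, 3, 2) @ k) * self.temperature, axis=-1
        )                                              # (B, H, d, d)
        out_c = vc @ a_channel.transpose(0, 1, 3, 2)   # (B, H, N, d)

        if return_weights:
            return a_spatial, a_channel

        def merge(t: Tensor) -> Tensor:
            return t.transpose(0, 2, 1, 3).reshape(b, n, self.channels)

        fused = self.fuse(nn.concat([merge(out_s), merge(out_c)], axis=-1))
        return fused

    def forward(self, x: Tensor, edge: int) -> Tensor:
        return self._forward(x, edge)


class TransformerBlock(nn.Module):
    """Positional embedding -> EPA (residual) -> conv/BN/LeakyReLU/dropout (residual)."""

    def __init__(self, channels: int, cfg: ArchitectureConfig, base_edge: int,
                 rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.base_edge = base_edge
        # positional embedding on a coarse lattice, trilinearly upsampled to
        # the working edge: keeps the parameter count width-dominated
        self.pos_edge = min(8, base_edge)
        self.pos_embed = nn.Parameter(
            rng.standard_normal((1, channels) + (self.pos_edge,) * 3)
            .astype(np.float32) * 0.02
        )
        self.attn = EPAAttention(channels, cfg.epa_heads, cfg.epa_spatial_proj,
                                 base_edge, rng)
        self.attn_drop = nn.Dropout(cfg.dropout_rate, rng)
        self.conv = nn.Conv3d(channels, channels, 3, rng)
        self.bn = nn.BatchNorm3d(channels)
        # near-zero norm gain: the conv residual branch starts close to
        # identity, the usual deep-residual initialization
        self.bn.gamma.data *= 0.1
        self.act = nn.LeakyReLU(cfg.negative_slope)
        self.drop = nn.Dropout(cfg.dropout_rate, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        edge = x.shape[2]
        x = x + _regrid(self.pos_embed, self.pos_edge, edge)
        tokens = x.reshape(b, c, edge**3).transpose(0, 2, 1)  # (B, N, C)
        attn_out = self.attn_drop(self.attn.forward(tokens, edge))
        tokens = tokens + attn_out
        x = tokens.transpose(0, 2, 1).reshape(b, c, edge, edge, edge)
        y = self.drop(self.act(self.bn(self.conv(x))))
        return x + y


class ConvResBlock(nn.Module):
    """Three conv + instance-norm pairs, two LeakyReLUs, residual to the third pair."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 negative_slope: float = 0.01):
        super().__init__()
        self.conv1 = nn.Conv3d(channels, channels, 3, rng)
        self.in1 = nn.InstanceNorm3d(channels)
        self.act1 = nn.LeakyReLU(negative_slope)
        self.conv2 = nn.Conv3d(channels, channels, 3, rng)
        self.in2 = nn.InstanceNorm3d(channels)
        self.act2 = nn.LeakyReLU(negative_slope)
        self.conv3 = nn.Conv3d(channels, channels, 3, rng)
        self.in3 = nn.InstanceNorm3d(channels)
        self.in3.gamma.data *= 0.1

    def forward(self, x: Tensor) -> Tensor:
        y = self.act1(self.in1(self.conv1(x)))
        y = self.act2(self.in2(self.conv2(y)))
        y = self.in3(self.conv3(y))
        return x + y


class EncoderStage(nn.Module):
    """Strided conv + batch norm + transformer blocks; halves the spatial edge."""

    def __init__(self, cfg: ArchitectureConfig, level: int, rng: np.random.Generator):
        super().__init__()
        in_ch = cfg.in_channels if level == 0 else cfg.channels_at(level - 1)
        out_ch = cfg.channels_at(level)
        self.down = nn.Conv3d(in_ch, out_ch, 3, rng, stride=2, pad=1)
        self.bn = nn.BatchNorm3d(out_ch)
        self.blocks = nn.ModuleList([
            TransformerBlock(out_ch, cfg, cfg.edge_at(level), rng)
            for _ in range(cfg.blocks_per_stage)
        ])

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn(self.down(x))
        for blk in self.blocks:
            x = blk(x)
        return x


class DecoderStage(nn.Module):
    """Skip fusion + transposed-conv upsampling + transformer blocks.

    Fuses the incoming features with the matching encoder's output (same
    resolution) by concatenation and a 1x1x1 reduction, then doubles the
    spatial edge and halves the channel count.
    """

    def __init__(self, cfg: ArchitectureConfig, level: int, rng: np.random.Generator):
        super().__init__()
        ch = cfg.channels_at(level)
        if level > 0:
            out_ch = cfg.channels_at(level - 1)
        else:
            out_ch = max(cfg.base_channels // 2, cfg.epa_heads)
        self.reduce = nn.Conv3d(2 * ch, ch, 1, rng, pad=0)
        self.up = nn.ConvTranspose3d2x(ch, out_ch, rng)
        self.blocks = nn.ModuleList([
            TransformerBlock(out_ch, cfg, 2 * cfg.edge_at(level), rng)
            for _ in range(cfg.blocks_per_stage)
        ])
        self.out_channels = out_ch

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        if x.shape != skip.shape:
            raise ValueError(f"skip shape {skip.shape} does not match {x.shape}")
        x = self.reduce(nn.concat([x, skip], axis=1))
        x = self.up(x)
        for blk in self.blocks:
            x = blk(x)
        return x


class EnhancerNetwork(nn.Module):
    """Full encoder/bottleneck/decoder stack, one channel in, one channel out."""

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoders = nn.ModuleList([
            EncoderStage(cfg, lvl, rng) for lvl in range(cfg.n_levels)
        ])
        deep_ch = cfg.channels_at(cfg.n_levels - 1)
        self.bottleneck = ConvResBlock(deep_ch, rng, cfg.negative_slope)
        self.decoders = nn.ModuleList([
            DecoderStage(cfg, lvl, rng) for lvl in reversed(range(cfg.n_levels))
        ])
        head_ch = self.decoders[len(self.decoders) - 1].out_channels
        self.head = nn.Conv3d(head_ch, 1, 1, rng, pad=0)

    def forward(self, x: Tensor) -> Tensor:
        edge = x.shape[2]
        if edge % (2**self.cfg.n_levels) != 0:
            raise ValueError(
                f"input edge {edge} not divisible by 2^{self.cfg.n_levels}"
            )
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
        x = self.bottleneck(x)
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(x, skip)
        return self.head(x)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Numpy-in/numpy-out inference (training-mode layers must be off)."""
        was_training = self.training
        self.eval()
        out = self.forward(Tensor(np.asarray(batch, dtype=np.float32))).data
        if was_training:
            self.train()
        return out

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def save_checkpoint(path, network: EnhancerNetwork, extra: dict | None = None) -> None:
    """Serialize parameters + ArchitectureConfig (+ provenance) to an .npz file."""
    meta = {"config": asdict(network.cfg), "extra": extra or {}}
    state = network.state_dict()
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[EnhancerNetwork, dict]:
    """Rebuild a network from a checkpoint; returns (network, extra metadata)."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = ArchitectureConfig(**meta["config"])
    net = EnhancerNetwork(cfg)
    net.load_state_dict(state)
    net.eval()
    return net, meta.get("extra", {})
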