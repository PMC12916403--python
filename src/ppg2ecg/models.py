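"""Generator, critic and AF-classifier architectures.

The generator is a 1-D UNet: a strided convolutional encoder halves the
sequence length at each of L layers, a Transformer with causal self-attention
models long-range structure at the bottleneck (channels expanded 8→16 before
tokenisation), and a transposed-convolution decoder restores the length with
encoder feature maps concatenated at mirrored depths.  The output passes
through Tanh, matching the (−1, 1) normalized-signal range.

The critic is a BERT-style Transformer: a three-layer stride-1 conv encoder
(kernels 65/33/17, channels 64/128/256, layer norm at the first layer and at
the output), average-pooled into ``s`` tokens, a CLS token plus learned
positional embeddings, and a 2-layer/2-head encoder.  The CLS representation
feeds either the Wasserstein scoring head (FC 2d→d→1, no squashing; the 2d
activation is the embedding used for distributional analysis) or the
six-task pretext head (two shared FC-128+ReLU layers, six binary logits).
A masked-point regression head (FC d→d/2→1) exists for architectural
completeness and is unused by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass(frozen=True)
class GeneratorConfig:
    depth: int = 4
    encoder_channels: tuple = (16, 16, 8, 8)    # ends at 8 before 8→16 expansion
    bottleneck_channels: int = 16
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 2
    dropout: float = 0.2
    kernel: int = 4                              # stride-2 conv taps
    max_tokens: int = 1300                       # 160 s at 130 Hz through 2^4

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.encoder_channels) != self.depth:
            raise ValueError("need one channel count per encoder layer")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass(frozen=True)
class DiscriminatorConfig:
    conv_kernels: tuple = (65, 33, 17)
    conv_channels: tuple = (64, 128, 256)
    d_model: int = 256
    n_layers: int = 2
    n_heads: int = 2
    ffn_dim: int = 512
    n_tokens: int = 64
    pretext_dim: int = 128
    masked_head_dim: int = 128
    dropout: float = 0.1

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.ffn_dim != 2 * self.d_model:
            raise ValueError("ffn_dim must equal 2 × d_model")


def reduced_generator_config(**overrides) -> GeneratorConfig:
    """Small generator for desk-scale experiments and tests."""
    base = dict(depth=2, encoder_channels=(8, 8), bottleneck_channels=16,
                d_model=16, n_layers=1, n_heads=2, dropout=0.0,
                max_tokens=520)
    base.update(overrides)
    return GeneratorConfig(**base)


def reduced_discriminator_config(**overrides) -> DiscriminatorConfig:
    """Small critic: same topology, desk-scale widths."""
    base = dict(conv_kernels=(17, 9, 5), conv_channels=(8, 16, 32),
                d_model=32, n_layers=1, n_heads=2, ffn_dim=64, n_tokens=16,
                pretext_dim=32, masked_head_dim=16, dropout=0.0)
    base.update(overrides)
    return DiscriminatorConfig(**base)


class Generator(nn.Module):
    """PPG window in, same-length ECG window out, values in (−1, 1)."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        chans = [1] + list(cfg.encoder_channels)
        self.enc = [nn.Conv1d(chans[i], chans[i + 1], cfg.kernel, rng,
                              stride=2, padding=(cfg.kernel - 2) // 2)
                    for i in range(cfg.depth)]
        c_bot = cfg.encoder_channels[-1]
        self.expand = nn.Conv1d(c_bot, cfg.bottleneck_channels, 1, rng, padding=0)
        self.tok_in = nn.Linear(cfg.bottleneck_channels, cfg.d_model, rng)
        self.pos = nn.parameter(rng.normal(0, 0.02, (cfg.max_tokens, cfg.d_model)))
        self.blocks = [nn.TransformerBlock(cfg.d_model, cfg.n_heads,
                                           2 * cfg.d_model, rng,
                                           dropout=cfg.dropout, causal=True)
                       for _ in range(cfg.n_layers)]
        self.tok_out = nn.Linear(cfg.d_model, cfg.bottleneck_channels, rng)
        self.compress = nn.Conv1d(cfg.bottleneck_channels, c_bot, 1, rng, padding=0)
        dec_in = []
        dec_out = []
        cur = c_bot
        for i in range(cfg.depth - 1, -1, -1):
            skip_c = cfg.encoder_channels[i]
            dec_in.append(cur + skip_c)
            cur = cfg.encoder_channels[i - 1] if i > 0 else 1
            dec_out.append(cur)
        self.dec = [nn.ConvTranspose1d(ci, co, cfg.kernel, rng, stride=2,
                                       padding=(cfg.kernel - 2) // 2)
                    for ci, co in zip(dec_in, dec_out)]

    def forward(self, p: Tensor) -> Tensor:
        if p.ndim == 1:
            p = p.reshape(1, 1, p.shape[0])
        elif p.ndim == 2:
            p = p.reshape(p.shape[0], 1, p.shape[1])
        if p.shape[2] == 0:
            raise ValueError("empty input window")
        t_in = p.shape[2]
        block = 2 ** self.cfg.depth
        pad = (-t_in) % block
        if pad:
            p = ad.concat([p, Tensor(np.zeros((p.shape[0], 1, pad)))], axis=2)
        skips = []
        x = p
        for conv in self.enc:
            x = ad.relu(conv(x))
            skips.append(x)
        # bottleneck: 8→16 channels, tokens over time, causal attention
        x = self.expand(x)
        tokens = self.tok_in(x.transpose(0, 2, 1))
        s = tokens.shape[1]
        if s > self.cfg.max_tokens:
            raise ValueError("input longer than the positional-embedding table")
        tokens = tokens + self.pos[:s, :]
        for blk in self.blocks:
            tokens = blk(tokens)
        x = self.tok_out(tokens).transpose(0, 2, 1)
        x = self.compress(x)
        for i, deconv in enumerate(self.dec):
            x = ad.concat([x, skips[len(skips) - 1 - i]], axis=1)
            x = deconv(x)
            if i < len(self.dec) - 1:
                x = ad.relu(x)
        out = ad.tanh(x)
        return out[:, 0, :t_in]


def _pool_matrix(t: int, s: int) -> np.ndarray:
    """Constant (t × s) averaging matrix splitting time into s near-equal bins."""
    bounds = np.linspace(0, t, s + 1).round().astype(int)
    mat = np.zeros((t, s))
    for j in range(s):
        lo, hi = bounds[j], max(bounds[j + 1], bounds[j] + 1)
        mat[lo:hi, j] = 1.0 / (hi - lo)
    return mat


class Discriminator(nn.Module):
    """Transformer critic with pretext / critic / masked-point heads."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        k, c = cfg.conv_kernels, cfg.conv_channels
        self.conv1 = nn.Conv1d(1, c[0], k[0], rng)
        self.ln1 = nn.LayerNorm(c[0], axis=1)
        self.conv2 = nn.Conv1d(c[0], c[1], k[1], rng)
        self.conv3 = nn.Conv1d(c[1], c[2], k[2], rng)
        self.ln_out = nn.LayerNorm(c[2], axis=1)
        self.proj = nn.Linear(c[2], cfg.d_model, rng)
        self.cls = nn.parameter(rng.normal(0, 0.02, (cfg.d_model,)))
        self.pos = nn.parameter(rng.normal(0, 0.02, (cfg.n_tokens + 1, cfg.d_model)))
        self.ln_z = nn.LayerNorm(cfg.d_model)
        self.blocks = [nn.TransformerBlock(cfg.d_model, cfg.n_heads, cfg.ffn_dim,
                                           rng, dropout=cfg.dropout, causal=False)
                       for _ in range(cfg.n_layers)]
        # Wasserstein head: d → 2d (embedding) → d → scalar
        self.critic_fc1 = nn.Linear(cfg.d_model, 2 * cfg.d_model, rng)
        self.critic_fc2 = nn.Linear(2 * cfg.d_model, cfg.d_model, rng)
        self.critic_out = nn.Linear(cfg.d_model, 1, rng)
        # pretext head: two shared FC layers then six binary logits
        self.task_fc1 = nn.Linear(cfg.d_model, cfg.pretext_dim, rng)
        self.task_fc2 = nn.Linear(cfg.pretext_dim, cfg.pretext_dim, rng)
        self.task_out = nn.Linear(cfg.pretext_dim, 6, rng)
        # masked-point head (architectural fidelity; unused by default)
        self.masked_fc = nn.Linear(cfg.d_model, cfg.masked_head_dim, rng)
        self.masked_out = nn.Linear(cfg.masked_head_dim, 1, rng)

    def transformer_parameters(self):
        """Parameters frozen when transferring the pre-trained critic."""
        out = []
        for blk in self.blocks:
            out.extend(p for _, p in blk.named_parameters())
        return out

    def encode(self, x: Tensor) -> Tensor:
        """Contextualised token matrix C = {e_CLS, e_1, …, e_s}."""
        if x.ndim == 1:
            x = x.reshape(1, 1, x.shape[0])
        elif x.ndim == 2:
            x = x.reshape(x.shape[0], 1, x.shape[1])
        t = x.shape[2]
        if t < self.cfg.n_tokens:
            raise ValueError("window shorter than the token count")
        h = ad.relu(self.ln1(self.conv1(x)))
        h = ad.relu(self.conv2(h))
        h = self.ln_out(ad.relu(self.conv3(h)))
        tokens = (h @ Tensor(_pool_matrix(t, self.cfg.n_tokens))).transpose(0, 2, 1)
        tokens = self.proj(tokens)
        b = tokens.shape[0]
        cls = ad.broadcast_to(self.cls.reshape(1, 1, -1), (b, 1, self.cfg.d_model))
        z = ad.concat([cls, tokens], axis=1) + self.pos
        z = self.ln_z(z)
        for blk in self.blocks:
            z = blk(z)
        return z

    def forward(self, x: Tensor, mode: str = "critic"):
        """Returns ``(score_or_logits, embedding, tokens)`` for the mode."""
        z = self.encode(x)
        c = z[:, 0, :]
        if mode == "critic":
            emb = ad.relu(self.critic_fc1(c))
            h = ad.relu(self.critic_fc2(emb))
            return self.critic_out(h)[:, 0], emb, z
        if mode == "pretext":
            h = ad.relu(self.task_fc1(c))
            h = ad.relu(self.task_fc2(h))
            return self.task_out(h), c, z
        if mode == "masked":
            h = ad.relu(self.masked_fc(z))
            return self.masked_out(h)[:, :, 0], c, z
        raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class AFClassifierConfig:
    hidden: int = 128
    fc_units: int = 256
    dropout: float = 0.5
    conv_kernel: int = 4          # CNN+LSTM front end only


class _BiLSTMStack(nn.Module):
    """Two bidirectional LSTM layers + dropout + two ReLU FC layers + sigmoid."""

    def __init__(self, input_size: int, cfg: AFClassifierConfig,
                 rng: np.random.Generator):
        super().__init__()
        h = cfg.hidden
        self.l1f = nn.LSTM(input_size, h, rng)
        self.l1b = nn.LSTM(input_size, h, rng)
        self.l2f = nn.LSTM(2 * h, h, rng)
        self.l2b = nn.LSTM(2 * h, h, rng)
        self.drop = nn.Dropout(cfg.dropout, rng)
        self.fc1 = nn.Linear(2 * h, cfg.fc_units, rng)
        self.fc2 = nn.Linear(cfg.fc_units, cfg.fc_units, rng)
        self.out = nn.Linear(cfg.fc_units, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        of, _ = self.l1f(x)
        ob, _ = self.l1b(x, reverse=True)
        h1 = ad.concat([of, ob], axis=2)
        _, hf = self.l2f(h1)
        _, hb = self.l2b(h1, reverse=True)
        h = self.drop(ad.concat([hf, hb], axis=1))
        h = ad.relu(self.fc1(h))
        h = ad.relu(self.fc2(h))
        return ad.sigmoid(self.out(h))[:, 0]


class BidLSTM(nn.Module):
    """AF-probability classifier on fixed-length normalized ECG windows."""

    def __init__(self, cfg: AFClassifierConfig, rng: np.random.Generator):
        super().__init__()
        self.stack = _BiLSTMStack(1, cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            x = x.reshape(x.shape[0], x.shape[1], 1)
        return self.stack(x)


class CNNLSTM(nn.Module):
    """Two conv(kernel 4)+maxpool(2,2) stages feeding the Bid-LSTM stack."""

    def __init__(self, cfg: AFClassifierConfig, rng: np.random.Generator,
                 conv_channels: int | None = None):
        super().__init__()
        c = conv_channels or cfg.hidden
        self.conv1 = nn.Conv1d(1, c, cfg.conv_kernel, rng, padding=1)
        self.pool1 = nn.MaxPool1d(2)
        self.conv2 = nn.Conv1d(c, c, cfg.conv_kernel, rng, padding=1)
        self.pool2 = nn.MaxPool1d(2)
        self.drop = nn.Dropout(cfg.dropout, rng)
        self.stack = _BiLSTMStack(c, cfg, rng)

    @staticmethod
    def _pad_right(x: Tensor) -> Tensor:
        # even kernel with symmetric padding loses one sample; restore it so
        # the temporal length after both pool stages is floor(floor(T/2)/2)
        from .nn import _pad_time
        return _pad_time(x, 0, 1)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            x = x.reshape(x.shape[0], 1, x.shape[1])
        if x.shape[2] < 16:
            raise ValueError("window too short for two conv/pool stages")
        h = self.pool1(ad.relu(self.conv1(self._pad_right(x))))
        h = self.pool2(ad.relu(self.conv2(self._pad_right(h))))
        h = self.drop(h)
        return self.stack(h.transpose(0, 2, 1))
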