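"""Multi-region attention decoder for clusterless spike-amplitude tensors.

Architecture
------------
Each microwire bundle ("region") contributes a 250-ms window tensor of
shape ``(2, 8, B)`` (polarity x channels x 5-ms bins). Per region, a
patch embedding (convolution with kernel = stride = patch shape, the
polarity axis acting as input channels) maps the window to a token
sequence, a learnable class token is prepended, and learnable positional
embeddings are added. A stack of blocks then alternates:

* region-wise self-attention (RSA): full pre-norm transformer block
  (multi-head attention + feed-forward, residual) over each region's
  own tokens;
* cross-region attention (CRA): each region's class token queries the
  class tokens of all *other* regions; the updated class token is
  written back into its sequence for the next block. With a single
  region CRA is the identity.

After the final block the class tokens are averaged across regions
(combiner) and a single linear head maps the pooled representation to
per-concept logits; element-wise sigmoids give activations in (0, 1)
that need not sum to one (multi-label).

Embeddings, positions and class tokens are region-specific; the RSA and
CRA weights are shared across regions so the parameter count does not
grow with electrode coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import DTYPE, Tensor, concat, no_grad, stack


@dataclass
class ModelConfig:
    """Decoder hyper-parameters. Defaults are the full-scale values."""

    hidden_size: int = 396
    intermediate_size: int = 792
    depth: int = 6
    heads: int = 6
    patch_width: int = 5        # (1, 5) patches for clusterless input
    n_concepts: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size % self.heads != 0:
            raise ValueError("hidden_size must be divisible by heads")


@dataclass
class TrainingConfig:
    lr: float = 1e-4
    epochs: int = 49
    batch_size: int = 64
    lr_step_epochs: int = 16
    lr_decay: float = 0.5
    min_combination_screentime_s: float = 50.0
    window_s: float = 0.25
    seed: int = 0


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    # resample outside +-2 std (simple rejection, matches ViT-style init)
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=bad.sum())
        bad = np.abs(x) > 2 * std
    return x.astype(DTYPE)


class Linear:
    """Dense layer with Xavier (Glorot) weight init.

    Xavier keeps activation scale stable through the attention stack at
    the small hidden sizes used for desk-scale studies, where a fixed
    0.02-SD init leaves the attention logits too close to uniform to
    train within a short budget. Class and positional tokens keep the
    conventional 0.02-SD truncated normal (see RegionEmbed).
    """

    def __init__(self, rng, n_in: int, n_out: int):
        std = float(np.sqrt(2.0 / (n_in + n_out)))
        w = rng.normal(0.0, std, size=(n_in, n_out)).astype(DTYPE)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class LayerNorm:
    """Layer normalization over the feature axis with learnable affine."""

    def __init__(self, hidden: int):
        self.g = Tensor(np.ones(hidden, dtype=DTYPE), requires_grad=True)
        self.b = Tensor(np.zeros(hidden, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm() * self.g + self.b

    def parameters(self):
        return [self.g, self.b]


class MultiHeadAttention:
    """Standard scaled dot-product attention; query and key/value
    sources may differ (used by CRA)."""

    def __init__(self, rng, hidden: int, heads: int):
        self.h = heads
        self.dk = hidden // heads
        self.wq = Linear(rng, hidden, hidden)
        self.wk = Linear(rng, hidden, hidden)
        self.wv = Linear(rng, hidden, hidden)
        self.wo = Linear(rng, hidden, hidden)

    def _split(self, x: Tensor, n: int, t: int) -> Tensor:
        # (n, t, hidden) -> (n, heads, t, dk)
        return x.reshape(n, t, self.h, self.dk).transpose((0, 2, 1, 3))

    def __call__(self, q_src: Tensor, kv_src: Tensor) -> Tensor:
        n, tq = q_src.shape[0], q_src.shape[1]
        tk = kv_src.shape[1]
        q = self._split(self.wq(q_src), n, tq)
        k = self._split(self.wk(kv_src), n, tk)
        v = self._split(self.wv(kv_src), n, tk)
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dk))
        att = att.softmax(axis=-1)
        out = att @ v  # (n, heads, tq, dk)
        out = out.transpose((0, 2, 1, 3)).reshape(n, tq, self.h * self.dk)
        return self.wo(out)

    def parameters(self):
        return (self.wq.parameters() + self.wk.parameters()
                + self.wv.parameters() + self.wo.parameters())


class FeedForward:
    def __init__(self, rng, hidden: int, intermediate: int):
        self.fc1 = Linear(rng, hidden, intermediate)
        self.fc2 = Linear(rng, intermediate, hidden)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


class RSABlock:
    """Pre-norm transformer block applied within one region."""

    def __init__(self, rng, hidden: int, intermediate: int, heads: int):
        self.ln1 = LayerNorm(hidden)
        self.attn = MultiHeadAttention(rng, hidden, heads)
        self.ln2 = LayerNorm(hidden)
        self.ff = FeedForward(rng, hidden, intermediate)

    def __call__(self, tokens: Tensor) -> Tensor:
        x = self.ln1(tokens)
        tokens = tokens + self.attn(x, x)
        tokens = tokens + self.ff(self.ln2(tokens))
        return tokens

    def parameters(self):
        return (self.ln1.parameters() + self.attn.parameters()
                + self.ln2.parameters() + self.ff.parameters())


class CRABlock:
    """Each region's class token attends to the other regions' class
    tokens (pre-norm cross-attention, residual)."""

    def __init__(self, rng, hidden: int, heads: int):
        self.ln = LayerNorm(hidden)
        self.attn = MultiHeadAttention(rng, hidden, heads)

    def __call__(self, class_tokens: list[Tensor]) -> list[Tensor]:
        r = len(class_tokens)
        if r == 1:
            return class_tokens
        normed = [self.ln(c) for c in class_tokens]
        updated = []
        for i in range(r):
            q = normed[i]  # (n, 1, hidden)
            kv = concat([normed[j] for j in range(r) if j != i], axis=1)
            updated.append(class_tokens[i] + self.attn(q, kv))
        return updated

    def parameters(self):
        return self.ln.parameters() + self.attn.parameters()


class RegionEmbed:
    """Patch embedding for one region stream.

    Input ``(n, P, C, B)`` (P polarity planes, C channels, B bins) is cut
    into ``(1, patch_width)`` patches with the polarity axis as
    convolution input channels, linearly projected to ``hidden``, a class
    token prepended and positional embeddings added.
    """

    def __init__(self, rng, n_planes: int, n_channels: int, n_bins: int,
                 hidden: int, patch_width: int):
        if n_bins % patch_width != 0:
            raise ValueError(
                f"bin count {n_bins} not divisible by patch width {patch_width}")
        self.pw = patch_width
        self.n_patches = n_channels * (n_bins // patch_width)
        self.proj = Linear(rng, n_planes * patch_width, hidden)
        self.cls = Tensor(_trunc_normal(rng, (1, 1, hidden)), requires_grad=True)
        self.pos = Tensor(_trunc_normal(rng, (1, self.n_patches + 1, hidden)),
                          requires_grad=True)

    def __call__(self, x: np.ndarray) -> Tensor:
        n, p, c, b = x.shape
        # (n, p, c, b) -> patches (n, c * b/pw, p * pw)
        patches = (x.reshape(n, p, c, b // self.pw, self.pw)
                    .transpose(0, 2, 3, 1, 4)
                    .reshape(n, self.n_patches, p * self.pw))
        tok = self.proj(Tensor(patches))
        ones = Tensor(np.ones((n, 1, 1), dtype=DTYPE))
        cls = ones @ self.cls  # broadcast class token over the batch
        return concat([cls, tok], axis=1) + self.pos

    def parameters(self):
        return self.proj.parameters() + [self.cls, self.pos]


class MultiRegionTransformer:
    """The full decoder: region embeddings, RSA/CRA stack, combiner, head."""

    def __init__(self, region_shapes: list[tuple], config: ModelConfig):
        """``region_shapes``: per region ``(planes, channels, bins)``."""
        self.config = config
        self.region_shapes = [tuple(s) for s in region_shapes]
        rng = np.random.default_rng(config.seed)
        h = config.hidden_size
        self.embeds = [RegionEmbed(rng, p, c, b, h, config.patch_width)
                       for (p, c, b) in self.region_shapes]
        self.rsa = [RSABlock(rng, h, config.intermediate_size, config.heads)
                    for _ in range(config.depth)]
        self.cra = [CRABlock(rng, h, config.heads) for _ in range(config.depth)]
        self.head = Linear(rng, h, config.n_concepts)

    # ---------------------------------------------------------------

    def logits(self, region_inputs: list[np.ndarray]) -> Tensor:
        if len(region_inputs) != len(self.embeds):
            raise ValueError("region count mismatch with trained channel map")
        for x, s in zip(region_inputs, self.region_shapes):
            if tuple(x.shape[1:]) != s:
                raise ValueError(f"region input shape {x.shape[1:]} != trained {s}")
        tokens = [emb(np.asarray(x, dtype=DTYPE))
                  for emb, x in zip(self.embeds, region_inputs)]
        for rsa, cra in zip(self.rsa, self.cra):
            tokens = [rsa(t) for t in tokens]
            cls = [t[:, 0:1, :] for t in tokens]
            cls = cra(cls)
            # write updated class tokens back for the next block
            tokens = [concat([c, t[:, 1:, :]], axis=1)
                      for c, t in zip(cls, tokens)]
        cls_final = [t[:, 0, :] for t in tokens]
        ht = stack(cls_final, axis=0).mean(axis=0)  # combiner: mean over regions
        return self.head(ht)

    def forward(self, region_inputs: list[np.ndarray]) -> np.ndarray:
        """Per-concept activations in (0, 1) for a batch of windows."""
        with no_grad():
            z = self.logits(region_inputs)
        return (1.0 / (1.0 + np.exp(-z.data.astype(np.float64))))

    def predict(self, region_inputs: list[np.ndarray],
                batch_size: int = 256) -> np.ndarray:
        n = region_inputs[0].shape[0]
        out = np.empty((n, self.config.n_concepts))
        for a in range(0, n, batch_size):
            b = min(a + batch_size, n)
            out[a:b] = self.forward([x[a:b] for x in region_inputs])
        return out

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for e in self.embeds:
            ps += e.parameters()
        for blk in self.rsa:
            ps += blk.parameters()
        for blk in self.cra:
            ps += blk.parameters()
        ps += self.head.parameters()
        return ps

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class LogisticBaseline:
    """Linear control model: the attention stack replaced by a single
    linear map on the flattened window tensor; training is otherwise
    identical to the transformer."""

    def __init__(self, region_shapes: list[tuple], config: ModelConfig):
        self.config = config
        self.region_shapes = [tuple(s) for s in region_shapes]
        n_in = int(sum(np.prod(s) for s in self.region_shapes))
        rng = np.random.default_rng(config.seed)
        self.lin = Linear(rng, n_in, config.n_concepts)

    def logits(self, region_inputs: list[np.ndarray]) -> Tensor:
        n = region_inputs[0].shape[0]
        flat = np.concatenate(
            [np.asarray(x, dtype=DTYPE).reshape(n, -1) for x in region_inputs],
            axis=1)
        return self.lin(Tensor(flat))

    def forward(self, region_inputs: list[np.ndarray]) -> np.ndarray:
        with no_grad():
            z = self.logits(region_inputs)
        return 1.0 / (1.0 + np.exp(-z.data.astype(np.float64)))

    def predict(self, region_inputs: list[np.ndarray],
                batch_size: int = 4096) -> np.ndarray:
        n = region_inputs[0].shape[0]
        out = np.empty((n, self.config.n_concepts))
        for a in range(0, n, batch_size):
            b = min(a + batch_size, n)
            out[a:b] = self.forward([x[a:b] for x in region_inputs])
        return out

    def parameters(self):
        return self.lin.parameters()

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    y = np.asarray(targets, dtype=DTYPE)
    z = logits.data
    # stable forward: max(z,0) - z*y + log1p(exp(-|z|))
    val = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(np.array(val.mean(), dtype=DTYPE))
    out.requires_grad = logits.requires_grad

    def bwd(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * (p - y) / z.size)

    out._backward, out._prev = bwd, (logits,)
    return out


class Adam:
    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
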