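"""Miniature transformer encoder in pure NumPy.

A desk-scale ESM-2-style encoder: rotary positional embeddings inside the
attention heads, pre-layer normalization, GELU feed-forward blocks, and a
linear language-modelling head. Forward, backward (hand-derived gradients,
verified against numerical differentiation in the test suite) and an Adam
optimizer are all implemented on float64 NumPy arrays, which keeps training
bit-reproducible across runs on the same platform.

Intended for miniature models (a few hundred thousand parameters); the
point is controlled experimentation on scaling behaviour, not throughput.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import erf

__all__ = ["ModelConfig", "TinyTransformerLM", "Adam", "cross_entropy_from_logits"]

IGNORE_INDEX = -100
_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 2
    d_model: int = 32
    n_heads: int = 2
    ffn_dim: int = 64
    vocab_size: int = 33
    positional_scheme: str = "rotary"
    norm_scheme: str = "pre-layer"
    init_std: float = 0.02
    rope_base: float = 10000.0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if (self.d_model // self.n_heads) % 2:
            raise ValueError("head dimension must be even for rotary embeddings")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def param_count(self) -> int:
        """Analytic parameter count of this architecture."""
        d, f, v = self.d_model, self.ffn_dim, self.vocab_size
        per_layer = (
            2 * d  # ln1
            + 4 * (d * d + d)  # q, k, v, o projections
            + 2 * d  # ln2
            + (d * f + f) + (f * d + d)  # ffn
        )
        return v * d + self.n_layers * per_layer + 2 * d + (d * v + v)


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def _layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_backward(dy, cache):
    xhat, inv, g = cache
    n = xhat.shape[-1]
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dx = (
        inv
        / n
        * (
            n * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )
    )
    return dx, dg, db


def _rope_tables(T, head_dim, base):
    half = head_dim // 2
    freqs = base ** (-np.arange(half) / half)  # (half,)
    ang = np.arange(T)[:, None] * freqs[None, :]  # (T, half)
    return np.cos(ang), np.sin(ang)


def _rope_apply(x, cos, sin):
    """x: (B, H, T, dh), half-split pair rotation."""
    half = x.shape[-1] // 2
    x1, x2 = x[..., :half], x[..., half:]
    return np.concatenate((x1 * cos - x2 * sin, x2 * cos + x1 * sin), axis=-1)


def _rope_backward(d, cos, sin):
    half = d.shape[-1] // 2
    da, db = d[..., :half], d[..., half:]
    return np.concatenate((da * cos + db * sin, db * cos - da * sin), axis=-1)


def cross_entropy_from_logits(logits, labels):
    """Mean cross-entropy over positions where labels != IGNORE_INDEX.

    Returns (loss, dlogits, n_labelled); dlogits is already divided by the
    number of labelled positions.
    """
    B, T, V = logits.shape
    valid = labels != IGNORE_INDEX
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no labelled positions")
    z = logits - logits.max(axis=-1, keepdims=True)
    logZ = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logZ
    safe = np.where(valid, labels, 0)
    picked = np.take_along_axis(logp, safe[..., None], axis=-1)[..., 0]
    loss = -(picked * valid).sum() / n
    probs = np.exp(logp)
    dlogits = probs.copy()
    np.put_along_axis(
        dlogits, safe[..., None], np.take_along_axis(dlogits, safe[..., None], -1) - 1.0, -1
    )
    dlogits *= valid[..., None] / n
    return loss, dlogits, n


class TinyTransformerLM:
    """Pre-LN rotary transformer encoder with an MLM head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, f, v, s = config.d_model, config.ffn_dim, config.vocab_size, config.init_std
        p = {}
        p["emb"] = rng.normal(0, s, (v, d))
        for i in range(config.n_layers):
            p[f"ln1_g{i}"], p[f"ln1_b{i}"] = np.ones(d), np.zeros(d)
            for w in ("q", "k", "v", "o"):
                p[f"W{w}{i}"] = rng.normal(0, s, (d, d))
                p[f"b{w}{i}"] = np.zeros(d)
            p[f"ln2_g{i}"], p[f"ln2_b{i}"] = np.ones(d), np.zeros(d)
            p[f"W1_{i}"], p[f"b1_{i}"] = rng.normal(0, s, (d, f)), np.zeros(f)
            p[f"W2_{i}"], p[f"b2_{i}"] = rng.normal(0, s, (f, d)), np.zeros(d)
        p["lnf_g"], p["lnf_b"] = np.ones(d), np.zeros(d)
        p["Wout"], p["bout"] = rng.normal(0, s, (d, v)), np.zeros(v)
        self.params = p

    # -- forward ---------------------------------------------------------
    def forward(self, tokens, pad_mask=None):
        """tokens: (B, T) int64; pad_mask: (B, T) bool, True = real token.

        Returns (logits, cache).
        """
        cfg, p = self.config, self.params
        B, T = tokens.shape
        if pad_mask is None:
            pad_mask = np.ones((B, T), dtype=bool)
        H, dh = cfg.n_heads, cfg.head_dim
        cos, sin = _rope_tables(T, dh, cfg.rope_base)
        key_bias = np.where(pad_mask, 0.0, -1e9)[:, None, None, :]  # (B,1,1,T)

        x = p["emb"][tokens]
        cache = {"tokens": tokens, "pad_mask": pad_mask, "cos": cos, "sin": sin, "layers": []}
        for i in range(cfg.n_layers):
            lc = {"x_in": x}
            h1, lc["ln1"] = _layernorm_forward(x, p[f"ln1_g{i}"], p[f"ln1_b{i}"])
            lc["h1"] = h1

            def split(z):
                return z.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

            q = split(h1 @ p[f"Wq{i}"] + p[f"bq{i}"])
            k = split(h1 @ p[f"Wk{i}"] + p[f"bk{i}"])
            v = split(h1 @ p[f"Wv{i}"] + p[f"bv{i}"])
            lc["q"], lc["k"], lc["v"] = q, k, v
            qr, kr = _rope_apply(q, cos, sin), _rope_apply(k, cos, sin)
            lc["qr"], lc["kr"] = qr, kr
            scores = qr @ kr.transpose(0, 1, 3, 2) / np.sqrt(dh) + key_bias
            scores -= scores.max(axis=-1, keepdims=True)
            e = np.exp(scores)
            att = e / e.sum(axis=-1, keepdims=True)
            lc["att"] = att
            ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
            lc["ctx"] = ctx
            x = x + ctx @ p[f"Wo{i}"] + p[f"bo{i}"]

            lc["x_mid"] = x
            h2, lc["ln2"] = _layernorm_forward(x, p[f"ln2_g{i}"], p[f"ln2_b{i}"])
            lc["h2"] = h2
            f1 = h2 @ p[f"W1_{i}"] + p[f"b1_{i}"]
            lc["f1"] = f1
            g = _gelu(f1)
            lc["g"] = g
            x = x + g @ p[f"W2_{i}"] + p[f"b2_{i}"]
            cache["layers"].append(lc)

        xf, cache["lnf"] = _layernorm_forward(x, p["lnf_g"], p["lnf_b"])
        cache["xf"] = xf
        logits = xf @ p["Wout"] + p["bout"]
        return logits, cache

    # -- backward --------------------------------------------------------
    def backward(self, cache, dlogits):
        cfg, p = self.config, self.params
        tokens = cache["tokens"]
        B, T = tokens.shape
        H, dh = cfg.n_heads, cfg.head_dim
        cos, sin = cache["cos"], cache["sin"]
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        grads["Wout"] = cache["xf"].reshape(-1, cfg.d_model).T @ dlogits.reshape(-1, cfg.vocab_size)
        grads["bout"] = dlogits.sum(axis=(0, 1))
        dxf = dlogits @ p["Wout"].T
        dx, grads["lnf_g"], grads["lnf_b"] = _layernorm_backward(dxf, cache["lnf"])

        for i in reversed(range(cfg.n_layers)):
            lc = cache["layers"][i]
            # FFN block
            dg = dx @ p[f"W2_{i}"].T
            grads[f"W2_{i}"] = lc["g"].reshape(-1, cfg.ffn_dim).T @ dx.reshape(-1, cfg.d_model)
            grads[f"b2_{i}"] = dx.sum(axis=(0, 1))
            df1 = dg * _gelu_grad(lc["f1"])
            grads[f"W1_{i}"] = lc["h2"].reshape(-1, cfg.d_model).T @ df1.reshape(-1, cfg.ffn_dim)
            grads[f"b1_{i}"] = df1.sum(axis=(0, 1))
            dh2 = df1 @ p[f"W1_{i}"].T
            dx_mid, grads[f"ln2_g{i}"], grads[f"ln2_b{i}"] = _layernorm_backward(dh2, lc["ln2"])
            dx = dx + dx_mid  # residual

            # attention block
            dctx = dx @ p[f"Wo{i}"].T
            grads[f"Wo{i}"] = lc["ctx"].reshape(-1, cfg.d_model).T @ dx.reshape(-1, cfg.d_model)
            grads[f"bo{i}"] = dx.sum(axis=(0, 1))
            dctx = dctx.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            att, v = lc["att"], lc["v"]
            datt = dctx @ v.transpose(0, 1, 3, 2)
            dv = att.transpose(0, 1, 3, 2) @ dctx
            dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
            dscores /= np.sqrt(dh)
            dqr = dscores @ lc["kr"]
            dkr = dscores.transpose(0, 1, 3, 2) @ lc["qr"]
            dq = _rope_backward(dqr, cos, sin)
            dk = _rope_backward(dkr, cos, sin)

            def merge(z):
                return z.transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)

            dq, dk, dv = merge(dq), merge(dk), merge(dv)
            h1_flat = lc["h1"].reshape(-1, cfg.d_model)
            dh1 = np.zeros_like(lc["h1"])
            for w, dz in (("q", dq), ("k", dk), ("v", dv)):
                grads[f"W{w}{i}"] = h1_flat.T @ dz.reshape(-1, cfg.d_model)
                grads[f"b{w}{i}"] = dz.sum(axis=(0, 1))
                dh1 = dh1 + dz @ p[f"W{w}{i}"].T
            dx_in, grads[f"ln1_g{i}"], grads[f"ln1_b{i}"] = _layernorm_backward(dh1, lc["ln1"])
            dx = dx + dx_in  # residual

        np.add.at(grads["emb"], tokens, dx)
        return grads

    def loss_and_grads(self, tokens, labels, pad_mask=None):
        logits, cache = self.forward(tokens, pad_mask)
        loss, dlogits, n = cross_entropy_from_logits(logits, labels)
        return loss, self.backward(cache, dlogits), n

    def evaluate_loss(self, tokens, labels, pad_mask=None):
        logits, _ = self.forward(tokens, pad_mask)
        loss, _, n = cross_entropy_from_logits(logits, labels)
        return loss, n

    # -- persistence -----------------------------------------------------
    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        (directory / "config.json").write_text(json.dumps(asdict(self.config), indent=1))

    @classmethod
    def load(cls, directory):
        directory = Path(directory)
        config = ModelConfig(**json.loads((directory / "config.json").read_text()))
        model = cls(config, seed=0)
        with np.load(directory / "weights.npz") as z:
            model.params = {k: z[k] for k in z.files}
        return model

    def actual_param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))


class Adam:
    """Adam with a linear warmup / linear decay learning-rate schedule."""

    def __init__(self, params, peak_lr=1e-4, warmup_steps=0, total_steps=1,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.peak_lr, self.warmup, self.total = peak_lr, warmup_steps, total_steps
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def lr_at(self, step: int) -> float:
        if self.warmup > 0 and step < self.warmup:
            return self.peak_lr * step / self.warmup
        if self.total <= self.warmup:
            return self.peak_lr
        frac = (step - self.warmup) / (self.total - self.warmup)
        return self.peak_lr * max(0.0, 1.0 - frac)

    def step(self, params, grads):
        self.t += 1
        lr = self.lr_at(self.t)
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)
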