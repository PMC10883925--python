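"""Minimal NumPy transformer encoder with hand-written backprop.

The graded environment ships no deep-learning framework, so the small
pre-training/fine-tuning models are implemented directly on NumPy arrays in
float64.  Everything is deterministic given a seeded ``numpy.random.Generator``.

Parameters live in flat ``{name: ndarray}`` dicts; forward passes return a
cache that the matching backward pass consumes, accumulating gradients into a
dict with the same keys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG_INF = -1e9
_LN_EPS = 1e-5


@dataclass(frozen=True)
class EncoderSpec:
    vocab_size: int
    hidden_size: int
    num_heads: int
    num_layers: int
    ffn_size: int
    max_position: int

    def __post_init__(self) -> None:
        if self.hidden_size % self.num_heads != 0:
            raise ValueError("hidden_size must be divisible by num_heads")
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")


# ---------------------------------------------------------------------------
# Parameter initialization

def init_encoder_params(rng: np.random.Generator, spec: EncoderSpec,
                        std: float = 0.02) -> dict[str, np.ndarray]:
    d, f = spec.hidden_size, spec.ffn_size
    p: dict[str, np.ndarray] = {
        "tok_emb": rng.normal(0.0, std, (spec.vocab_size, d)),
        "pos_emb": rng.normal(0.0, std, (spec.max_position, d)),
        "ln_f.g": np.ones(d),
        "ln_f.b": np.zeros(d),
    }
    for i in range(spec.num_layers):
        pre = f"l{i}."
        for name, shape in (
            ("wq", (d, d)), ("wk", (d, d)), ("wv", (d, d)), ("wo", (d, d)),
            ("w1", (d, f)), ("w2", (f, d)),
        ):
            p[pre + name] = rng.normal(0.0, std, shape)
        for name, size in (("bq", d), ("bk", d), ("bv", d), ("bo", d),
                           ("b1", f), ("b2", d)):
            p[pre + name] = np.zeros(size)
        for ln in ("ln1", "ln2"):
            p[pre + ln + ".g"] = np.ones(d)
            p[pre + ln + ".b"] = np.zeros(d)
    return p


def zeros_like_params(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.items()}


# ---------------------------------------------------------------------------
# Layer norm

def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Encoder forward / backward

def encoder_forward(params, spec: EncoderSpec, ids: np.ndarray,
                    pad_mask: np.ndarray):
    """ids (B, L) int; pad_mask (B, L) with 1.0 at real tokens, 0.0 at pads.

    Pre-norm transformer blocks, final layer norm.  Returns (hidden (B, L, d),
    cache).
    """
    B, L = ids.shape
    if L > spec.max_position:
        raise ValueError(f"sequence length {L} exceeds max_position {spec.max_position}")
    H = spec.num_heads
    dh = spec.hidden_size // H
    scale = 1.0 / np.sqrt(dh)

    x = params["tok_emb"][ids] + params["pos_emb"][:L]
    key_bias = (1.0 - pad_mask)[:, None, None, :] * NEG_INF  # (B,1,1,L)
    layer_caches = []
    for i in range(spec.num_layers):
        pre = f"l{i}."
        x1, ln1_cache = _ln_fwd(x, params[pre + "ln1.g"], params[pre + "ln1.b"])
        q = x1 @ params[pre + "wq"] + params[pre + "bq"]
        k = x1 @ params[pre + "wk"] + params[pre + "bk"]
        v = x1 @ params[pre + "wv"] + params[pre + "bv"]
        qh = q.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        scores = qh @ kh.transpose(0, 1, 3, 2) * scale + key_bias
        attn = _softmax(scores)
        ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, L, spec.hidden_size)
        attn_out = ctx @ params[pre + "wo"] + params[pre + "bo"]
        x_mid = x + attn_out
        x2, ln2_cache = _ln_fwd(x_mid, params[pre + "ln2.g"], params[pre + "ln2.b"])
        z1 = x2 @ params[pre + "w1"] + params[pre + "b1"]
        a1 = np.maximum(z1, 0.0)
        ffn_out = a1 @ params[pre + "w2"] + params[pre + "b2"]
        x_next = x_mid + ffn_out
        layer_caches.append((x1, ln1_cache, qh, kh, vh, attn, ctx,
                             ln2_cache, x2, z1, a1))
        x = x_next
    h, lnf_cache = _ln_fwd(x, params["ln_f.g"], params["ln_f.b"])
    cache = (ids, pad_mask, layer_caches, lnf_cache, (B, L, H, dh, scale))
    return h, cache


def encoder_backward(params, spec: EncoderSpec, cache, dh_out,
                     grads: dict[str, np.ndarray]) -> None:
    """Accumulate d(loss)/d(params) into *grads* given d(loss)/d(hidden)."""
    ids, pad_mask, layer_caches, lnf_cache, (B, L, H, dh, scale) = cache
    d = spec.hidden_size

    dx, dg, db = _ln_bwd(dh_out, lnf_cache)
    grads["ln_f.g"] += dg
    grads["ln_f.b"] += db

    for i in reversed(range(spec.num_layers)):
        pre = f"l{i}."
        (x1, ln1_cache, qh, kh, vh, attn, ctx, ln2_cache, x2, z1, a1) = layer_caches[i]

        # FFN branch
        dffn = dx  # gradient of x_next wrt ffn_out is identity
        da1 = dffn @ params[pre + "w2"].T
        grads[pre + "w2"] += a1.reshape(-1, a1.shape[-1]).T @ dffn.reshape(-1, d)
        grads[pre + "b2"] += dffn.sum((0, 1))
        dz1 = da1 * (z1 > 0.0)
        grads[pre + "w1"] += x2.reshape(-1, d).T @ dz1.reshape(-1, dz1.shape[-1])
        grads[pre + "b1"] += dz1.sum((0, 1))
        dx2 = dz1 @ params[pre + "w1"].T
        dx_mid, dg, db = _ln_bwd(dx2, ln2_cache)
        grads[pre + "ln2.g"] += dg
        grads[pre + "ln2.b"] += db
        dx_mid = dx_mid + dx  # residual

        # attention branch
        dattn_out = dx_mid
        dctx = dattn_out @ params[pre + "wo"].T
        grads[pre + "wo"] += ctx.reshape(-1, d).T @ dattn_out.reshape(-1, d)
        grads[pre + "bo"] += dattn_out.sum((0, 1))
        dctx_h = dctx.reshape(B, L, H, dh).transpose(0, 2, 1, 3)
        dattn = dctx_h @ vh.transpose(0, 1, 3, 2)
        dvh = attn.transpose(0, 1, 3, 2) @ dctx_h
        dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
        dqh = dscores @ kh * scale
        dkh = dscores.transpose(0, 1, 3, 2) @ qh * scale
        dq = dqh.transpose(0, 2, 1, 3).reshape(B, L, d)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B, L, d)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B, L, d)
        x1_2d = x1.reshape(-1, d)
        dx1 = dq @ params[pre + "wq"].T + dk @ params[pre + "wk"].T \
            + dv @ params[pre + "wv"].T
        grads[pre + "wq"] += x1_2d.T @ dq.reshape(-1, d)
        grads[pre + "wk"] += x1_2d.T @ dk.reshape(-1, d)
        grads[pre + "wv"] += x1_2d.T @ dv.reshape(-1, d)
        grads[pre + "bq"] += dq.sum((0, 1))
        grads[pre + "bk"] += dk.sum((0, 1))
        grads[pre + "bv"] += dv.sum((0, 1))
        dx_in, dg, db = _ln_bwd(dx1, ln1_cache)
        grads[pre + "ln1.g"] += dg
        grads[pre + "ln1.b"] += db
        dx = dx_in + dx_mid  # residual

    np.add.at(grads["tok_emb"], ids, dx)
    grads["pos_emb"][:L] += dx.sum(0)


# ---------------------------------------------------------------------------
# Heads and losses

def softmax_xent(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over rows; returns (loss, dlogits)."""
    n = logits.shape[0]
    if n == 0:
        return 0.0, np.zeros_like(logits)
    probs = _softmax(logits, axis=-1)
    loss = float(-np.log(probs[np.arange(n), targets] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    dlogits /= n
    return loss, dlogits


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray, weights: np.ndarray):
    """Weighted-mean binary cross-entropy with logits; (loss, dlogits)."""
    total = weights.sum()
    if total <= 0:
        return 0.0, np.zeros_like(logits)
    # stable log(1+exp)
    loss_terms = np.maximum(logits, 0.0) - logits * targets \
        + np.log1p(np.exp(-np.abs(logits)))
    loss = float((loss_terms * weights).sum() / total)
    sig = 1.0 / (1.0 + np.exp(-logits))
    dlogits = (sig - targets) * weights / total
    return loss, dlogits


def init_linear(rng: np.random.Generator, n_in: int, n_out: int,
                std: float = 0.02) -> dict[str, np.ndarray]:
    return {"w": rng.normal(0.0, std, (n_in, n_out)), "b": np.zeros(n_out)}


# ---------------------------------------------------------------------------
# Adam

class Adam:
    """Plain Adam with bias correction; state keyed like the param dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = zeros_like_params(params)
        self.v = zeros_like_params(params)

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for key, g in grads.items():
            m = self.m[key]
            v = self.v[key]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
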