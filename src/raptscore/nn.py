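"""Numerical core: a compact BERT-style transformer encoder in NumPy.

Forward and backward passes are written out explicitly over a flat parameter
dictionary, which keeps checkpoints trivially portable (a single ``.npz``)
and makes the parameter count directly enumerable.  The architecture is the
standard post-layer-norm encoder: token + learned position embeddings,
multi-head self-attention and a GELU feed-forward block per layer, and an
MLM head (dense + GELU + layer norm + untied output projection).

Only what masked-language-model pretraining and pseudo-log-likelihood
scoring need is implemented: no pooler, no token-type embeddings, no
autoregressive cache.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

import numpy as np

DTYPE = np.float32
_NEG = DTYPE(-1e9)

_GELU_C = math.sqrt(2.0 / math.pi)
_GELU_A = 0.044715


# ---------------------------------------------------------------------------
# parameter bookkeeping

def param_spec(cfg, include_mlm_head: bool = True) -> Dict[str, Tuple[int, ...]]:
    """Name -> shape for every trainable tensor of a given configuration."""
    H, I, V, P = cfg.hidden_size, cfg.intermediate_size, cfg.vocab_size, cfg.max_positions
    spec: Dict[str, Tuple[int, ...]] = {
        "emb_tok": (V, H),
        "emb_pos": (P, H),
        "emb_ln_g": (H,),
        "emb_ln_b": (H,),
    }
    for i in range(cfg.num_layers):
        p = f"l{i}_"
        spec.update({
            p + "wq": (H, H), p + "bq": (H,),
            p + "wk": (H, H), p + "bk": (H,),
            p + "wv": (H, H), p + "bv": (H,),
            p + "wo": (H, H), p + "bo": (H,),
            p + "attn_ln_g": (H,), p + "attn_ln_b": (H,),
            p + "w1": (H, I), p + "b1": (I,),
            p + "w2": (I, H), p + "b2": (H,),
            p + "ffn_ln_g": (H,), p + "ffn_ln_b": (H,),
        })
    if include_mlm_head:
        spec.update({
            "head_w": (H, H), "head_b": (H,),
            "head_ln_g": (H,), "head_ln_b": (H,),
            "out_w": (H, V), "out_b": (V,),
        })
    return spec


def init_params(cfg, seed: int) -> Dict[str, np.ndarray]:
    """Truncated-normal(0.02) weights, zero biases, unit layer-norm gains."""
    rng = np.random.default_rng(seed)
    params: Dict[str, np.ndarray] = {}
    for name, shape in param_spec(cfg, include_mlm_head=True).items():
        if name.endswith("_g"):
            params[name] = np.ones(shape, dtype=DTYPE)
        elif name.endswith(("_b", "bq", "bk", "bv", "bo", "b1", "b2")) or name == "out_b":
            params[name] = np.zeros(shape, dtype=DTYPE)
        else:
            w = rng.normal(0.0, 0.02, size=shape)
            np.clip(w, -0.04, 0.04, out=w)
            params[name] = w.astype(DTYPE)
    return params


# ---------------------------------------------------------------------------
# primitive ops with explicit backward rules

def _gelu(x):
    # tanh approximation (fast elementwise path; matches BERT's gelu_new)
    x2 = x * x
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + _GELU_A * x2 * x)))


def _gelu_grad(x):
    x2 = x * x
    t = np.tanh(_GELU_C * (x + _GELU_A * x2 * x))
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * _GELU_C * (1.0 + 3.0 * _GELU_A * x2)


def _ln_fwd(x, g, b, eps=1e-12):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = (dxhat - dxhat.mean(-1, keepdims=True)
          - xhat * (dxhat * xhat).mean(-1, keepdims=True)) * inv
    return dx, dg.astype(x := dy.dtype), db.astype(x)


def _linear_fwd(x, w, b):
    # flatten leading dims so BLAS sees one large GEMM instead of B small ones
    y = x.reshape(-1, x.shape[-1]) @ w
    y += b
    return y.reshape(x.shape[:-1] + (w.shape[1],))


def _linear_bwd(dy, x, w):
    dy2 = dy.reshape(-1, dy.shape[-1])
    x2 = x.reshape(-1, x.shape[-1])
    dx = (dy2 @ w.T).reshape(x.shape)
    dw = x2.T @ dy2
    db = dy2.sum(axis=0)
    return dx, dw, db


def log_softmax(z):
    m = z.max(-1, keepdims=True)
    s = z - m
    return s - np.log(np.exp(s).sum(-1, keepdims=True))


# ---------------------------------------------------------------------------
# forward / backward through the full encoder

def forward(params: Dict[str, np.ndarray], cfg, ids: np.ndarray,
            attn_mask: Optional[np.ndarray] = None, train: bool = False,
            drop_rng: Optional[np.random.Generator] = None,
            want_cache: bool = False):
    """Compute per-position vocabulary log-probabilities.

    ids: (B, T) int token ids; attn_mask: (B, T) with 1 = real token, 0 = PAD.
    Returns (log_probs, cache); cache is None unless ``want_cache``.
    """
    B, T = ids.shape
    if T > cfg.max_positions:
        raise ValueError(f"sequence length {T} exceeds max_positions {cfg.max_positions}")
    if attn_mask is None:
        attn_mask = np.ones((B, T), dtype=DTYPE)
    nh = cfg.num_heads
    hd = cfg.hidden_size // nh
    scale = 1.0 / math.sqrt(hd)
    p_drop = cfg.dropout if train else 0.0

    def dropout(x):
        if p_drop <= 0.0:
            return x, None
        keep = (drop_rng.random(x.shape, dtype=np.float32) >= p_drop).astype(DTYPE) / DTYPE(1.0 - p_drop)
        return x * keep, keep

    key_bias = ((1.0 - attn_mask)[:, None, None, :] * _NEG).astype(DTYPE)

    x0 = params["emb_tok"][ids] + params["emb_pos"][:T][None, :, :]
    x, emb_ln_cache = _ln_fwd(x0, params["emb_ln_g"], params["emb_ln_b"])
    x, emb_keep = dropout(x)

    layer_caches: List[dict] = []
    for i in range(cfg.num_layers):
        p = f"l{i}_"
        x_in = x
        q = _linear_fwd(x, params[p + "wq"], params[p + "bq"])
        k = _linear_fwd(x, params[p + "wk"], params[p + "bk"])
        v = _linear_fwd(x, params[p + "wv"], params[p + "bv"])
        qh = q.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        kh = k.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        vh = v.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale + key_bias
        scores -= scores.max(-1, keepdims=True)
        ex = np.exp(scores)
        attn = ex / ex.sum(-1, keepdims=True)
        ctx = (attn @ vh).transpose(0, 2, 1, 3).reshape(B, T, cfg.hidden_size)
        attn_out = _linear_fwd(ctx, params[p + "wo"], params[p + "bo"])
        attn_out, attn_keep = dropout(attn_out)
        x1, attn_ln_cache = _ln_fwd(x_in + attn_out, params[p + "attn_ln_g"], params[p + "attn_ln_b"])

        h1 = _linear_fwd(x1, params[p + "w1"], params[p + "b1"])
        gact = _gelu(h1)
        ffn = _linear_fwd(gact, params[p + "w2"], params[p + "b2"])
        ffn, ffn_keep = dropout(ffn)
        x2, ffn_ln_cache = _ln_fwd(x1 + ffn, params[p + "ffn_ln_g"], params[p + "ffn_ln_b"])

        if want_cache:
            layer_caches.append(dict(
                x_in=x_in, qh=qh, kh=kh, vh=vh, attn=attn, ctx=ctx,
                attn_keep=attn_keep, attn_ln_cache=attn_ln_cache,
                x1=x1, h1=h1, gact=gact, ffn_keep=ffn_keep, ffn_ln_cache=ffn_ln_cache,
            ))
        x = x2

    hh_pre = _linear_fwd(x, params["head_w"], params["head_b"])
    hh = _gelu(hh_pre)
    hn, head_ln_cache = _ln_fwd(hh, params["head_ln_g"], params["head_ln_b"])
    logits = _linear_fwd(hn, params["out_w"], params["out_b"])
    log_probs = log_softmax(logits)

    cache = None
    if want_cache:
        cache = dict(
            ids=ids, T=T, nh=nh, hd=hd, scale=scale,
            emb_ln_cache=emb_ln_cache, emb_keep=emb_keep,
            layers=layer_caches, x_final=x,
            hh_pre=hh_pre, head_ln_cache=head_ln_cache, hn=hn,
            log_probs=log_probs,
        )
    return log_probs, cache


def loss_and_grads(params: Dict[str, np.ndarray], cfg, ids: np.ndarray,
                   attn_mask: np.ndarray, labels: np.ndarray,
                   drop_rng: Optional[np.random.Generator] = None):
    """Masked-token cross-entropy and gradients for all parameters.

    labels: (B, T) int with -100 at positions that do not contribute.
    """
    log_probs, cache = forward(params, cfg, ids, attn_mask, train=True,
                               drop_rng=drop_rng, want_cache=True)
    B, T, V = log_probs.shape
    sel = labels >= 0
    n_lab = int(sel.sum())
    if n_lab == 0:
        raise ValueError("no labeled positions in batch")
    probs = np.exp(log_probs)
    loss = float(-log_probs[sel, labels[sel]].mean())

    dlogits = np.zeros_like(log_probs)
    dlogits[sel] = probs[sel]
    dlogits[sel, labels[sel]] -= 1.0
    dlogits /= n_lab

    grads: Dict[str, np.ndarray] = {}
    nh, hd, scale = cache["nh"], cache["hd"], cache["scale"]

    dhn, grads["out_w"], grads["out_b"] = _linear_bwd(dlogits, cache["hn"], params["out_w"])
    dhh, grads["head_ln_g"], grads["head_ln_b"] = _ln_bwd(dhn, cache["head_ln_cache"])
    dhh_pre = dhh * _gelu_grad(cache["hh_pre"])
    dx, grads["head_w"], grads["head_b"] = _linear_bwd(dhh_pre, cache["x_final"], params["head_w"])

    for i in reversed(range(cfg.num_layers)):
        p = f"l{i}_"
        lc = cache["layers"][i]
        dres2, grads[p + "ffn_ln_g"], grads[p + "ffn_ln_b"] = _ln_bwd(dx, lc["ffn_ln_cache"])
        dffn = dres2 if lc["ffn_keep"] is None else dres2 * lc["ffn_keep"]
        dgact, grads[p + "w2"], grads[p + "b2"] = _linear_bwd(dffn, lc["gact"], params[p + "w2"])
        dh1 = dgact * _gelu_grad(lc["h1"])
        dx1_ffn, grads[p + "w1"], grads[p + "b1"] = _linear_bwd(dh1, lc["x1"], params[p + "w1"])
        dx1 = dres2 + dx1_ffn

        dres1, grads[p + "attn_ln_g"], grads[p + "attn_ln_b"] = _ln_bwd(dx1, lc["attn_ln_cache"])
        dattn_out = dres1 if lc["attn_keep"] is None else dres1 * lc["attn_keep"]
        dctx, grads[p + "wo"], grads[p + "bo"] = _linear_bwd(dattn_out, lc["ctx"], params[p + "wo"])
        dctxh = dctx.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)
        attn, vh, qh, kh = lc["attn"], lc["vh"], lc["qh"], lc["kh"]
        dattn = dctxh @ vh.transpose(0, 1, 3, 2)
        dvh = attn.transpose(0, 1, 3, 2) @ dctxh
        dscores = (dattn - (dattn * attn).sum(-1, keepdims=True)) * attn
        dqh = (dscores @ kh) * scale
        dkh = (dscores.transpose(0, 1, 3, 2) @ qh) * scale
        dq = dqh.transpose(0, 2, 1, 3).reshape(B, T, cfg.hidden_size)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B, T, cfg.hidden_size)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B, T, cfg.hidden_size)
        x_in = lc["x_in"]
        dx_q, grads[p + "wq"], grads[p + "bq"] = _linear_bwd(dq, x_in, params[p + "wq"])
        dx_k, grads[p + "wk"], grads[p + "bk"] = _linear_bwd(dk, x_in, params[p + "wk"])
        dx_v, grads[p + "wv"], grads[p + "bv"] = _linear_bwd(dv, x_in, params[p + "wv"])
        dx = dres1 + dx_q + dx_k + dx_v

    if cache["emb_keep"] is not None:
        dx = dx * cache["emb_keep"]
    dx0, grads["emb_ln_g"], grads["emb_ln_b"] = _ln_bwd(dx, cache["emb_ln_cache"])
    demb_tok = np.zeros_like(params["emb_tok"])
    np.add.at(demb_tok, cache["ids"], dx0)
    grads["emb_tok"] = demb_tok
    demb_pos = np.zeros_like(params["emb_pos"])
    demb_pos[:T] = dx0.sum(0)
    grads["emb_pos"] = demb_pos
    return loss, grads


# ---------------------------------------------------------------------------
# optimizer

class AdamW:
    """Decoupled-weight-decay Adam with linear warmup then linear decay."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float, total_steps: int,
                 warmup_fraction: float = 0.1, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.lr = lr
        self.total_steps = max(1, total_steps)
        self.warmup_steps = max(1, int(round(warmup_fraction * self.total_steps)))
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def current_lr(self) -> float:
        t = self.t
        if t < self.warmup_steps:
            return self.lr * (t + 1) / self.warmup_steps
        frac = (self.total_steps - t) / max(1, self.total_steps - self.warmup_steps)
        return self.lr * max(0.0, frac)

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        lr = self.current_lr()
        b1, b2 = self.betas
        self.t += 1
        t = self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if params[k].ndim >= 2 and self.weight_decay > 0:
                upd = upd + self.weight_decay * params[k]
            params[k] -= DTYPE(lr) * upd.astype(DTYPE)
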