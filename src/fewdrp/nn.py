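"""Layers, initialisers and the Adam optimiser on flat parameter dicts.

Parameters live in a flat ``dict[str, Tensor]`` keyed by dotted names
(``"cell.gcn0.W"``).  All layer functions are pure: they read parameters
from the dict and return new tensors, which is what lets MAML thread
adapted (non-leaf) parameter copies through the same forward code.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


# ----------------------------------------------------------------------
# initialisation
# ----------------------------------------------------------------------

def glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


def init_dense(params: dict, name: str, rng, d_in: int, d_out: int) -> None:
    params[f"{name}.W"] = Tensor(glorot(rng, d_in, d_out))
    params[f"{name}.b"] = Tensor(np.zeros(d_out))


def init_layer_norm(params: dict, name: str, d: int) -> None:
    params[f"{name}.g"] = Tensor(np.ones(d))
    params[f"{name}.b"] = Tensor(np.zeros(d))


# ----------------------------------------------------------------------
# layers
# ----------------------------------------------------------------------

def dense(x: Tensor, params: dict, name: str) -> Tensor:
    return x @ params[f"{name}.W"] + params[f"{name}.b"]


def layer_norm(x: Tensor, params: dict, name: str, eps: float = 1e-5) -> Tensor:
    return ad.layer_norm_core(x, eps) * params[f"{name}.g"] + params[f"{name}.b"]


def dropout(x: Tensor, rate: float, rng, train: bool) -> Tensor:
    if not train or rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * Tensor(keep)


def ffn(x: Tensor, params: dict, name: str) -> Tensor:
    """Two-layer feed-forward block with ReLU."""
    return dense(ad.relu(dense(x, params, f"{name}.l1")), params, f"{name}.l2")


def init_ffn(params: dict, name: str, rng, d_in: int, d_hidden: int, d_out: int) -> None:
    init_dense(params, f"{name}.l1", rng, d_in, d_hidden)
    init_dense(params, f"{name}.l2", rng, d_hidden, d_out)


def init_attention(params: dict, name: str, rng, d: int) -> None:
    for proj in ("q", "k", "v", "o"):
        init_dense(params, f"{name}.{proj}", rng, d, d)


def split_heads(x: Tensor, n_heads: int) -> Tensor:
    """[B, T, d] -> [B, H, T, d/H]"""
    B, T, d = x.shape
    return ad.transpose(ad.reshape(x, (B, T, n_heads, d // n_heads)), (0, 2, 1, 3))


def merge_heads(x: Tensor) -> Tensor:
    """[B, H, T, dh] -> [B, T, H*dh]"""
    B, H, T, dh = x.shape
    return ad.reshape(ad.transpose(x, (0, 2, 1, 3)), (B, T, H * dh))


def multihead_attention(params: dict, name: str, q_in: Tensor, kv_in: Tensor,
                        n_heads: int, bias: Tensor | None = None):
    """Scaled dot-product attention over [B, T, d] token matrices.

    ``bias`` (optional) is added to the pre-softmax logits and must be
    broadcastable to [B, H, Tq, Tk] — used for the structural encodings of
    the drug branch.  Returns (output [B, Tq, d], probs [B, H, Tq, Tk]).
    """
    q = split_heads(dense(q_in, params, f"{name}.q"), n_heads)
    k = split_heads(dense(kv_in, params, f"{name}.k"), n_heads)
    v = split_heads(dense(kv_in, params, f"{name}.v"), n_heads)
    dh = q.shape[-1]
    logits = (q @ ad.swap_last(k)) / float(np.sqrt(dh))
    if bias is not None:
        logits = logits + bias
    probs = ad.softmax(logits, axis=-1)
    out = dense(merge_heads(probs @ v), params, f"{name}.o")
    return out, probs


def init_transformer_block(params: dict, name: str, rng, d: int, d_ffn: int,
                           zero_out: bool = False) -> None:
    """``zero_out`` zeroes the block's output projections so the residual
    stream starts as the identity (the block fades in through training —
    keeps pathway tokens local until mixing is actually useful)."""
    init_attention(params, f"{name}.attn", rng, d)
    init_layer_norm(params, f"{name}.ln1", d)
    init_layer_norm(params, f"{name}.ln2", d)
    init_ffn(params, f"{name}.ffn", rng, d, d_ffn, d)
    if zero_out:
        params[f"{name}.attn.o.W"] = Tensor(np.zeros((d, d)))
        params[f"{name}.ffn.l2.W"] = Tensor(np.zeros((d_ffn, d)))


def transformer_block(params: dict, name: str, x: Tensor, n_heads: int,
                      bias: Tensor | None = None, drop: float = 0.0,
                      rng=None, train: bool = False):
    """Pre-norm transformer block; returns (tokens, attention probs)."""
    xn = layer_norm(x, params, f"{name}.ln1")
    a, probs = multihead_attention(params, f"{name}.attn", xn, xn,
                                   n_heads, bias=bias)
    x = x + dropout(a, drop, rng, train)
    f = ffn(layer_norm(x, params, f"{name}.ln2"), params, f"{name}.ffn")
    x = x + dropout(f, drop, rng, train)
    return x, probs


# ----------------------------------------------------------------------
# parameter-dict helpers
# ----------------------------------------------------------------------

def subset(params: dict, prefix: str) -> dict:
    return {k: v for k, v in params.items() if k.startswith(prefix)}


def detach_all(params: dict) -> dict:
    return {k: ad.detach(v) for k, v in params.items()}


# ----------------------------------------------------------------------
# optimiser
# ----------------------------------------------------------------------

class Adam:
    """Adam on a flat parameter dict; returns fresh leaf tensors each step."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                out[k] = Tensor(p.data)
                continue
            g = g.data if isinstance(g, Tensor) else np.asarray(g)
            m = self.m.get(k, np.zeros_like(p.data))
            v = self.v.get(k, np.zeros_like(p.data))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self.m[k], self.v[k] = m, v
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            out[k] = Tensor(p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out
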