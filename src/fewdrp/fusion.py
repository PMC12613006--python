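"""Cross-attention fusion of pathway and drug embeddings and the
feed-forward response predictor.

The P pathway tokens and the single drug token are concatenated (drug token
last, row index P), jointly attended, fused and passed through two
feed-forward networks to a scalar LN_IC50 prediction.  The drug-token
attention row over pathway columns is the explainer's pathway-importance
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class FusionState:
    """Intermediate fusion tensors for one (sample batch, drug) pair."""

    H: Tensor                    # [S, P+1, n_e] concatenated tokens
    attention: Tensor | None = None  # [S, heads, P+1, P+1]
    H_prime: Tensor | None = None    # [S, P+1, n_e]

    @property
    def n_pathways(self) -> int:
        return self.H.shape[1] - 1


def init_predictor_params(params: dict, rng, n_e: int, d_ffn: int | None = None) -> None:
    d_ffn = d_ffn or 2 * n_e
    nn.init_attention(params, "pred.attn", rng, n_e)
    nn.init_ffn(params, "pred.ffn1", rng, n_e, d_ffn, n_e)
    nn.init_ffn(params, "pred.ffn2", rng, n_e, d_ffn, 1)


def concat_embeddings(cell: Tensor, drug: Tensor) -> FusionState:
    """Stack pathway tokens [S, P, n_e] and a drug token (appended last)."""
    S, P, n_e = cell.shape
    if drug.shape[-1] != n_e:
        raise ValueError(f"embedding width mismatch: cell {n_e}, drug {drug.shape[-1]}")
    drug_tok = ad.broadcast_to(ad.reshape(drug, (1, 1, n_e)), (S, 1, n_e))
    return FusionState(H=ad.concat([cell, drug_tok], axis=1))


def cross_attention(state: FusionState, params: dict, n_heads: int = 4,
                    drop: float = 0.0, rng=None, train: bool = False) -> FusionState:
    """Joint multi-head attention over the P+1 tokens.

    Q, K, V are linear maps of H; rows of each head's attention matrix sum
    to 1; head outputs are concatenated and projected.  The attention
    probabilities are retained for the explainer.
    """
    out, probs = nn.multihead_attention(params, "pred.attn", state.H, state.H,
                                        n_heads)
    state.attention = probs
    state.H_prime = nn.dropout(out, drop, rng, train)
    return state


def predict_response(state: FusionState, params: dict,
                     fusion_mode: str = "mean") -> Tensor:
    """Fuse tokens and regress LN_IC50; returns predictions [S].

    ``fusion_mode``: "mean" averages the P+1 transformed tokens;
    "drug_token" uses only the drug token's attended representation.
    """
    if state.H_prime is None:
        raise ValueError("run cross_attention before predict_response")
    if fusion_mode == "mean":
        fused = ad.tmean(state.H_prime, axis=1)      # [S, n_e]
    elif fusion_mode == "drug_token":
        fused = state.H_prime[:, -1]                 # [S, n_e]
    else:
        raise ValueError(f"unknown fusion mode {fusion_mode!r}")
    z_cd = nn.ffn(fused, params, "pred.ffn1")        # joint representation
    y = nn.ffn(z_cd, params, "pred.ffn2")            # [S, 1]
    return ad.reshape(y, (y.shape[0],))


def drug_pathway_attention(state: FusionState) -> np.ndarray:
    """Head-averaged attention paid by the drug token to each pathway.

    Returns a [S, P] array of non-negative weights; each row sums to at
    most 1 (the remainder is the drug token's self-attention).
    """
    if state.attention is None:
        raise ValueError("run cross_attention first")
    probs = state.attention.data          # [S, H, P+1, P+1]
    drug_row = probs[:, :, -1, :-1]       # attention from drug token to pathways
    return drug_row.mean(axis=1)
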