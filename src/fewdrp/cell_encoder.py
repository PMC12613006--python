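"""Cell-line branch: residual GCN over the gene network, pathway-masked
sparse aggregation, and self-attention over pathway tokens.

The sparse layer is the interpretability anchor of the branch: each pathway
unit sees only its member genes, enforced by multiplying the weight matrix
by the binary membership mask in *every* forward pass, so no optimiser step
can leak weight onto non-member genes.
"""

from __future__ import annotations

import logging

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .pathway_network import PathwayCollection

logger = logging.getLogger(__name__)

N_GCN_LAYERS = 3  # 3-hop receptive field


def build_pathway_mask(pathways: PathwayCollection, gene_ids: list[str]) -> np.ndarray:
    """Binary [P, n] membership mask; errors on genes missing from the network."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    mask = np.zeros((len(pathways), len(gene_ids)), dtype=np.float64)
    for p, (name, genes) in enumerate(pathways.pathways):
        for g in genes:
            if g not in idx:
                raise ValueError(f"gene {g!r} of pathway {name!r} absent from gene list")
            mask[p, idx[g]] = 1.0
    return mask


def init_cell_params(params: dict, rng, n_omics: int, hidden: int, n_e: int,
                     mask: np.ndarray, heads: int, n_blocks: int = 1) -> None:
    P, n = mask.shape
    nn.init_dense(params, "cell.in", rng, n_omics, hidden)
    for i in range(N_GCN_LAYERS):
        nn.init_dense(params, f"cell.gcn{i}", rng, hidden, hidden)
    # sparse gene->pathway weights, scaled by pathway size so aggregates stay O(1)
    W = rng.normal(0.0, 1.0, size=(P, n)) * mask
    sizes = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
    params["cell.sparse.W"] = Tensor(W / np.sqrt(sizes))
    # per-pathway linear maps (hidden -> n_e)
    limit = np.sqrt(6.0 / (hidden + n_e))
    params["cell.emb.W"] = Tensor(rng.uniform(-limit, limit, size=(P, hidden, n_e)))
    params["cell.emb.b"] = Tensor(np.zeros((P, n_e)))
    for b in range(n_blocks):
        nn.init_transformer_block(params, f"cell.blk{b}", rng, n_e, 2 * n_e,
                                  zero_out=True)
    nn.init_layer_norm(params, "cell.lnf", n_e)


def gcn_forward(x, adj_norm_self: np.ndarray, params: dict,
                drop: float = 0.0, rng=None, train: bool = False) -> Tensor:
    """Three residual graph-convolution layers.

    ``x``: [S, n, n_omics] imputed omics features; ``adj_norm_self``:
    symmetric-normalised adjacency with self-loops.  Each layer computes
    ``relu(Ã H W + b) + H`` (residual added post-activation).
    """
    x = ad.as_tensor(x)
    sparse_adj = hasattr(adj_norm_self, "tocsr")
    A = adj_norm_self if sparse_adj else Tensor(adj_norm_self)
    h = nn.dense(x, params, "cell.in")
    for i in range(N_GCN_LAYERS):
        hw = nn.dense(h, params, f"cell.gcn{i}")
        conv = ad.spmm(A, hw) if sparse_adj else A @ hw
        h = ad.relu(conv) + h
        h = nn.dropout(h, drop, rng, train)
    return h


def sparse_aggregate(gene_features: Tensor, params: dict, mask: np.ndarray) -> Tensor:
    """Pathway-masked aggregation: [S, n, h] -> [S, P, n_e].

    Pathway ``p``'s output depends only on genes with ``mask[p, g] = 1``.
    """
    if np.any(mask.sum(axis=1) == 0):
        logger.warning("pathway mask contains empty rows; their outputs are bias-only")
    W = params["cell.sparse.W"] * Tensor(mask)   # re-masked every call
    agg = W @ gene_features                      # [P,n] @ [S,n,h] -> [S,P,h]
    S, P, h = agg.shape
    n_e = params["cell.emb.W"].shape[-1]
    out = ad.reshape(agg, (S, P, 1, h)) @ params["cell.emb.W"]  # [S,P,1,n_e]
    return ad.reshape(out, (S, P, n_e)) + params["cell.emb.b"]


def pathway_self_attention(pathway_features: Tensor, params: dict, heads: int,
                           n_blocks: int = 1, drop: float = 0.0, rng=None,
                           train: bool = False):
    """Transformer block(s) over the P pathway tokens.

    Returns (embedding [S, P, n_e], attention probs of the last block
    [S, H, P, P]) — the probabilities are retained for inspection.
    """
    z = pathway_features
    probs = None
    for b in range(n_blocks):
        z, probs = nn.transformer_block(params, f"cell.blk{b}", z, heads,
                                        drop=drop, rng=rng, train=train)
    z = nn.layer_norm(z, params, "cell.lnf")
    return z, probs


def encode_cell(x, adj_norm_self: np.ndarray, params: dict, mask: np.ndarray,
                heads: int, n_blocks: int = 1, drop: float = 0.0, rng=None,
                train: bool = False):
    """Full cell branch: omics [S, n, n_o] -> pathway embedding [S, P, n_e]."""
    h = gcn_forward(x, adj_norm_self, params, drop=drop, rng=rng, train=train)
    z = sparse_aggregate(h, params, mask)
    z = nn.dropout(z, drop, rng, train)
    return pathway_self_attention(z, params, heads, n_blocks=n_blocks,
                                  drop=drop, rng=rng, train=train)
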