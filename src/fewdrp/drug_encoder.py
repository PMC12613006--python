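"""Drug branch: a slim graph transformer over molecular graphs.

Atom tokens carry summed categorical-attribute embeddings plus a degree
(centrality) embedding; attention logits are biased additively by a
shortest-path (spatial) table and a bond-feature (edge) term; a dedicated
global readout token attending to all atoms produces the drug embedding.
Includes scaled-down lipophilicity pretraining of the scalar output head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .constants import ATOM_FEATURE_DIMS, BOND_FEATURE_DIMS, SPD_UNREACHABLE
from .drug_graphs import MolecularGraph
from .utils import rng_for


@dataclass
class DrugEncoderConfig:
    d_model: int = 80
    n_layers: int = 6
    n_heads: int = 8
    n_e: int = 32            # output embedding width (matched to cell branch)
    max_degree: int = 8      # centrality table cap
    max_spd: int = 8         # spatial buckets 0..max_spd, then clipped
    dropout: float = 0.1

    # derived bucket indices of the spatial bias table
    @property
    def bucket_unreachable(self) -> int:
        return self.max_spd + 1

    @property
    def bucket_global(self) -> int:
        return self.max_spd + 2

    @property
    def n_spatial_buckets(self) -> int:
        return self.max_spd + 3


def init_drug_params(params: dict, rng, cfg: DrugEncoderConfig) -> None:
    d, H = cfg.d_model, cfg.n_heads
    for k, dim in enumerate(ATOM_FEATURE_DIMS):
        params[f"drug.atom{k}.E"] = Tensor(rng.normal(0, 0.1, size=(dim, d)))
    params["drug.centrality.E"] = Tensor(
        rng.normal(0, 0.1, size=(cfg.max_degree + 1, d)))
    params["drug.spatial.B"] = Tensor(
        rng.normal(0, 0.1, size=(cfg.n_spatial_buckets, H)))
    for k, dim in enumerate(BOND_FEATURE_DIMS):
        params[f"drug.edge{k}.E"] = Tensor(rng.normal(0, 0.1, size=(dim, H)))
    params["drug.gtok"] = Tensor(rng.normal(0, 0.1, size=(1, d)))
    for b in range(cfg.n_layers):
        nn.init_transformer_block(params, f"drug.blk{b}", rng, d, 2 * d)
    nn.init_layer_norm(params, "drug.lnf", d)
    nn.init_dense(params, "drug.out", rng, d, cfg.n_e)
    nn.init_dense(params, "drug.head", rng, cfg.n_e, 1)  # pretraining scalar head


def structural_encodings(graph: MolecularGraph, cfg: DrugEncoderConfig):
    """Deterministic index tensors for the three structural encodings.

    Returns (centrality index [m], spatial bucket matrix [m+1, m+1] covering
    the global token at position 0, and per-bond-attribute index matrices
    [m+1, m+1] with a bond mask).
    """
    m = graph.n_atoms
    degree = np.zeros(m, dtype=np.int64)
    src = graph.bond_edges[0]
    np.add.at(degree, src, 1)
    centrality = np.minimum(degree, cfg.max_degree)

    spatial = np.empty((m + 1, m + 1), dtype=np.int64)
    spatial[:] = cfg.bucket_global
    spd = np.minimum(np.where(graph.spd == SPD_UNREACHABLE,
                              cfg.bucket_unreachable, graph.spd), cfg.max_spd)
    spd[graph.spd == SPD_UNREACHABLE] = cfg.bucket_unreachable
    spatial[1:, 1:] = spd
    spatial[0, 0] = 0  # global token to itself: distance-0 bucket

    bond_mask = np.zeros((m + 1, m + 1), dtype=np.float64)
    edge_idx = [np.zeros((m + 1, m + 1), dtype=np.int64)
                for _ in BOND_FEATURE_DIMS]
    for e in range(graph.bond_edges.shape[1]):
        i, j = graph.bond_edges[0, e] + 1, graph.bond_edges[1, e] + 1
        bond_mask[i, j] = 1.0
        for k in range(len(BOND_FEATURE_DIMS)):
            edge_idx[k][i, j] = graph.bond_features[e, k]
    return centrality, spatial, (edge_idx, bond_mask)


def _attention_bias(params: dict, cfg: DrugEncoderConfig, spatial: np.ndarray,
                    edge_encoding) -> Tensor:
    """Additive attention-bias tensor [1, H, T, T]."""
    T = spatial.shape[0]
    H = cfg.n_heads
    bias = ad.reshape(ad.take(params["drug.spatial.B"], spatial.ravel()),
                      (T, T, H))
    edge_idx, bond_mask = edge_encoding
    mask_t = Tensor(bond_mask[:, :, None])
    for k, idx in enumerate(edge_idx):
        contrib = ad.reshape(ad.take(params[f"drug.edge{k}.E"], idx.ravel()),
                             (T, T, H))
        bias = bias + contrib * mask_t
    return ad.reshape(ad.transpose(bias, (2, 0, 1)), (1, H, T, T))


def graphormer_forward(graph: MolecularGraph, params: dict,
                       cfg: DrugEncoderConfig, rng=None, train: bool = False,
                       return_tokens: bool = False):
    """Encode one molecule into a drug embedding z^d of width ``n_e``.

    Invariant to atom relabeling: all inputs are per-atom or per-pair, and
    the readout is the global token.
    """
    m = graph.n_atoms
    centrality, spatial, edge_enc = structural_encodings(graph, cfg)

    tokens = ad.take(params["drug.atom0.E"], graph.atom_features[:, 0])
    for k in range(1, len(ATOM_FEATURE_DIMS)):
        tokens = tokens + ad.take(params[f"drug.atom{k}.E"],
                                  graph.atom_features[:, k])
    tokens = tokens + ad.take(params["drug.centrality.E"], centrality)
    x = ad.reshape(ad.concat([params["drug.gtok"], tokens], axis=0),
                   (1, m + 1, cfg.d_model))

    bias = _attention_bias(params, cfg, spatial, edge_enc)
    for b in range(cfg.n_layers):
        x, _ = nn.transformer_block(params, f"drug.blk{b}", x, cfg.n_heads,
                                    bias=bias, drop=cfg.dropout, rng=rng,
                                    train=train)
    x = nn.layer_norm(x, params, "drug.lnf")
    z = ad.reshape(nn.dense(x[:, 0], params, "drug.out"), (cfg.n_e,))  # global readout token
    if return_tokens:
        return z, x
    return z


def logp_head(z: Tensor, params: dict) -> Tensor:
    """Scalar lipophilicity prediction from a drug embedding."""
    return ad.reshape(nn.dense(ad.reshape(z, (1, -1)), params, "drug.head"), ())


def warmup_cosine_lr(step: int, total_steps: int, warmup_steps: int,
                     peak_lr: float, floor: float = 0.0) -> float:
    """Linear warmup to ``peak_lr`` then cosine decay to ``floor``."""
    if warmup_steps > 0 and step < warmup_steps:
        return peak_lr * (step + 1) / warmup_steps
    frac = (step - warmup_steps) / max(1, total_steps - warmup_steps)
    return floor + 0.5 * (peak_lr - floor) * (1.0 + np.cos(np.pi * min(frac, 1.0)))


@dataclass
class PretrainConfig:
    epochs: int = 500
    batch_size: int = 32
    warmup_epochs: int = 30
    peak_lr: float = 1e-3
    encoder: DrugEncoderConfig = field(default_factory=DrugEncoderConfig)


#: configuration mirroring the published full-scale pretraining run
PRETRAIN_FULL_SCALE = PretrainConfig(epochs=10_000, batch_size=64,
                                     warmup_epochs=600, peak_lr=5e-7)


def pretrain_logp(molecules: list[MolecularGraph], labels, config: PretrainConfig,
                  seed: int = 0, params: dict | None = None):
    """Fit the drug encoder's scalar head to lipophilicity labels.

    Minimises squared error with Adam under a warmup-then-cosine learning
    rate schedule.  Returns (params, per-epoch mean loss trace).
    """
    labels = np.asarray(labels, dtype=np.float64)
    if len(molecules) != len(labels) or len(molecules) < 2:
        raise ValueError("need >= 2 molecules with matching labels")
    cfg = config.encoder
    rng = rng_for(seed, "pretrain")
    if params is None:
        params = {}
        init_drug_params(params, rng, cfg)
    opt = nn.Adam(lr=config.peak_lr)
    n = len(molecules)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    total = config.epochs * steps_per_epoch
    warm = config.warmup_epochs * steps_per_epoch
    trace, step = [], 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for s in range(steps_per_epoch):
            batch = order[s * config.batch_size:(s + 1) * config.batch_size]
            if batch.size == 0:
                continue
            losses = []
            for i in batch:
                z = graphormer_forward(molecules[i], params, cfg, rng=rng,
                                       train=True)
                pred = logp_head(z, params)
                losses.append((pred - labels[i]) ** 2)
            loss = ad.tmean(ad.concat([ad.reshape(l, (1,)) for l in losses]))
            grads = ad.grad(loss, list(params.values()))
            gdict = dict(zip(params.keys(), grads))
            opt.lr = warmup_cosine_lr(step, total, warm, config.peak_lr)
            params = opt.step(params, gdict)
            epoch_losses.append(loss.item())
            step += 1
        trace.append(float(np.mean(epoch_losses)))
    return params, trace
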