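"""The full drug-response model: cell branch + drug branch + predictor.

``DrugResponseModel`` owns the static structures (gene network, pathway
mask, normalised adjacency, model hyperparameters) while all trainable
state lives in a flat parameter dict, so meta-learning can thread adapted
parameter copies through the same forward code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse import csr_matrix

from . import cell_encoder, drug_encoder, fusion
from .drug_graphs import MolecularGraph
from .drug_encoder import DrugEncoderConfig
from .pathway_network import GeneNetwork, PathwayCollection, normalize_adjacency
from .utils import rng_for, save_checkpoint, load_checkpoint


@dataclass
class ModelConfig:
    hidden: int = 32          # GCN hidden width h
    n_e: int = 32             # pathway/drug embedding width
    cell_heads: int = 4
    cell_blocks: int = 1
    fusion_heads: int = 4
    fusion_mode: str = "mean"  # or "drug_token"
    dropout: float = 0.1
    drug: DrugEncoderConfig = field(default_factory=DrugEncoderConfig)

    def __post_init__(self):
        if isinstance(self.drug, dict):
            self.drug = DrugEncoderConfig(**self.drug)
        self.drug.n_e = self.n_e
        self.drug.dropout = self.dropout

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Small configuration for CPU-scale experiments."""
        cfg = cls(hidden=8, n_e=8, cell_heads=2, fusion_heads=2,
                  dropout=0.05,
                  drug=DrugEncoderConfig(d_model=16, n_layers=2, n_heads=4))
        for k, v in overrides.items():
            setattr(cfg, k, v)
        cfg.drug.n_e = cfg.n_e
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


class DrugResponseModel:
    """Pathway-interpretable few-shot LN_IC50 regressor."""

    def __init__(self, network: GeneNetwork, pathways: PathwayCollection,
                 config: ModelConfig | None = None, n_omics: int = 4):
        self.network = network
        self.pathways = pathways
        self.config = config or ModelConfig()
        self.n_omics = n_omics
        self.mask = cell_encoder.build_pathway_mask(pathways, network.gene_ids)
        # sparse graph operator: GCN cost scales with edges, not n^2
        self.adj_norm_self = csr_matrix(
            normalize_adjacency(network, add_self_loops=True))

    @property
    def n_pathways(self) -> int:
        return self.mask.shape[0]

    # -- parameters ----------------------------------------------------
    def init_params(self, seed: int = 0) -> dict:
        params: dict = {}
        cfg = self.config
        cell_encoder.init_cell_params(params, rng_for(seed, "init", "cell"),
                                      self.n_omics, cfg.hidden, cfg.n_e,
                                      self.mask, cfg.cell_heads, cfg.cell_blocks)
        drug_encoder.init_drug_params(params, rng_for(seed, "init", "drug"),
                                      cfg.drug)
        fusion.init_predictor_params(params, rng_for(seed, "init", "pred"),
                                     cfg.n_e)
        return params

    # -- forward pieces ------------------------------------------------
    def encode_cell(self, params: dict, x: np.ndarray, rng=None,
                    train: bool = False):
        cfg = self.config
        return cell_encoder.encode_cell(
            x, self.adj_norm_self, params, self.mask, cfg.cell_heads,
            n_blocks=cfg.cell_blocks, drop=cfg.dropout if train else 0.0,
            rng=rng, train=train)

    def encode_drug(self, params: dict, graph: MolecularGraph, rng=None,
                    train: bool = False):
        return drug_encoder.graphormer_forward(graph, params, self.config.drug,
                                               rng=rng, train=train)

    def forward(self, params: dict, x: np.ndarray, graph: MolecularGraph,
                rng=None, train: bool = False):
        """Predict LN_IC50 for a batch of samples against one drug.

        ``x``: imputed omics [S, n, n_omics].  Returns (predictions [S],
        FusionState with retained cross-attention, cell attention probs).
        """
        cfg = self.config
        z_c, cell_attn = self.encode_cell(params, x, rng=rng, train=train)
        z_d = self.encode_drug(params, graph, rng=rng, train=train)
        state = fusion.concat_embeddings(z_c, z_d)
        state = fusion.cross_attention(state, params, cfg.fusion_heads,
                                       drop=cfg.dropout if train else 0.0,
                                       rng=rng, train=train)
        preds = fusion.predict_response(state, params, cfg.fusion_mode)
        return preds, state, cell_attn

    # -- persistence ---------------------------------------------------
    def save(self, path, params: dict) -> None:
        save_checkpoint(path, params, {"model": self.config.to_dict(),
                                       "n_omics": self.n_omics})

    @staticmethod
    def load_params(path) -> tuple[dict, dict]:
        return load_checkpoint(path)
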