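"""Bundles the static inputs a trained model needs at run time:
gene network, pathway collection, imputed per-sample omics profiles and
per-drug molecular graphs, plus the response records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drug_graphs import MolecularGraph, smiles_to_graph
from .pathway_network import (GeneNetwork, OmicsProfile, PathwayCollection,
                              normalize_adjacency, propagate_features)
from .task_builder import ResponseRecord, Task, group_tasks


@dataclass
class ResponseDataset:
    network: GeneNetwork
    pathways: PathwayCollection
    profiles: dict[str, OmicsProfile]       # sample_id -> imputed profile
    graphs: dict[str, MolecularGraph]       # drug_id -> molecular graph
    records: list[ResponseRecord] = field(default_factory=list)

    def omics_batch(self, records: list[ResponseRecord]) -> np.ndarray:
        """Stack imputed omics matrices for a record batch: [S, n, n_o]."""
        return np.stack([self.profiles[r.sample_id].values for r in records])

    def drug_graph(self, drug_id: str) -> MolecularGraph:
        return self.graphs[drug_id]

    def tasks(self, min_size: int = 30) -> list[Task]:
        return group_tasks(self.records, min_size=min_size)

    @property
    def n_omics(self) -> int:
        first = next(iter(self.profiles.values()))
        return first.n_channels

    def impute_all(self, iterations: int = 40) -> None:
        """Feature-propagate every profile in place (idempotent)."""
        adj = normalize_adjacency(self.network)
        for sid, prof in self.profiles.items():
            if not prof.observed.all():
                self.profiles[sid] = propagate_features(prof, adj, iterations)

    @classmethod
    def build(cls, network, pathways, profiles, smiles_by_drug: dict[str, str],
              records, impute_iterations: int = 40) -> "ResponseDataset":
        graphs = {d: smiles_to_graph(d, s) for d, s in smiles_by_drug.items()}
        ds = cls(network=network, pathways=pathways,
                 profiles={p.sample_id: p for p in profiles},
                 graphs=graphs, records=list(records))
        ds.impute_all(impute_iterations)
        return ds
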