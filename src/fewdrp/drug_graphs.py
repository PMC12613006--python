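"""SMILES parsing into featurised molecular graphs.

Heavy-atom graphs with nine categorical atom attributes, three bond
attributes (both encoded against the vocabularies in
:mod:`fewdrp.constants`) and an all-pairs unweighted shortest-path matrix
used by the drug encoder's spatial attention bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .constants import (ATOM_FEATURES, ATOM_FEATURE_ORDER, ATOM_FEATURE_DIMS,
                        BOND_FEATURES, BOND_FEATURE_ORDER, BOND_FEATURE_DIMS,
                        SPD_UNREACHABLE, safe_index)

RDLogger.DisableLog("rdApp.*")

SMILES_MAX_LEN = 120


@dataclass
class MolecularGraph:
    drug_id: str
    smiles: str
    atom_features: np.ndarray   # [m, 9] int
    bond_edges: np.ndarray      # [2, 2E] int (both directions)
    bond_features: np.ndarray   # [2E, 3] int
    spd: np.ndarray             # [m, m] int, -1 for unreachable pairs

    def __post_init__(self):
        m = self.atom_features.shape[0]
        if m < 1:
            raise ValueError("molecule must have at least one heavy atom")
        if self.spd.shape != (m, m):
            raise ValueError("spd shape mismatch")
        if not np.array_equal(self.spd, self.spd.T) or np.any(np.diag(self.spd) != 0):
            raise ValueError("spd must be symmetric with zero diagonal")

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    def to_dict(self) -> dict:
        return {"drug_id": self.drug_id, "smiles": self.smiles,
                "atom_features": self.atom_features, "bond_edges": self.bond_edges,
                "bond_features": self.bond_features, "spd": self.spd}

    @classmethod
    def from_dict(cls, d: dict) -> "MolecularGraph":
        return cls(drug_id=str(d["drug_id"]), smiles=str(d["smiles"]),
                   atom_features=np.asarray(d["atom_features"], dtype=np.int64),
                   bond_edges=np.asarray(d["bond_edges"], dtype=np.int64),
                   bond_features=np.asarray(d["bond_features"], dtype=np.int64),
                   spd=np.asarray(d["spd"], dtype=np.int64))


def filter_smiles(records, max_len: int = SMILES_MAX_LEN):
    """Keep (drug_id, smiles) records that are short and chemically valid.

    Length must be strictly below ``max_len`` characters and the string must
    parse.  Returns (retained records, rejected [(drug_id, smiles, reason)]).
    """
    retained, rejected = [], []
    for drug_id, smiles in records:
        if len(smiles) >= max_len:
            rejected.append((drug_id, smiles, f"length {len(smiles)} >= {max_len}"))
            continue
        if Chem.MolFromSmiles(smiles) is None:
            rejected.append((drug_id, smiles, "parse failure"))
            continue
        retained.append((drug_id, smiles))
    return retained, rejected


def _atom_feature_vector(atom: Chem.Atom) -> list[int]:
    F = ATOM_FEATURES
    return [
        safe_index(F["atomic_num"], atom.GetAtomicNum()),
        safe_index(F["degree"], atom.GetDegree()),
        safe_index(F["formal_charge"], atom.GetFormalCharge()),
        safe_index(F["hybridization"], str(atom.GetHybridization())),
        safe_index(F["chirality"], str(atom.GetChiralTag())),
        F["is_aromatic"].index(bool(atom.GetIsAromatic())),
        safe_index(F["num_hs"], atom.GetTotalNumHs()),
        safe_index(F["total_valence"], atom.GetTotalValence()),
        F["is_in_ring"].index(bool(atom.IsInRing())),
    ]


def _bond_feature_vector(bond: Chem.Bond) -> list[int]:
    F = BOND_FEATURES
    return [
        safe_index(F["bond_type"], str(bond.GetBondType())),
        F["is_conjugated"].index(bool(bond.GetIsConjugated())),
        safe_index(F["stereo"], str(bond.GetStereo()).replace("STEREO", "STEREO")),
    ]


def smiles_to_graph(drug_id: str, smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a featurised heavy-atom graph.

    Atoms are renumbered to RDKit's canonical order first, so any SMILES
    variant of the same molecule (relabelings, kekulization forms) yields a
    bit-identical graph — order-dependent attributes such as chirality tags
    are always computed on the canonical ordering.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES parse failure for drug {drug_id!r}: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))  # canonical atom order
    m = mol.GetNumAtoms()
    atom_features = np.array([_atom_feature_vector(a) for a in mol.GetAtoms()],
                             dtype=np.int64).reshape(m, len(ATOM_FEATURE_ORDER))
    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        fv = _bond_feature_vector(bond)
        src += [i, j]
        dst += [j, i]
        feats += [fv, fv]
    bond_edges = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    bond_features = (np.array(feats, dtype=np.int64).reshape(-1, 3)
                     if feats else np.zeros((0, 3), dtype=np.int64))
    graph = MolecularGraph(drug_id=drug_id, smiles=smiles,
                           atom_features=atom_features, bond_edges=bond_edges,
                           bond_features=bond_features,
                           spd=np.zeros((m, m), dtype=np.int64))
    graph.spd = shortest_path_matrix(graph)
    return graph


def shortest_path_matrix(graph: MolecularGraph) -> np.ndarray:
    """All-pairs unweighted hop counts; ``-1`` marks disconnected pairs."""
    m = graph.n_atoms
    data = np.ones(graph.bond_edges.shape[1])
    adj = csr_matrix((data, (graph.bond_edges[0], graph.bond_edges[1])),
                     shape=(m, m))
    dist = _csgraph_shortest_path(adj, method="D", unweighted=True, directed=False)
    out = np.where(np.isfinite(dist), dist, SPD_UNREACHABLE).astype(np.int64)
    np.fill_diagonal(out, 0)
    return out


def validate_feature_ranges(graph: MolecularGraph) -> None:
    """Raise if any categorical index exceeds its vocabulary cardinality."""
    for j, dim in enumerate(ATOM_FEATURE_DIMS):
        col = graph.atom_features[:, j]
        if col.min(initial=0) < 0 or col.max(initial=0) >= dim:
            raise ValueError(f"atom feature {ATOM_FEATURE_ORDER[j]} out of range")
    for j, dim in enumerate(BOND_FEATURE_DIMS):
        if graph.bond_features.shape[0] == 0:
            continue
        col = graph.bond_features[:, j]
        if col.min() < 0 or col.max() >= dim:
            raise ValueError(f"bond feature {BOND_FEATURE_ORDER[j]} out of range")
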