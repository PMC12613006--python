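"""Gene networks, pathway collections, multi-omics profiles and
graph-based imputation of missing omics values.

The imputation is iterative feature propagation: missing entries start at
zero, every iteration diffuses values over the symmetrically normalised
adjacency ``D^{-1/2} A D^{-1/2}``, and observed entries are clamped back to
their measured values.  Observed values are therefore preserved bit-exactly
and the iteration converges (the update restricted to the missing block is
a strict contraction whenever each connected component contains at least
one observed value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: fixed omics channel order: expression, CNV, methylation, CRISPR effect
OMICS_CHANNELS = ("E", "C", "D", "P")


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class GeneNetwork:
    """Undirected, unweighted gene–gene interaction network."""

    gene_ids: list[str]
    edges: set[frozenset]
    adjacency: np.ndarray  # [n, n] binary, symmetric, zero diagonal

    def __post_init__(self):
        A = self.adjacency
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.gene_ids):
            raise ValueError("adjacency shape does not match gene list")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1))

    def index_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class PathwayCollection:
    """Ordered list of (name, member-gene set) pairs."""

    pathways: list[tuple[str, frozenset]]

    def __post_init__(self):
        names = [n for n, _ in self.pathways]
        if len(set(names)) != len(names):
            raise ValueError("pathway names must be unique")
        if any(len(g) == 0 for _, g in self.pathways):
            raise ValueError("empty pathway after loading")

    def __len__(self) -> int:
        return len(self.pathways)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.pathways]

    @property
    def gene_universe(self) -> frozenset:
        out: set = set()
        for _, genes in self.pathways:
            out |= genes
        return frozenset(out)

    def members(self, name: str) -> frozenset:
        for n, genes in self.pathways:
            if n == name:
                return genes
        raise KeyError(f"unknown pathway: {name}")


@dataclass
class OmicsProfile:
    """Per-sample gene × omics-channel matrix with an observed mask."""

    sample_id: str
    tissue: str
    values: np.ndarray     # [n, n_o]
    observed: np.ndarray   # [n, n_o] boolean

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values/observed shape mismatch")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise ValueError("observed entries must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class CellGraph:
    """Gene network plus a fully imputed omics profile."""

    network: GeneNetwork
    profile: OmicsProfile

    def __post_init__(self):
        if self.profile.values.shape[0] != self.network.n:
            raise ValueError("profile gene count does not match network")
        if not self.profile.observed.all() and np.isnan(self.profile.values).any():
            raise ValueError("profile must be imputed (no missing entries)")


# ----------------------------------------------------------------------
# loading
# ----------------------------------------------------------------------

def load_gene_sets(path) -> PathwayCollection:
    """Read a GMT file (name, description, member genes, tab-separated)."""
    pathways: list[tuple[str, frozenset]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT line "
                             f"(needs name, description, >=1 gene)")
        name = fields[0]
        seen: dict[str, None] = {}
        for g in fields[2:]:
            if g:
                seen.setdefault(g)
        if not seen:
            raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
        pathways.append((name, frozenset(seen)))
    return PathwayCollection(pathways)


def load_ppi_edges(path) -> list[tuple[str, str]]:
    """Read a two-column (plus optional ignored score) TSV edge list."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two gene-id columns")
    return [(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def build_subnetwork(ppi_edges: list[tuple[str, str]],
                     pathways: PathwayCollection) -> GeneNetwork:
    """Restrict a PPI edge list to the pathway gene universe.

    Genes covered by pathways but absent from the PPI remain in the network
    as isolated (degree-0) nodes, so pathway membership is never silently
    dropped.
    """
    universe = pathways.gene_universe
    if not universe:
        raise ValueError("empty pathway gene universe")
    gene_ids = sorted(universe)
    idx = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    A = np.zeros((n, n), dtype=np.float64)
    edges: set[frozenset] = set()
    for a, b in ppi_edges:
        if a == b or a not in idx or b not in idx:
            continue
        e = frozenset((a, b))
        if e in edges:
            continue
        edges.add(e)
        A[idx[a], idx[b]] = 1.0
        A[idx[b], idx[a]] = 1.0
    return GeneNetwork(gene_ids=gene_ids, edges=edges, adjacency=A)


# ----------------------------------------------------------------------
# feature propagation
# ----------------------------------------------------------------------

def normalize_adjacency(network: GeneNetwork, add_self_loops: bool = False) -> np.ndarray:
    """Symmetric normalisation ``D^{-1/2} A D^{-1/2}``.

    Degree-0 rows/columns are left all-zero instead of dividing by zero.
    With ``add_self_loops`` the GCN convention ``D^{-1/2}(A+I)D^{-1/2}`` is
    returned instead (used by the cell-line encoder, not by imputation).
    """
    A = network.adjacency.copy()
    if add_self_loops:
        A = A + np.eye(network.n)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    return (A * dinv[:, None]) * dinv[None, :]


def _propagation_setup(profile: OmicsProfile, adj_norm: np.ndarray):
    if adj_norm.shape[0] != profile.values.shape[0]:
        raise ValueError("adjacency dimension does not match profile")
    x = np.where(profile.observed, profile.values, 0.0)
    x[~np.isfinite(x)] = 0.0
    return x


def propagate_features(profile: OmicsProfile, adj_norm: np.ndarray,
                       iterations: int = 40) -> OmicsProfile:
    """Impute missing omics entries by clamped diffusion.

    Each iteration applies ``x <- Ã x`` per channel and then resets observed
    entries to their measured values.  Default 40 iterations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    obs, vals = profile.observed, profile.values
    x = _propagation_setup(profile, adj_norm)
    for _ in range(iterations):
        x = adj_norm @ x
        x[obs] = vals[obs]
    return OmicsProfile(sample_id=profile.sample_id, tissue=profile.tissue,
                        values=x, observed=np.ones_like(obs, dtype=bool))


def convergence_series(profile: OmicsProfile, adj_norm: np.ndarray,
                       max_iterations: int = 40) -> list[float]:
    """L2 norm of the full-matrix difference between consecutive iterates."""
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    obs, vals = profile.observed, profile.values
    x = _propagation_setup(profile, adj_norm)
    series = []
    for _ in range(max_iterations):
        x_new = adj_norm @ x
        x_new[obs] = vals[obs]
        series.append(float(np.linalg.norm(x_new - x)))
        x = x_new
    return series


# ----------------------------------------------------------------------
# omics matrix IO
# ----------------------------------------------------------------------

def load_omics_csv(path, sample_id: str, tissue: str,
                   gene_ids: list[str]) -> OmicsProfile:
    """Read one sample's genes × channels CSV (empty cell / NaN = missing).

    Rows are reindexed to ``gene_ids``; genes absent from the file are
    treated as missing in every channel.
    """
    df = pd.read_csv(path, index_col=0)
    df = df.reindex(index=gene_ids, columns=list(OMICS_CHANNELS)[: df.shape[1]])
    values = df.to_numpy(dtype=np.float64)
    observed = np.isfinite(values)
    values = np.where(observed, values, 0.0)
    return OmicsProfile(sample_id=sample_id, tissue=tissue,
                        values=values, observed=observed)
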