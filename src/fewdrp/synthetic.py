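"""Synthetic fixture generation with known ground truth.

Emulates the structure of a drug-sensitivity screen at desk scale: a
scale-free gene network, overlapping pathway gene sets, multi-omics
profiles with realistic per-channel missingness (whole-channel-per-sample
absence plus sparse per-gene dropout), a small valid-SMILES drug library
with planted target pathways, and drug-tissue response tasks whose LN_IC50
follows a planted pathway-activity × drug-potency interaction plus tissue
offsets and noise.  Every piece of latent state used to generate responses
is returned as :class:`GroundTruth`, which is what makes recovery testable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen

from .cell_encoder import build_pathway_mask
from .data import ResponseDataset
from .drug_graphs import filter_smiles, smiles_to_graph
from .pathway_network import (GeneNetwork, OmicsProfile, PathwayCollection,
                              build_subnetwork)
from .task_builder import ResponseRecord, Task, group_tasks
from .utils import rng_for

# Curated library of valid drug-like SMILES (all < 120 characters).  An
# enumerated list avoids generating invalid chemistry without needing any
# external dataset.
SMILES_LIBRARY: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "CC(=O)Nc1ccc(O)cc1", "c1ccc2c(c1)cccc2O", "Clc1ccccc1Cl",
    "CCO", "CCN(CC)CC", "c1ccc(cc1)C(=O)O",
    "OCC(O)CO", "CC(C)NCC(O)c1ccc(O)c(O)c1", "CN1CCC[C@H]1c1cccnc1",
    "CC(N)Cc1ccccc1", "NCCc1ccc(O)c(O)c1", "Oc1ccc(CCN)cc1",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1", "CN(C)CCCN1c2ccccc2Sc2ccccc21",
    "Clc1ccc(cc1)C(c1ccccc1)N1CCN(CCOCCO)CC1",
    "CC(C)Cc1ccccc1", "c1ccc2[nH]ccc2c1", "O=C(O)c1ccccc1O",
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O", "CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1",
    "O=c1[nH]c(=O)c2[nH]cnc2[nH]1",
    "Nc1ncnc2[nH]cnc12", "OC(=O)CC(O)(CC(=O)O)C(=O)O", "NC(CC(=O)O)C(=O)O",
    "NCC(=O)O", "CC(N)C(=O)O", "CC(O)C(N)C(=O)O",
    "N[C@@H](Cc1ccccc1)C(=O)O", "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O",
    "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O",
    "COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O", "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",
    "CC(C)C1CCC(C)CC1O",
    "CC1=CC(=O)CC(C)(C)C1", "CC(=CCCC(=CC=O)C)C", "c1ccsc1",
    "c1ccoc1", "c1cc[nH]c1", "c1ccncc1",
    "c1ccc(nc1)N", "Nc1ccccc1", "Oc1ccccc1",
    "CSc1ccccc1", "FC(F)(F)c1ccccc1", "NS(=O)(=O)c1ccc(N)cc1",
    "CC(=O)c1ccccc1", "O=Cc1ccccc1", "N#Cc1ccccc1",
    "O=[N+]([O-])c1ccccc1", "Ic1ccccc1", "Brc1ccccc1",
    "OCC1OC(O)C(O)C(O)C1O", "CC(C)(C)c1ccc(O)cc1", "CCOC(=O)c1ccccc1N",
    "CN(C)c1ccc(cc1)C(=O)O", "COC(=O)c1ccccc1O", "CC1CCCCN1C",
    "C1CCNCC1", "C1CCOC1", "O=C1CCCCC1",
    "CC(=O)CC(=O)C", "CC(=O)NC1CCCCC1", "Clc1cnc2ccccc2n1",
    "CN1CCN(CC1)c1ccccc1", "COc1ccccc1OC", "Cc1ccc(C)cc1",
    "CC(=O)OCC(COC(C)=O)OC(C)=O", "NC(=O)c1cccnc1", "OCc1ccccc1",
    "CCCCCCCCCC(=O)O", "C(CCCCCCCC(=O)O)CCCCCCCC", "NCCS(=O)(=O)O",
    "OC(=O)C=Cc1ccccc1", "COc1ccc(C=CC(=O)O)cc1",
    "CC(C)=CCc1c(O)cc(O)c2c1oc(-c1ccc(O)cc1)cc2=O",
    "CC(CS)C(=O)N1CCCC1C(=O)O", "CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2)cc1",
    "CC(C)(C)NCC(O)COc1cccc2ccccc12",
    "CCOC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]", "CN1CCCC1CCO",
    "NC(Cc1ccc(O)cc1)C(=O)O",
    "OCC(N)CO", "CC(C)(N)CO", "CNCC(O)c1ccc(O)c(O)c1",
    "CNC(C)Cc1ccccc1", "COc1cc2c(cc1OC)CC(N)C2", "CC(C)(C)OC(=O)NC(Cc1ccccc1)C(=O)O",
    "O=S(=O)(O)c1ccccc1", "CCOCC", "CC#N",
    "CC(Cl)C(=O)O", "ClCC(=O)O", "CC(Br)C(=O)O",
    "OC(=O)c1cc(O)c(O)c(O)c1", "Oc1ccc(cc1)C(=O)c1ccc(O)cc1", "O=C(Nc1ccccc1)c1ccccc1",
    "CN(C)C(=O)c1ccccc1", "CCN(CC)C(=O)c1cccnc1", "Cc1cccc(C)c1NC(=O)CN(CC)CC",
    "CC(=O)Nc1nnc(s1)S(N)(=O)=O", "Nc1nc2ccccc2s1", "Clc1ccc2nc(N)sc2c1",
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",
)


@dataclass
class FixtureConfig:
    n_genes: int = 150
    n_pathways: int = 20
    pathway_size: tuple[int, int] = (6, 14)
    overlap: float = 0.2          # 0 -> pairwise-disjoint pathways
    network_model: str = "scale_free"   # or "small_world"
    ba_m: int = 3                 # scale-free attachment edges
    ws_k: int = 6                 # small-world ring degree
    ws_p: float = 0.1             # small-world rewiring probability
    n_omics: int = 4              # channel order E, C, D, P
    missing_rates: tuple[float, ...] = (0.2050, 0.0055, 0.5400, 0.3997)
    entry_missing_rate: float = 0.05  # per-gene dropout within present channels
    n_drugs: int = 24
    n_target_classes: int = 6     # structural mechanism classes
    n_tissues: int = 3
    samples_per_tissue: int = 40
    driver_fraction: float = 0.3  # fraction of target-pathway genes that drive
    gamma: float = 1.2            # potency x pathway-activity effect size
    tissue_offset_scale: float = 0.4
    noise: float = 0.3            # response noise sigma
    beta0: float = 2.0            # baseline LN_IC50
    nonlinear: bool = False       # add an activity^2 term
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.pathway_size
        if lo < 1 or hi < lo:
            raise ValueError("invalid pathway size range")
        if any(not 0.0 <= r < 1.0 for r in self.missing_rates):
            raise ValueError("missing rates must be in [0, 1)")
        if self.n_genes < hi:
            raise ValueError("pathway size exceeds n_genes")

    def strong_effect(self) -> "FixtureConfig":
        """High signal-to-noise variant for mechanism-recovery studies."""
        return replace(self, gamma=1.5, noise=0.1)


@dataclass
class DrugTruth:
    drug_id: str
    smiles: str
    target_pathway: str
    driver_genes: frozenset
    potency: float


@dataclass
class GroundTruth:
    drugs: dict[str, DrugTruth]
    activities: np.ndarray            # [n_samples, P] latent pathway activity
    sample_ids: list[str]
    pathway_names: list[str]
    tissue_offsets: dict[str, float]
    drivers: dict[str, frozenset]     # pathway -> planted driver genes
    config: FixtureConfig
    classes: "DrugClassModel | None" = None

    def activity(self, sample_id: str, pathway: str) -> float:
        return float(self.activities[self.sample_ids.index(sample_id),
                                     self.pathway_names.index(pathway)])


# ----------------------------------------------------------------------
# network + pathways
# ----------------------------------------------------------------------

def _random_graph(config: FixtureConfig, rng) -> nx.Graph:
    seed = int(rng.integers(2 ** 31))
    if config.network_model == "scale_free":
        return nx.barabasi_albert_graph(config.n_genes, config.ba_m, seed=seed)
    if config.network_model == "small_world":
        return nx.watts_strogatz_graph(config.n_genes, config.ws_k, config.ws_p,
                                       seed=seed)
    raise ValueError(f"unknown network model {config.network_model!r}")


def _grow_pathway(G: nx.Graph, rng, size: int, available: set, overlap: float,
                  gene_name) -> set:
    """Random connected-ish growth from a seed node.

    With overlap 0 only unused genes are eligible; otherwise used genes are
    re-admitted with probability ``overlap``.
    """
    def eligible(n):
        return n in available or (overlap > 0 and rng.random() < overlap)

    pool = [n for n in G.nodes if n in available]
    if not pool:
        pool = list(G.nodes)
    current = {int(rng.choice(pool))}
    frontier = set(G.neighbors(next(iter(current))))
    while len(current) < size:
        cands = [n for n in frontier - current if eligible(n)]
        if not cands:
            rest = [n for n in G.nodes if n not in current and eligible(n)]
            if not rest:
                break
            nxt = int(rng.choice(rest))
        else:
            nxt = int(rng.choice(cands))
        current.add(nxt)
        frontier |= set(G.neighbors(nxt))
    return {gene_name(n) for n in current}


def make_network_and_pathways(config: FixtureConfig):
    """Random network restricted to sampled pathway gene sets.

    Returns (GeneNetwork, PathwayCollection, pathway mask [P, n]).
    """
    rng = rng_for(config.seed, "network")
    G = _random_graph(config, rng)
    width = len(str(config.n_genes))
    gene_name = lambda i: f"G{i:0{width}d}"
    available = set(G.nodes)
    pathways = []
    for p in range(config.n_pathways):
        size = int(rng.integers(config.pathway_size[0],
                                config.pathway_size[1] + 1))
        members = _grow_pathway(G, rng, size, available, config.overlap,
                                gene_name)
        available -= {int(m[1:]) for m in members}
        pathways.append((f"PW{p:03d}", frozenset(members)))
    collection = PathwayCollection(pathways)
    edges = [(gene_name(a), gene_name(b)) for a, b in G.edges]
    network = build_subnetwork(edges, collection)
    mask = build_pathway_mask(collection, network.gene_ids)
    return network, collection, mask


# ----------------------------------------------------------------------
# omics profiles
# ----------------------------------------------------------------------

def _plant_drivers(collection: PathwayCollection, config: FixtureConfig,
                   rng) -> dict[str, frozenset]:
    drivers = {}
    for name, genes in collection.pathways:
        k = max(2, int(np.ceil(config.driver_fraction * len(genes))))
        k = min(k, len(genes))
        drivers[name] = frozenset(rng.choice(sorted(genes), size=k,
                                             replace=False))
    return drivers


def make_cell_profiles(network: GeneNetwork, collection: PathwayCollection,
                       config: FixtureConfig, n_samples: int | None = None,
                       tissues: list[str] | None = None):
    """Sample omics profiles with latent pathway activities.

    Gene expression is loading × activity of the containing pathways plus
    noise (planted driver genes carry the larger loadings); the other
    channels are correlated transforms of expression plus noise.  Channel
    missingness combines whole-channel-per-sample absence with sparse
    per-gene dropout, calibrated so the total missing fraction per channel
    matches ``config.missing_rates``.

    Returns (profiles, activities [n_samples, P], drivers).
    """
    rng = rng_for(config.seed, "profiles")
    if n_samples is None:
        n_samples = config.n_tissues * config.samples_per_tissue
    if tissues is None:
        tissues = [f"tissue{t}" for t in range(config.n_tissues)
                   for _ in range(config.samples_per_tissue)][:n_samples]
    P, n = len(collection), network.n
    gene_idx = network.index_of()
    drivers = _plant_drivers(collection, config, rng)

    loadings = np.zeros((P, n))
    for p, (name, genes) in enumerate(collection.pathways):
        for g in sorted(genes):   # fixed order: draws must not depend on set order
            lo, hi = (0.8, 1.2) if g in drivers[name] else (0.2, 0.6)
            loadings[p, gene_idx[g]] = rng.uniform(lo, hi)

    activities = rng.normal(size=(n_samples, P))
    expr = activities @ loadings + rng.normal(0, 0.3, size=(n_samples, n))
    channels = np.stack([
        expr,
        0.6 * expr + rng.normal(0, 0.4, size=expr.shape),    # copy number
        -0.5 * expr + rng.normal(0, 0.4, size=expr.shape),   # methylation
        -0.7 * expr + rng.normal(0, 0.4, size=expr.shape),   # CRISPR effect
    ], axis=-1)[:, :, :config.n_omics]

    e = config.entry_missing_rate
    observed = np.ones((n_samples, n, config.n_omics), dtype=bool)
    for c, r_total in enumerate(config.missing_rates[:config.n_omics]):
        e_c = min(e, r_total)
        r_sample = (r_total - e_c) / (1.0 - e_c) if e_c < 1 else 0.0
        # exact-count draw of which samples lack the channel entirely
        n_absent = int(round(r_sample * n_samples))
        absent = rng.choice(n_samples, size=n_absent, replace=False)
        observed[absent, :, c] = False
        present = np.setdiff1d(np.arange(n_samples), absent)
        observed[present, :, c] = rng.random((present.size, n)) >= e_c
    profiles = []
    for s in range(n_samples):
        values = np.where(observed[s], channels[s], 0.0)
        profiles.append(OmicsProfile(sample_id=f"S{s:04d}", tissue=tissues[s],
                                     values=values, observed=observed[s]))
    return profiles, activities, drivers


# ----------------------------------------------------------------------
# drugs and responses
# ----------------------------------------------------------------------

def crippen_logp(smiles: str) -> float:
    """Deterministic atom-contribution lipophilicity estimate."""
    return float(Crippen.MolLogP(Chem.MolFromSmiles(smiles)))


def drug_descriptors(smiles: str) -> np.ndarray:
    """Small physicochemical descriptor vector for structural clustering."""
    from rdkit.Chem import Descriptors, rdMolDescriptors
    mol = Chem.MolFromSmiles(smiles)
    return np.array([
        Crippen.MolLogP(mol),
        Descriptors.MolWt(mol) / 100.0,
        rdMolDescriptors.CalcNumRings(mol),
        rdMolDescriptors.CalcNumHBA(mol),
        rdMolDescriptors.CalcNumHBD(mol),
        rdMolDescriptors.CalcTPSA(mol) / 50.0,
    ], dtype=np.float64)


@dataclass
class DrugClassModel:
    """Structure → mechanism map planted in the fixture.

    Drugs are clustered by physicochemical descriptors; each cluster
    shares a target pathway and a potency sign, so mechanism is (noisily)
    predictable from structure — the property that makes pretrained drug
    embeddings informative and unseen drugs partially predictable.
    """

    centers: np.ndarray               # [G, D] standardised centroids
    mean: np.ndarray
    std: np.ndarray
    cluster_pathway: list[str]
    cluster_sign: list[float]

    def assign(self, smiles: str) -> int:
        z = (drug_descriptors(smiles) - self.mean) / self.std
        return int(np.argmin(((self.centers - z) ** 2).sum(axis=1)))


def make_drug_library(collection: PathwayCollection, config: FixtureConfig,
                      drivers: dict[str, frozenset]):
    """Drugs from the enumerated SMILES library with planted mechanisms.

    Drugs are clustered by physicochemical descriptors into mechanism
    classes; each class gets a distinct target pathway and potency sign
    (structure predicts mechanism, as for real compound series), and each
    drug a potency magnitude and a Crippen logP label for pretraining.
    Returns (graphs, {drug_id: DrugTruth}, logp labels, DrugClassModel).
    """
    rng = rng_for(config.seed, "drugs")
    retained, _ = filter_smiles(
        [(f"D{i:03d}", s) for i, s in enumerate(SMILES_LIBRARY)])
    if config.n_drugs > len(retained):
        raise ValueError("n_drugs exceeds the SMILES library")

    chosen = [retained[i] for i in
              rng.choice(len(retained), size=config.n_drugs, replace=False)]

    # cluster the selected drugs by physicochemical descriptors; the
    # clusters become the planted mechanism classes
    from sklearn.cluster import KMeans
    desc = np.stack([drug_descriptors(s) for _, s in chosen])
    mean, std = desc.mean(axis=0), desc.std(axis=0) + 1e-9
    n_classes = min(config.n_target_classes, len(collection), config.n_drugs)
    km = KMeans(n_clusters=n_classes, n_init=4,
                random_state=int(rng.integers(2 ** 31))).fit((desc - mean) / std)
    labels = [int(l) for l in km.labels_]

    pathway_order = rng.permutation(len(collection))
    classes = DrugClassModel(
        centers=km.cluster_centers_, mean=mean, std=std,
        cluster_pathway=[collection.names[pathway_order[g]]
                         for g in range(n_classes)],
        cluster_sign=[float(rng.choice([-1.0, 1.0])) for _ in range(n_classes)])

    graphs, truths, logp = [], {}, []
    for (drug_id, smiles), g in zip(chosen, labels):
        target = classes.cluster_pathway[g]
        potency = float(rng.uniform(0.8, 1.2)) * classes.cluster_sign[g]
        graphs.append(smiles_to_graph(drug_id, smiles))
        truths[drug_id] = DrugTruth(drug_id=drug_id, smiles=smiles,
                                    target_pathway=target,
                                    driver_genes=drivers[target],
                                    potency=potency)
        logp.append(crippen_logp(smiles))
    return graphs, truths, np.array(logp), classes


def make_response_tasks(collection: PathwayCollection, profiles, activities,
                        truths: dict[str, DrugTruth], config: FixtureConfig,
                        offsets: dict[str, float] | None = None):
    """Planted-mechanism LN_IC50 records grouped into drug-tissue tasks.

    ln_ic50 = β₀ + tissue_offset + γ·potency·activity(sample, target) + ε.
    Returns (tasks, records, tissue_offsets).
    """
    rng = rng_for(config.seed, "responses")
    pw_index = {n: i for i, n in enumerate(collection.names)}
    tissues = sorted({p.tissue for p in profiles})
    if offsets is None:
        offsets = {t: float(rng.normal(0, config.tissue_offset_scale))
                   for t in tissues}
    records = []
    for truth in truths.values():
        t_idx = pw_index[truth.target_pathway]
        for s, prof in enumerate(profiles):
            act = activities[s, t_idx]
            signal = config.gamma * truth.potency * act
            if config.nonlinear:
                signal += 0.5 * config.gamma * truth.potency * (act ** 2 - 1.0)
            y = (config.beta0 + offsets[prof.tissue] + signal
                 + rng.normal(0, config.noise))
            records.append(ResponseRecord(sample_id=prof.sample_id,
                                          drug_id=truth.drug_id,
                                          tissue=prof.tissue, ln_ic50=y))
    tasks = group_tasks(records)
    return tasks, records, offsets


def make_meta_test_drugs(fixture: "Fixture", n_drugs: int, seed: int = 1):
    """Fresh drugs from the same distribution for meta-test evaluation.

    Draws SMILES not used by the fixture's training library, assigns target
    pathways / potencies by the same rules, and generates response tasks
    against the *same* cell panel (cell lines are shared across drug splits,
    as in a screen).  The new drug graphs are registered on the fixture's
    dataset; the returned tasks and truths stay separate from it.
    """
    config = fixture.truth.config
    rng = rng_for(seed, "meta-test-drugs")
    used = {t.smiles for t in fixture.truth.drugs.values()}
    retained, _ = filter_smiles(
        [(f"T{i:03d}", s) for i, s in enumerate(SMILES_LIBRARY) if s not in used])
    if n_drugs > len(retained):
        raise ValueError("n_drugs exceeds the unused SMILES library")
    chosen = [retained[i] for i in
              rng.choice(len(retained), size=n_drugs, replace=False)]
    collection = fixture.dataset.pathways
    classes = fixture.truth.classes
    truths = {}
    for drug_id, smiles in chosen:
        g = classes.assign(smiles)
        target = classes.cluster_pathway[g]
        potency = float(rng.uniform(0.8, 1.2)) * classes.cluster_sign[g]
        fixture.dataset.graphs[drug_id] = smiles_to_graph(drug_id, smiles)
        truths[drug_id] = DrugTruth(drug_id=drug_id, smiles=smiles,
                                    target_pathway=target,
                                    driver_genes=fixture.truth.drivers[target],
                                    potency=potency)
    profiles = [fixture.dataset.profiles[s] for s in fixture.truth.sample_ids]
    tasks, _, _ = make_response_tasks(collection, profiles,
                                      fixture.truth.activities, truths,
                                      replace(config, seed=int(rng.integers(2 ** 31))),
                                      offsets=fixture.truth.tissue_offsets)
    return tasks, truths


# ----------------------------------------------------------------------
# one-call fixture
# ----------------------------------------------------------------------

@dataclass
class Fixture:
    dataset: ResponseDataset
    tasks: list[Task]
    truth: GroundTruth
    mask: np.ndarray
    logp: np.ndarray


def make_fixture(config: FixtureConfig | None = None,
                 impute_iterations: int = 40) -> Fixture:
    """Generate a complete, imputed, ground-truthed synthetic dataset."""
    config = config or FixtureConfig()
    network, collection, mask = make_network_and_pathways(config)
    profiles, activities, drivers = make_cell_profiles(network, collection,
                                                       config)
    graphs, truths, logp, classes = make_drug_library(collection, config,
                                                      drivers)
    tasks, records, offsets = make_response_tasks(collection, profiles,
                                                  activities, truths, config)
    dataset = ResponseDataset(network=network, pathways=collection,
                              profiles={p.sample_id: p for p in profiles},
                              graphs={g.drug_id: g for g in graphs},
                              records=records)
    dataset.impute_all(impute_iterations)
    truth = GroundTruth(drugs=truths, activities=activities,
                        sample_ids=[p.sample_id for p in profiles],
                        pathway_names=collection.names,
                        tissue_offsets=offsets, drivers=drivers, config=config,
                        classes=classes)
    return Fixture(dataset=dataset, tasks=tasks, truth=truth, mask=mask,
                   logp=logp)
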