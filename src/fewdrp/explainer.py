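"""Intrinsic interpretability: attention-head confidence scoring,
repeated fine-tune averaging, pathway and gene importance rankings, and
feature-zeroing omics-channel importance.

Pathway importance for a (sample, drug) pair is read off the pathway–drug
cross-attention: the drug token's attention row, averaged over the most
*confident* heads (confidence = mean per-row maximum attention weight)
across repeated support-resampled fine-tunes.  Gene importance within a
pathway is the absolute weight linking the gene to the pathway unit in the
sparse aggregation layer of the cell branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ResponseDataset
from .meta_learning import MetaConfig, inner_update, k_shot_finetune
from .model import DrugResponseModel
from .pathway_network import OMICS_CHANNELS, OmicsProfile
from .task_builder import ResponseRecord, Task
from .utils import rng_for


@dataclass
class AttentionRecord:
    layer: int
    head: int
    matrix: np.ndarray          # [T, T], rows sum to 1
    sample_id: str = ""
    drug_id: str = ""

    def __post_init__(self):
        if not np.allclose(self.matrix.sum(axis=-1), 1.0, atol=1e-5):
            raise ValueError("attention rows must sum to 1")


@dataclass
class ExplanationResult:
    sample_id: str
    drug_id: str
    pathway_ranking: list[tuple[str, float]]          # descending score
    gene_rankings: dict[str, list[tuple[str, float]]]  # per top pathway
    target_pathway: str | None = None
    target_genes: frozenset | None = None
    pathway_top10_hit: bool | None = None
    gene_top25_hit: bool | None = None


def head_confidence(records: list[AttentionRecord]) -> dict[tuple[int, int], float]:
    """Mean per-row maximum attention weight per (layer, head).

    One-hot rows give 1.0; uniform rows over T tokens give 1/T.
    """
    if not records:
        raise ValueError("need at least one attention record")
    sums: dict[tuple[int, int], list[float]] = {}
    for rec in records:
        sums.setdefault((rec.layer, rec.head), []).append(
            float(rec.matrix.max(axis=-1).mean()))
    return {key: float(np.mean(v)) for key, v in sums.items()}


def averaged_attention(model: DrugResponseModel, params: dict,
                       dataset: ResponseDataset, task: Task,
                       target: ResponseRecord, config: MetaConfig,
                       repeats: int = 10, seed: int = 0, top_k: int = 1):
    """Fine-tune repeatedly (target held out of support), average the
    attention of the most confident fusion head(s).

    Returns (averaged [T, T] matrix, per-repeat head confidences).
    """
    others = [r for r in task.records if r.sample_id != target.sample_id]
    if len(others) < config.n_support:
        raise ValueError("task too small to sample support excluding target")
    x_target = dataset.omics_batch([target])
    graph = dataset.drug_graph(target.drug_id)
    matrices, confidences, sparse_weights = [], [], []
    for rep in range(repeats):
        rng = rng_for(seed, "explain", task.drug_id, task.tissue, rep)
        idx = rng.choice(len(others), size=config.n_support, replace=False)
        support = [others[i] for i in idx]
        adapted = inner_update(model, params, dataset, support,
                               config.inner_lr, config.inner_steps,
                               second_order=False)
        _, state, _ = model.forward(adapted, x_target, graph)
        probs = state.attention.data[0]        # [H, T, T]
        recs = [AttentionRecord(layer=0, head=h, matrix=probs[h],
                                sample_id=target.sample_id,
                                drug_id=target.drug_id)
                for h in range(probs.shape[0])]
        conf = head_confidence(recs)
        confidences.append(conf)
        best = sorted(conf, key=lambda k: (-conf[k], k))[:top_k]
        matrices.append(np.mean([probs[h] for (_, h) in best], axis=0))
        sparse_weights.append(np.abs(adapted["cell.sparse.W"].data))
    return np.mean(matrices, axis=0), confidences, np.mean(sparse_weights, axis=0)


def rank_pathways(drug_row: np.ndarray, pathway_names: list[str],
                  target: str | None = None, top: int = 10):
    """Descending attention ranking; ties broken by pathway name.

    Returns (ordered [(name, score)], hit flag — target in the first
    ``top`` — or None without a target annotation).
    """
    drug_row = np.asarray(drug_row, dtype=np.float64)
    if drug_row.shape[0] != len(pathway_names):
        raise ValueError("attention vector length must equal pathway count")
    order = sorted(range(len(pathway_names)),
                   key=lambda i: (-drug_row[i], pathway_names[i]))
    ranking = [(pathway_names[i], float(drug_row[i])) for i in order]
    hit = None
    if target is not None:
        hit = target in [name for name, _ in ranking[:top]]
    return ranking, hit


def rank_genes(sparse_weights: np.ndarray, mask: np.ndarray,
               pathway_names: list[str], gene_ids: list[str], pathway: str,
               quantile: float = 0.25) -> list[tuple[str, float]]:
    """Top-fraction member genes of a pathway by absolute sparse weight.

    ``sparse_weights``: the [P, n] gene→pathway weight matrix (typically
    the fine-tune-averaged absolute weights).  Scores the
    ``ceil(quantile × pathway size)`` strongest genes, ties broken by gene
    identifier.
    """
    if pathway not in pathway_names:
        raise KeyError(f"unknown pathway: {pathway!r}")
    p = pathway_names.index(pathway)
    W = np.abs(sparse_weights) * mask
    members = np.flatnonzero(mask[p] > 0)
    scored = sorted(((gene_ids[g], float(W[p, g])) for g in members),
                    key=lambda t: (-t[1], t[0]))
    k = math.ceil(quantile * len(members))
    return scored[:k]


def explain(model: DrugResponseModel, params: dict, dataset: ResponseDataset,
            task: Task, target: ResponseRecord, config: MetaConfig,
            annotation: dict | None = None, repeats: int = 10,
            seed: int = 0, top_pathways: int = 10,
            gene_quantile: float = 0.25) -> ExplanationResult:
    """Full single-sample interpretation for one (sample, drug) pair.

    ``annotation`` (optional): {"pathway": name, "genes": iterable} — the
    known mechanism used only for hit flags, never for ranking.
    """
    avg, _, weights = averaged_attention(model, params, dataset, task, target,
                                         config, repeats=repeats, seed=seed)
    drug_row = avg[-1, :-1]                      # drug token -> pathway columns
    names = dataset.pathways.names
    target_pw = annotation.get("pathway") if annotation else None
    ranking, top10_hit = rank_pathways(drug_row, names, target=target_pw,
                                       top=top_pathways)
    gene_rankings = {
        name: rank_genes(weights, model.mask, names, dataset.network.gene_ids,
                         name, quantile=gene_quantile)
        for name, _ in ranking[:top_pathways]
    }
    gene_hit = None
    target_genes = frozenset(annotation.get("genes", ())) if annotation else None
    if target_pw is not None and target_genes:
        ranked_target = rank_genes(weights, model.mask, names,
                                   dataset.network.gene_ids, target_pw,
                                   quantile=gene_quantile)
        gene_hit = bool(target_genes & {g for g, _ in ranked_target})
    return ExplanationResult(sample_id=target.sample_id, drug_id=target.drug_id,
                             pathway_ranking=ranking,
                             gene_rankings=gene_rankings,
                             target_pathway=target_pw,
                             target_genes=target_genes,
                             pathway_top10_hit=top10_hit,
                             gene_top25_hit=gene_hit)


# ----------------------------------------------------------------------
# feature zeroing
# ----------------------------------------------------------------------

def _zero_channel(dataset: ResponseDataset, channel_idx: int) -> ResponseDataset:
    profiles = {}
    for sid, prof in dataset.profiles.items():
        values = prof.values.copy()
        values[:, channel_idx] = 0.0
        profiles[sid] = OmicsProfile(sample_id=prof.sample_id,
                                     tissue=prof.tissue, values=values,
                                     observed=prof.observed)
    return ResponseDataset(network=dataset.network, pathways=dataset.pathways,
                           profiles=profiles, graphs=dataset.graphs,
                           records=dataset.records)


def feature_zeroing_importance(model: DrugResponseModel, params: dict,
                               dataset: ResponseDataset, tasks: list[Task],
                               channel: str, config: MetaConfig,
                               k: int = 10, seed: int = 0) -> pd.DataFrame:
    """Drug-level SCC drop when one omics channel is zeroed at test time.

    No retraining: k-shot predictions are computed on the intact and the
    channel-zeroed inputs, and ΔSCC^d = SCC^d(full) − SCC^d(zeroed) is
    reported per drug.
    """
    if channel not in OMICS_CHANNELS[:dataset.n_omics]:
        raise ValueError(f"unknown omics channel {channel!r}")
    zeroed = _zero_channel(dataset, OMICS_CHANNELS.index(channel))
    rows: dict[str, dict[str, list]] = {}
    for ds, key in ((dataset, "full"), (zeroed, "zeroed")):
        for task in tasks:
            _, frame = k_shot_finetune(model, params, ds, task, k, config,
                                       seed=seed)
            rows.setdefault(task.drug_id, {}).setdefault(key, []).append(frame)
    out = []
    for drug_id, frames in sorted(rows.items()):
        sccs = {}
        for key in ("full", "zeroed"):
            merged = pd.concat(frames[key])
            if merged["y_pred"].nunique() > 1 and merged["y_true"].nunique() > 1:
                sccs[key] = float(stats.spearmanr(merged["y_pred"],
                                                  merged["y_true"]).statistic)
            else:
                sccs[key] = 0.0   # constant predictions carry no ranking signal
        out.append({"drug_id": drug_id, "scc_full": sccs["full"],
                    "scc_zeroed": sccs["zeroed"],
                    "delta_scc": sccs["full"] - sccs["zeroed"]})
    return pd.DataFrame(out)
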