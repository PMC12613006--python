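"""MAML dual-loop training over drug-tissue tasks, k-shot fine-tuning and
the conventionally trained ablation.

Inner loop: a handful of SGD steps on a task's support records (MAE loss)
producing adapted parameters θ from the meta-parameters θ_meta.  Outer
loop: Adam on the mean post-adaptation query loss across a task batch.  In
second-order mode the outer gradient is backpropagated through the inner
SGD steps (exact meta-gradients); first-order mode detaches the inner
gradients (FOMAML) and is considerably cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .data import ResponseDataset
from .model import DrugResponseModel
from .task_builder import Episode, Task, sample_episode
from .utils import rng_for


@dataclass
class MetaConfig:
    inner_lr: float = 0.001       # α, fixed inner-loop step size
    inner_steps: int = 2          # inner updates per adaptation
    outer_lr: float = 1e-3        # β, Adam step size for θ_meta
    meta_batch_size: int = 8      # tasks per outer step
    batches_per_epoch: int | None = None  # None: cover all train tasks
    epochs: int = 100
    patience: int = 50            # early stop on non-decreasing val loss
    second_order: bool = True
    n_support: int = 10
    n_query: int = 20
    n_total: int = 30
    dropout_train: bool = True
    clip_norm: float | None = 10.0   # global outer-gradient norm clip

    def __post_init__(self):
        if self.inner_lr <= 0 or self.outer_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.inner_steps < 1 or self.patience < 1:
            raise ValueError("inner_steps and patience must be >= 1")


def mae_loss(predictions, labels) -> Tensor:
    """Mean absolute error as a differentiable scalar."""
    labels = np.asarray(labels, dtype=np.float64)
    preds = ad.as_tensor(predictions)
    if preds.shape != labels.shape or labels.size == 0:
        raise ValueError("predictions and labels must have equal nonzero length")
    return ad.tmean(ad.absolute(preds - Tensor(labels)))


def _forward_records(model: DrugResponseModel, params: dict,
                     dataset: ResponseDataset, records, rng=None,
                     train: bool = False) -> Tensor:
    x = dataset.omics_batch(records)
    graph = dataset.drug_graph(records[0].drug_id)
    preds, _, _ = model.forward(params, x, graph, rng=rng, train=train)
    return preds


def inner_update(model: DrugResponseModel, params: dict,
                 dataset: ResponseDataset, support, alpha: float,
                 steps: int, second_order: bool = True, rng=None,
                 train: bool = False) -> dict:
    """Task adaptation: ``steps`` SGD steps on the support MAE.

    ``params`` (θ_meta) is never mutated; the returned dict holds adapted
    copies that, in second-order mode, stay connected to θ_meta on the tape.
    """
    if not support:
        raise ValueError("support set must be nonempty")
    y = np.array([r.ln_ic50 for r in support])
    adapted = dict(params)
    names = list(params.keys())
    for _ in range(steps):
        preds = _forward_records(model, adapted, dataset, support, rng=rng,
                                 train=train)
        loss = mae_loss(preds, y)
        grads = ad.grad(loss, [adapted[k] for k in names])
        if not second_order:
            grads = [ad.detach(g) for g in grads]
        adapted = {k: adapted[k] - Tensor(alpha) * g
                   for k, g in zip(names, grads)}
    return adapted


def outer_step(model: DrugResponseModel, params: dict, optimizer: nn.Adam,
               dataset: ResponseDataset, episodes: list[Episode],
               config: MetaConfig, rng=None) -> tuple[dict, float]:
    """One meta-update from a batch of episodes; returns (θ_meta, L_outer)."""
    if not episodes:
        raise ValueError("episode batch must be nonempty")
    train = config.dropout_train
    losses = []
    for ep in episodes:
        adapted = inner_update(model, params, dataset, ep.support,
                               config.inner_lr, config.inner_steps,
                               second_order=config.second_order, rng=rng,
                               train=train)
        preds = _forward_records(model, adapted, dataset, ep.query, rng=rng,
                                 train=train)
        losses.append(mae_loss(preds, [r.ln_ic50 for r in ep.query]))
    l_outer = ad.tmean(ad.concat([ad.reshape(l, (1,)) for l in losses]))
    names = list(params.keys())
    grads = ad.grad(l_outer, [params[k] for k in names])
    gdict = {k: g.data for k, g in zip(names, grads)}
    if config.clip_norm is not None:
        total = float(np.sqrt(sum(float((g * g).sum()) for g in gdict.values())))
        if total > config.clip_norm:
            scale = config.clip_norm / total
            gdict = {k: g * scale for k, g in gdict.items()}
    new_params = optimizer.step(params, gdict)
    return new_params, l_outer.item()


def evaluate_tasks(model: DrugResponseModel, params: dict,
                   dataset: ResponseDataset, tasks: list[Task],
                   config: MetaConfig, seed: int) -> tuple[float, float]:
    """Post-adaptation query loss and mean query SCC over tasks.

    Each task gets a fresh support/query episode (seeded), first-order
    adaptation on support, and evaluation on query.
    """
    losses, sccs = [], []
    for task in tasks:
        ep = sample_episode(task, config.n_total, config.n_support,
                            config.n_query, seed=seed)
        adapted = inner_update(model, params, dataset, ep.support,
                               config.inner_lr, config.inner_steps,
                               second_order=False)
        preds = _forward_records(model, adapted, dataset, ep.query)
        y = np.array([r.ln_ic50 for r in ep.query])
        losses.append(float(np.mean(np.abs(preds.data - y))))
        if np.ptp(preds.data) > 0 and np.ptp(y) > 0:
            sccs.append(float(stats.spearmanr(preds.data, y).statistic))
    return float(np.mean(losses)), float(np.mean(sccs)) if sccs else float("nan")


def meta_train(model: DrugResponseModel, dataset: ResponseDataset,
               train_tasks: list[Task], val_tasks: list[Task],
               config: MetaConfig, seed: int = 0,
               init_params: dict | None = None) -> tuple[dict, list[dict]]:
    """Dual-loop meta-training with early stopping.

    The best checkpoint is selected by validation SCC^dt; early stopping
    monitors the validation loss (halt after ``patience`` consecutive
    non-decreasing epochs).  Returns (θ_meta, per-epoch log).
    """
    if not train_tasks or not val_tasks:
        raise ValueError("task lists must be nonempty")
    params = init_params if init_params is not None else model.init_params(seed)
    optimizer = nn.Adam(lr=config.outer_lr)
    log: list[dict] = []
    best_params, best_scc = nn.detach_all(params), -np.inf
    best_val_loss, stall = np.inf, 0

    for epoch in range(config.epochs):
        rng_order = rng_for(seed, "order", epoch)
        order = rng_order.permutation(len(train_tasks))
        batches = [order[i:i + config.meta_batch_size]
                   for i in range(0, len(order), config.meta_batch_size)]
        if config.batches_per_epoch is not None:
            batches = batches[:config.batches_per_epoch]
        drop_rng = rng_for(seed, "dropout", epoch)
        epoch_losses = []
        for batch in batches:
            episodes = [sample_episode(train_tasks[i], config.n_total,
                                       config.n_support, config.n_query,
                                       seed=rng_for(seed, "ep", epoch, i)
                                       .integers(2 ** 31))
                        for i in batch]
            params, l_outer = outer_step(model, params, optimizer, dataset,
                                         episodes, config, rng=drop_rng)
            epoch_losses.append(l_outer)
        val_loss, val_scc = evaluate_tasks(model, params, dataset, val_tasks,
                                           config, seed=epoch)
        log.append({"epoch": epoch, "l_outer": float(np.mean(epoch_losses)),
                    "val_loss": val_loss, "val_scc_dt": val_scc})
        if val_scc > best_scc:
            best_scc, best_params = val_scc, nn.detach_all(params)
        if val_loss < best_val_loss - 1e-12:
            best_val_loss, stall = val_loss, 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return best_params, log


def k_shot_finetune(model: DrugResponseModel, params: dict,
                    dataset: ResponseDataset, task: Task, k: int,
                    config: MetaConfig, seed: int = 0):
    """Adapt on k sampled records, predict the remaining ones.

    k = 0 is zero-shot: parameters are returned unchanged and every record
    is predicted.  Returns (adapted params, predictions DataFrame).
    """
    if k < 0 or k >= len(task.records):
        raise ValueError(f"k must be in [0, {len(task.records) - 1}]")
    if k == 0:
        adapted, remaining = dict(params), list(task.records)
    else:
        rng = rng_for(seed, "finetune", task.drug_id, task.tissue)
        idx = rng.choice(len(task.records), size=k, replace=False)
        chosen = set(idx.tolist())
        shots = [task.records[i] for i in sorted(chosen)]
        remaining = [r for i, r in enumerate(task.records) if i not in chosen]
        adapted = inner_update(model, params, dataset, shots, config.inner_lr,
                               config.inner_steps, second_order=False)
    preds = _forward_records(model, adapted, dataset, remaining)
    frame = pd.DataFrame({
        "sample_id": [r.sample_id for r in remaining],
        "drug_id": [r.drug_id for r in remaining],
        "tissue": [r.tissue for r in remaining],
        "y_true": [r.ln_ic50 for r in remaining],
        "y_pred": preds.data,
    })
    return adapted, frame


def conventional_train(model: DrugResponseModel, dataset: ResponseDataset,
                       train_tasks: list[Task], config: MetaConfig,
                       seed: int = 0,
                       init_params: dict | None = None) -> tuple[dict, list[dict]]:
    """Single-loop baseline sharing the architecture (no inner adaptation).

    Minimises pooled MAE by Adam over minibatches; each minibatch is one
    task's episode-sized record draw, so batches stay single-drug (which is
    what the shared drug encoding requires) while all tasks are visited.
    The result serves the no-fine-tune ablation directly and the
    fine-tuned one after :func:`k_shot_finetune`.
    """
    if not train_tasks:
        raise ValueError("task list must be nonempty")
    params = init_params if init_params is not None else model.init_params(seed)
    optimizer = nn.Adam(lr=config.outer_lr)
    log: list[dict] = []
    names = list(params.keys())
    for epoch in range(config.epochs):
        order = rng_for(seed, "conv-order", epoch).permutation(len(train_tasks))
        if config.batches_per_epoch is not None:
            order = order[:config.batches_per_epoch * config.meta_batch_size]
        drop_rng = rng_for(seed, "conv-dropout", epoch)
        epoch_losses = []
        for i in order:
            task = train_tasks[i]
            ep = sample_episode(task, config.n_total, config.n_support,
                                config.n_query,
                                seed=rng_for(seed, "conv-ep", epoch, i)
                                .integers(2 ** 31))
            batch = ep.support + ep.query
            preds = _forward_records(model, params, dataset, batch,
                                     rng=drop_rng, train=config.dropout_train)
            loss = mae_loss(preds, [r.ln_ic50 for r in batch])
            grads = ad.grad(loss, [params[k] for k in names])
            gdict = {k: g.data for k, g in zip(names, grads)}
            if config.clip_norm is not None:
                total = float(np.sqrt(sum(float((g * g).sum())
                                          for g in gdict.values())))
                if total > config.clip_norm:
                    scale = config.clip_norm / total
                    gdict = {k: g * scale for k, g in gdict.items()}
            params = optimizer.step(params, gdict)
            epoch_losses.append(loss.item())
        log.append({"epoch": epoch, "loss": float(np.mean(epoch_losses))})
    return nn.detach_all(params), log
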