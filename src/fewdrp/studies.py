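"""Reference desk-scale study protocols.

These functions bundle the synthetic-benchmark experiments the package is
validated with: the few-shot-advantage comparison (meta-learning vs the
conventionally trained ablation on fresh meta-test drugs) and the
mechanism-recovery study for the explainer (strong-effect fixture with the
full 186-pathway collection).  Problem sizes are chosen for single-CPU
runs of a few minutes each; every random draw descends from the ``seed``
arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .drug_encoder import PretrainConfig, pretrain_logp
from .explainer import explain
from .meta_learning import (MetaConfig, conventional_train, k_shot_finetune,
                            meta_train)
from .model import DrugResponseModel, ModelConfig
from .synthetic import Fixture, FixtureConfig, make_fixture, make_meta_test_drugs
from .task_builder import holdout_unseen_drugs, split_train_val

#: training preset for the desk-scale studies (first-order MAML)
DESK_TRAIN = dict(second_order=False, meta_batch_size=2, batches_per_epoch=12,
                  outer_lr=3e-3, inner_lr=0.1, patience=999,
                  dropout_train=False)

#: evaluation-time adaptation preset shared by every compared model
DESK_EVAL = MetaConfig(inner_lr=0.05, inner_steps=2, second_order=False)


def _desk_model(fixture: Fixture, **overrides) -> DrugResponseModel:
    cfg = ModelConfig.desk(hidden=16, n_e=16, fusion_mode="drug_token",
                           fusion_heads=2)
    cfg.dropout = 0.0
    cfg.drug.dropout = 0.0
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.drug.n_e = cfg.n_e
    return DrugResponseModel(fixture.dataset.network, fixture.dataset.pathways,
                             cfg, n_omics=4)


def _pretrained_drug_params(fixture: Fixture, model: DrugResponseModel,
                            epochs: int = 40, seed: int = 7) -> dict:
    ids = sorted(fixture.truth.drugs)
    graphs = [fixture.dataset.graphs[d] for d in ids]
    logp_by_id = dict(zip(fixture.truth.drugs.keys(), fixture.logp))
    params, _ = pretrain_logp(
        graphs, [logp_by_id[d] for d in ids],
        PretrainConfig(epochs=epochs, batch_size=12,
                       warmup_epochs=max(1, epochs // 10), peak_lr=2e-3,
                       encoder=model.config.drug), seed=seed)
    return {k: v for k, v in params.items() if k.startswith("drug.")}


def task_scc(model, params, dataset, tasks, k, config, seed) -> np.ndarray:
    """Per-task Spearman of k-shot predictions on the held-out records."""
    sccs = []
    for task in tasks:
        _, frame = k_shot_finetune(model, params, dataset, task, k, config,
                                   seed=seed)
        if frame["y_pred"].nunique() > 1 and frame["y_true"].nunique() > 1:
            sccs.append(float(stats.spearmanr(frame["y_pred"],
                                              frame["y_true"]).statistic))
        else:
            sccs.append(0.0)
    return np.array(sccs)


@dataclass
class FewShotResult:
    meta_scc: dict          # k -> per-task SCC array
    conv_scc: dict          # k in {0, 10}
    seed: int
    meta_params: dict | None = None


def few_shot_study_one_seed(fixture: Fixture, test_tasks, pre_drug: dict,
                            seed: int, epochs: int = 40,
                            ks=(0, 1, 5, 10)) -> FewShotResult:
    """Train one meta-learner and one conventional ablation from the same
    pretrained initialisation, evaluate k-shot SCC on meta-test tasks."""
    ds = fixture.dataset
    model = _desk_model(fixture)
    remaining, _ = holdout_unseen_drugs(fixture.tasks, seed=seed)
    train, val = split_train_val(remaining, seed=seed)
    train_cfg = MetaConfig(epochs=epochs, **DESK_TRAIN)
    init = model.init_params(seed)
    init.update(pre_drug)
    meta_params, _ = meta_train(model, ds, train, val, train_cfg, seed=seed,
                                init_params=dict(init))
    conv_params, _ = conventional_train(model, ds, train, train_cfg, seed=seed,
                                        init_params=dict(init))
    meta_scc = {k: task_scc(model, meta_params, ds, test_tasks, k,
                            DESK_EVAL, seed) for k in ks}
    conv_scc = {k: task_scc(model, conv_params, ds, test_tasks, k,
                            DESK_EVAL, seed) for k in (0, 10)}
    return FewShotResult(meta_scc=meta_scc, conv_scc=conv_scc, seed=seed,
                         meta_params=meta_params)


def few_shot_study(seeds=(1, 2, 3, 4, 5), epochs: int = 40,
                   n_test_drugs: int = 17, fixture_seed: int = 0):
    """The full comparison: default fixture, fresh meta-test drugs,
    one (meta, conventional) pair per seed.  Returns (fixture, results)."""
    fixture = make_fixture(FixtureConfig(seed=fixture_seed))
    test_tasks, _ = make_meta_test_drugs(fixture, n_test_drugs, seed=99)
    model = _desk_model(fixture)
    pre_drug = _pretrained_drug_params(fixture, model, epochs=40, seed=7)
    results = [few_shot_study_one_seed(fixture, test_tasks, pre_drug, seed,
                                       epochs=epochs)
               for seed in seeds]
    return fixture, test_tasks, results


EXPLAINER_FIXTURE = FixtureConfig(
    n_genes=760, n_pathways=186, pathway_size=(3, 4), overlap=0.0,
    n_drugs=15, n_target_classes=5, n_tissues=2, samples_per_tissue=30,
    gamma=1.5, noise=0.1, seed=11)


def explainer_study(train_seed: int = 1, epochs: int = 70,
                    samples_per_task: int = 2, repeats: int = 10,
                    explain_seed: int = 5, fixture_seed: int | None = None):
    """Mechanism recovery on the strong-effect 186-pathway fixture.

    Trains the meta-learner, then runs the full single-sample explanation
    protocol (support resampling excluding the target, fine-tune averaging
    over the most confident head) and scores planted-target recovery.
    Returns (fixture, model, params, pathway hits, gene hits).
    """
    fcfg = EXPLAINER_FIXTURE
    if fixture_seed is not None:
        from dataclasses import replace
        fcfg = replace(fcfg, seed=fixture_seed)
    fixture = make_fixture(fcfg)
    ds = fixture.dataset
    model = _desk_model(fixture, hidden=8, n_e=12, fusion_heads=1)
    pre_drug = _pretrained_drug_params(fixture, model, epochs=30, seed=7)
    remaining, _ = holdout_unseen_drugs(fixture.tasks, seed=train_seed)
    train, val = split_train_val(remaining, seed=train_seed)
    train_cfg = MetaConfig(epochs=epochs, **{**DESK_TRAIN,
                                             "batches_per_epoch": 8,
                                             "outer_lr": 4e-3})
    init = model.init_params(train_seed)
    init.update(pre_drug)
    params, _ = meta_train(model, ds, train, val, train_cfg, seed=train_seed,
                           init_params=init)

    pathway_hits, gene_hits = [], []
    for task in fixture.tasks:
        truth = fixture.truth.drugs[task.drug_id]
        annotation = {"pathway": truth.target_pathway,
                      "genes": truth.driver_genes}
        for target in task.records[:samples_per_task]:
            res = explain(model, params, ds, task, target, DESK_EVAL,
                          annotation=annotation, repeats=repeats,
                          seed=explain_seed)
            pathway_hits.append(bool(res.pathway_top10_hit))
            gene_hits.append(bool(res.gene_top25_hit))
    return fixture, model, params, np.array(pathway_hits), np.array(gene_hits)
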