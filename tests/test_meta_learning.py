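"""MAML mechanics: losses, inner/outer updates, fine-tuning, training loops."""

import numpy as np
import pytest

from fewdrp import autodiff as ad
from fewdrp import nn
from fewdrp.autodiff import Tensor
from fewdrp.meta_learning import (MetaConfig, conventional_train,
                                  inner_update, k_shot_finetune, mae_loss,
                                  meta_train, outer_step)
from fewdrp.task_builder import Episode, ResponseRecord, Task


class LinearToyModel:
    """f(x) = w·x + b on scalar features — a stand-in with the real
    model's forward signature, small enough for finite differences."""

    def forward(self, params, x, graph, rng=None, train=False):
        preds = ad.as_tensor(x) @ params["w"] + params["b"]
        return ad.reshape(preds, (x.shape[0],)), None, None


class ToyDataset:
    def __init__(self, features):
        self.features = features  # sample_id -> feature vector

    def omics_batch(self, records):
        return np.stack([self.features[r.sample_id] for r in records])

    def drug_graph(self, drug_id):
        return None


def _toy(n=12, d=3, slope=None, seed=0):
    rng = np.random.default_rng(seed)
    slope = slope if slope is not None else rng.normal(size=d)
    feats, records = {}, []
    for i in range(n):
        x = rng.normal(size=d)
        feats[f"s{i}"] = x
        records.append(ResponseRecord(sample_id=f"s{i}", drug_id="d0",
                                      tissue="t0",
                                      ln_ic50=float(x @ slope + 0.1)))
    params = {"w": Tensor(rng.normal(size=(d, 1)) * 0.3),
              "b": Tensor(np.zeros(1))}
    return LinearToyModel(), ToyDataset(feats), records, params


# ----------------------------------------------------------------------
# loss
# ----------------------------------------------------------------------

def test_mae_examples():
    assert mae_loss(ad.as_tensor([1.0, 2.0]), [0.0, 0.0]).item() == pytest.approx(1.5)
    assert mae_loss(ad.as_tensor([2.0, -1.0]), [2.0, -1.0]).item() == 0.0
    assert mae_loss(ad.as_tensor([3.0]), [-3.0]).item() == pytest.approx(6.0)


def test_mae_length_mismatch():
    with pytest.raises(ValueError):
        mae_loss(ad.as_tensor([1.0]), [1.0, 2.0])


# ----------------------------------------------------------------------
# inner loop
# ----------------------------------------------------------------------

def test_zero_learning_rate_is_identity():
    model, ds, records, params = _toy()
    adapted = inner_update(model, params, ds, records[:5], alpha=0.0, steps=2)
    for k in params:
        assert np.array_equal(adapted[k].data, params[k].data)


def test_single_parameter_gradient_step():
    # f(x) = theta*x, support {(x=1, y=0)}: dMAE/dtheta = sign(theta) = 1
    model = LinearToyModel()
    ds = ToyDataset({"s0": np.array([1.0])})
    rec = [ResponseRecord(sample_id="s0", drug_id="d", tissue="t", ln_ic50=0.0)]
    params = {"w": Tensor(np.array([[1.0]])), "b": Tensor(np.zeros(1))}
    adapted = inner_update(model, params, ds, rec, alpha=0.001, steps=1)
    assert adapted["w"].data[0, 0] == pytest.approx(0.999)


def test_two_steps_equal_two_single_steps_first_order():
    model, ds, records, params = _toy(seed=1)
    support = records[:6]
    two = inner_update(model, params, ds, support, 0.05, 2, second_order=False)
    one = inner_update(model, params, ds, support, 0.05, 1, second_order=False)
    one_again = inner_update(model, one, ds, support, 0.05, 1, second_order=False)
    for k in params:
        assert np.allclose(two[k].data, one_again[k].data, atol=1e-14)


def test_meta_parameters_never_mutated():
    model, ds, records, params = _toy(seed=2)
    before = {k: v.data.copy() for k, v in params.items()}
    inner_update(model, params, ds, records[:6], 0.1, 3)
    for k in params:
        assert np.array_equal(params[k].data, before[k])


def test_second_order_meta_gradient_matches_finite_differences():
    model, ds, records, params = _toy(n=16, seed=3)
    support, query = records[:8], records[8:]
    y_query = [r.ln_ic50 for r in query]
    alpha, steps = 0.05, 2

    def meta_loss(p):
        adapted = inner_update(model, p, ds, support, alpha, steps,
                               second_order=True)
        preds, _, _ = model.forward(adapted, ds.omics_batch(query), None)
        return mae_loss(preds, y_query)

    names = list(params)
    grads = ad.grad(meta_loss(params), [params[k] for k in names])
    for k, g in zip(names, grads):
        fd = np.zeros_like(params[k].data)
        for idx in np.ndindex(*params[k].shape):
            eps = 1e-6
            orig = params[k].data[idx]
            params[k].data[idx] = orig + eps
            lp = meta_loss(params).item()
            params[k].data[idx] = orig - eps
            lm = meta_loss(params).item()
            params[k].data[idx] = orig
            fd[idx] = (lp - lm) / (2 * eps)
        denom = np.maximum(np.abs(fd), 1e-8)
        assert np.max(np.abs(g.data - fd) / denom) < 1e-4


# ----------------------------------------------------------------------
# outer loop
# ----------------------------------------------------------------------

def test_outer_loss_of_identical_tasks_equals_single_task():
    model, ds, records, params = _toy(n=30, seed=4)
    ep = Episode(support=records[:10], query=records[10:30])
    opt = nn.Adam(lr=1e-4)
    cfg = MetaConfig(inner_lr=0.01, inner_steps=1, outer_lr=1e-4,
                     second_order=False, dropout_train=False)
    _, l_batch = outer_step(model, params, opt, ds, [ep, ep, ep], cfg)
    opt2 = nn.Adam(lr=1e-4)
    _, l_single = outer_step(model, params, opt2, ds, [ep], cfg)
    assert l_batch == pytest.approx(l_single, abs=1e-12)


def test_outer_step_descends_on_a_fixed_batch():
    model, ds, records, params = _toy(n=30, seed=5)
    ep = Episode(support=records[:10], query=records[10:30])
    cfg = MetaConfig(inner_lr=0.01, inner_steps=1, outer_lr=1e-4,
                     second_order=True, dropout_train=False)

    def batch_loss(p):
        adapted = inner_update(model, p, ds, ep.support, cfg.inner_lr, 1,
                               second_order=False)
        preds, _, _ = model.forward(adapted, ds.omics_batch(ep.query), None)
        return mae_loss(preds, [r.ln_ic50 for r in ep.query]).item()

    before = batch_loss(params)
    opt = nn.Adam(lr=cfg.outer_lr)
    new_params, _ = outer_step(model, params, opt, ds, [ep], cfg)
    assert batch_loss(new_params) < before


# ----------------------------------------------------------------------
# k-shot fine-tuning
# ----------------------------------------------------------------------

def _toy_task(records):
    return Task(drug_id="d0", tissue="t0", records=records)


def test_zero_shot_is_a_parameter_noop():
    model, ds, records, params = _toy(n=31, seed=6)
    cfg = MetaConfig(inner_lr=0.05, second_order=False)
    adapted, frame = k_shot_finetune(model, params, ds, _toy_task(records),
                                     k=0, config=cfg, seed=0)
    for k in params:
        assert np.array_equal(adapted[k].data, params[k].data)  # bit-identical
    assert len(frame) == 31


def test_ten_shot_on_thirty_records_yields_twenty_predictions():
    model, ds, records, params = _toy(n=30, seed=7)
    cfg = MetaConfig(inner_lr=0.05, second_order=False)
    _, frame = k_shot_finetune(model, params, ds, _toy_task(records), k=10,
                               config=cfg, seed=0)
    assert len(frame) == 20


def test_finetune_determinism_and_k_validation():
    model, ds, records, params = _toy(n=30, seed=8)
    cfg = MetaConfig(inner_lr=0.05, second_order=False)
    _, f1 = k_shot_finetune(model, params, ds, _toy_task(records), 5, cfg, seed=3)
    _, f2 = k_shot_finetune(model, params, ds, _toy_task(records), 5, cfg, seed=3)
    assert f1.equals(f2)
    with pytest.raises(ValueError):
        k_shot_finetune(model, params, ds, _toy_task(records), 30, cfg, seed=0)


# ----------------------------------------------------------------------
# training loops (on the real model, tiny scale)
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def mini_setup(request):
    from fewdrp.model import DrugResponseModel, ModelConfig
    from fewdrp.synthetic import FixtureConfig, make_fixture
    fx = make_fixture(FixtureConfig(n_genes=60, n_pathways=6,
                                    pathway_size=(5, 8), n_drugs=6,
                                    n_target_classes=3, n_tissues=2,
                                    samples_per_tissue=31, seed=5))
    cfg = ModelConfig.desk()
    cfg.dropout = 0.0
    cfg.drug.dropout = 0.0
    model = DrugResponseModel(fx.dataset.network, fx.dataset.pathways, cfg,
                              n_omics=4)
    return fx, model


def test_meta_train_runs_logs_and_improves_nothing_breaks(mini_setup):
    fx, model = mini_setup
    cfg = MetaConfig(second_order=False, epochs=3, meta_batch_size=2,
                     batches_per_epoch=2, outer_lr=3e-3, inner_lr=0.05,
                     patience=50, dropout_train=False)
    params, log = meta_train(model, fx.dataset, fx.tasks[:6], fx.tasks[6:8],
                             cfg, seed=0)
    assert len(log) == 3
    assert all(np.isfinite(e["val_loss"]) for e in log)
    assert set(params) == set(model.init_params(0))


def test_meta_train_early_stopping_respects_patience(mini_setup, monkeypatch):
    fx, model = mini_setup
    # validation loss sequence 1.0, 1.1, 1.2, ... never improves after the
    # first epoch; with patience=1 training must stop after epoch 2
    seq = iter([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7])

    def fake_eval(model_, params_, dataset_, tasks_, config_, seed):
        return next(seq), 0.0

    import fewdrp.meta_learning as ml
    monkeypatch.setattr(ml, "evaluate_tasks", fake_eval)
    cfg = MetaConfig(second_order=False, epochs=30, meta_batch_size=2,
                     batches_per_epoch=1, outer_lr=1e-5, inner_lr=1e-5,
                     patience=1, dropout_train=False)
    _, log = ml.meta_train(model, fx.dataset, fx.tasks[:4], fx.tasks[4:6],
                           cfg, seed=0)
    assert len(log) == 2


def test_meta_train_is_reproducible(mini_setup):
    fx, model = mini_setup
    cfg = MetaConfig(second_order=False, epochs=2, meta_batch_size=2,
                     batches_per_epoch=2, outer_lr=3e-3, inner_lr=0.05,
                     patience=50, dropout_train=False)
    p1, l1 = meta_train(model, fx.dataset, fx.tasks[:4], fx.tasks[4:6], cfg, seed=7)
    p2, l2 = meta_train(model, fx.dataset, fx.tasks[:4], fx.tasks[4:6], cfg, seed=7)
    assert l1 == l2
    for k in p1:
        assert np.array_equal(p1[k].data, p2[k].data)


def test_conventional_training_shares_shapes_and_descends(mini_setup):
    fx, model = mini_setup
    cfg = MetaConfig(second_order=False, epochs=6, meta_batch_size=2,
                     batches_per_epoch=3, outer_lr=3e-3, inner_lr=0.05,
                     dropout_train=False)
    params, log = conventional_train(model, fx.dataset, fx.tasks[:6], cfg, seed=0)
    assert set(params) == set(model.init_params(0))
    assert log[-1]["loss"] < log[0]["loss"]
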