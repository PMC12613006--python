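"""Cell-line branch: GCN, pathway-masked aggregation, self-attention."""

import numpy as np
import pytest

from fewdrp import autodiff as ad
from fewdrp import nn
from fewdrp.autodiff import Tensor
from fewdrp.cell_encoder import (build_pathway_mask, encode_cell, gcn_forward,
                                 init_cell_params, pathway_self_attention,
                                 sparse_aggregate)
from fewdrp.pathway_network import PathwayCollection


# ----------------------------------------------------------------------
# mask
# ----------------------------------------------------------------------

def test_mask_rows_match_membership():
    coll = PathwayCollection([("P1", frozenset({"g1", "g2"}))])
    mask = build_pathway_mask(coll, ["g1", "g2", "g3"])
    assert np.array_equal(mask, [[1, 1, 0]])


def test_mask_total_equals_sum_of_sizes(tiny_collection, tiny_network):
    mask = build_pathway_mask(tiny_collection, tiny_network.gene_ids)
    assert mask.sum() == sum(len(g) for _, g in tiny_collection.pathways)


def test_overlapping_pathways_share_columns():
    coll = PathwayCollection([("P1", frozenset({"a", "b"})),
                              ("P2", frozenset({"b", "c"}))])
    mask = build_pathway_mask(coll, ["a", "b", "c"])
    assert mask[:, 1].sum() == 2


def test_mask_missing_gene_is_an_error():
    coll = PathwayCollection([("P1", frozenset({"a", "zz"}))])
    with pytest.raises(ValueError, match="zz"):
        build_pathway_mask(coll, ["a", "b"])


# ----------------------------------------------------------------------
# GCN
# ----------------------------------------------------------------------

def test_zero_conv_weights_reduce_to_input_projection(tiny_model, tiny_params):
    params = dict(tiny_params)
    for i in range(3):
        params[f"cell.gcn{i}.W"] = Tensor(np.zeros_like(params[f"cell.gcn{i}.W"].data))
        params[f"cell.gcn{i}.b"] = Tensor(np.zeros_like(params[f"cell.gcn{i}.b"].data))
    x = np.random.default_rng(0).normal(size=(2, tiny_model.network.n, 4))
    h = gcn_forward(x, tiny_model.adj_norm_self, params)
    proj = nn.dense(ad.as_tensor(x), params, "cell.in")
    assert np.allclose(h.data, proj.data)


def test_gcn_is_permutation_equivariant(tiny_model, tiny_params):
    rng = np.random.default_rng(1)
    n = tiny_model.network.n
    x = rng.normal(size=(1, n, 4))
    h = gcn_forward(x, tiny_model.adj_norm_self, tiny_params).data
    perm = rng.permutation(n)
    A = tiny_model.adj_norm_self.toarray()
    hp = gcn_forward(x[:, perm], A[np.ix_(perm, perm)], tiny_params).data
    assert np.allclose(hp, h[:, perm], atol=1e-10)


def test_isolated_node_sees_only_self_loop():
    # degree-0 node with self loop: normalised weight 1, one layer by hand
    from fewdrp.pathway_network import GeneNetwork, normalize_adjacency
    net = GeneNetwork(gene_ids=["a"], edges=set(), adjacency=np.zeros((1, 1)))
    A = normalize_adjacency(net, add_self_loops=True)
    assert A[0, 0] == pytest.approx(1.0)
    params = {}
    rng = np.random.default_rng(2)
    init_cell_params(params, rng, 2, 4, 4, np.ones((1, 1)), heads=2)
    x = rng.normal(size=(1, 1, 2))
    h = gcn_forward(x, A, params)
    # hand evaluation of layer 1 on the projected input
    p = x[0, 0] @ params["cell.in.W"].data + params["cell.in.b"].data
    conv = p @ params["cell.gcn0.W"].data + params["cell.gcn0.b"].data
    l1 = np.maximum(conv, 0) + p
    conv2 = l1 @ params["cell.gcn1.W"].data + params["cell.gcn1.b"].data
    l2 = np.maximum(conv2, 0) + l1
    conv3 = l2 @ params["cell.gcn2.W"].data + params["cell.gcn2.b"].data
    l3 = np.maximum(conv3, 0) + l2
    assert np.allclose(h.data[0, 0], l3)


# ----------------------------------------------------------------------
# sparse aggregation
# ----------------------------------------------------------------------

def test_non_member_perturbation_leaves_pathway_untouched(tiny_model, tiny_params):
    rng = np.random.default_rng(3)
    n = tiny_model.network.n
    h = rng.normal(size=(1, n, tiny_model.config.hidden))
    base = sparse_aggregate(ad.as_tensor(h), tiny_params, tiny_model.mask).data
    for _ in range(20):
        p = rng.integers(tiny_model.n_pathways)
        non_members = np.flatnonzero(tiny_model.mask[p] == 0)
        g = rng.choice(non_members)
        h2 = h.copy()
        h2[0, g] += rng.normal(size=tiny_model.config.hidden) * 10
        out = sparse_aggregate(ad.as_tensor(h2), tiny_params, tiny_model.mask).data
        assert np.array_equal(out[0, p], base[0, p])  # bit-exact


def test_unit_weights_identity_map_equals_loop_sum(tiny_model):
    cfg = tiny_model.config
    P, n = tiny_model.mask.shape
    params = {
        "cell.sparse.W": Tensor(np.ones((P, n))),
        "cell.emb.W": Tensor(np.stack([np.eye(cfg.hidden)] * P)),
        "cell.emb.b": Tensor(np.zeros((P, cfg.hidden))),
    }
    rng = np.random.default_rng(4)
    h = rng.normal(size=(2, n, cfg.hidden))
    out = sparse_aggregate(ad.as_tensor(h), params, tiny_model.mask).data
    for p in range(P):
        members = np.flatnonzero(tiny_model.mask[p])
        expected = h[:, members].sum(axis=1)
        assert np.allclose(out[:, p], expected, atol=1e-12)


def test_empty_pathway_row_warns_and_is_bias_only(tiny_model, tiny_params, caplog):
    import logging
    mask = tiny_model.mask.copy()
    mask[0, :] = 0
    rng = np.random.default_rng(5)
    h = rng.normal(size=(1, tiny_model.network.n, tiny_model.config.hidden))
    with caplog.at_level(logging.WARNING):
        out = sparse_aggregate(ad.as_tensor(h), tiny_params, mask).data
    assert "empty" in caplog.text
    assert np.allclose(out[0, 0], tiny_params["cell.emb.b"].data[0])


def test_off_mask_weights_stay_zero_through_training(tiny_model, tiny_params):
    # gradient steps cannot leak weight outside the mask because the mask
    # multiplies the weights in every forward pass
    params = dict(tiny_params)
    opt = nn.Adam(lr=0.05)
    rng = np.random.default_rng(6)
    names = list(params)
    for _ in range(3):
        h = rng.normal(size=(1, tiny_model.network.n, tiny_model.config.hidden))
        out = sparse_aggregate(ad.as_tensor(h), params, tiny_model.mask)
        loss = ad.tsum(out * out)
        grads = ad.grad(loss, [params[k] for k in names])
        params = opt.step(params, dict(zip(names, grads)))
    W = params["cell.sparse.W"].data * (1 - tiny_model.mask)
    # the raw parameter may drift, but the effective (masked) weight is 0
    eff = (params["cell.sparse.W"].data * tiny_model.mask)[tiny_model.mask == 0]
    assert np.all(eff == 0)
    out = sparse_aggregate(ad.as_tensor(np.zeros((1, tiny_model.network.n,
                                                  tiny_model.config.hidden))),
                           params, tiny_model.mask)
    assert np.all(np.isfinite(out.data))


# ----------------------------------------------------------------------
# pathway self-attention
# ----------------------------------------------------------------------

def test_attention_rows_sum_to_one(tiny_model, tiny_params):
    rng = np.random.default_rng(7)
    z = rng.normal(size=(2, tiny_model.n_pathways, tiny_model.config.n_e))
    _, probs = pathway_self_attention(ad.as_tensor(z), tiny_params,
                                      tiny_model.config.cell_heads)
    assert np.allclose(probs.data.sum(axis=-1), 1.0, atol=1e-6)


def test_single_pathway_attention_weight_is_one():
    params = {}
    init_cell_params(params, np.random.default_rng(8), 2, 4, 4,
                     np.ones((1, 3)), heads=2)
    z = np.random.default_rng(9).normal(size=(1, 1, 4))
    _, probs = pathway_self_attention(ad.as_tensor(z), params, 2)
    assert np.allclose(probs.data, 1.0)


def test_identical_tokens_attend_uniformly(tiny_model, tiny_params):
    P = tiny_model.n_pathways
    z = np.tile(np.random.default_rng(10).normal(size=(1, 1, tiny_model.config.n_e)),
                (1, P, 1))
    _, probs = pathway_self_attention(ad.as_tensor(z), tiny_params,
                                      tiny_model.config.cell_heads)
    assert np.allclose(probs.data, 1.0 / P, atol=1e-9)


def test_full_branch_output_shape_and_permutation_invariance(tiny_model, tiny_params):
    rng = np.random.default_rng(11)
    n, P = tiny_model.network.n, tiny_model.n_pathways
    x = rng.normal(size=(2, n, 4))
    z, _ = encode_cell(x, tiny_model.adj_norm_self, tiny_params,
                       tiny_model.mask, tiny_model.config.cell_heads)
    assert z.shape == (2, P, tiny_model.config.n_e)

    perm = rng.permutation(n)
    A = tiny_model.adj_norm_self.toarray()
    params_p = dict(tiny_params)
    params_p["cell.sparse.W"] = Tensor(tiny_params["cell.sparse.W"].data[:, perm])
    zp, _ = encode_cell(x[:, perm], A[np.ix_(perm, perm)], params_p,
                        tiny_model.mask[:, perm], tiny_model.config.cell_heads)
    assert np.allclose(zp.data, z.data, atol=1e-5)
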