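"""Gene-set loading, subnetwork extraction and clamped feature propagation."""

import numpy as np
import pytest

from fewdrp.pathway_network import (GeneNetwork, OmicsProfile,
                                    PathwayCollection, build_subnetwork,
                                    convergence_series, load_gene_sets,
                                    normalize_adjacency, propagate_features)


# ----------------------------------------------------------------------
# GMT loading
# ----------------------------------------------------------------------

def test_gmt_parsing_counts_and_dedup(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("P1\tdesc\tA\tB\tC\nP2\tdesc\tD\tE\tF\tG1\tG1\n")
    coll = load_gene_sets(p)
    assert len(coll) == 2
    assert len(coll.members("P1")) == 3
    assert len(coll.members("P2")) == 4  # G1 counted once


def test_gmt_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.gmt"
    p.write_text("P1\tdesc\tA\nP2\tonlytwo\n")
    with pytest.raises(ValueError, match="bad.gmt:2"):
        load_gene_sets(p)


def test_gmt_empty_file_rejected(tmp_path):
    p = tmp_path / "empty.gmt"
    p.write_text("")
    with pytest.raises(ValueError, match="empty"):
        load_gene_sets(p)


# ----------------------------------------------------------------------
# subnetwork
# ----------------------------------------------------------------------

def test_subnetwork_restricts_to_pathway_universe():
    coll = PathwayCollection([("P1", frozenset("abc"))])
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
    net = build_subnetwork(edges, coll)
    assert net.gene_ids == ["a", "b", "c"]
    assert net.edges == {frozenset("ab"), frozenset("bc")}


def test_subnetwork_keeps_isolated_pathway_genes():
    coll = PathwayCollection([("P1", frozenset({"a", "b", "z"}))])
    net = build_subnetwork([("a", "b")], coll)
    assert "z" in net.gene_ids
    assert net.degree[net.gene_ids.index("z"), net.gene_ids.index("z")] == 0


def test_subnetwork_complete_graph_edge_count():
    # brute-force enumeration: K4 has C(4,2) = 6 edges
    genes = ["a", "b", "c", "d"]
    coll = PathwayCollection([("P1", frozenset(genes))])
    edges = [(g1, g2) for i, g1 in enumerate(genes) for g2 in genes[i + 1:]]
    assert len(edges) == 6
    net = build_subnetwork(edges, coll)
    assert len(net.edges) == 6


# ----------------------------------------------------------------------
# normalisation
# ----------------------------------------------------------------------

def test_normalized_single_edge_and_path():
    net = GeneNetwork(gene_ids=["a", "b"], edges={frozenset("ab")},
                      adjacency=np.array([[0., 1.], [1., 0.]]))
    A = normalize_adjacency(net)
    assert A[0, 1] == pytest.approx(1.0)  # 1/sqrt(1*1)
    assert np.all(np.diag(A) == 0)

    path = GeneNetwork(gene_ids=["a", "b", "c"],
                       edges={frozenset("ab"), frozenset("bc")},
                       adjacency=np.array([[0., 1., 0.], [1., 0., 1.],
                                           [0., 1., 0.]]))
    Ap = normalize_adjacency(path)
    assert Ap[0, 1] == pytest.approx(1 / np.sqrt(2))
    assert np.allclose(Ap, Ap.T)


def test_normalized_isolated_node_row_is_zero():
    net = GeneNetwork(gene_ids=["a", "b", "z"], edges={frozenset("ab")},
                      adjacency=np.array([[0., 1., 0.], [1., 0., 0.],
                                          [0., 0., 0.]]))
    A = normalize_adjacency(net)
    assert np.all(A[2] == 0) and np.all(A[:, 2] == 0)


# ----------------------------------------------------------------------
# feature propagation
# ----------------------------------------------------------------------

def test_fully_observed_profile_is_fixed_point(tiny_network):
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(tiny_network.n, 2))
    prof = OmicsProfile(sample_id="s", tissue="t", values=vals,
                        observed=np.ones_like(vals, dtype=bool))
    A = normalize_adjacency(tiny_network)
    out = propagate_features(prof, A, iterations=7)
    assert np.array_equal(out.values, vals)
    assert all(d == 0 for d in convergence_series(prof, A, 5))


def test_path_imputation_hand_value(path_profile):
    # middle node: (1 + 3)/sqrt(2) = 2*sqrt(2), reached in one step and fixed
    net, prof = path_profile
    A = normalize_adjacency(net)
    out = propagate_features(prof, A, iterations=1)
    assert out.values[1, 0] == pytest.approx(2 * np.sqrt(2), abs=1e-12)
    out40 = propagate_features(prof, A, iterations=40)
    assert out40.values[1, 0] == pytest.approx(2 * np.sqrt(2), abs=1e-12)
    series = convergence_series(prof, A, 5)
    assert series[0] > 0
    assert all(s == pytest.approx(0, abs=1e-15) for s in series[1:])


def test_observed_entries_clamped_bit_exactly(tiny_network):
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(tiny_network.n, 4))
    obs = rng.random(vals.shape) > 0.4
    prof = OmicsProfile(sample_id="s", tissue="t",
                        values=np.where(obs, vals, 0.0), observed=obs)
    A = normalize_adjacency(tiny_network)
    out = propagate_features(prof, A, iterations=40)
    assert np.array_equal(out.values[obs], vals[obs])  # bit-exact
    assert np.all(np.isfinite(out.values))


def test_missing_value_on_isolated_node_stays_zero():
    net = GeneNetwork(gene_ids=["a", "b", "z"], edges={frozenset("ab")},
                      adjacency=np.array([[0., 1., 0.], [1., 0., 0.],
                                          [0., 0., 0.]]))
    prof = OmicsProfile(sample_id="s", tissue="t",
                        values=np.array([[1.], [2.], [0.]]),
                        observed=np.array([[True], [True], [False]]))
    out = propagate_features(prof, normalize_adjacency(net), iterations=40)
    assert out.values[2, 0] == 0.0


def test_convergence_series_non_increasing_tail(tiny_network):
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(tiny_network.n, 1))
    obs = rng.random(vals.shape) > 0.5
    prof = OmicsProfile(sample_id="s", tissue="t",
                        values=np.where(obs, vals, 0.0), observed=obs)
    series = convergence_series(prof, normalize_adjacency(tiny_network), 40)
    assert len(series) == 40
    tail = np.array(series[1:])
    assert np.all(np.diff(tail) <= 1e-12)


def test_propagation_is_permutation_consistent(tiny_network):
    rng = np.random.default_rng(3)
    n = tiny_network.n
    vals = rng.normal(size=(n, 2))
    obs = rng.random(vals.shape) > 0.5
    prof = OmicsProfile(sample_id="s", tissue="t",
                        values=np.where(obs, vals, 0.0), observed=obs)
    A = normalize_adjacency(tiny_network)
    out = propagate_features(prof, A, iterations=15).values

    perm = rng.permutation(n)
    prof_p = OmicsProfile(sample_id="s", tissue="t",
                          values=np.where(obs, vals, 0.0)[perm],
                          observed=obs[perm])
    out_p = propagate_features(prof_p, A[np.ix_(perm, perm)],
                               iterations=15).values
    assert np.allclose(out_p, out[perm], atol=1e-12)


def test_iteration_count_must_be_positive(path_profile):
    net, prof = path_profile
    with pytest.raises(ValueError):
        propagate_features(prof, normalize_adjacency(net), iterations=0)
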