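"""Correlation, mutual rank, decay weights and network assembly."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import coexpnet as cx
from coexpnet.network import CorrelationError

from . import oracles


# -- correlation ------------------------------------------------------------

def test_linear_pair_has_unit_correlation(toy_matrix):
    for method in ("pearson", "spearman"):
        corr = cx.correlation_all_pairs(toy_matrix, method)
        i, j = corr.gene_ids.index("gA"), corr.gene_ids.index("gB")
        assert corr.values[i, j] == pytest.approx(1.0)


def test_monotone_nonlinear_pair_separates_methods():
    m = pd.DataFrame(
        {"s%d" % k: [v, math.exp(v)] for k, v in enumerate([0.1, 0.5, 1.5, 2.5, 4.0])},
        index=["gA", "gB"],
    )
    rho = cx.correlation_all_pairs(m, "spearman").values[0, 1]
    r = cx.correlation_all_pairs(m, "pearson").values[0, 1]
    assert rho == pytest.approx(1.0)
    assert r < 1.0


@pytest.mark.parametrize("method", ["pearson", "spearman"])
def test_correlation_matches_bruteforce_on_toy(toy_matrix, method):
    corr = cx.correlation_all_pairs(toy_matrix, method)
    expect = oracles.correlation_matrix_brute(toy_matrix.to_numpy().tolist(), method)
    assert np.allclose(corr.values, expect, atol=1e-12)
    assert np.allclose(corr.values, corr.values.T)
    assert np.allclose(np.diag(corr.values), 1.0)


def test_zero_variance_genes_are_rejected_and_listable(toy_matrix):
    bad = toy_matrix.copy()
    bad.loc["gFlat"] = 2.0
    with pytest.raises(CorrelationError, match="gFlat"):
        cx.correlation_all_pairs(bad, "pearson")
    kept, dropped = cx.drop_zero_variance(bad)
    assert dropped == ["gFlat"]
    assert list(kept.index) == list(toy_matrix.index)


def test_too_few_samples_rejected(toy_matrix):
    with pytest.raises(CorrelationError, match="3 samples"):
        cx.correlation_all_pairs(toy_matrix.iloc[:, :2], "pearson")


# -- rank lists and mutual rank --------------------------------------------

def test_rank_lists_match_sort_oracle(toy_matrix):
    corr = cx.correlation_all_pairs(toy_matrix, "pearson")
    got = cx.rank_lists(corr)
    expect = oracles.rank_lists_brute(corr.values.tolist(), list(corr.gene_ids))
    assert got.tolist() == expect


def test_rank_best_correlate_is_rank_one(toy_matrix):
    corr = cx.correlation_all_pairs(toy_matrix, "pearson")
    ranks = cx.rank_lists(corr)
    i = corr.gene_ids.index("gA")
    j = corr.gene_ids.index("gB")
    assert ranks[i, j] == 1  # gB is gA's perfect correlate


def test_rank_ties_broken_by_ascending_gene_id():
    # gX correlates identically with gB and gC (duplicated profiles).
    m = pd.DataFrame(
        [[1.0, 2, 3, 4], [2.0, 4, 6, 9], [2.0, 4, 6, 9], [9, 2, 7, 1]],
        index=["gA", "gB", "gC", "gD"],
        columns=list("wxyz"),
    )
    corr = cx.correlation_all_pairs(m, "pearson")
    ranks = cx.rank_lists(corr)
    ia = corr.gene_ids.index("gA")
    assert ranks[ia, corr.gene_ids.index("gB")] == 1
    assert ranks[ia, corr.gene_ids.index("gC")] == 2


def test_mutual_rank_matches_double_loop_oracle(toy_matrix):
    corr = cx.correlation_all_pairs(toy_matrix, "pearson")
    mr = cx.mutual_rank(corr)
    expect = oracles.mutual_rank_brute(corr.values.tolist(), list(corr.gene_ids))
    n = len(corr.gene_ids)
    for i in range(n):
        for j in range(n):
            if i != j:
                assert mr.values[i, j] == pytest.approx(expect[i][j], abs=1e-12)
    off = mr.values[~np.eye(n, dtype=bool)]
    assert np.all(off >= 1.0)
    assert np.allclose(mr.values[~np.eye(n, dtype=bool)],
                       mr.values.T[~np.eye(n, dtype=bool)])


def test_mutual_best_partners_have_mr_one(toy_matrix):
    corr = cx.correlation_all_pairs(toy_matrix, "pearson")
    mr = cx.mutual_rank(corr)
    i, j = corr.gene_ids.index("gA"), corr.gene_ids.index("gB")
    assert mr.values[i, j] == pytest.approx(1.0)


# -- decay weights ----------------------------------------------------------

def test_decay_weight_formula_and_monotonicity():
    for x in (5, 10, 25):
        assert cx.decay_weight(1.0, x) == pytest.approx(1.0, abs=1e-15)
    assert cx.decay_weight(4.0, 10) == pytest.approx(math.exp(-0.3), abs=1e-15)
    # rank(A->B)=2, rank(B->A)=8 gives MR=4
    assert math.sqrt(2 * 8) == 4.0
    # analytic 0.1 crossing at MR = 1 + x ln 10
    for x in (5, 10, 25):
        assert cx.decay_weight(1 + x * math.log(10), x) == pytest.approx(0.1, abs=1e-12)
    assert cx.decay_weight(10, 25) > cx.decay_weight(10, 10) > cx.decay_weight(10, 5)
    with pytest.raises(ValueError):
        cx.decay_weight(0.5, 10)
    with pytest.raises(ValueError):
        cx.decay_weight(5.0, 0)


# -- network assembly -------------------------------------------------------

def test_mr_network_filter_is_a_conjunction():
    # gA,gB,gC tightly correlated; gD anti-correlated with all (pcc < 0.3)
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, 30)
    m = pd.DataFrame(
        [base, base + rng.normal(0, 0.05, 30), base + rng.normal(0, 0.05, 30), -base],
        index=["gA", "gB", "gC", "gD"],
        columns=[f"s{i}" for i in range(30)],
    )
    net = cx.build_mr_network(m, x=10)
    assert net.has_edge("gA", "gB")
    assert not any("gD" in e for e in net.edges)  # PCC filter removes gD
    for _, _, d in net.edges(data=True):
        assert d["weight"] >= 0.1 and d["pcc"] >= 0.3


def test_network_nesting_on_rare_scenario(rare_scenario):
    matrix, _ = rare_scenario
    nets = cx.build_mr_networks(matrix)
    e05 = set(map(frozenset, nets["NET05"].edges))
    e10 = set(map(frozenset, nets["NET10"].edges))
    e25 = set(map(frozenset, nets["NET25"].edges))
    assert e05 <= e10 <= e25
    assert len(e05) < len(e25)
    assert nets["NET05"].graph["name"] == "NET05"
    assert nets["NET25"].graph["x"] == 25.0


def test_scc_network_uses_absolute_rho(toy_matrix):
    net = cx.build_scc_network(toy_matrix, rho_min=0.5)
    assert net.has_edge("gA", "gB")
    assert net.edges["gA", "gB"]["rho"] == pytest.approx(1.0)
    assert net.has_edge("gA", "gC")  # anti-monotone pair kept, signed rho
    assert net.edges["gA", "gC"]["rho"] < 0


def test_scc_network_of_independent_noise_is_nearly_empty():
    rng = np.random.default_rng(7)
    m = pd.DataFrame(
        rng.normal(4, 0.5, (40, 150)),
        index=[f"g{i:02d}" for i in range(40)],
        columns=[f"s{i}" for i in range(150)],
    )
    net = cx.build_scc_network(m, rho_min=0.5)
    assert net.number_of_edges() == 0


def test_spearman_network_invariant_under_monotone_transform(rare_scenario):
    matrix, _ = rare_scenario
    sub = matrix.iloc[:60]
    net_a = cx.build_scc_network(sub)
    transformed = sub.copy()
    transformed.iloc[::2] = np.exp(transformed.iloc[::2] / 4.0)  # monotone per gene
    transformed.iloc[1::2] = transformed.iloc[1::2] ** 3 + 1.0
    net_b = cx.build_scc_network(transformed)
    assert set(map(frozenset, net_a.edges)) == set(map(frozenset, net_b.edges))


def test_mr_advantage_for_rare_groups(rare_scenario):
    """Planted pairs sit in each other's MR top-10 far more often than
    confounder-group pairs do."""
    matrix, truth = rare_scenario
    mr = cx.mutual_rank(cx.correlation_all_pairs(matrix, "pearson"))
    gi = {g: i for i, g in enumerate(mr.gene_ids)}
    in_frac = []
    for members in truth.group_members.values():
        idx = [gi[g] for g in sorted(members)]
        sub = mr.values[np.ix_(idx, idx)]
        pairs = sub[~np.eye(len(idx), dtype=bool)]
        in_frac.append(np.mean(pairs <= 10))
    planted = sorted(set().union(*truth.group_members.values()))
    pidx = [gi[g] for g in planted]
    cidx = [gi[g] for g in sorted(truth.confounders)]
    conf_frac = np.mean(mr.values[np.ix_(cidx, pidx)] <= 10)
    assert np.mean(in_frac) > conf_frac


def test_subnetwork_containing_components(clique_pair):
    g = clique_pair.copy()
    g.add_node("lonely")
    sub = cx.subnetwork_containing(g, {"lonely"})
    assert set(sub.nodes) == {"lonely"}
    # both cliques are one component (bridged): returned once
    sub2 = cx.subnetwork_containing(g, {"a1", "b2"})
    assert sub2.number_of_nodes() == 10
    big = cx.largest_component(g)
    assert big.number_of_nodes() == 10


def test_regulator_component_contains_target_groups(compendium, compendium_networks):
    _, truth = compendium
    scc = compendium_networks["SCC"]
    for reg in sorted(truth.global_regulators):
        comp = cx.subnetwork_containing(scc, {reg})
        for t in truth.regulator_targets[reg]:
            members = truth.group_members[t]
            frac = len(members & set(comp.nodes)) / len(members)
            assert frac >= 0.8
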