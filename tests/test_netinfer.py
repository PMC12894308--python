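"""Spearman matrices (vs exhaustive permutation), thresholding, subnetworks."""

from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import n2onet as nn
from n2onet.datatypes import InsufficientDataError, NormalizedTable


def norm_from(matrix: np.ndarray) -> NormalizedTable:
    matrix = np.asarray(matrix, dtype=float)
    idx = [f"t{i}" for i in range(matrix.shape[0])]
    cols = [f"s{j}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, index=idx, columns=cols)
    return NormalizedTable(
        rel_abund=df,
        tmm_factor=pd.Series(1.0, index=cols),
        effective_libsize=pd.Series(1.0, index=cols),
    )


def exact_spearman_p(x, y):
    """Two-sided p by full enumeration of rank permutations (distinct ranks)."""
    x = np.asarray(x, float)
    n = len(x)
    xc = x - x.mean()
    denom = np.sqrt((xc**2).sum())

    def rho_of(v):
        vc = v - v.mean()
        return float((xc * vc).sum() / (denom * np.sqrt((vc**2).sum())))

    observed = rho_of(np.asarray(y, float))
    rhos = np.array([rho_of(np.asarray(p, float)) for p in permutations(range(n))])
    return observed, float(np.mean(np.abs(rhos) >= abs(observed) - 1e-12))


def test_monotone_pairs_give_extreme_rho():
    m = np.array([[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [5, 4, 3, 2, 1]], float)
    corr = nn.spearman_matrix(norm_from(m))
    assert corr.rho.iloc[0, 1] == pytest.approx(1.0)
    assert corr.pval.iloc[0, 1] == 0.0
    assert corr.rho.iloc[0, 2] == pytest.approx(-1.0)
    assert corr.pval.iloc[0, 2] == 0.0


def test_rho_and_p_against_exhaustive_enumeration():
    x = [1, 2, 3, 4, 5]
    y = [1, 3, 2, 5, 4]
    corr = nn.spearman_matrix(norm_from(np.array([x, y], float)))
    rho_exact, p_exact = exact_spearman_p(x, y)
    assert rho_exact == pytest.approx(0.8)
    assert corr.rho.iloc[0, 1] == pytest.approx(rho_exact, abs=1e-12)
    # t approximation agrees with the permutation null to its granularity
    assert corr.pval.iloc[0, 1] == pytest.approx(p_exact, abs=0.10)


def test_constant_row_flagged():
    m = np.array([[1, 2, 3, 4, 5], [2, 2, 2, 2, 2]], float)
    corr = nn.spearman_matrix(norm_from(m))
    assert corr.constant_taxa == ["t1"]
    assert corr.rho.iloc[0, 1] == 0.0
    assert corr.pval.iloc[0, 1] == 1.0


def test_too_few_samples_raises():
    with pytest.raises(InsufficientDataError):
        nn.spearman_matrix(norm_from(np.ones((3, 3))))


def test_symmetry_and_bounds_random():
    rng = np.random.default_rng(2)
    corr = nn.spearman_matrix(norm_from(rng.random((12, 9))))
    r, p = corr.rho.to_numpy(), corr.pval.to_numpy()
    assert np.allclose(r, r.T) and np.allclose(p, p.T)
    assert (np.abs(r) <= 1).all() and ((p >= 0) & (p <= 1)).all()
    assert np.allclose(np.diag(r), 1.0) and np.allclose(np.diag(p), 0.0)


# ---------------------------------------------------------------------------
# thresholding


def corr_from(rho: np.ndarray, pval: np.ndarray) -> nn.CorrelationResult:
    idx = [f"t{i}" for i in range(rho.shape[0])]
    return nn.CorrelationResult(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        pval=pd.DataFrame(pval, index=idx, columns=idx),
        n_used=9,
    )


def test_threshold_boundary_cases():
    rho = np.eye(3)
    rho[0, 1] = rho[1, 0] = 0.71
    rho[0, 2] = rho[2, 0] = 0.69
    pval = np.full((3, 3), 0.001)
    np.fill_diagonal(pval, 0.0)
    net = nn.threshold_network(corr_from(rho, pval))
    assert net.has_edge("t0", "t1") and net["t0"]["t1"]["sign"] == "+"
    assert not net.has_edge("t0", "t2")  # fails the rho criterion
    assert net.graph["rho_min"] == 0.7 and net.graph["p_max"] == 0.05


def test_threshold_matches_brute_force_double_loop():
    rng = np.random.default_rng(5)
    n = 6
    a = rng.uniform(-1, 1, size=(n, n))
    rho = (a + a.T) / 2
    np.fill_diagonal(rho, 1.0)
    p = rng.uniform(0, 0.2, size=(n, n))
    p = (p + p.T) / 2
    np.fill_diagonal(p, 0.0)
    net = nn.threshold_network(corr_from(rho, p))
    expected = set()
    for i in range(n):
        for j in range(i + 1, n):
            if abs(rho[i, j]) > 0.7 and p[i, j] < 0.05:
                expected.add((f"t{i}", f"t{j}"))
    assert {tuple(sorted(e)) for e in net.edges} == expected
    for a_, b_ in net.edges:
        assert net[a_][b_]["sign"] == ("+" if net[a_][b_]["weight"] > 0 else "-")


def test_threshold_monotone_in_thresholds():
    rng = np.random.default_rng(8)
    a = rng.uniform(-1, 1, size=(10, 10))
    rho = (a + a.T) / 2
    np.fill_diagonal(rho, 1.0)
    p = rng.uniform(0, 0.1, size=(10, 10))
    p = (p + p.T) / 2
    np.fill_diagonal(p, 0.0)
    base = nn.threshold_network(corr_from(rho, p), rho_min=0.5, p_max=0.05)
    stricter = nn.threshold_network(corr_from(rho, p), rho_min=0.7, p_max=0.01)
    assert set(stricter.edges) <= set(base.edges)


# ---------------------------------------------------------------------------
# subnetworks


@pytest.fixture
def presence_fixture():
    counts = pd.DataFrame(
        {
            "s1": [5, 5, 5, 5],  # all taxa
            "s2": [5, 0, 0, 5],  # t0, t3 only
            "s3": [0, 5, 0, 0],
        },
        index=["t0", "t1", "t2", "t3"],
    )
    md = pd.DataFrame(
        {"treatment": ["a", "a", "b"]}, index=counts.columns
    )
    table = nn.CountTable(counts, md)
    net = nx.Graph(rho_min=0.7, p_max=0.05)
    net.add_nodes_from(["t0", "t1", "t2", "t3"])
    net.add_edge("t0", "t1", weight=0.9, sign="+")
    net.add_edge("t2", "t3", weight=-0.8, sign="-")
    return table, net


def test_sample_subnetwork_full_and_induced(presence_fixture):
    table, net = presence_fixture
    full = nn.sample_subnetwork(net, table, "s1")
    assert set(full.edges) == set(net.edges)
    sub = nn.sample_subnetwork(net, table, "s2")
    assert set(sub.nodes) == {"t0", "t3"}
    assert sub.number_of_edges() == 0
    with pytest.raises(KeyError):
        nn.sample_subnetwork(net, table, "nope")


def test_treatment_subnetwork_union_presence(presence_fixture):
    table, net = presence_fixture
    sub = nn.treatment_subnetwork(net, table, "a")
    assert set(sub.nodes) == {"t0", "t1", "t2", "t3"}
    assert set(map(tuple, map(sorted, sub.edges))) == {("t0", "t1"), ("t2", "t3")}
    b = nn.treatment_subnetwork(net, table, "b")
    assert set(b.nodes) == {"t1"}
    with pytest.raises(KeyError):
        nn.treatment_subnetwork(net, table, "zzz")


def test_subnetwork_nesting_on_generated_data():
    table, *_ = nn.generate_community(nn.power_config(seed=1))
    filt = nn.filter_low_abundance(table)
    net = nn.threshold_network(nn.spearman_matrix(nn.normalize(filt)))
    for t in dict.fromkeys(table.treatments):
        tnet = nn.treatment_subnetwork(net, filt, t)
        assert set(tnet.edges) <= set(net.edges)
        samples = table.metadata.index[table.metadata["treatment"] == t]
        for s in samples[:2]:
            snet = nn.sample_subnetwork(net, filt, s)
            assert set(snet.edges) <= set(tnet.edges)


def test_background_taxa_false_edge_rate():
    """Independent (module-0) taxa rarely pass the edge thresholds."""
    rates = []
    for seed in range(30):
        table, *_ = nn.generate_community(nn.power_config(seed=seed))
        filt = nn.filter_low_abundance(table)
        corr = nn.spearman_matrix(nn.normalize(filt))
        net = nn.threshold_network(corr)
        background = [t for t in filt.taxa if int(t[2:]) >= 30]  # modules 1-3 use 0..29
        bg = set(background)
        n_bg_edges = sum(1 for a, b in net.edges if a in bg and b in bg)
        n_pairs = len(background) * (len(background) - 1) / 2
        rates.append(n_bg_edges / n_pairs)
    assert np.mean(rates) <= 5 * 0.05
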