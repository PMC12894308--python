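"""Spearman correlation matrices and thresholded co-occurrence networks.

Edges connect genus pairs whose absolute Spearman correlation exceeds the rho
threshold with a two-sided p-value below the p threshold; edge sign follows
the correlation sign. Negative edges are first-class citizens — the absolute
value is thresholded, not the signed coefficient. Per-sample and
per-treatment subnetworks are induced from the single all-sample network on
the taxa present there, rather than re-estimated (per-treatment correlation
at n = 3 is degenerate).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ConsistencyError,
    CorrelationResult,
    CountTable,
    InsufficientDataError,
    NormalizedTable,
)


def spearman_matrix(norm: NormalizedTable) -> CorrelationResult:
    """All-pairs Spearman rho with two-sided t-approximation p-values.

    Mid-ranks are used for ties. p = 2 P(T_{n-2} > |t|) with
    t = rho sqrt((n-2)/(1-rho^2)); |rho| = 1 gives p = 0 exactly. Rows with
    zero variance get rho = 0, p = 1 and are flagged.
    """
    X = norm.rel_abund.to_numpy(dtype=float)
    n_taxa, n = X.shape
    if n < 4:
        raise InsufficientDataError(
            "Spearman p-values need at least 4 samples"
        )
    if n_taxa < 2:
        raise InsufficientDataError("need at least 2 taxa")
    ranks = stats.rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    rc = ranks.copy()
    # give constant rows unit variance so corrcoef stays finite; overwritten below
    rc[constant, :] = np.arange(n)
    rho = np.corrcoef(rc)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    pval = _spearman_p(rho, n)
    pval[constant, :] = 1.0
    pval[:, constant] = 1.0
    np.fill_diagonal(pval, 0.0)

    taxa = norm.taxa
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        pval=pd.DataFrame(pval, index=taxa, columns=taxa),
        n_used=n,
        constant_taxa=[t for t, c in zip(taxa, constant) if c],
    )


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with df = n - 2."""
    r = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0 - 1e-12, 0.0, p)
    return np.clip(p, 0.0, 1.0)


def threshold_network(
    corr: CorrelationResult, rho_min: float = 0.7, p_max: float = 0.05
) -> nx.Graph:
    """Build the signed co-occurrence graph from a correlation result.

    Edge (i, j) exists iff |rho_ij| > rho_min and p_ij < p_max; the edge
    carries ``weight`` (signed rho) and ``sign`` ('+'/'-'). All taxa stay in
    the node set; isolated ones get ``isolated=True``. Thresholds are
    recorded in ``G.graph`` for provenance.
    """
    if not (0.0 <= rho_min < 1.0):
        raise ValueError("rho_min must be in [0, 1)")
    rho = corr.rho.to_numpy()
    pval = corr.pval.to_numpy()
    taxa = corr.taxa
    G = nx.Graph(rho_min=rho_min, p_max=p_max, n_samples=corr.n_used)
    G.add_nodes_from(taxa)
    iu, ju = np.triu_indices(len(taxa), k=1)
    hit = (np.abs(rho[iu, ju]) > rho_min) & (pval[iu, ju] < p_max)
    for i, j in zip(iu[hit], ju[hit]):
        r = float(rho[i, j])
        G.add_edge(taxa[i], taxa[j], weight=r, sign="+" if r > 0 else "-")
    for node in G.nodes:
        G.nodes[node]["isolated"] = G.degree(node) == 0
    return G


def sample_subnetwork(net: nx.Graph, table: CountTable, sample_id: str) -> nx.Graph:
    """Induced subgraph on the taxa present (count > 0) in one sample."""
    if sample_id not in table.counts.columns:
        raise KeyError(f"unknown sample: {sample_id!r}")
    present = table.counts.index[table.counts[sample_id] > 0]
    return _induced(net, present)


def treatment_subnetwork(net: nx.Graph, table: CountTable, treatment: str) -> nx.Graph:
    """Induced subgraph on taxa present in >= 1 sample of a treatment."""
    samples = table.metadata.index[table.metadata["treatment"] == treatment]
    samples = [s for s in samples if s in table.counts.columns]
    if not samples:
        raise KeyError(f"unknown treatment: {treatment!r}")
    present = table.counts.index[(table.counts[samples] > 0).any(axis=1)]
    return _induced(net, present)


def _induced(net: nx.Graph, taxa) -> nx.Graph:
    nodes = [t for t in taxa if t in net]
    sub = net.subgraph(nodes).copy()
    sub.graph.update(net.graph)
    for node in sub.nodes:
        sub.nodes[node]["isolated"] = sub.degree(node) == 0
    return sub


def consistency_check(net: nx.Graph, corr: CorrelationResult) -> None:
    if set(net.nodes) - set(corr.taxa):
        raise ConsistencyError("network contains taxa absent from correlation")
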