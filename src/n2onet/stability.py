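"""Network robustness under random node removal, and community cohesion.

Robustness of a network after removing a fraction f of its nodes is the
proportion of surviving nodes that keep at least one surviving edge. Cohesion
summarizes, per sample, how strongly the community's abundant taxa are
correlated with the rest of the community: positive and negative taxon
connectedness (mean positive / negative off-diagonal correlation per taxon)
weighted by relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConsistencyError, CorrelationResult, NormalizedTable


@dataclass
class RobustnessCurve:
    fractions: list[float]
    values: np.ndarray  # fractions x reps, in [0, 1]
    reps: int
    seed: int
    summary_at: float = 0.5

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def sd(self) -> np.ndarray:
        return self.values.std(axis=1, ddof=1) if self.reps > 1 else np.zeros(len(self.fractions))

    def at(self, fraction: float) -> np.ndarray:
        for f, row in zip(self.fractions, self.values):
            if np.isclose(f, fraction):
                return row
        raise KeyError(f"fraction {fraction} not in curve")


@dataclass
class CohesionResult:
    pos_cohesion: pd.Series
    neg_cohesion: pd.Series
    connectedness_pos: pd.Series
    connectedness_neg: pd.Series
    null_corrected: bool = False


def robustness_curve(
    net: nx.Graph,
    fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    reps: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """Monte-Carlo robustness at each removal fraction.

    Each repetition removes floor(f * V) uniformly random nodes and scores
    the proportion of remaining nodes with >= 1 surviving edge. Edgeless
    networks score 0 everywhere.
    """
    fractions = list(fractions)
    if any(f >= 1.0 or f <= 0.0 for f in fractions):
        raise ValueError("removal fractions must be in (0, 1)")
    nodes = sorted(net.nodes)
    v = len(nodes)
    if v < 2:
        raise ValueError("network needs at least 2 nodes")
    idx = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((v, v), dtype=np.float64)
    for a, b in net.edges:
        adj[idx[a], idx[b]] = 1.0
        adj[idx[b], idx[a]] = 1.0

    rng = np.random.default_rng(seed)
    values = np.empty((len(fractions), reps))
    for fi, f in enumerate(fractions):
        n_remove = int(np.floor(f * v))
        n_keep = v - n_remove
        if n_keep == 0:
            values[fi, :] = 0.0
            continue
        # exact-count removal: keep the n_keep smallest uniform draws
        u = rng.random((reps, v))
        order = np.argsort(u, axis=1)
        keep = np.zeros((reps, v), dtype=bool)
        np.put_along_axis(keep, order[:, :n_keep], True, axis=1)
        kept_neighbors = keep.astype(np.float64) @ adj
        connected = (kept_neighbors > 0) & keep
        values[fi, :] = connected.sum(axis=1) / n_keep
    return RobustnessCurve(fractions=fractions, values=values, reps=reps, seed=seed)


def compare_robustness(
    a: RobustnessCurve, b: RobustnessCurve, at: float = 0.5
) -> tuple[float, float, float, bool]:
    """Welch two-sided t-test on repetition values at one removal fraction.

    Returns (t, df, p, degenerate_flag). Zero variance in both samples with
    equal means gives p = 1 by convention, flagged.
    """
    x, y = a.at(at), b.at(at)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 repetitions per curve")
    if x.std() == 0 and y.std() == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, float(len(x) + len(y) - 2), 1.0, True
        return np.inf if x.mean() > y.mean() else -np.inf, float(len(x) + len(y) - 2), 0.0, True
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue), False


def cohesion(
    norm: NormalizedTable,
    corr: CorrelationResult,
    null_iters: int = 0,
    seed: int = 0,
) -> CohesionResult:
    """Per-sample positive and negative cohesion.

    connectedness+_i = mean of positive off-diagonal correlations in row i
    (0 if none); connectedness-_i analogous over negative entries.
    cohesion+-_j = sum_i p_ij * connectedness+-_i with p the relative
    abundance. With ``null_iters`` > 0, connectedness is replaced by
    observed minus the mean over taxa-shuffle null iterations (each
    permutes every taxon's abundances across samples independently and
    recomputes the Spearman matrix).
    """
    taxa = list(norm.taxa)
    if taxa != list(corr.taxa):
        raise ConsistencyError("taxa mismatch between abundance and correlation")
    rho = corr.rho.to_numpy().copy()
    np.fill_diagonal(rho, 0.0)
    conn_pos = _row_signed_mean(rho, positive=True)
    conn_neg = _row_signed_mean(rho, positive=False)

    corrected = null_iters > 0
    if corrected:
        rng = np.random.default_rng(seed)
        X = norm.rel_abund.to_numpy()
        null_pos = np.zeros_like(conn_pos)
        null_neg = np.zeros_like(conn_neg)
        for _ in range(null_iters):
            perm = np.array([rng.permutation(row) for row in X])
            r = stats.spearmanr(perm, axis=1).statistic
            r = np.atleast_2d(r)
            np.fill_diagonal(r, 0.0)
            null_pos += _row_signed_mean(r, positive=True)
            null_neg += _row_signed_mean(r, positive=False)
        conn_pos = conn_pos - null_pos / null_iters
        conn_neg = conn_neg - null_neg / null_iters

    p = norm.rel_abund.to_numpy()
    pos = p.T @ conn_pos
    neg = p.T @ conn_neg
    samples = norm.samples
    return CohesionResult(
        pos_cohesion=pd.Series(pos, index=samples, name="pos_cohesion"),
        neg_cohesion=pd.Series(neg, index=samples, name="neg_cohesion"),
        connectedness_pos=pd.Series(conn_pos, index=taxa),
        connectedness_neg=pd.Series(conn_neg, index=taxa),
        null_corrected=corrected,
    )


def _row_signed_mean(rho: np.ndarray, positive: bool) -> np.ndarray:
    if positive:
        mask = rho > 0
    else:
        mask = rho < 0
    counts = mask.sum(axis=1)
    sums = np.where(mask, rho, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return out
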