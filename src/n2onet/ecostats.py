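"""Ecological statistics: alpha diversity, niche breadth, ANOSIM, ANOVA+LSD,
N2O rate derivation, module-abundance regressions, and Pearson screening.

Conventions: Shannon entropy is in nats; Simpson is reported as Gini-Simpson
(1 - sum p^2); Good's coverage counts singleton taxa (count exactly 1);
Faith's PD includes the path to the root, matching common amplicon
toolchains. ANOSIM uses mid-ranks and a seeded label-permutation p-value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .datatypes import (
    ConsistencyError,
    CountTable,
    InsufficientDataError,
    N2OMeasurements,
    NormalizedTable,
)


# ---------------------------------------------------------------------------
# alpha diversity


def alpha_diversity(table: CountTable, tree: str | None = None) -> pd.DataFrame:
    """Per-sample diversity indices (rows = samples).

    Columns: shannon (nats), simpson (Gini-Simpson), pielou, coverage
    (Good's), heip, and pd (Faith's phylogenetic diversity, only when a
    newick tree covering every observed taxon is supplied).
    """
    counts = table.counts
    if (counts.sum(axis=0) <= 0).any():
        raise InsufficientDataError("every sample needs > 0 reads")
    rows = {}
    for s in counts.columns:
        col = counts[s].to_numpy(dtype=float)
        n_reads = col.sum()
        nz = col[col > 0]
        p = nz / n_reads
        s_rich = len(nz)
        h = float(-(p * np.log(p)).sum())
        gini = float(1.0 - (p * p).sum())
        pielou = h / np.log(s_rich) if s_rich > 1 else 0.0
        f1 = int((col == 1).sum())
        coverage = 1.0 - f1 / n_reads
        heip = (np.exp(h) - 1.0) / (s_rich - 1.0) if s_rich > 1 else 0.0
        rows[s] = {
            "shannon": h,
            "simpson": gini,
            "pielou": pielou,
            "coverage": coverage,
            "heip": heip,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[list(counts.columns)]
    if tree is not None:
        parsed = _parse_tree(tree)
        out["pd"] = [
            faith_pd(parsed, list(counts.index[counts[s] > 0])) for s in counts.columns
        ]
    return out


def _parse_tree(tree: str):
    from skbio import TreeNode

    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(io.StringIO(tree))


def faith_pd(tree, observed_taxa: list[str]) -> float:
    """Total branch length of the minimal subtree spanning the observed taxa,
    including the path to the root."""
    tree = _parse_tree(tree)
    tips = {t.name for t in tree.tips()}
    missing = set(observed_taxa) - tips
    if missing:
        raise ConsistencyError(f"tree is missing observed taxa: {sorted(missing)}")
    observed = set(observed_taxa)
    has_obs: dict[int, bool] = {}
    total = 0.0
    for node in tree.postorder():
        if node.is_tip():
            flag = node.name in observed
        else:
            flag = any(has_obs[id(c)] for c in node.children)
        has_obs[id(node)] = flag
        if flag and not node.is_root() and node.length is not None:
            total += node.length
    return float(total)


# ---------------------------------------------------------------------------
# N2O rate from incubation series


def n2o_rate(
    series: list[tuple[float, float]],
    beta: float,
    v_gas: float,
    v_liquid: float,
) -> float:
    """Emission rate from a headspace concentration time series.

    Each headspace concentration is converted to a total (gas + dissolved)
    concentration per liquid volume using the Bunsen solubility coefficient,
    ``total = conc * (v_gas + beta * v_liquid) / v_liquid``; the rate is the
    OLS slope of total concentration against time.
    """
    if beta <= 0:
        raise ValueError("Bunsen coefficient must be positive")
    if len(series) < 2:
        raise InsufficientDataError("need at least 2 time points")
    t = np.array([p[0] for p in series], dtype=float)
    c = np.array([p[1] for p in series], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("singular fit: all timestamps identical")
    total = c * (v_gas + beta * v_liquid) / v_liquid
    tc = t - t.mean()
    return float((tc * (total - total.mean())).sum() / (tc * tc).sum())


# ---------------------------------------------------------------------------
# niche breadth


@dataclass
class NicheBreadthResult:
    levins_b: pd.Series  # per-taxon
    community_mean: float
    n_excluded: int
    group: str


def levins_breadth(table: CountTable, group: str) -> NicheBreadthResult:
    """Levins' niche breadth over a treatment's samples.

    For taxon i, q_ij is sample j's share of the taxon's group-wide total and
    B_i = 1 / sum_j q_ij^2 (1 = specialist, n_samples = uniform generalist).
    Taxa absent from the group are excluded and counted. The community value
    is the unweighted mean over retained taxa.
    """
    samples = table.metadata.index[table.metadata["treatment"] == group]
    samples = [s for s in samples if s in table.counts.columns]
    if len(samples) < 2:
        raise InsufficientDataError(f"group {group!r} needs >= 2 samples")
    sub = table.counts[samples].to_numpy(dtype=float)
    totals = sub.sum(axis=1)
    present = totals > 0
    q = sub[present] / totals[present, None]
    b = 1.0 / (q * q).sum(axis=1)
    levins = pd.Series(b, index=table.counts.index[present], name="levins_B")
    return NicheBreadthResult(
        levins_b=levins,
        community_mean=float(b.mean()),
        n_excluded=int((~present).sum()),
        group=group,
    )


# ---------------------------------------------------------------------------
# ANOSIM


def bray_curtis(norm: NormalizedTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (on relative abundances)."""
    X = norm.rel_abund.to_numpy().T  # samples x taxa
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=norm.samples, columns=norm.samples)


def anosim(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Analysis of similarities: R statistic and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M / 2) with
    M = n(n-1)/2 and mid-ranks for ties; p = (1 + #{perm R >= observed}) /
    (1 + n_perm) under seeded random relabeling.
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = np.asarray(list(groups))
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("group labels must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups, each with >= 2 samples")

    iu, ju = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu, ju], method="average")
    m = len(ranks)
    denom = m / 2.0

    def r_stat(lbl_rows: np.ndarray) -> np.ndarray:
        # lbl_rows: (k, n) label matrix -> (k,) R values
        within = lbl_rows[:, iu] == lbl_rows[:, ju]
        rw = (ranks[None, :] * within).sum(axis=1) / within.sum(axis=1)
        rb = (ranks[None, :] * ~within).sum(axis=1) / (~within).sum(axis=1)
        return (rb - rw) / denom

    observed = float(r_stat(labels[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=labels.dtype)
    for k in range(n_perm):
        perms[k] = labels[rng.permutation(n)]
    null = r_stat(perms)
    p = (1 + int((null >= observed - 1e-12).sum())) / (1 + n_perm)
    return observed, float(p)


# ---------------------------------------------------------------------------
# one-way ANOVA with Fisher's LSD


@dataclass
class AnovaLSDResult:
    f_stat: float
    p_value: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    degenerate: bool = False


def anova_lsd(values, groups, alpha: float = 0.05) -> AnovaLSDResult:
    """One-way ANOVA followed by Fisher's LSD pairwise comparisons.

    LSD p-values use the pooled mean squared error and its df; the compact
    letter display gives two groups a shared letter iff their pairwise
    p >= ``alpha`` (letters from maximal cliques of the not-significantly-
    different graph, ordered by descending group mean).
    """
    vals = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    uniq = list(dict.fromkeys(labels.tolist()))  # stable order, python scalars
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: vals[labels == g] for g in uniq}
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("each group needs >= 2 values")

    k, n_total = len(uniq), len(vals)
    grand = vals.mean()
    means = {g: v.mean() for g, v in by_group.items()}
    ssb = sum(len(v) * (means[g] - grand) ** 2 for g, v in by_group.items())
    ssw = sum(((v - means[g]) ** 2).sum() for g, v in by_group.items())
    df_b, df_w = k - 1, n_total - k
    msb = ssb / df_b
    mse = ssw / df_w

    degenerate = False
    if mse == 0:
        degenerate = True
        if np.isclose(ssb, 0.0):
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    else:
        f = msb / mse
        p = float(stats.f.sf(f, df_b, df_w))

    pw = pd.DataFrame(np.ones((k, k)), index=uniq, columns=uniq)
    for i, gi in enumerate(uniq):
        for gj in uniq[i + 1 :]:
            if mse == 0:
                pij = 1.0 if np.isclose(means[gi], means[gj]) else 0.0
            else:
                se = np.sqrt(mse * (1 / len(by_group[gi]) + 1 / len(by_group[gj])))
                t = (means[gi] - means[gj]) / se
                pij = float(2 * stats.t.sf(abs(t), df_w))
            pw.loc[gi, gj] = pw.loc[gj, gi] = pij
    np.fill_diagonal(pw.values, 1.0)

    letters = _compact_letters(uniq, means, pw, alpha)
    return AnovaLSDResult(float(f), float(p), pw, letters, degenerate)


def _compact_letters(groups, means, pairwise_p, alpha) -> dict[str, str]:
    import networkx as nx

    order = sorted(groups, key=lambda g: -means[g])
    nsd = nx.Graph()
    nsd.add_nodes_from(order)
    for i, gi in enumerate(order):
        for gj in order[i + 1 :]:
            if pairwise_p.loc[gi, gj] >= alpha:
                nsd.add_edge(gi, gj)
    cliques = list(nx.find_cliques(nsd))
    pos = {g: i for i, g in enumerate(order)}
    cliques.sort(key=lambda c: min(pos[g] for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in groups}


# ---------------------------------------------------------------------------
# regressions and correlation screening


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    degenerate: bool = False


def module_abundance_regression(
    z: pd.DataFrame,
    part,
    n2o: N2OMeasurements,
) -> dict[int, RegressionResult]:
    """OLS of N2O rate on per-module mean z-scored abundance.

    Module abundance in a sample is the mean z-score over the module's taxa;
    one regression per module, N2O as response.
    """
    y = n2o.aligned_to(z.columns)
    out: dict[int, RegressionResult] = {}
    for m in part.modules:
        taxa = [t for t in part.members(m) if t in z.index]
        if not taxa:
            continue
        x = z.loc[taxa].mean(axis=0).to_numpy(dtype=float)
        if np.allclose(x.std(), 0.0):
            out[m] = RegressionResult(np.nan, np.nan, np.nan, np.nan, len(x), True)
            continue
        res = stats.linregress(x, y)
        out[m] = RegressionResult(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            p_value=float(res.pvalue),
            n=len(x),
        )
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_screen(features: pd.DataFrame, n2o: N2OMeasurements) -> pd.DataFrame:
    """Pearson correlation of each per-sample feature with the N2O rate.

    Returns a table (rows = features) with r, p, and star coding; constant
    features are flagged ``excluded`` and carry NaN statistics.
    """
    y = n2o.aligned_to(features.index)
    if len(y) < 3:
        raise InsufficientDataError("Pearson screen needs >= 3 samples")
    rows = {}
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if not np.isfinite(x).all() or np.allclose(x.std(), 0.0):
            rows[name] = {"r": np.nan, "p": np.nan, "stars": "", "excluded": True}
            continue
        r, p = stats.pearsonr(x, y)
        rows[name] = {
            "r": float(r),
            "p": float(p),
            "stars": significance_stars(float(p)),
            "excluded": False,
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(features.columns)]
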