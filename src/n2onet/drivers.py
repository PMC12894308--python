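"""PCA composite indices and random-forest driver attribution for N2O rates.

Predictor blocks (soil properties, per-kingdom diversity, per-kingdom network
features) are each collapsed to their first principal component; composites
plus per-module abundances then enter a regression random forest whose
"increase in node purity" importance ranks the drivers, with permutation
p-values for each predictor and for the model R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._forest import fit_forest
from .datatypes import InsufficientDataError


@dataclass
class CompositeIndex:
    """First principal component of a z-scored variable block.

    The sign is oriented so that the scores correlate non-negatively with the
    mean of the standardized variables (eigenvectors are sign-ambiguous);
    when that mean is constant, the first loading is made positive instead.
    """

    name: str
    scores: pd.Series
    variance_explained: float
    loadings: pd.Series
    orientation_sign: int
    dropped: list[str] = field(default_factory=list)


def composite_index(variables: pd.DataFrame, name: str = "PC1") -> CompositeIndex:
    """PC1 of a per-sample variable block (rows = samples)."""
    if variables.shape[0] < 3:
        raise InsufficientDataError("composite index needs >= 3 samples")
    vals = variables.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    constant = (sd == 0) | ~np.isfinite(sd)
    dropped = [c for c, flag in zip(variables.columns, constant) if flag]
    if dropped:
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
    keep = ~constant
    if keep.sum() < 2:
        raise ValueError("need >= 2 non-constant variables")
    cols = [c for c, k in zip(variables.columns, keep) if k]
    z = (vals[:, keep] - vals[:, keep].mean(axis=0)) / sd[keep]

    corr = (z.T @ z) / (z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    v1 = eigvec[:, order[0]]
    scores = z @ v1

    zbar = z.mean(axis=1)
    c = float(np.dot(scores - scores.mean(), zbar - zbar.mean()))
    if abs(c) > 1e-12:
        sign = 1 if c > 0 else -1
    else:
        nz = v1[np.abs(v1) > 1e-12]
        sign = 1 if (len(nz) == 0 or nz[0] > 0) else -1
    scores = sign * scores
    v1 = sign * v1

    return CompositeIndex(
        name=name,
        scores=pd.Series(scores, index=variables.index, name=name),
        variance_explained=float(eigval[0] / eigval.sum()),
        loadings=pd.Series(v1, index=cols),
        orientation_sign=sign,
        dropped=dropped,
    )


@dataclass
class DriverImportance:
    """Random-forest driver ranking (the importance-plot analogue)."""

    importance: pd.Series  # increase in node purity, per predictor
    model_r2: float
    n_trees: int
    mtry: int
    seed: int
    perm_p: pd.Series | None = None
    model_p: float | None = None

    def table(self) -> pd.DataFrame:
        from .ecostats import significance_stars

        out = pd.DataFrame({"inc_node_purity": self.importance})
        if self.perm_p is not None:
            out["perm_p"] = self.perm_p
            out["stars"] = [significance_stars(p) for p in self.perm_p]
        return out.sort_values("inc_node_purity", ascending=False)


def rf_importance(
    predictors: pd.DataFrame,
    response,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
) -> DriverImportance:
    """Regression forest importance (increase in node purity) plus OOB R^2.

    Bootstrap per tree, mtry = max(1, floor(p/3)) candidate predictors per
    split, variance-reduction split criterion; model_r2 = 1 - MSE_OOB /
    var(response).
    """
    X = predictors.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if X.shape[0] < 5:
        raise InsufficientDataError("random forest needs >= 5 samples")
    if X.shape[1] < 1:
        raise ValueError("need >= 1 predictor")
    if np.var(y) == 0:
        raise ValueError("constant response")
    if mtry is None:
        mtry = max(1, X.shape[1] // 3)
    imp, r2 = fit_forest(X, y, n_trees=n_trees, mtry=mtry, seed=seed)
    return DriverImportance(
        importance=pd.Series(imp, index=predictors.columns, name="inc_node_purity"),
        model_r2=float(r2),
        n_trees=n_trees,
        mtry=mtry,
        seed=seed,
    )


def permutation_significance(
    predictors: pd.DataFrame,
    response,
    n_perm: int = 1000,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
) -> DriverImportance:
    """Permutation p-values for forest importances and the model R^2.

    The response is permuted ``n_perm`` times (seeded); per-predictor
    p = (1 + #{null importance >= observed}) / (1 + n_perm), and the model
    p is computed the same way on the OOB R^2. The add-one rule keeps every
    p strictly positive.
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives coarse p-value resolution", stacklevel=2)
    ss = np.random.SeedSequence(seed)
    forest_seed = int(ss.generate_state(1)[0] % (2**31))
    obs = rf_importance(predictors, response, n_trees=n_trees, mtry=mtry, seed=forest_seed)

    rng = np.random.default_rng(ss.spawn(1)[0])
    y = np.asarray(response, dtype=float)
    p = predictors.shape[1]
    exceed = np.zeros(p)
    exceed_r2 = 0
    obs_imp = obs.importance.to_numpy()
    obs_r2 = obs.model_r2
    for k in range(n_perm):
        y_perm = rng.permutation(y)
        null = rf_importance(
            predictors, y_perm, n_trees=n_trees, mtry=mtry,
            seed=(forest_seed + 1 + k) % (2**31),
        )
        exceed += null.importance.to_numpy() >= obs_imp - 1e-12
        if null.model_r2 >= obs_r2 - 1e-12:
            exceed_r2 += 1
    obs.perm_p = pd.Series((1 + exceed) / (1 + n_perm), index=predictors.columns)
    obs.model_p = float((1 + exceed_r2) / (1 + n_perm))
    return obs
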