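"""Low-abundance filtering, TMM normalization, and z-score standardization.

Order of operations mirrors the analysis chain: exclude low-abundance genera,
compute trimmed-mean-of-M-values (TMM) scaling factors, derive effective
library sizes, and build the relative-abundance matrix that correlation-based
network inference consumes. Z-scored abundances feed the module-abundance
regressions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    CountTable,
    DegenerateOverlapError,
    EmptyResultError,
    InsufficientDataError,
    NormalizedTable,
)


def filter_low_abundance(
    table: CountTable, min_rel_abund: float = 0.0001, min_prevalence: int = 2
) -> CountTable:
    """Drop genera below a mean relative-abundance and prevalence floor.

    A taxon is retained iff its mean relative abundance (mean over samples of
    count / library size) is >= ``min_rel_abund`` AND it is present (count >
    0) in at least ``min_prevalence`` samples. Samples are never dropped.
    """
    if not (0.0 <= min_rel_abund < 1.0):
        raise ValueError("min_rel_abund must be in [0, 1)")
    n_samples = len(table.samples)
    if not (0 <= min_prevalence <= n_samples):
        raise ValueError("min_prevalence must be in [0, n_samples]")
    counts = table.counts
    libsize = counts.sum(axis=0)
    rel = counts / libsize
    mean_rel = rel.mean(axis=1)
    prevalence = (counts > 0).sum(axis=1)
    keep_abund = mean_rel >= min_rel_abund
    keep_prev = prevalence >= min_prevalence
    keep = keep_abund & keep_prev
    if not keep.any():
        raise EmptyResultError(
            "all taxa removed by abundance/prevalence filter",
            casualties={
                "below_min_rel_abund": int((~keep_abund).sum()),
                "below_min_prevalence": int((~keep_prev).sum()),
            },
        )
    kingdom = table.kingdom.loc[keep] if table.kingdom is not None else None
    return CountTable(counts.loc[keep], table.metadata, kingdom)


def tmm_factors(
    table: CountTable,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the library whose 75th-percentile count fraction
    is closest to the mean of that quantity (ties broken by lowest sample
    index). For each sample, M-values (log2 fraction ratios vs the reference)
    are computed over taxa nonzero in both libraries, doubly trimmed
    (``logratio_trim`` from each M tail, ``abs_trim`` from each A tail), and
    averaged with inverse-asymptotic-variance (binomial precision) weights;
    the factor is 2 to that weighted mean.
    """
    counts = table.counts.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("every sample must have positive library size")
    frac = counts / libsize

    q75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    n_samples = counts.shape[1]
    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref], libsize[j], libsize[ref],
            logratio_trim, abs_trim,
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.samples, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, abs_trim) -> float:
    """Doubly-trimmed precision-weighted mean of M-values (log2 scale)."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise DegenerateOverlapError(
            "sample shares no nonzero taxa with the TMM reference"
        )
    o, r = obs[mask], ref[mask]
    fo, fr = o / n_obs, r / n_ref
    m = np.log2(fo / fr)
    a = 0.5 * np.log2(fo * fr)
    # binomial asymptotic variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.allclose(np.abs(m), 0.0, atol=1e-10):
        return 0.0

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    keep &= np.isfinite(m) & np.isfinite(a) & (w > 0)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def _rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def normalize(
    table: CountTable,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> NormalizedTable:
    """TMM-normalized relative abundances plus effective library sizes."""
    factors = tmm_factors(table, logratio_trim, abs_trim)
    libsize = table.library_sizes().astype(float)
    eff = libsize * factors
    eff.name = "effective_libsize"
    rel = table.counts / eff
    rel = rel / rel.sum(axis=0)
    return NormalizedTable(rel_abund=rel, tmm_factor=factors, effective_libsize=eff)


def zscore(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise standardization to mean 0, sample sd 1.

    Zero-variance rows come back as all-zeros and are reported in the second
    return value rather than raising — degenerate taxa must not abort the
    pipeline, and zeros contribute nothing to module means.
    """
    if matrix.shape[1] < 2:
        raise InsufficientDataError("z-score needs at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[flat] = 1.0
    z = (vals - mean) / sd
    z[flat, :] = 0.0
    flagged = [t for t, f in zip(matrix.index, flat) if f]
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged
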