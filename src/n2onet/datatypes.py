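"""Shared containers and exceptions for the pipeline.

The pipeline's entry point is a :class:`CountTable`: a genus x sample matrix of
non-negative integer counts with per-sample treatment metadata and a per-taxon
kingdom tag. Downstream stages consume the derived :class:`NormalizedTable`
(TMM-scaled relative abundances) and :class:`CorrelationResult` (Spearman rho
and p matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PipelineError(Exception):
    """Base class for pipeline-specific failures."""


class ConfigurationError(PipelineError, ValueError):
    """An invalid parameter or simulation configuration."""


class EmptyResultError(PipelineError, ValueError):
    """A filtering step removed every taxon.

    Carries per-criterion casualty counts so the caller can see which
    threshold was responsible.
    """

    def __init__(self, message: str, casualties: dict[str, int] | None = None):
        super().__init__(message)
        self.casualties = dict(casualties or {})


class InsufficientDataError(PipelineError, ValueError):
    """Too few samples (or taxa) for the requested statistic."""


class ConsistencyError(PipelineError, ValueError):
    """Mismatched taxa or samples between two inputs that must align."""


class DegenerateOverlapError(PipelineError, ValueError):
    """A sample shares no nonzero taxa with the TMM reference sample."""


@dataclass
class CountTable:
    """Genus-level taxon x sample count matrix with metadata.

    Parameters
    ----------
    counts : DataFrame
        Rows are taxa, columns are samples, values are non-negative integers.
    metadata : DataFrame
        Indexed by sample ID with at least a ``treatment`` column; a
        ``replicate`` column is carried when available.
    kingdom : Series, optional
        Per-taxon kingdom tag ("bacteria"/"fungi"), indexed like ``counts``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    kingdom: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ConsistencyError("duplicate taxon IDs in count table")
        if c.columns.has_duplicates:
            raise ConsistencyError("duplicate sample IDs in count table")
        vals = c.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ConsistencyError("counts must be finite and non-negative")
        missing = c.columns.difference(self.metadata.index)
        if len(missing):
            raise ConsistencyError(
                f"samples without metadata/treatment: {sorted(missing)}"
            )
        if self.kingdom is not None:
            self.kingdom = self.kingdom.reindex(c.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def treatments(self) -> pd.Series:
        return self.metadata.loc[self.counts.columns, "treatment"]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountTable":
        sub = self.counts.loc[:, list(sample_ids)]
        return CountTable(sub, self.metadata.loc[list(sample_ids)], self.kingdom)


@dataclass
class NormalizedTable:
    """TMM-normalized relative abundances.

    ``rel_abund`` columns are count fractions computed against the effective
    library size (raw library size x TMM factor) and renormalized to sum to 1;
    ``tmm_factor`` has geometric mean 1 across samples.
    """

    rel_abund: pd.DataFrame
    tmm_factor: pd.Series
    effective_libsize: pd.Series
    zero_variance_taxa: list[str] = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return list(self.rel_abund.index)

    @property
    def samples(self) -> list[str]:
        return list(self.rel_abund.columns)


@dataclass
class CorrelationResult:
    """Pairwise Spearman correlation and two-sided p-value matrices.

    Both matrices are symmetric taxon x taxon DataFrames; ``rho`` has a unit
    diagonal, ``pval`` a zero diagonal. ``constant_taxa`` lists rows with zero
    variance, for which rho is set to 0 and p to 1.
    """

    rho: pd.DataFrame
    pval: pd.DataFrame
    n_used: int
    constant_taxa: list[str] = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return list(self.rho.index)


@dataclass
class N2OMeasurements:
    """Per-sample potential denitrification N2O emission rates.

    Rates are in nmol N per gram dry soil per hour, as derived from linear
    fitting of the anaerobic slurry-incubation concentration series.
    """

    rates: pd.Series
    series: dict[str, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rates.to_numpy(dtype=float)).all():
            raise ConsistencyError("N2O rates must be finite")

    def aligned_to(self, samples) -> np.ndarray:
        missing = [s for s in samples if s not in self.rates.index]
        if missing:
            raise ConsistencyError(f"N2O rates missing for samples: {missing}")
        return self.rates.loc[list(samples)].to_numpy(dtype=float)
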