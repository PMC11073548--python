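"""Structural covariance networks from subject-by-node feature tables.

A structural covariance network links two nodes (brain regions, mesh sample
points, ...) by the across-subject correlation of a morphometric measure
(e.g. Jacobian determinants from tensor-based morphometry, or FA values).
Because each group yields a single correlation matrix, leave-one-out
jackknife resampling is used to produce one group-level network per subject,
which the topological inference then treats as the group's sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientSampleError, InvalidParameterError
from .network import WeightedNetwork

__all__ = ["FeatureTable", "correlation_network", "jackknife_networks"]


@dataclass(frozen=True)
class FeatureTable:
    """Subject-by-node measurements: ``values[s, k]`` for subject s, node k."""

    subjects: tuple
    node_ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidParameterError(f"values must be 2D, got shape {v.shape}")
        if v.shape != (len(self.subjects), len(self.node_ids)):
            raise InvalidParameterError(
                f"values shape {v.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.node_ids)} nodes"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("feature table contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def q(self) -> int:
        return len(self.node_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.subjects), columns=list(self.node_ids))

    def drop_subject(self, i: int) -> "FeatureTable":
        keep = [k for k in range(self.n_subjects) if k != i]
        return FeatureTable(
            tuple(self.subjects[k] for k in keep), self.node_ids, self.values[keep]
        )


def correlation_network(
    table: FeatureTable,
    method: str = "pearson",
    absolute: bool = False,
) -> WeightedNetwork:
    """Across-subject node-by-node correlation matrix as a weighted network.

    The diagonal is set to 0 (self-edges take no part in the filtration) and
    negative correlations are kept as-is unless ``absolute=True``.  A
    zero-variance node column raises an error naming the node rather than
    propagating NaN.
    """
    if table.n_subjects < 2:
        raise InsufficientSampleError("correlation needs at least 2 subjects")
    sd = table.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [table.node_ids[k] for k in dead[:5]]
        raise InvalidParameterError(f"zero-variance node column(s): {names}")
    if method == "pearson":
        corr = np.corrcoef(table.values, rowvar=False)
    elif method == "spearman":
        corr = stats.spearmanr(table.values).statistic
        corr = np.atleast_2d(corr)
    else:
        raise InvalidParameterError(f"unknown correlation method {method!r}")
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    if absolute:
        corr = np.abs(corr)
    np.fill_diagonal(corr, 0.0)
    # correlations of exactly 0 are legitimate edges; mark the graph complete
    mask = np.ones_like(corr, dtype=bool)
    return WeightedNetwork(corr, node_labels=table.node_ids, mask=mask)


def jackknife_networks(
    table: FeatureTable,
    method: str = "pearson",
    absolute: bool = False,
) -> list[WeightedNetwork]:
    """Leave-one-subject-out correlation networks, one per subject, in order."""
    if table.n_subjects < 3:
        raise InsufficientSampleError(
            f"jackknife needs >= 3 subjects, got {table.n_subjects}"
        )
    return [
        correlation_network(table.drop_subject(i), method=method, absolute=absolute)
        for i in range(table.n_subjects)
    ]
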