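"""Pairwise participant similarity per metric, affine combination, correlations.

For each metric, the similarity value between two participants is the
absolute difference of their (min-max normalized) metric values — the 1-D
Euclidean distance. The tensor stores dissimilarities: 0 means identical.
Metrics are combined with affine weights (non-negative, summing to 1),
either on the similarity tensor (for clustering) or directly on the
normalized metric columns (the derived "W-Avg" parallel-coordinates axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class NormalizationRecord:
    """Per-metric min/max used for scaling; reapplicable to new rows."""

    lo: pd.Series
    hi: pd.Series
    constant: list[str] = field(default_factory=list)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        span = (self.hi - self.lo).replace(0.0, 1.0)
        out = (table - self.lo) / span
        out[self.constant] = 0.0
        return out


def normalize_metric_table(table: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationRecord]:
    """Min-max scale every metric column to [0, 1].

    Constant columns map to all zeros and are listed in the record's
    ``constant`` field so downstream stages can flag them.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 participants to normalize")
    lo = table.min(axis=0)
    hi = table.max(axis=0)
    constant = [c for c in table.columns if hi[c] == lo[c]]
    rec = NormalizationRecord(lo=lo, hi=hi, constant=constant)
    return rec.apply(table), rec


@dataclass
class SimilarityTensor:
    """p × p × n per-metric pairwise dissimilarities in [0, 1]."""

    values: np.ndarray  # (p, p, n)
    participants: list[str]
    metrics: list[str]
    normalization: NormalizationRecord | None = None

    @property
    def p(self) -> int:
        return len(self.participants)

    def slice(self, metric: str) -> np.ndarray:
        return self.values[:, :, self.metrics.index(metric)]

    def n_pairs(self) -> int:
        """Distinct unordered participant pairs per metric: p(p−1)/2."""
        return self.p * (self.p - 1) // 2

    def to_long_frame(self) -> pd.DataFrame:
        p, n = self.p, len(self.metrics)
        rows = []
        for k, m in enumerate(self.metrics):
            for i in range(p):
                for l in range(p):
                    rows.append((self.participants[i], self.participants[l], m, self.values[i, l, k]))
        return pd.DataFrame(rows, columns=["row", "col", "metric", "value"])


def pairwise_similarity(normalized_table: pd.DataFrame) -> SimilarityTensor:
    """Build the per-metric similarity tensor from a normalized table.

    For scalar metrics the Euclidean distance reduces to the absolute
    difference ``|m_i − m_l|``; every slice is symmetric with zero diagonal.
    """
    if len(normalized_table) < 2:
        raise ValueError("need at least 2 participants")
    vals = normalized_table.to_numpy(dtype=float)
    # broadcast abs differences: (p, 1, n) - (1, p, n)
    tensor = np.abs(vals[:, None, :] - vals[None, :, :])
    return SimilarityTensor(
        values=tensor,
        participants=[str(i) for i in normalized_table.index],
        metrics=[str(c) for c in normalized_table.columns],
    )


def _check_weights(weights: Mapping[str, float], metrics: list[str], renormalize: bool) -> pd.Series:
    w = pd.Series(0.0, index=metrics)
    unknown = [m for m in weights if m not in metrics]
    if unknown:
        raise KeyError(f"weights refer to unknown metric(s): {unknown}")
    for m, v in weights.items():
        if v < 0:
            raise ValueError(f"negative weight for {m}")
        w[m] = float(v)
    total = float(w.sum())
    if abs(total - 1.0) > 1e-9:
        if not renormalize:
            raise ValueError(
                f"weights sum to {total}, not 1; pass renormalize=True to rescale"
            )
        if total == 0:
            raise ValueError("all weights are zero")
        w = w / total
    return w


def combine_metrics(
    tensor: SimilarityTensor, weights: Mapping[str, float], renormalize: bool = False
) -> np.ndarray:
    """Affine combination of metric slices into one p × p matrix."""
    w = _check_weights(weights, tensor.metrics, renormalize)
    return np.tensordot(tensor.values, w.to_numpy(), axes=([2], [0]))


def weighted_metric_column(
    normalized_table: pd.DataFrame,
    weights: Mapping[str, float],
    renormalize: bool = False,
    name: str = "W-Avg",
) -> pd.Series:
    """Per-participant weighted average of normalized metrics (a derived axis)."""
    w = _check_weights(weights, [str(c) for c in normalized_table.columns], renormalize)
    col = normalized_table.to_numpy(dtype=float) @ w.to_numpy()
    return pd.Series(col, index=normalized_table.index, name=name)


def metric_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between every pair of metrics, across participants.

    Constant metrics have undefined correlation; their entries are set to 0
    (diagonal stays 1) and the metric is returned in the flag list.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 participants for correlations")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    corr = table.corr(method="pearson")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr, constant
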