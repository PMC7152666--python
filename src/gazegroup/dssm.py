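"""Dimensionally Stacked Similarity Matrix (DSSM) layout and assembly.

Each cell of the participant × participant similarity matrix is subdivided
into a g × g sub-grid (g = 2^o) holding one similarity value per metric.
Metrics are placed along a Hilbert space-filling curve so metrics adjacent
in the redundancy ordering occupy edge-adjacent sub-cells, preserving
locality of the color layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import SimilarityTensor


def hilbert_order(o: int) -> list[tuple[int, int]]:
    """Visit sequence of the order-o Hilbert curve on a 2^o × 2^o grid.

    Returns (row, col) cells; the orientation is fixed: the curve starts at
    the top-left cell and ends at the top-right cell (at order 1 the first
    step goes downward). Consecutive cells always share an edge.
    Implemented by bit-interleaved index-to-coordinate conversion.
    """
    if o < 1:
        raise ValueError(f"Hilbert order must be >= 1, got {o}")
    n = 1 << o
    out: list[tuple[int, int]] = []
    for d in range(n * n):
        x = y = 0
        t = d
        s = 1
        while s < n:
            rx = 1 & (t // 2)
            ry = 1 & (t ^ rx)
            if ry == 0:
                if rx == 1:
                    x = s - 1 - x
                    y = s - 1 - y
                x, y = y, x
            x += s * rx
            y += s * ry
            t //= 4
            s *= 2
        out.append((y, x))  # row = y so the first step is downward
    return out


@dataclass
class HilbertLayout:
    """Metric-rank → sub-cell placement inside one matrix cell."""

    order: int
    visit: list[tuple[int, int]]
    cell_of_rank: dict[int, tuple[int, int]]
    empty_cells: list[tuple[int, int]]

    @property
    def g(self) -> int:
        return 1 << self.order

    @property
    def n_metrics(self) -> int:
        return len(self.cell_of_rank)


def assign_metrics(metric_order: list[str], o: int | None = None) -> HilbertLayout:
    """Place metrics (in redundancy order) along the Hilbert visit sequence.

    The k-th metric occupies the k-th visited sub-cell; when the metric
    count is not a power of four, the tail of the visit sequence is left
    empty. ``o`` defaults to the minimal order with 4^o ≥ n.
    """
    n = len(metric_order)
    if n < 1:
        raise ValueError("need at least one metric")
    if o is None:
        o = 1
        while 4**o < n:
            o += 1
    if n > 4**o:
        raise ValueError(f"{n} metrics do not fit in a 4^{o} sub-grid")
    visit = hilbert_order(o)
    cell_of_rank = {k: visit[k] for k in range(n)}
    empty = visit[n:]
    return HilbertLayout(order=o, visit=visit, cell_of_rank=cell_of_rank, empty_cells=empty)


@dataclass
class DSSMGrid:
    """Assembled DSSM: per-pair, per-metric values with sub-cell placement."""

    values: np.ndarray  # (p, p, n) reordered by participant_order
    participant_order: list[str]
    metric_order: list[str]
    layout: HilbertLayout

    @property
    def p(self) -> int:
        return len(self.participant_order)

    def value_grid(self, fill: float = np.nan) -> np.ndarray:
        """Dense (p·g) × (p·g) array of stacked values; empty sub-cells = fill."""
        g = self.layout.g
        p = self.p
        grid = np.full((p * g, p * g), fill)
        for k in range(len(self.metric_order)):
            r, c = self.layout.cell_of_rank[k]
            grid[r::g, c::g] = self.values[:, :, k]
        return grid

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for k, m in enumerate(self.metric_order):
            r, c = self.layout.cell_of_rank[k]
            for i, pi in enumerate(self.participant_order):
                for l, pl in enumerate(self.participant_order):
                    rows.append((pi, pl, m, self.values[i, l, k], r, c))
        return pd.DataFrame(
            rows, columns=["row_participant", "col_participant", "metric", "value", "subrow", "subcol"]
        )


def assemble_dssm(
    tensor: SimilarityTensor,
    participant_order: list[str],
    layout: HilbertLayout | None = None,
    metric_order: list[str] | None = None,
) -> DSSMGrid:
    """Reorder the similarity tensor and stack metrics into sub-cells.

    ``metric_order`` defaults to the tensor's metric list; ``layout``
    defaults to the minimal Hilbert layout for that many metrics.
    """
    if sorted(participant_order) != sorted(tensor.participants):
        raise ValueError("participant_order must be a permutation of the tensor roster")
    if metric_order is None:
        metric_order = list(tensor.metrics)
    if sorted(metric_order) != sorted(tensor.metrics):
        raise ValueError("metric_order must be a permutation of the tensor metrics")
    if layout is None:
        layout = assign_metrics(metric_order)
    if layout.n_metrics != len(metric_order):
        raise ValueError("layout was built for a different number of metrics")
    pidx = [tensor.participants.index(pid) for pid in participant_order]
    midx = [tensor.metrics.index(m) for m in metric_order]
    values = tensor.values[np.ix_(pidx, pidx, midx)]
    return DSSMGrid(
        values=values,
        participant_order=list(participant_order),
        metric_order=list(metric_order),
        layout=layout,
    )
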