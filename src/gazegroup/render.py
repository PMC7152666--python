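"""Static SVG/PNG rendering of the DSSM and parallel-coordinates plots."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .colors import ColorScheme, encode_value
from .dssm import DSSMGrid
from .pcp import AxisSpec, Polyline, SampledCurve, visible_axes

_EMPTY_GRAY = np.array([0.82, 0.82, 0.82])


def dssm_image(grid: DSSMGrid, scheme: ColorScheme) -> np.ndarray:
    """Render the stacked matrix to an RGB array of (p·g, p·g, 3).

    Each sub-cell gets its metric's hue with lightness encoding the
    normalized dissimilarity; unused sub-cells are neutral gray.
    """
    g = grid.layout.g
    p = grid.p
    img = np.empty((p * g, p * g, 3))
    img[:] = _EMPTY_GRAY
    for k, metric in enumerate(grid.metric_order):
        r, c = grid.layout.cell_of_rank[k]
        vals = np.clip(grid.values[:, :, k], 0.0, 1.0)
        # cache distinct values: similarity slices are coarse, palette calls cost
        uniq, inv = np.unique(np.round(vals, 6), return_inverse=True)
        lut = np.array([encode_value(scheme, metric, v) for v in uniq])
        img[r::g, c::g] = lut[inv].reshape(p, p, 3)
    return img


def render_dssm(
    grid: DSSMGrid,
    scheme: ColorScheme,
    path,
    group_boundaries: Sequence[int] | None = None,
    dpi: int = 150,
) -> None:
    """Write the DSSM to SVG/PNG; optional white lines mark group boundaries."""
    img = dssm_image(grid, scheme)
    g = grid.layout.g
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(img, interpolation="nearest")
    if group_boundaries:
        for b in group_boundaries:
            ax.axhline(b * g - 0.5, color="white", lw=2)
            ax.axvline(b * g - 0.5, color="white", lw=2)
    ticks = np.arange(grid.p) * g + (g - 1) / 2.0
    ax.set_xticks(ticks, grid.participant_order, rotation=90, fontsize=6)
    ax.set_yticks(ticks, grid.participant_order, fontsize=6)
    ax.set_title("Dimensionally stacked similarity matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def render_pcp(
    lines: Sequence[Polyline | SampledCurve],
    axes: Sequence[AxisSpec],
    path,
    brushes: Mapping[str, tuple[float, float]] | None = None,
    dpi: int = 150,
) -> None:
    """Write a parallel-coordinates plot of polylines or sampled curves."""
    vis = visible_axes(axes)
    m = len(vis)
    fig, ax = plt.subplots(figsize=(max(6, 0.9 * m), 5))
    for line in lines:
        color = line.color or "#3465a4"
        if isinstance(line, SampledCurve):
            ax.plot(line.x, line.y, color=color, lw=0.9, alpha=0.75)
        else:
            ax.plot(np.arange(m), line.heights, color=color, lw=0.9, alpha=0.75)
    for a in vis:
        ax.axvline(a.position, color="0.3", lw=1)
    if brushes:
        pos = {a.metric: a.position for a in vis}
        for metric, (lo, hi) in brushes.items():
            if metric in pos:
                ax.add_patch(
                    plt.Rectangle((pos[metric] - 0.07, lo), 0.14, hi - lo, color="orange", alpha=0.4)
                )
    labels = [a.metric + (" (inv)" if a.inverted else "") for a in vis]
    ax.set_xticks(np.arange(m), labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylim(-0.05, 1.05)
    ax.set_ylabel("normalized value")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
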