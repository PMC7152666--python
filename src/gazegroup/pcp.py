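"""Parallel-coordinates geometry: axes, polylines, brushing, smoothing, bundling.

Each participant is a polyline across one vertical axis per metric. All
geometry is computed in normalized coordinates — axis positions are the
integers 0..m−1 and heights live in [0, 1] — so rendering is a thin
matplotlib layer and every operation is testable numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import colors as _colors
from .io import Dataset
from .similarity import weighted_metric_column


@dataclass
class AxisSpec:
    metric: str
    position: int
    lo: float
    hi: float
    inverted: bool = False
    hidden: bool = False
    constant: bool = False


@dataclass
class Polyline:
    """One participant's vertex heights, one per visible axis, in axis order."""

    participant_id: str
    heights: np.ndarray
    group: int | None = None
    color: str | None = None


@dataclass
class SampledCurve:
    """Dense (x, y) samples of a smoothed/bundled polyline."""

    participant_id: str
    x: np.ndarray
    y: np.ndarray
    group: int | None = None
    color: str | None = None


@dataclass
class BrushSelection:
    axis: str
    interval: tuple[float, float]
    selected: set[str] = field(default_factory=set)

    def __and__(self, other: "BrushSelection") -> "BrushSelection":
        return BrushSelection(
            axis=f"{self.axis}&{other.axis}",
            interval=(0.0, 1.0),
            selected=self.selected & other.selected,
        )


def default_axes(table: pd.DataFrame, order: Sequence[str] | None = None) -> list[AxisSpec]:
    """One axis per metric column, scaled to the column's min/max."""
    cols = list(order) if order is not None else [str(c) for c in table.columns]
    axes = []
    for pos, c in enumerate(cols):
        lo, hi = float(table[c].min()), float(table[c].max())
        axes.append(AxisSpec(metric=c, position=pos, lo=lo, hi=hi, constant=hi == lo))
    return axes


def visible_axes(axes: Iterable[AxisSpec]) -> list[AxisSpec]:
    vis = sorted((a for a in axes if not a.hidden), key=lambda a: a.position)
    return [replace(a, position=i) for i, a in enumerate(vis)]


def layout_polylines(table: pd.DataFrame, axes: Sequence[AxisSpec] | None = None) -> list[Polyline]:
    """Compute vertex heights for every participant.

    Height is (v − lo) / (hi − lo), flipped for inverted axes; a constant
    column places every vertex at 0.5.
    """
    if axes is None:
        axes = default_axes(table)
    axes = visible_axes(axes)
    missing = [a.metric for a in axes if a.metric not in table.columns]
    if missing:
        raise KeyError(f"axes reference missing metric(s): {missing}")
    out = []
    for pid, row in table.iterrows():
        hts = np.empty(len(axes))
        for j, a in enumerate(axes):
            if a.constant or a.hi == a.lo:
                h = 0.5
            else:
                h = (float(row[a.metric]) - a.lo) / (a.hi - a.lo)
            hts[j] = 1.0 - h if a.inverted else h
        out.append(Polyline(participant_id=str(pid), heights=hts))
    return out


def brush(
    polylines: Sequence[Polyline],
    axes: Sequence[AxisSpec],
    axis: str,
    interval: tuple[float, float],
) -> BrushSelection:
    """Select the participants whose vertex on ``axis`` lies in the closed interval."""
    axes = visible_axes(axes)
    pos = next((a.position for a in axes if a.metric == axis), None)
    if pos is None:
        raise KeyError(f"unknown axis {axis!r}")
    a, b = interval
    sel = {pl.participant_id for pl in polylines if a <= pl.heights[pos] <= b}
    return BrushSelection(axis=axis, interval=(a, b), selected=sel)


def delete_selection(obj, selection: BrushSelection | set[str]):
    """Remove the selected participants from a metric table or Dataset."""
    ids = selection.selected if isinstance(selection, BrushSelection) else set(selection)
    if not ids:
        return obj
    if isinstance(obj, Dataset):
        return obj.drop_participants(ids)
    keep = [i for i in obj.index if str(i) not in ids]
    if not keep:
        raise ValueError("cannot delete every participant")
    return obj.loc[keep]


def _blend_curve(
    ctrl_x: np.ndarray, ctrl_y: np.ndarray, s: float, samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (1−s)·piecewise-linear + s·PCHIP through the control points.

    PCHIP is an interpolating piecewise cubic whose shape-preserving
    tangents never overshoot the data, so the blend passes through every
    control point for any s and degenerates to the exact polyline at s=0.
    """
    x = np.linspace(ctrl_x[0], ctrl_x[-1], samples)
    # include the control abscissae exactly
    x = np.unique(np.concatenate([x, ctrl_x]))
    lin = np.interp(x, ctrl_x, ctrl_y)
    if s == 0.0 or len(ctrl_x) < 3:
        y = lin
    else:
        y = (1.0 - s) * lin + s * PchipInterpolator(ctrl_x, ctrl_y)(x)
    return x, y


def smooth_polyline(polyline: Polyline, s: float, samples_per_gap: int = 24) -> SampledCurve:
    """Smooth a polyline with tension s in [0, 1].

    s = 0 reproduces the polyline exactly; s = 1 is the fully smoothed
    shape-preserving cubic. All axis vertices are interpolated exactly and
    the curve never overshoots the data range between vertices.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("smoothing parameter s must be in [0, 1]")
    m = len(polyline.heights)
    if m < 2:
        raise ValueError("need at least 2 vertices to smooth")
    ctrl_x = np.arange(m, dtype=float)
    n_samples = samples_per_gap * (m - 1) + 1
    x, y = _blend_curve(ctrl_x, polyline.heights.astype(float), s, n_samples)
    return SampledCurve(polyline.participant_id, x, y, polyline.group, polyline.color)


def bundle_curves(
    polylines: Sequence[Polyline],
    groups: Mapping[str, int],
    beta: float,
    s: float = 1.0,
    samples_per_gap: int = 24,
) -> list[SampledCurve]:
    """Bundle each group's curves toward its centroid between axes.

    A mid-gap control point is inserted halfway between adjacent axes at
    c = (1−β)·own_mid + β·group_centroid_mid, then the curve is smoothed
    through vertices and controls. Axis vertices are never displaced;
    β = 0 leaves every curve unchanged.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("tightness beta must be in [0, 1]")
    unknown = [pl.participant_id for pl in polylines if pl.participant_id not in groups]
    if unknown:
        raise KeyError(f"no group label for participant(s): {unknown}")
    heights = np.array([pl.heights for pl in polylines], dtype=float)
    m = heights.shape[1]
    mids = (heights[:, :-1] + heights[:, 1:]) / 2.0
    labels = np.array([groups[pl.participant_id] for pl in polylines])
    centroid_mid = np.empty_like(mids)
    for g in np.unique(labels):
        centroid_mid[labels == g] = mids[labels == g].mean(axis=0)
    ctrl_mid = (1.0 - beta) * mids + beta * centroid_mid

    out = []
    ctrl_x = np.empty(2 * m - 1)
    ctrl_x[0::2] = np.arange(m)
    ctrl_x[1::2] = np.arange(m - 1) + 0.5
    for i, pl in enumerate(polylines):
        ctrl_y = np.empty(2 * m - 1)
        ctrl_y[0::2] = heights[i]
        ctrl_y[1::2] = ctrl_mid[i]
        n_samples = 2 * samples_per_gap * (m - 1) + 1
        x, y = _blend_curve(ctrl_x, ctrl_y, s, n_samples)
        out.append(SampledCurve(pl.participant_id, x, y, int(labels[i]), pl.color))
    return out


def merge_axes(
    normalized_table: pd.DataFrame,
    weights: Mapping[str, float],
    name: str = "W-Avg",
    renormalize: bool = False,
) -> pd.DataFrame:
    """Append a weighted-average axis (e.g. the W-Avg combined metric)."""
    col = weighted_metric_column(normalized_table, weights, renormalize=renormalize, name=name)
    out = normalized_table.copy()
    out[name] = col
    return out


def color_by_axis(
    polylines: Sequence[Polyline],
    axes: Sequence[AxisSpec],
    axis: str,
    k: int,
    method: str = "quantile",
) -> list[Polyline]:
    """Cluster one axis' values into k 1-D groups and color lines by group.

    Default is equal-frequency (quantile) binning; ``method="kmeans"``
    uses a deterministic 1-D k-means seeded from quantile centers.
    """
    if k < 1 or k > len(polylines):
        raise ValueError(f"k must be in [1, {len(polylines)}]")
    vis = visible_axes(axes)
    pos = next((a.position for a in vis if a.metric == axis), None)
    if pos is None:
        raise KeyError(f"unknown axis {axis!r}")
    vals = np.array([pl.heights[pos] for pl in polylines])
    order = np.argsort(vals, kind="stable")
    labels = np.empty(len(vals), dtype=int)
    labels[order] = (np.arange(len(vals)) * k) // len(vals)
    if method == "kmeans":
        centers = np.array([vals[labels == g].mean() for g in range(k)])
        for _ in range(50):
            new_labels = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centers = np.array(
                [vals[labels == g].mean() if np.any(labels == g) else centers[g] for g in range(k)]
            )
    elif method != "quantile":
        raise ValueError(f"unknown method {method!r}")
    scheme = _colors.base_palette(
        [f"group{g}" for g in range(k)], hue_step=360.0 / k, chroma=50.0, lightness=60.0
    )
    hexes = [_colors.rgb_to_hex(_colors.lch_to_rgb(c.lightness, c.chroma, c.hue)) for c in scheme.colors]
    return [
        replace(pl, group=int(g), color=hexes[int(g)]) for pl, g in zip(polylines, labels)
    ]
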