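import numpy as np
import pandas as pd
import pytest

from gazegroup.pcp import (
    AxisSpec,
    Polyline,
    brush,
    bundle_curves,
    color_by_axis,
    default_axes,
    delete_selection,
    layout_polylines,
    merge_axes,
    smooth_polyline,
)
from gazegroup.similarity import normalize_metric_table, pairwise_similarity


def table_of(values, columns):
    return pd.DataFrame(values, columns=columns, index=[f"P{i}" for i in range(len(values))])


@pytest.fixture
def simple_table():
    return table_of(
        [[0.0, 10.0, 5.0], [5.0, 20.0, 5.0], [10.0, 30.0, 5.0]], ["a", "b", "c"]
    )


class TestLayout:
    def test_endpoints(self, simple_table):
        lines = layout_polylines(simple_table)
        assert lines[0].heights[0] == 0.0 and lines[2].heights[0] == 1.0

    def test_inverted_axis_reflects(self, simple_table):
        axes = default_axes(simple_table)
        plain = layout_polylines(simple_table, axes)
        axes[0].inverted = True
        flipped = layout_polylines(simple_table, axes)
        for a, b in zip(plain, flipped):
            assert b.heights[0] == pytest.approx(1.0 - a.heights[0])
            assert b.heights[1] == a.heights[1]

    def test_identical_columns_give_parallel_segments(self, simple_table):
        simple_table["b"] = simple_table["a"] * 3 + 1  # same normalized profile
        lines = layout_polylines(simple_table)
        for pl in lines:
            assert pl.heights[0] == pytest.approx(pl.heights[1])

    def test_constant_column_centered(self, simple_table):
        lines = layout_polylines(simple_table)
        assert all(pl.heights[2] == 0.5 for pl in lines)

    def test_missing_metric_rejected(self, simple_table):
        axes = [AxisSpec("nope", 0, 0, 1)]
        with pytest.raises(KeyError):
            layout_polylines(simple_table, axes)

    def test_hidden_axis_skipped_and_positions_consecutive(self, simple_table):
        axes = default_axes(simple_table)
        axes[1].hidden = True
        lines = layout_polylines(simple_table, axes)
        assert lines[0].heights.shape == (2,)

    def test_axis_reorder_permutes_heights(self, simple_table):
        lines1 = layout_polylines(simple_table, default_axes(simple_table, order=["a", "b", "c"]))
        lines2 = layout_polylines(simple_table, default_axes(simple_table, order=["c", "a", "b"]))
        for p1, p2 in zip(lines1, lines2):
            assert p2.heights.tolist() == [p1.heights[2], p1.heights[0], p1.heights[1]]


class TestBrush:
    def test_full_interval_selects_all(self, simple_table):
        axes = default_axes(simple_table)
        lines = layout_polylines(simple_table, axes)
        sel = brush(lines, axes, "a", (0.0, 1.0))
        assert sel.selected == {"P0", "P1", "P2"}

    def test_empty_interval(self, simple_table):
        axes = default_axes(simple_table)
        lines = layout_polylines(simple_table, axes)
        assert brush(lines, axes, "a", (0.8, 0.2)).selected == set()

    def test_membership(self):
        t = table_of([[0.2], [0.6], [0.9]], ["a"])
        axes = [AxisSpec("a", 0, 0.0, 1.0)]
        sel = brush(layout_polylines(t, axes), axes, "a", (0.5, 1.0))
        assert sel.selected == {"P1", "P2"}

    def test_brushes_compose_by_intersection(self, simple_table):
        axes = default_axes(simple_table)
        lines = layout_polylines(simple_table, axes)
        s1 = brush(lines, axes, "a", (0.4, 1.0))
        s2 = brush(lines, axes, "b", (0.0, 0.6))
        assert (s1 & s2).selected == s1.selected & s2.selected

    def test_brush_commutes_with_deletion(self, simple_table):
        """Selecting on the full table then deleting equals deleting then selecting."""
        axes = default_axes(simple_table)
        lines = layout_polylines(simple_table, axes)
        doomed = {"P1"}
        sel_then_del = brush(lines, axes, "a", (0.0, 0.4)).selected - doomed
        smaller = delete_selection(simple_table, doomed)
        # keep the original axis scaling: geometry commutes under fixed axes
        sel_after = brush(layout_polylines(smaller, axes), axes, "a", (0.0, 0.4)).selected
        assert sel_then_del == sel_after

    def test_unknown_axis(self, simple_table):
        axes = default_axes(simple_table)
        lines = layout_polylines(simple_table, axes)
        with pytest.raises(KeyError):
            brush(lines, axes, "zz", (0, 1))


class TestDelete:
    def test_counts(self, simple_table):
        out = delete_selection(simple_table, {"P1"})
        assert len(out) == 2
        assert delete_selection(simple_table, set()) is simple_table

    def test_tensor_pair_count_shrinks(self, simple_table):
        norm, _ = normalize_metric_table(simple_table.drop(columns="c"))
        assert pairwise_similarity(norm).n_pairs() == 3
        smaller, _ = normalize_metric_table(delete_selection(simple_table, {"P0"}).drop(columns="c"))
        assert pairwise_similarity(smaller).n_pairs() == 1

    def test_delete_all_rejected(self, simple_table):
        with pytest.raises(ValueError):
            delete_selection(simple_table, {"P0", "P1", "P2"})


class TestSmoothing:
    def test_s0_is_exact_polyline(self):
        pl = Polyline("P", np.array([0.1, 0.9, 0.3, 0.6]))
        curve = smooth_polyline(pl, 0.0)
        assert np.allclose(curve.y, np.interp(curve.x, np.arange(4), pl.heights), atol=1e-9)

    @pytest.mark.parametrize("s", [0.0, 0.3, 1.0])
    def test_passes_through_every_vertex(self, s):
        pl = Polyline("P", np.array([0.2, 0.8, 0.1, 0.5, 0.5]))
        curve = smooth_polyline(pl, s)
        for i, h in enumerate(pl.heights):
            j = np.argmin(np.abs(curve.x - i))
            assert curve.x[j] == pytest.approx(i)
            assert curve.y[j] == pytest.approx(h, abs=1e-9)

    def test_monotone_input_no_oscillation(self):
        pl = Polyline("P", np.array([0.0, 0.2, 0.5, 0.9]))
        curve = smooth_polyline(pl, 1.0)
        assert np.all(np.diff(curve.y) >= -1e-9)

    def test_no_overshoot_between_vertices(self):
        pl = Polyline("P", np.array([0.1, 0.9, 0.2]))
        curve = smooth_polyline(pl, 1.0)
        for i in range(2):
            seg = (curve.x >= i) & (curve.x <= i + 1)
            lo, hi = sorted((pl.heights[i], pl.heights[i + 1]))
            assert curve.y[seg].min() >= lo - 0.1
            assert curve.y[seg].max() <= hi + 0.1


class TestBundling:
    def lines(self):
        return [
            Polyline("P0", np.array([0.8, 0.9, 0.8])),
            Polyline("P1", np.array([0.9, 0.8, 0.9])),
            Polyline("P2", np.array([0.1, 0.2, 0.1])),
            Polyline("P3", np.array([0.2, 0.1, 0.2])),
        ]

    def groups(self):
        return {"P0": 0, "P1": 0, "P2": 1, "P3": 1}

    def test_beta_zero_identity(self):
        # with no smoothing the collinear mid-gap controls leave the polyline intact
        bundled = bundle_curves(self.lines(), self.groups(), beta=0.0, s=0.0)
        for pl, c in zip(self.lines(), bundled):
            assert np.allclose(c.y, np.interp(c.x, np.arange(3), pl.heights), atol=1e-9)

    def test_beta_one_group_midpoints_coincide(self):
        curves = bundle_curves(self.lines(), self.groups(), beta=1.0)
        mids = {}
        for c in curves:
            j = np.argmin(np.abs(c.x - 0.5))
            mids.setdefault(c.group, []).append(c.y[j])
        for vals in mids.values():
            assert np.allclose(vals, vals[0], atol=1e-9)

    def test_axis_vertices_never_move(self):
        curves = bundle_curves(self.lines(), self.groups(), beta=0.7)
        for pl, c in zip(self.lines(), curves):
            for i, h in enumerate(pl.heights):
                j = np.argmin(np.abs(c.x - i))
                assert c.y[j] == pytest.approx(h, abs=1e-9)

    def test_separated_groups_envelopes_disjoint(self):
        curves = bundle_curves(self.lines(), self.groups(), beta=1.0)
        gap = (curves[0].x > 0.1) & (curves[0].x < 0.9)
        top = min(c.y[gap].min() for c in curves if c.group == 0)
        bottom = max(c.y[gap].max() for c in curves if c.group == 1)
        assert top > bottom

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            bundle_curves(self.lines(), {"P0": 0}, beta=0.5)


class TestMergeAndColor:
    def test_merge_appends_weighted_column(self, simple_table):
        norm, _ = normalize_metric_table(simple_table.drop(columns="c"))
        out = merge_axes(norm, {"a": 0.5, "b": 0.5})
        assert list(out.columns) == ["a", "b", "W-Avg"]
        assert np.allclose(out["W-Avg"], 0.5 * norm["a"] + 0.5 * norm["b"])

    def test_merge_weight_one_duplicates_axis(self, simple_table):
        norm, _ = normalize_metric_table(simple_table.drop(columns="c"))
        out = merge_axes(norm, {"a": 1.0}, name="copy")
        assert np.allclose(out["copy"], norm["a"])

    def test_merged_axis_brushed_at_threshold(self, simple_table):
        norm, _ = normalize_metric_table(simple_table.drop(columns="c"))
        merged = merge_axes(norm, {"a": 0.7, "b": 0.3})
        axes = default_axes(merged)
        # scale brush interval to the merged axis' own range
        spec = next(a for a in axes if a.metric == "W-Avg")
        lo = (0.3 - spec.lo) / (spec.hi - spec.lo) if spec.hi > spec.lo else 0.3
        sel = brush(layout_polylines(merged, axes), axes, "W-Avg", (lo, 1.0))
        expected = {str(i) for i, v in merged["W-Avg"].items() if v >= 0.3}
        assert sel.selected == expected

    def test_color_by_axis_extremes(self, simple_table):
        axes = default_axes(simple_table)
        lines = layout_polylines(simple_table, axes)
        one = color_by_axis(lines, axes, "a", k=1)
        assert len({pl.color for pl in one}) == 1
        alldiff = color_by_axis(lines, axes, "a", k=3)
        assert len({pl.color for pl in alldiff}) == 3

    def test_reciprocal_metric_reverses_color_order(self):
        rng = np.random.default_rng(0)
        avgfix = rng.uniform(100, 500, 12)
        t = table_of(np.column_stack([avgfix, 1000.0 / avgfix]), ["AvgFix", "FixRate"])
        axes = default_axes(t)
        lines = color_by_axis(layout_polylines(t, axes), axes, "AvgFix", k=3)
        # group index rises with AvgFix but falls with FixRate
        by_group = {}
        for pl in lines:
            by_group.setdefault(pl.group, []).append(pl.heights[1])
        g_sorted = sorted(by_group)
        means = [np.mean(by_group[g]) for g in g_sorted]
        assert means[0] > means[-1]

    def test_k_too_large_rejected(self, simple_table):
        axes = default_axes(simple_table)
        lines = layout_polylines(simple_table, axes)
        with pytest.raises(ValueError):
            color_by_axis(lines, axes, "a", k=4)
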