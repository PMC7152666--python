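"""End-to-end workflow: metrics → similarity → clustering → DSSM and PCP renders."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import colors, dssm, grouping, io, metrics, pcp, render, similarity
from .simulate import ArchetypeConfig, default_recovery_benchmark, generate_dataset

logger = logging.getLogger("gazegroup")


@dataclass
class RunConfig:
    """Everything a reproducible run needs; serialized next to the outputs."""

    input_path: str | None = None  # fixation CSV/TSV; None → synthetic
    synthetic: list[dict] | str | None = "benchmark"  # archetype dicts or "benchmark"
    seed: int = 0
    aggregation: str = "mean"
    weights: dict[str, float] = field(default_factory=dict)  # empty → equal weights
    linkage_method: str = "average"
    cut_k: int = 2
    hilbert_order: int | None = None
    hue_step: float = 20.0
    chroma: float = 50.0
    base_lightness: float = 60.0
    lightness_range: tuple[float, float] = (30.0, 90.0)
    smoothing: float = 0.0
    bundle_beta: float = 0.0
    figure_format: str = "svg"
    out_dir: str = "gazegroup_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_input(config: RunConfig):
    """Resolve the configured input into a Dataset (+ truth labels if synthetic)."""
    if config.input_path is not None:
        return io.read_fixation_table(config.input_path), None
    if config.synthetic == "benchmark" or config.synthetic is None:
        return default_recovery_benchmark(config.seed)
    cfgs = [ArchetypeConfig(**d) for d in config.synthetic]
    return generate_dataset(cfgs, config.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the artifact bundle to ``config.out_dir``.

    Returns a dict of the in-memory stage products (metric table, tensor,
    dendrogram, group assignment, DSSM grid, file paths).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.weights:
        total = sum(config.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"configured weights sum to {total}, not 1")

    stage = "load"
    try:
        dataset, truth = load_input(config)

        stage = "metrics"
        table = metrics.compute_metric_table(dataset, aggregation=config.aggregation)
        io.write_metric_table(table, out / "metric_table.csv")

        stage = "normalize"
        norm, record = similarity.normalize_metric_table(table)

        stage = "similarity"
        tensor = similarity.pairwise_similarity(norm)
        weights = config.weights or {m: 1.0 / len(tensor.metrics) for m in tensor.metrics}
        combined = similarity.combine_metrics(tensor, weights, renormalize=True)
        io.write_matrix(combined, out / "combined_matrix.csv", labels=tensor.participants)

        stage = "cluster"
        dend = grouping.linkage(combined, method=config.linkage_method, labels=tensor.participants)
        io.write_json(dend.to_dict(), out / "dendrogram.json")
        groups = grouping.cut(dend, k=config.cut_k)
        io.write_groups(groups, out / "groups.csv")
        order = grouping.participant_order(dend)

        stage = "metric_order"
        corr, _ = similarity.metric_correlations(table)
        morder = grouping.metric_order(corr, method=config.linkage_method)

        stage = "dssm"
        layout = dssm.assign_metrics(morder, o=config.hilbert_order)
        grid = dssm.assemble_dssm(tensor, order, layout=layout, metric_order=morder)
        grid.to_long_frame().to_csv(out / "dssm_long.csv", index=False)

        stage = "render"
        scheme = colors.base_palette(
            morder,
            hue_step=config.hue_step,
            chroma=config.chroma,
            lightness=config.base_lightness,
        )
        scheme.lightness_range = config.lightness_range
        io.write_json(scheme.to_dict(), out / "palette.json")
        fmt = config.figure_format
        boundaries = _group_boundaries(groups, order)
        render.render_dssm(grid, scheme, out / f"dssm.{fmt}", group_boundaries=boundaries)
        axes = pcp.default_axes(table, order=morder)
        lines = pcp.layout_polylines(table, axes)
        if config.bundle_beta > 0:
            curves = pcp.bundle_curves(lines, groups, beta=config.bundle_beta, s=max(config.smoothing, 1.0))
            render.render_pcp(curves, axes, out / f"pcp.{fmt}")
        elif config.smoothing > 0:
            curves = [pcp.smooth_polyline(pl, config.smoothing) for pl in lines]
            render.render_pcp(curves, axes, out / f"pcp.{fmt}")
        else:
            render.render_pcp(lines, axes, out / f"pcp.{fmt}")

        io.write_json(config.to_dict(), out / "run_config.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    logger.info("pipeline complete; artifacts in %s", out)
    return {
        "dataset": dataset,
        "truth": truth,
        "metric_table": table,
        "tensor": tensor,
        "combined": combined,
        "dendrogram": dend,
        "groups": groups,
        "participant_order": order,
        "metric_order": morder,
        "grid": grid,
        "out_dir": str(out),
    }


def _group_boundaries(groups: dict[str, int], order: list[str]) -> list[int]:
    bounds = []
    for i in range(1, len(order)):
        if groups[order[i]] != groups[order[i - 1]]:
            bounds.append(i)
    return bounds
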