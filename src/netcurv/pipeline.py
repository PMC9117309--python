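"""High-level orchestration: per-subject measure curves and cohort tensors.

These helpers glue graph construction, curvature and standard measures
into the subject x density (global) and subject x node (AUC) arrays the
statistics stage consumes.
"""

from __future__ import annotations

import numpy as np

from .connectivity import FCMatrix
from .curvature import (
    ORCConfig,
    average_edge_curvature,
    edge_curvatures,
    node_curvature,
)
from .errors import ConfigurationError
from .graphs import DensityGrid, build_graph_series
from .measures import global_measures, nodal_measures
from .stats import MeasureTensor, nodal_auc_tensor
from .synthetic import SubjectRecord

#: global measures computable per density
GLOBAL_MEASURES = (
    "avg_frc",
    "avg_orc",
    "avg_clustering",
    "modularity",
    "avg_shortest_path",
    "avg_node_betweenness",
    "global_efficiency",
    "avg_local_efficiency",
)

#: nodal measures (per node, per density; collapsed to AUC downstream)
NODAL_MEASURES = ("frc_node", "orc_node", "clustering", "betweenness")


def subject_global_curves(
    fc: FCMatrix,
    grid: DensityGrid,
    measures: tuple[str, ...] = ("avg_frc", "avg_clustering", "modularity"),
    frc_variant: str = "augmented",
    orc_cfg: ORCConfig | None = None,
    rank_by: str = "signed",
) -> dict[str, np.ndarray]:
    """Per-density values of the requested global measures for one subject."""
    unknown = set(measures) - set(GLOBAL_MEASURES)
    if unknown:
        raise ConfigurationError(f"unknown global measures: {sorted(unknown)}")
    series = build_graph_series(fc, grid, rank_by=rank_by)
    out = {m: np.empty(len(series)) for m in measures}
    need_std = bool(set(measures) & set(GLOBAL_MEASURES[2:]))
    for gi in range(len(series)):
        g = series.to_networkx(gi)
        if "avg_frc" in out:
            out["avg_frc"][gi] = average_edge_curvature(
                edge_curvatures(g, "frc", variant=frc_variant)
            )
        if "avg_orc" in out:
            out["avg_orc"][gi] = average_edge_curvature(
                edge_curvatures(g, "orc", cfg=orc_cfg)
            )
        if need_std:
            gm = global_measures(g)
            for m in measures:
                if m in ("avg_frc", "avg_orc"):
                    continue
                out[m][gi] = getattr(gm, m)
    return out


def subject_nodal_curves(
    fc: FCMatrix,
    grid: DensityGrid,
    measures: tuple[str, ...] = ("frc_node",),
    frc_variant: str = "augmented",
    orc_cfg: ORCConfig | None = None,
    rank_by: str = "signed",
) -> dict[str, np.ndarray]:
    """Per-density x per-node arrays (len(grid), n_rois) for one subject."""
    unknown = set(measures) - set(NODAL_MEASURES)
    if unknown:
        raise ConfigurationError(f"unknown nodal measures: {sorted(unknown)}")
    series = build_graph_series(fc, grid, rank_by=rank_by)
    n = fc.n_rois
    out = {m: np.empty((len(series), n)) for m in measures}
    for gi in range(len(series)):
        g = series.to_networkx(gi)
        if "frc_node" in out:
            nc = node_curvature(edge_curvatures(g, "frc", variant=frc_variant), g)
            out["frc_node"][gi] = [nc[i] for i in range(n)]
        if "orc_node" in out:
            nc = node_curvature(edge_curvatures(g, "orc", cfg=orc_cfg), g)
            out["orc_node"][gi] = [nc[i] for i in range(n)]
        if "clustering" in out or "betweenness" in out:
            nm = nodal_measures(g)
            if "clustering" in out:
                out["clustering"][gi] = [nm.clustering[i] for i in range(n)]
            if "betweenness" in out:
                out["betweenness"][gi] = [nm.betweenness[i] for i in range(n)]
    return out


def cohort_global_tensors(
    fcs: list[FCMatrix],
    records: list[SubjectRecord],
    grid: DensityGrid,
    measures: tuple[str, ...] = ("avg_frc", "avg_clustering", "modularity"),
    **kwargs,
) -> dict[str, MeasureTensor]:
    """subject x density tensors of global measures for a labeled cohort."""
    curves = [subject_global_curves(fc, grid, measures, **kwargs) for fc in fcs]
    sids = [r.subject_id for r in records]
    groups = [r.group for r in records]
    return {
        m: MeasureTensor(sids, grid.values, np.array([c[m] for c in curves]), groups)
        for m in measures
    }


def cohort_nodal_auc_tensors(
    fcs: list[FCMatrix],
    records: list[SubjectRecord],
    grid: DensityGrid,
    measures: tuple[str, ...] = ("frc_node",),
    **kwargs,
) -> dict[str, MeasureTensor]:
    """subject x node tensors of AUCs over the density grid."""
    curves = [subject_nodal_curves(fc, grid, measures, **kwargs) for fc in fcs]
    sids = [r.subject_id for r in records]
    groups = [r.group for r in records]
    roi_ids = fcs[0].roi_ids
    out = {}
    for m in measures:
        arr = np.stack([c[m] for c in curves])  # (S, D, N)
        out[m] = nodal_auc_tensor(sids, groups, arr, grid, roi_ids)
    return out
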