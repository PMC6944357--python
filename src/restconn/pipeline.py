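"""End-to-end analysis: config -> group matrices -> graph panel ->
triangle segregation -> group comparisons -> report bundle.

Every emitted table is plain CSV with a provenance comment header (tool
version, config hash, seed), and every number in them is reproducible by
calling the underlying module functions directly.  Scopes analysed per
group: each named network, all networks combined (RSNs) and the whole
brain.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasTable, load_atlas, load_networks, resolve_members
from .connectivity import (
    BinaryGraph,
    ConnectivityMatrix,
    apply_threshold,
    connection_count,
    density_sweep,
    group_mean,
    pearson_matrix,
    read_matrix,
    read_time_series,
    write_matrix,
)
from .exceptions import AlignmentError, ParameterError
from .metrics import compute_metrics
from .stats import chisq_equal_prob, compare_nodal_metrics, ranksum_test
from .triangles import area_threshold, enumerate_triangles, triangle_estimators

logger = logging.getLogger("restconn")

DEFAULT_SWEEP = [round(0.40 + 0.01 * i, 2) for i in range(11)]


@dataclass
class PipelineConfig:
    """Run configuration; loadable from YAML via :func:`load_config`.

    ``inputs`` maps group name -> list of file paths; ``input_kind`` is
    ``"timeseries"`` (ROI x time delimited text) or ``"matrix"``
    (precomputed labelled correlation CSV).
    """

    inputs: dict[str, list[str]]
    out_dir: str
    input_kind: str = "timeseries"
    atlas_path: str | None = None
    networks_path: str | None = None
    threshold: float = 0.5
    sweep: list[float] = field(default_factory=lambda: list(DEFAULT_SWEEP))
    triangle_side: float = 0.6
    include_isolated: bool = False
    threshold_level: str = "group"  # or "subject": threshold before averaging
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_kind not in ("timeseries", "matrix"):
            raise ParameterError("input_kind must be 'timeseries' or 'matrix'")
        if self.threshold_level not in ("group", "subject"):
            raise ParameterError("threshold_level must be 'group' or 'subject'")
        lo, hi = min(self.sweep), max(self.sweep)
        if not lo <= self.threshold <= hi:
            raise ParameterError(
                f"main threshold {self.threshold} outside sweep range [{lo}, {hi}]"
            )

    def config_hash(self) -> str:
        # out_dir is where results land, not part of what they are
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _provenance(config: PipelineConfig) -> list[str]:
    return [
        f"restconn {__version__}",
        f"config_hash={config.config_hash()} seed={config.seed}",
        f"threshold={config.threshold} triangle_side={config.triangle_side} "
        f"include_isolated={config.include_isolated}",
    ]


def _write_table(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _load_group(config: PipelineConfig, atlas: AtlasTable, group: str) -> list[ConnectivityMatrix]:
    labels = tuple(atlas.labels)
    mats = []
    for path in config.inputs[group]:
        if config.input_kind == "timeseries":
            mats.append(pearson_matrix(read_time_series(path, labels)))
        else:
            mats.append(read_matrix(path, labels))
    return mats


def group_matrix(config: PipelineConfig, atlas: AtlasTable, group: str) -> ConnectivityMatrix:
    """Aggregate a group's subject matrices (z-space mean, back to r)."""
    mats = _load_group(config, atlas, group)
    if config.threshold_level == "subject":
        mats = [apply_threshold(m, config.threshold, "weighted") for m in mats]
    return group_mean(mats)


def _scopes(atlas: AtlasTable, networks) -> dict[str, list[int]]:
    scopes = {name: resolve_members(atlas, net) for name, net in networks.items()}
    rsn_union = sorted(set().union(*scopes.values())) if scopes else []
    scopes["RSNs"] = rsn_union
    scopes["whole_brain"] = list(range(atlas.n_regions))
    return scopes


def metric_row(graph: BinaryGraph, include_isolated: bool) -> dict:
    """Tables 4-8 style row for one group x scope graph."""
    if connection_count(graph) == 0:
        return {"computable": False}
    m = compute_metrics(graph, include_isolated=include_isolated)
    row = {
        "computable": True,
        "path_length": m.characteristic_path_length,
        "global_efficiency": m.global_efficiency,
        "n_unreachable_pairs": m.n_unreachable_pairs,
    }
    for name, summ in (
        ("clustering", m.clustering_summary),
        ("local_efficiency", m.local_efficiency_summary),
        ("degree", m.degree_summary),
    ):
        row[f"{name}_mean"] = summ.mean if summ else None
        row[f"{name}_std"] = summ.std if summ else None
    row["n_nodes_used"] = m.degree_summary.n_used if m.degree_summary else 0
    return row


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a summary dict (also written as ``manifest.json``): per group
    and scope the connection counts, metric rows, triangle-estimator rows,
    and the between-group comparisons.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)

    atlas = load_atlas(config.atlas_path)
    networks = load_networks(config.networks_path)
    scopes = _scopes(atlas, networks)
    groups = list(config.inputs)
    tri_thr = area_threshold(config.triangle_side)

    gm: dict[str, ConnectivityMatrix] = {}
    for group in groups:
        gm[group] = group_matrix(config, atlas, group)
        write_matrix(gm[group], out / f"matrix_{group}.csv", prov)

    metric_rows, tri_rows, count_rows, sweep_frames = [], [], [], []
    tri_sets: dict[tuple[str, str], object] = {}
    graphs: dict[tuple[str, str], BinaryGraph] = {}
    for group in groups:
        binary = apply_threshold(gm[group], config.threshold, "binary")
        for scope, idx in scopes.items():
            if len(idx) < 3:
                logger.warning("scope %s has <3 nodes; skipped", scope)
                continue
            g = binary.subgraph(idx)
            graphs[(group, scope)] = g
            count_rows.append(
                {"group": group, "scope": scope,
                 "directed_connections": connection_count(g)}
            )
            row = metric_row(g, config.include_isolated)
            if not row["computable"]:
                logger.warning("no above-threshold edges for %s/%s; metrics not computable",
                               group, scope)
            metric_rows.append({"group": group, "scope": scope, **row})
            ts = enumerate_triangles(gm[group], idx, tri_thr, scope=scope)
            tri_sets[(group, scope)] = ts
            tri_rows.append({
                "group": group, "scope": scope, **triangle_estimators(ts),
                "n_candidates": ts.n_candidates, "n_invalid": ts.n_invalid,
            })
            sw = density_sweep(gm[group], config.sweep, idx)
            sw.insert(0, "scope", scope)
            sw.insert(0, "group", group)
            sweep_frames.append(sw)

    _write_table(pd.DataFrame(count_rows), out / "connection_counts.csv", prov)
    _write_table(pd.DataFrame(metric_rows), out / "graph_metrics.csv", prov)
    _write_table(pd.DataFrame(tri_rows), out / "triangle_estimators.csv", prov)
    _write_table(pd.concat(sweep_frames, ignore_index=True), out / "density_sweep.csv", prov)

    comparison_rows = []
    if len(groups) == 2:
        a, b = groups
        for scope in scopes:
            ga, gb = graphs.get((a, scope)), graphs.get((b, scope))
            if ga is None or gb is None:
                continue
            if connection_count(ga) and connection_count(gb):
                ma = compute_metrics(ga, config.include_isolated)
                mb = compute_metrics(gb, config.include_isolated)
                for res in compare_nodal_metrics(
                    {"degree": ma.degree.astype(float), "clustering": ma.clustering,
                     "local_efficiency": ma.local_efficiency},
                    {"degree": mb.degree.astype(float), "clustering": mb.clustering,
                     "local_efficiency": mb.local_efficiency},
                    scope,
                ):
                    comparison_rows.append({
                        "test": res.test, "metric": res.metric, "scope": res.scope,
                        "statistic": res.statistic, "df": "", "p": res.p_value,
                        "p_fdr": res.p_fdr,
                    })
            ta, tb = tri_sets[(a, scope)], tri_sets[(b, scope)]
            chi2, df, p = chisq_equal_prob([len(ta), len(tb)])
            comparison_rows.append({
                "test": "chisq_triangle_counts", "metric": "n_triangles",
                "scope": scope, "statistic": chi2, "df": df, "p": p, "p_fdr": None,
            })
            if len(ta) and len(tb):
                z, p = ranksum_test(ta.areas, tb.areas)
                comparison_rows.append({
                    "test": "ranksum_triangle_areas", "metric": "area",
                    "scope": scope, "statistic": z, "df": "", "p": p, "p_fdr": None,
                })
        _write_table(pd.DataFrame(comparison_rows), out / "group_comparisons.csv", prov)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "groups": groups,
        "scopes": {k: len(v) for k, v in scopes.items()},
        "connection_counts": count_rows,
        "metrics": metric_rows,
        "triangles": tri_rows,
        "comparisons": comparison_rows,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def export_brainnet(
    atlas: AtlasTable,
    G: BinaryGraph | ConnectivityMatrix,
    node_path: str | Path,
    edge_path: str | Path,
    indices: list[int] | None = None,
    color: int = 1,
) -> None:
    """Write BrainNet Viewer .node / .edge text files.

    .node rows: x y z color size label (size = node degree/strength);
    .edge: the square matrix, whitespace-separated.  Reading the .edge
    file back reproduces the matrix exactly.
    """
    values = G.adjacency if isinstance(G, BinaryGraph) else G.values
    labels = G.labels
    if indices is None:
        if len(labels) != atlas.n_regions or tuple(atlas.labels) != tuple(labels):
            raise AlignmentError("graph labels do not match the atlas; pass indices")
        indices = list(range(atlas.n_regions))
    else:
        expect = tuple(atlas.labels[i] for i in indices)
        if tuple(labels) != expect:
            raise AlignmentError("graph labels do not match atlas rows at the given indices")
    coords = atlas.coordinates[indices]
    sizes = np.asarray(values, dtype=float).sum(axis=1)
    with open(node_path, "w") as fh:
        for (x, y, z), size, label in zip(coords, sizes, labels):
            fh.write(f"{x:g}\t{y:g}\t{z:g}\t{color}\t{size:g}\t{label}\n")
    np.savetxt(edge_path, np.asarray(values, dtype=float), fmt="%.17g", delimiter="\t")
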