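"""Per-subject and group orchestration of the full workflow.

A subject run goes: regional time-course extraction → neuronality
filtering → template matching → GLM t-values → significance threshold →
correlation / anti-correlation graphs per network (plus the classical
whole-brain graph when spatial maps are available) → metric battery.
Subjects are processed independently and aggregated afterwards; every
numeric decision is carried in :class:`PipelineConfig` and logged to a
machine-readable provenance block in each output directory.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as icga_io
from .graphs import aggregate_group, build_classical_network, build_subject_graph
from .metrics import compute_metrics_record
from .regression import compute_t_threshold, extract_region_timecourses, fit_glm
from .selection import TemplateSet, classify_neuronal, match_templates, spectral_classifier
from .stats import COMPARABLE_METRICS, compare_networks, mask_classical_to_network
from .types import ICDecomposition, MetricsRecord, ParcellationVolume, RegionTimeSeries


@dataclass
class PipelineConfig:
    """Every tunable the workflow exposes, with the canonical defaults."""

    significance_p: float = 0.001
    presence_fraction: float = 0.25
    n_random_nulls: int = 20
    seed: int = 0
    neuronal_cutoff: float = 0.5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    drop_initial_volumes: int = 3
    use_all_components: bool = False
    build_classical: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _network_map(decomposition, templates, neuronal_ids):
    """Name → component id for the graphs to build.

    With templates: the multiple-template assignment restricted to neuronal
    components.  Without: every neuronal component under the name IC<id>.
    """
    selection = None
    if templates is not None:
        if decomposition.spatial_maps is None:
            raise ValueError("template matching requires component spatial maps")
        neuronal_index = [
            i
            for i, c in enumerate(decomposition.component_ids)
            if c in neuronal_ids
        ]
        if not neuronal_index:
            return {}, None
        maps = decomposition.spatial_maps[..., neuronal_index]
        ids = [decomposition.component_ids[i] for i in neuronal_index]
        selection = match_templates(maps, templates, component_ids=ids)
        networks = {
            name: cid
            for name, cid in selection.assignment.items()
            if cid != "absent"
        }
        return networks, selection
    return {f"IC{c}": c for c in sorted(neuronal_ids, key=str)}, selection


def run_subject(
    out_dir,
    decomposition: ICDecomposition,
    region_series: RegionTimeSeries | None = None,
    bold=None,
    parcellation: ParcellationVolume | None = None,
    templates: TemplateSet | None = None,
    config: PipelineConfig | None = None,
    classifier=None,
) -> dict:
    """Run the full single-subject workflow and write all artifacts.

    Provide either ``region_series`` directly or ``bold`` (a 4-D array or
    nibabel image, already trimmed of initial volumes when passed as an
    array) together with ``parcellation``.  Returns a dict with the
    t-value table, graphs, metrics and the parameters used.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if region_series is None:
        if bold is None or parcellation is None:
            raise ValueError(
                "stage extract: need region_series, or bold plus parcellation"
            )
        region_series = extract_region_timecourses(
            bold, parcellation, tr_seconds=decomposition.tr_seconds
        )
    icga_io.write_timeseries_tsv(
        region_series.values, region_series.region_ids,
        out_dir / "region_timecourses.tsv",
    )

    if classifier is None:
        classifier = spectral_classifier(
            band_hz=(config.band_low_hz, config.band_high_hz),
            cutoff=config.neuronal_cutoff,
        )
    neuronal_ids = classify_neuronal(decomposition, classifier)
    networks, selection = _network_map(decomposition, templates, neuronal_ids)

    if config.use_all_components:
        design_ids = list(decomposition.component_ids)
    else:
        design_ids = [c for c in decomposition.component_ids if c in neuronal_ids]
    if not design_ids:
        raise ValueError("stage classify: no neuronal components retained")
    idx = [decomposition.index_of(c) for c in design_ids]
    design = ICDecomposition(
        timecourses=decomposition.timecourses[idx],
        tr_seconds=decomposition.tr_seconds,
        component_ids=design_ids,
    )

    table = fit_glm(region_series, design)
    t_thr = compute_t_threshold(table.dof, config.significance_p)
    icga_io.write_tvalue_table(table, out_dir / "tvalues.tsv")

    graphs = {}
    records = []
    for name, cid in sorted(networks.items()):
        if cid not in design_ids:
            continue
        for flavor in ("correlation", "anticorrelation"):
            g = build_subject_graph(table, cid, flavor, t_thr)
            graphs[(name, flavor)] = g
            icga_io.write_graph(g, out_dir / f"{name}_{flavor}.tsv", "tsv")
            icga_io.write_graph(g, out_dir / f"{name}_{flavor}.graphml", "graphml")
            records.append(
                compute_metrics_record(
                    g,
                    network_id=f"{name}_{flavor}",
                    n_random=config.n_random_nulls,
                    seed=config.seed,
                )
            )

    classical = None
    if config.build_classical and decomposition.spatial_maps is not None:
        if parcellation is None:
            warnings.warn(
                "classical network skipped: no parcellation available",
                stacklevel=2,
            )
        else:
            classical = build_classical_network(
                decomposition, design_ids, parcellation, t_thr
            )
            icga_io.write_graph(classical, out_dir / "classical.tsv", "tsv")
    elif config.build_classical and decomposition.spatial_maps is None and parcellation is not None:
        raise ValueError(
            "stage classical: reconstruction of the cleaned voxel signal "
            "requires component spatial maps"
        )

    icga_io.write_metrics_json(records, out_dir / "metrics.json")

    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "dof": int(table.dof),
        "t_threshold": t_thr,
        "edge_weight_cutoff": 2.0 * t_thr,
        "neuronal_ids": sorted(map(str, neuronal_ids)),
        "design_component_ids": list(map(str, design_ids)),
        "networks": {k: str(v) for k, v in networks.items()},
    }
    if selection is not None:
        provenance["gof_matrix"] = selection.gof_matrix.tolist()
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )

    return {
        "table": table,
        "t_threshold": t_thr,
        "graphs": graphs,
        "classical": classical,
        "records": records,
        "networks": networks,
        "neuronal_ids": neuronal_ids,
    }


def _discover_networks(subject_dirs) -> dict:
    found = {}
    for d in subject_dirs:
        for path in Path(d).glob("*_correlation.tsv"):
            name = path.name[: -len("_correlation.tsv")]
            found.setdefault(name, set()).add(str(d))
    return found


def run_group(
    subject_dirs,
    out_dir,
    config: PipelineConfig | None = None,
) -> dict:
    """Aggregate per-subject outputs into group graphs, tables and tests.

    For every network present in at least one subject: the 25%-presence
    group graph per flavor, the detection percentage (fraction of subjects
    in which the network was found), the pooled per-subject metrics table,
    and — when classical graphs exist — the ANOVA + Tukey comparison of
    each network against the classical network masked to that network's
    constellation.
    """
    config = config or PipelineConfig()
    subject_dirs = [Path(d) for d in subject_dirs]
    if len(subject_dirs) < 2:
        raise ValueError("need at least 2 subjects for a group analysis")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    networks = _discover_networks(subject_dirs)
    n_subjects = len(subject_dirs)

    group_graphs = {}
    detection = {}
    for name in sorted(networks):
        present_dirs = sorted(networks[name])
        detection[name] = 100.0 * len(present_dirs) / n_subjects
        for flavor in ("correlation", "anticorrelation"):
            graphs = [
                icga_io.read_graph(Path(d) / f"{name}_{flavor}.tsv")
                for d in present_dirs
                if (Path(d) / f"{name}_{flavor}.tsv").exists()
            ]
            if not graphs:
                continue
            # presence is counted against the full cohort: a subject without
            # the network contributes an absent (empty) graph
            template = graphs[0]
            absent = n_subjects - len(graphs)
            if absent:
                from .types import SubjectGraph

                empty = SubjectGraph(
                    component_id=template.component_id,
                    flavor=flavor,
                    weights=np.zeros_like(template.weights),
                    region_ids=template.region_ids,
                    threshold_applied=template.threshold_applied,
                )
                graphs = graphs + [empty] * absent
            gg = aggregate_group(graphs, config.presence_fraction)
            group_graphs[(name, flavor)] = gg
            icga_io.write_graph(gg, out_dir / f"{name}_{flavor}_group.tsv", "tsv")
            icga_io.write_graph(
                gg, out_dir / f"{name}_{flavor}_group.graphml", "graphml"
            )

    pooled = _pooled_metrics_table(subject_dirs, networks, detection)
    pooled.to_csv(out_dir / "metrics_table.tsv", sep="\t", index=False)

    comparison = _compare_to_classical(
        subject_dirs, networks, group_graphs, config
    )
    if comparison is not None:
        comparison.to_csv(out_dir / "comparison.tsv", sep="\t", index=False)
        (out_dir / "comparison.json").write_text(
            comparison.to_json(orient="records", indent=2) + "\n"
        )

    (out_dir / "detection.json").write_text(
        json.dumps(detection, indent=2, sort_keys=True) + "\n"
    )
    return {
        "group_graphs": group_graphs,
        "detection_pct": detection,
        "metrics_table": pooled,
        "comparison": comparison,
    }


def _pooled_metrics_table(subject_dirs, networks, detection) -> pd.DataFrame:
    """Per-network mean ± sd of the subject-level metric battery."""
    rows = []
    per_network = {}
    for d in subject_dirs:
        path = Path(d) / "metrics.json"
        if not path.exists():
            continue
        for rec in icga_io.read_metrics_json(path):
            nid = rec["network_id"]
            if nid.endswith("_correlation"):
                name = nid[: -len("_correlation")]
                per_network.setdefault(name, []).append(rec)
    for name in sorted(networks):
        recs = per_network.get(name, [])
        if not recs:
            continue

        def agg(key):
            vals = np.array([r[key] for r in recs], dtype=float)
            vals = vals[np.isfinite(vals)]
            return (np.nan, np.nan) if vals.size == 0 else (vals.mean(), vals.std())

        e_m, e_s = agg("n_edges")
        k_m, k_s = agg("avg_degree")
        t_m, t_s = agg("triangles_normalized")
        s_m, s_s = agg("small_worldness")
        nodes_m, _ = agg("n_connected_nodes")
        rows.append(
            {
                "network": name,
                "pct_detected": detection.get(name, np.nan),
                "nodes_mean": nodes_m,
                "edges_mean": e_m,
                "edges_sd": e_s,
                "degree_mean": k_m,
                "degree_sd": k_s,
                "triangles_norm_mean": t_m,
                "triangles_norm_sd": t_s,
                "sigma_mean": s_m,
                "sigma_sd": s_s,
            }
        )
    return pd.DataFrame(rows)


def _compare_to_classical(subject_dirs, networks, group_graphs, config):
    """ANOVA + Tukey of each network vs the node-masked classical network."""
    classical = {}
    for d in subject_dirs:
        path = Path(d) / "classical.tsv"
        if path.exists():
            classical[str(d)] = icga_io.read_graph(path)
    if not classical:
        return None

    frames = []
    for name in sorted(networks):
        gg = group_graphs.get((name, "correlation"))
        if gg is None:
            continue
        from .metrics import connected_constellation

        nodes = sorted(connected_constellation(gg).nodes())
        if len(nodes) < 2:
            warnings.warn(
                f"network {name!r} has an empty group constellation; "
                "excluded from comparison",
                stacklevel=2,
            )
            continue
        groups = {name: [], f"{name}_CN": []}
        for d in sorted(networks[name]):
            path = Path(d) / "metrics.json"
            if not path.exists():
                continue
            for rec in icga_io.read_metrics_json(path):
                if rec["network_id"] == f"{name}_correlation":
                    groups[name].append(rec)
        for d, cg in sorted(classical.items()):
            masked = mask_classical_to_network(cg, nodes)
            groups[f"{name}_CN"].append(
                compute_metrics_record(
                    masked,
                    network_id=f"{name}_CN",
                    n_random=config.n_random_nulls,
                    seed=config.seed,
                ).to_dict()
            )
        if min(len(v) for v in groups.values()) < 2:
            continue
        for metric in COMPARABLE_METRICS:
            try:
                report = compare_networks(groups, metric)
            except ValueError:
                continue
            frames.append(report.to_frame())
    if not frames:
        return None
    return pd.concat(frames, ignore_index=True)
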