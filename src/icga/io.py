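"""Readers and writers for every external format the pipeline touches.

NIfTI-1 for images and label volumes (via nibabel), TSV for matrices and
edge lists, GraphML for graphs, JSON for metrics.  Every reader/writer pair
is a lossless round trip at the declared precision; floats in text formats
are written with ``repr`` so round trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    GroupGraph,
    ICDecomposition,
    ParcellationVolume,
    RegionTimeSeries,
    SubjectGraph,
    TValueTable,
)


# ---------------------------------------------------------------------------
# imaging

def read_bold(path, drop_initial: int = 0) -> nib.Nifti1Image:
    """Load a 4-D BOLD series, optionally discarding leading volumes.

    Dropping the first few volumes avoids T1-saturation transients; the
    conventional choice for the acquisitions this pipeline targets is 3.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D BOLD image, got {img.ndim}D: {path}")
    n_vol = img.shape[3]
    if n_vol < 2:
        raise ValueError("BOLD image must contain at least 2 volumes")
    if drop_initial < 0 or drop_initial >= n_vol:
        raise ValueError(
            f"drop_initial={drop_initial} invalid for {n_vol} volumes"
        )
    if drop_initial:
        data = np.asanyarray(img.dataobj)[..., drop_initial:]
        img = nib.Nifti1Image(data, img.affine, img.header)
    return img


def read_parcellation(path) -> ParcellationVolume:
    """Load an integer label volume; background (0) is never a region."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D label volume, got {img.ndim}D: {path}")
    labels = np.asanyarray(img.dataobj)
    return ParcellationVolume(labels=labels, affine=img.affine)


def write_nifti(data: np.ndarray, path, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


# ---------------------------------------------------------------------------
# matrices as TSV (header row of column ids, one row per time point)

def write_timeseries_tsv(values: np.ndarray, ids, path) -> None:
    """Write a series×time matrix as TSV: columns = ids, rows = time points."""
    df = pd.DataFrame(np.asarray(values).T, columns=[str(i) for i in ids])
    df.to_csv(path, sep="\t", index=False, float_format=None)


def _read_matrix_tsv(path):
    df = pd.read_csv(path, sep="\t")
    ids = [_maybe_int(c) for c in df.columns]
    return df.to_numpy(dtype=float).T, ids


def _maybe_int(token: str):
    try:
        return int(token)
    except (TypeError, ValueError):
        return token


def read_region_timeseries(path, tr_seconds: float) -> RegionTimeSeries:
    values, ids = _read_matrix_tsv(path)
    return RegionTimeSeries(values=values, region_ids=ids, tr_seconds=tr_seconds)


def read_ic_timecourses(path, tr_seconds: float) -> ICDecomposition:
    values, ids = _read_matrix_tsv(path)
    return ICDecomposition(
        timecourses=values, component_ids=ids, tr_seconds=tr_seconds
    )


def read_ic_maps(path) -> tuple[np.ndarray, np.ndarray]:
    """Load 4-D component spatial maps; returns (data, affine)."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D component maps, got {img.ndim}D")
    return np.asanyarray(img.dataobj).astype(float), img.affine


# ---------------------------------------------------------------------------
# t-value tables

def write_tvalue_table(table: TValueTable, tsv_path, json_path=None) -> None:
    """TSV of t-values (components × regions) plus a JSON metadata sidecar."""
    tsv_path = Path(tsv_path)
    df = pd.DataFrame(
        table.tvalues,
        index=[str(c) for c in table.component_ids],
        columns=[str(r) for r in table.region_ids],
    )
    df.index.name = "component"
    df.to_csv(tsv_path, sep="\t")
    if json_path is None:
        json_path = tsv_path.with_suffix(".json")
    meta = {
        "dof": int(table.dof),
        "n_volumes": int(table.n_volumes),
        "n_components": int(table.n_components),
        "flagged_regions": [
            str(r)
            for r, f in zip(table.region_ids, table.flagged_regions)
            if f
        ],
    }
    Path(json_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# graphs

def _graph_kind(graph) -> str:
    return "group" if isinstance(graph, GroupGraph) else "subject"


def write_graph(graph, path, format: str = "tsv") -> None:
    """Write a graph as an edge-list TSV or as GraphML.

    The TSV carries ``node_a<TAB>node_b<TAB>weight`` (plus ``presence_count``
    for group graphs) and a comment header preserving the node universe and
    threshold, so that reading it back reproduces weights to better than
    1e-9 (exactly, in fact: floats are serialised with repr).
    """
    if format == "tsv":
        _write_graph_tsv(graph, path)
    elif format == "graphml":
        nx.write_graphml(to_networkx(graph, weighted=True), str(path))
    else:
        raise ValueError(f"unknown graph format {format!r}")


def _write_graph_tsv(graph, path) -> None:
    ids = list(graph.region_ids)
    lines = []
    meta = {
        "kind": _graph_kind(graph),
        "flavor": graph.flavor,
        "component": graph.component_id,
        "regions": ",".join(str(i) for i in ids),
    }
    if isinstance(graph, GroupGraph):
        meta["n_subjects"] = graph.n_subjects
        meta["presence_fraction_min"] = repr(float(graph.presence_fraction_min))
    elif graph.threshold_applied is not None:
        meta["threshold_applied"] = repr(float(graph.threshold_applied))
    lines.append("# " + " ".join(f"{k}={v}" for k, v in meta.items()))
    if isinstance(graph, GroupGraph):
        lines.append("node_a\tnode_b\tweight\tpresence_count")
        mask = np.triu(graph.retained_mask(), k=1)
        for i, j in zip(*np.nonzero(mask)):
            lines.append(
                f"{ids[i]}\t{ids[j]}\t{float(graph.mean_weights[i, j])!r}"
                f"\t{int(graph.presence_counts[i, j])}"
            )
    else:
        lines.append("node_a\tnode_b\tweight")
        mask = np.triu(graph.weights, k=1) > 0
        for i, j in zip(*np.nonzero(mask)):
            lines.append(f"{ids[i]}\t{ids[j]}\t{float(graph.weights[i, j])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph(path):
    """Read back a graph written by :func:`write_graph` (TSV format)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"missing graph metadata header in {path}")
    meta = dict(tok.split("=", 1) for tok in lines[0][1:].strip().split(" "))
    ids = [_maybe_int(t) for t in meta["regions"].split(",")]
    index = {i: k for k, i in enumerate(ids)}
    r = len(ids)
    weights = np.zeros((r, r))
    counts = np.zeros((r, r), dtype=int)
    for line in lines[2:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        a, b = index[_maybe_int(parts[0])], index[_maybe_int(parts[1])]
        w = float(parts[2])
        weights[a, b] = weights[b, a] = w
        if len(parts) > 3:
            counts[a, b] = counts[b, a] = int(parts[3])
    component = _maybe_int(meta.get("component", "None"))
    if component == "None":
        component = None
    if meta["kind"] == "group":
        return GroupGraph(
            presence_counts=counts,
            n_subjects=int(meta["n_subjects"]),
            presence_fraction_min=float(meta["presence_fraction_min"]),
            mean_weights=weights,
            region_ids=ids,
            flavor=meta["flavor"],
            component_id=component,
        )
    thr = meta.get("threshold_applied")
    return SubjectGraph(
        component_id=component,
        flavor=meta["flavor"],
        weights=weights,
        region_ids=ids,
        threshold_applied=float(thr) if thr is not None else None,
    )


def to_networkx(graph, weighted: bool = True, binarize: bool = False) -> nx.Graph:
    """Convert a SubjectGraph/GroupGraph to networkx over all region nodes."""
    g = nx.Graph()
    ids = list(graph.region_ids)
    g.add_nodes_from(ids)
    if isinstance(graph, GroupGraph):
        mask = np.triu(graph.retained_mask(), k=1)
        for i, j in zip(*np.nonzero(mask)):
            attrs = {"presence_count": int(graph.presence_counts[i, j])}
            if weighted and not binarize:
                attrs["weight"] = float(graph.mean_weights[i, j])
            g.add_edge(ids[i], ids[j], **attrs)
    else:
        mask = np.triu(graph.weights, k=1) > 0
        for i, j in zip(*np.nonzero(mask)):
            if weighted and not binarize:
                g.add_edge(ids[i], ids[j], weight=float(graph.weights[i, j]))
            else:
                g.add_edge(ids[i], ids[j])
    return g


# ---------------------------------------------------------------------------
# metrics

def write_metrics_json(records, path) -> None:
    payload = [r.to_dict() for r in records]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_metrics_json(path) -> list[dict]:
    return json.loads(Path(path).read_text())
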