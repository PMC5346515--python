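"""Edge weighting, thresholding, group aggregation and the classical network.

The weighting scheme turns the per-region t-values of one component into a
graph: for nodes a, b with t-values t_a, t_b,

    W(a,b)    = |t_a| + |t_b| - |t_a - t_b|      (correlation flavor)
    W_AC(a,b) = |t_a| + |t_b| - |t_a + t_b|      (anti-correlation flavor)

W equals 2*min(|t_a|, |t_b|) when the signs agree and 0 when they oppose;
W_AC is the complement, so W + W_AC == 2*min(|t_a|, |t_b|) for every pair.
An edge survives thresholding iff its weight reaches 2*t_threshold, which
is exactly the requirement that both node t-values be individually
significant (|t| >= t_threshold) under the flavor's sign condition.

Group graphs keep edges present in at least a fraction (default 25%) of
the subjects.  The classical network is built from the artifact-cleaned
voxel signal (the linear combination of the neuronal components weighted
by their spatial maps), region-averaged and correlated pairwise, with each
correlation converted to a t-statistic on the same degrees of freedom.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .types import (
    GroupGraph,
    ICDecomposition,
    ParcellationVolume,
    SubjectGraph,
    TValueTable,
)


def edge_weight(t_a: float, t_b: float) -> float:
    """Correlation-flavor weight: |t_a| + |t_b| - |t_a - t_b|.

    Equals 2*min(|t_a|, |t_b|) for same-sign t-values and 0 for opposite
    signs, so strong edges join regions that load strongly, and with
    similar strength and the same polarity, on the component.
    """
    if not (math.isfinite(t_a) and math.isfinite(t_b)):
        raise ValueError("edge_weight requires finite t-values")
    return abs(t_a) + abs(t_b) - abs(t_a - t_b)


def edge_weight_anticorr(t_a: float, t_b: float) -> float:
    """Anti-correlation-flavor weight: |t_a| + |t_b| - |t_a + t_b|.

    Nonzero only for opposite-sign t-values; complements
    :func:`edge_weight` so the two flavors' supports are disjoint.
    """
    if not (math.isfinite(t_a) and math.isfinite(t_b)):
        raise ValueError("edge_weight_anticorr requires finite t-values")
    return abs(t_a) + abs(t_b) - abs(t_a + t_b)


def _pairwise_weights(t: np.ndarray, flavor: str) -> np.ndarray:
    abs_t = np.abs(t)
    s = abs_t[:, None] + abs_t[None, :]
    if flavor == "correlation":
        w = s - np.abs(t[:, None] - t[None, :])
    elif flavor == "anticorrelation":
        w = s - np.abs(t[:, None] + t[None, :])
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    np.fill_diagonal(w, 0.0)
    # clip numerical dust at exactly-cancelling pairs
    return np.maximum(w, 0.0)


def build_subject_graph(
    tvalues: TValueTable,
    component_id,
    flavor: str,
    t_threshold: float,
) -> SubjectGraph:
    """Weight all region pairs from one component's t-values and threshold.

    Edges with weight below 2*t_threshold are discarded; ties at exactly
    the threshold are kept.  Regions flagged with infinite t-values (zero
    residual variance) are excluded with a warning.
    """
    t = tvalues.component_row(component_id).copy()
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} region(s) with non-finite t-values "
            f"from component {component_id!r} graph",
            stacklevel=2,
        )
        t[bad] = 0.0
    w = _pairwise_weights(t, flavor)
    cutoff = 2.0 * t_threshold
    w[w < cutoff] = 0.0
    if bad.any():
        w[bad, :] = 0.0
        w[:, bad] = 0.0
    return SubjectGraph(
        component_id=component_id,
        flavor=flavor,
        weights=w,
        region_ids=tvalues.region_ids,
        threshold_applied=cutoff,
    )


def aggregate_group(
    graphs: list[SubjectGraph], presence_fraction_min: float = 0.25
) -> GroupGraph:
    """Keep edges present in at least ``presence_fraction_min`` of subjects.

    Presence means a nonzero post-threshold weight.  Mean weights on the
    retained edges are averaged over the contributing subjects only; they
    are a convenience — group-level metrics are computed per subject.
    """
    if not graphs:
        raise ValueError("need at least one subject graph")
    first = graphs[0]
    for g in graphs[1:]:
        if not np.array_equal(np.asarray(g.region_ids), np.asarray(first.region_ids)):
            raise ValueError("subject graphs have mismatched node sets")
        if g.flavor != first.flavor:
            raise ValueError("subject graphs have mismatched flavors")
    n = len(graphs)
    stack = np.stack([g.weights for g in graphs])
    present = stack > 0
    counts = present.sum(axis=0)
    retained = counts / n >= presence_fraction_min - 1e-12
    np.fill_diagonal(retained, False)
    with np.errstate(invalid="ignore"):
        mean_w = np.where(
            retained & (counts > 0),
            stack.sum(axis=0) / np.maximum(counts, 1),
            0.0,
        )
    return GroupGraph(
        presence_counts=counts,
        n_subjects=n,
        presence_fraction_min=presence_fraction_min,
        mean_weights=mean_w,
        region_ids=first.region_ids,
        flavor=first.flavor,
        component_id=first.component_id,
    )


def correlation_to_t(r: np.ndarray, dof: int) -> np.ndarray:
    """Map Pearson correlations to t-statistics on ``dof`` degrees of freedom."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    t[np.isclose(np.abs(r), 1.0)] = np.sign(r[np.isclose(np.abs(r), 1.0)]) * np.inf
    return t


def reconstruct_clean_signal(
    decomposition: ICDecomposition, neuronal_ids
) -> np.ndarray:
    """Voxelwise artifact-cleaned signal: sum of neuronal map_i * course_i."""
    if decomposition.spatial_maps is None:
        raise ValueError(
            "classical-network construction requires component spatial maps"
        )
    if not neuronal_ids:
        raise ValueError("need at least one neuronal component")
    idx = [decomposition.index_of(c) for c in neuronal_ids]
    maps = decomposition.spatial_maps[..., idx]  # x,y,z,K
    courses = decomposition.timecourses[idx]  # K × P
    flat = maps.reshape(-1, len(idx))
    return (flat @ courses).reshape(maps.shape[:3] + (courses.shape[1],))


def build_classical_network(
    decomposition: ICDecomposition,
    neuronal_ids,
    parcellation: ParcellationVolume,
    t_threshold: float,
    tr_seconds: float | None = None,
) -> SubjectGraph:
    """Whole-brain graph from the cleaned signal's regional correlations.

    The cleaned voxel signal is averaged per region, regional courses are
    correlated pairwise, each r is converted to a t-statistic with
    DOF = n_timepoints - n_neuronal - 1, and an edge is kept iff t reaches
    t_threshold, with weight 2*t so that it lives on the same scale as the
    component-graph weights.  Perfectly correlated pairs carry an infinite
    t and are retained with infinite weight (flagged by the caller's I/O).
    """
    from .regression import extract_region_timecourses

    clean = reconstruct_clean_signal(decomposition, neuronal_ids)
    series = extract_region_timecourses(
        clean, parcellation, tr_seconds or decomposition.tr_seconds
    )
    dof = decomposition.n_timepoints - len(list(neuronal_ids)) - 1
    values = series.values
    sd = values.std(axis=1)
    keep = sd > 0
    r = np.zeros((values.shape[0], values.shape[0]))
    if keep.sum() >= 2:
        r[np.ix_(keep, keep)] = np.corrcoef(values[keep])
    t = correlation_to_t(r, dof)
    w = np.where(t >= t_threshold, 2.0 * t, 0.0)
    np.fill_diagonal(w, 0.0)
    w = np.maximum(w, 0.0)
    return SubjectGraph(
        component_id=None,
        flavor="classical",
        weights=w,
        region_ids=series.region_ids,
        threshold_applied=2.0 * t_threshold,
    )
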