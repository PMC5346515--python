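"""Shared domain types for the independent-component graph pipeline.

All containers are thin dataclasses around numpy arrays with eager invariant
checks, so that every downstream stage can assume well-formed inputs.  Row
ordering of regions is fixed at construction and identical across all types
within one pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

VALID_FLAVORS = ("correlation", "anticorrelation", "classical")


def _as_2d(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={a.ndim}")
    return a


@dataclass
class ICDecomposition:
    """An ICA decomposition: component time-courses and optional spatial maps.

    Parameters
    ----------
    timecourses : array, shape (n_components, n_timepoints)
        One row per independent component.
    tr_seconds : float
        Repetition time of the underlying acquisition, in seconds.
    component_ids : sequence
        Ordered identifiers aligned to the rows of ``timecourses``.
    spatial_maps : array, shape (x, y, z, n_components), optional
        Per-component spatial maps in percent-signal-change units, one
        volume per component.
    affine : array, shape (4, 4), optional
        Voxel-to-world affine of the spatial maps.
    """

    timecourses: np.ndarray
    tr_seconds: float
    component_ids: Sequence = None
    spatial_maps: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.timecourses = _as_2d(self.timecourses, "timecourses")
        n, p = self.timecourses.shape
        if n < 1:
            raise ValueError("need at least one component")
        if p <= n + 1:
            raise ValueError(
                f"n_timepoints={p} must exceed n_components+1={n + 1} "
                "(degrees of freedom would be <= 0)"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.component_ids is None:
            self.component_ids = list(range(1, n + 1))
        self.component_ids = list(self.component_ids)
        if len(self.component_ids) != n:
            raise ValueError("component_ids length must match timecourse rows")
        if self.spatial_maps is not None:
            self.spatial_maps = np.asarray(self.spatial_maps, dtype=float)
            if self.spatial_maps.ndim != 4:
                raise ValueError("spatial_maps must be 4-D (x, y, z, component)")
            if self.spatial_maps.shape[3] != n:
                raise ValueError(
                    f"spatial_maps has {self.spatial_maps.shape[3]} volumes, "
                    f"expected {n}"
                )

    @property
    def n_components(self) -> int:
        return self.timecourses.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.timecourses.shape[1]

    def index_of(self, component_id) -> int:
        try:
            return self.component_ids.index(component_id)
        except ValueError:
            raise KeyError(f"unknown component id {component_id!r}") from None


@dataclass
class ParcellationVolume:
    """Integer label volume; 0 is background, positive labels are regions."""

    labels: np.ndarray
    affine: np.ndarray | None = None
    region_names: Mapping[int, str] | None = None
    region_ids: np.ndarray = field(init=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded, atol=1e-6):
                raise ValueError("label volume is not integer-valued")
            self.labels = rounded.astype(np.int64)
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if ids.size == 0:
            raise ValueError("empty parcellation: no nonzero labels")
        if ids.size < 2:
            raise ValueError("parcellation must contain at least 2 regions")
        self.region_ids = ids

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)


@dataclass
class RegionTimeSeries:
    """Region-averaged BOLD signal, one row per parcellation region."""

    values: np.ndarray
    region_ids: Sequence
    tr_seconds: float

    def __post_init__(self):
        self.values = _as_2d(self.values, "values")
        self.region_ids = np.asarray(self.region_ids)
        if self.region_ids.shape[0] != self.values.shape[0]:
            raise ValueError("region_ids must align with value rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("region time series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class TValueTable:
    """Regression coefficients and t-values of regions on component courses.

    ``dof`` follows the volumes − components − 1 accounting: the design
    carries the component courses plus an intercept, and the intercept is
    the "−1".  Regions whose residual variance is exactly zero carry
    infinite t-values and are flagged in ``flagged_regions``.
    """

    betas: np.ndarray
    tvalues: np.ndarray
    residual_variance: np.ndarray
    dof: int
    n_volumes: int
    n_components: int
    component_ids: Sequence
    region_ids: Sequence
    flagged_regions: np.ndarray | None = None

    def __post_init__(self):
        self.betas = _as_2d(self.betas, "betas")
        self.tvalues = _as_2d(self.tvalues, "tvalues")
        if self.betas.shape != self.tvalues.shape:
            raise ValueError("betas and tvalues must share a shape")
        self.residual_variance = np.asarray(self.residual_variance, dtype=float)
        if self.dof != self.n_volumes - self.n_components - 1:
            raise ValueError("dof must equal n_volumes - n_components - 1")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        self.component_ids = list(self.component_ids)
        self.region_ids = np.asarray(self.region_ids)
        if self.flagged_regions is None:
            self.flagged_regions = self.residual_variance == 0.0
        self.flagged_regions = np.asarray(self.flagged_regions, dtype=bool)
        finite_ok = np.isfinite(self.tvalues) | self.flagged_regions[None, :]
        if not np.all(finite_ok):
            raise ValueError(
                "non-finite t-values outside zero-residual-variance regions"
            )

    def component_row(self, component_id) -> np.ndarray:
        try:
            i = self.component_ids.index(component_id)
        except ValueError:
            raise KeyError(f"unknown component id {component_id!r}") from None
        return self.tvalues[i]


def _check_symmetric_zero_diag(w: np.ndarray, name: str):
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(w, w.T, atol=1e-12, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diagonal(w) != 0):
        raise ValueError(f"{name} must have a zero diagonal")


@dataclass
class SubjectGraph:
    """One weighted graph over the parcellation regions for one component."""

    component_id: object
    flavor: str
    weights: np.ndarray
    region_ids: Sequence
    threshold_applied: float | None = None

    def __post_init__(self):
        if self.flavor not in VALID_FLAVORS:
            raise ValueError(f"flavor must be one of {VALID_FLAVORS}")
        self.weights = _as_2d(self.weights, "weights")
        _check_symmetric_zero_diag(self.weights, "weights")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        self.region_ids = np.asarray(self.region_ids)
        if self.region_ids.shape[0] != self.weights.shape[0]:
            raise ValueError("region_ids must align with the weight matrix")
        if self.threshold_applied is not None:
            nz = self.weights[self.weights > 0]
            if nz.size and np.min(nz) < self.threshold_applied - 1e-12:
                raise ValueError(
                    "nonzero weight below the declared applied threshold"
                )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edge_set(self) -> set:
        """Edges as frozen pairs of region ids (upper triangle)."""
        a, b = np.nonzero(np.triu(self.weights, k=1))
        ids = self.region_ids
        return {(ids[i], ids[j]) for i, j in zip(a.tolist(), b.tolist())}


@dataclass
class GroupGraph:
    """Subject-count aggregated graph (edges present in >= a fraction kept)."""

    presence_counts: np.ndarray
    n_subjects: int
    presence_fraction_min: float
    mean_weights: np.ndarray
    region_ids: Sequence
    flavor: str = "correlation"
    component_id: object = None

    def __post_init__(self):
        self.presence_counts = np.asarray(self.presence_counts)
        _check_symmetric_zero_diag(self.presence_counts, "presence_counts")
        self.mean_weights = _as_2d(self.mean_weights, "mean_weights")
        _check_symmetric_zero_diag(self.mean_weights, "mean_weights")
        if not (0 < self.presence_fraction_min <= 1):
            raise ValueError("presence_fraction_min must lie in (0, 1]")
        if np.any(self.presence_counts > self.n_subjects):
            raise ValueError("presence count exceeds the number of subjects")
        self.region_ids = np.asarray(self.region_ids)
        retained = self.retained_mask()
        if np.any(self.mean_weights[~retained] != 0):
            raise ValueError("mean weight set on a non-retained edge")

    def retained_mask(self) -> np.ndarray:
        frac = self.presence_counts / self.n_subjects
        mask = frac >= self.presence_fraction_min - 1e-12
        np.fill_diagonal(mask, False)
        return mask

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.retained_mask(), k=1)))

    def edge_set(self) -> set:
        a, b = np.nonzero(np.triu(self.retained_mask(), k=1))
        ids = self.region_ids
        return {(ids[i], ids[j]) for i, j in zip(a.tolist(), b.tolist())}


@dataclass
class MetricsRecord:
    """Summary metrics of one network graph after isolated-node removal."""

    network_id: object
    n_connected_nodes: int
    n_edges: int
    avg_degree: float
    n_triangles: int
    triangles_normalized: float
    clustering: float
    path_length: float
    small_worldness: float
    disconnected_pair_fraction: float = 0.0

    def __post_init__(self):
        if self.n_connected_nodes > 0:
            expected = 2 * self.n_edges / self.n_connected_nodes
            if not np.isclose(self.avg_degree, expected):
                raise ValueError("avg_degree must equal 2E/n")

    def to_dict(self) -> dict:
        return {
            "network_id": self.network_id,
            "n_connected_nodes": self.n_connected_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "n_triangles": self.n_triangles,
            "triangles_normalized": self.triangles_normalized,
            "clustering": self.clustering,
            "path_length": self.path_length,
            "small_worldness": self.small_worldness,
            "disconnected_pair_fraction": self.disconnected_pair_fraction,
        }
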