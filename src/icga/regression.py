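"""Regional time-course extraction and the GLM t-value transform.

Each parcellation region's BOLD course (the unweighted mean over its
voxels) is regressed on the component time-courses plus an intercept by
ordinary least squares.  Coefficients are converted to t-values with the
usual GLM contrast form

    t_i = c_i' beta / sqrt( sigma^2 * c_i' (A'A)^{-1} c_i )

where A is the design matrix, c_i the indicator contrast of component i,
and sigma^2 the residual variance on DOF = n_volumes - n_components - 1
degrees of freedom (the "-1" is the intercept column).  The Student-t
quantile at the chosen significance level then serves as the node-level
threshold from which the edge rule is derived.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .types import ICDecomposition, ParcellationVolume, RegionTimeSeries, TValueTable


def extract_region_timecourses(
    bold, parcellation: ParcellationVolume, tr_seconds: float | None = None
) -> RegionTimeSeries:
    """Average the BOLD signal over the voxels of each labeled region.

    ``bold`` may be a nibabel image or a plain 4-D array on the
    parcellation's voxel grid.  No resampling is performed; a grid mismatch
    is a hard error because alignment is an upstream responsibility and
    silent resampling would hide it.
    """
    if hasattr(bold, "dataobj"):
        data = np.asanyarray(bold.dataobj).astype(float)
        if tr_seconds is None:
            zooms = bold.header.get_zooms()
            tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    else:
        data = np.asarray(bold, dtype=float)
    if tr_seconds is None:
        raise ValueError("tr_seconds must be given when absent from the header")
    if data.ndim != 4:
        raise ValueError("BOLD data must be 4-D")
    if data.shape[:3] != parcellation.labels.shape:
        raise ValueError(
            f"grid mismatch: BOLD {data.shape[:3]} vs "
            f"parcellation {parcellation.labels.shape}"
        )
    flat = data.reshape(-1, data.shape[3])
    lab = parcellation.labels.reshape(-1)
    rows = np.empty((parcellation.n_regions, data.shape[3]))
    for i, rid in enumerate(parcellation.region_ids):
        voxels = flat[lab == rid]
        if voxels.shape[0] == 0:
            raise ValueError(f"region {rid} has no voxels")
        rows[i] = voxels.mean(axis=0)
    return RegionTimeSeries(
        values=rows, region_ids=parcellation.region_ids, tr_seconds=tr_seconds
    )


def _design_matrix(x: ICDecomposition, include_intercept: bool) -> np.ndarray:
    a = x.timecourses.T  # P × N
    if include_intercept:
        a = np.column_stack([a, np.ones(a.shape[0])])
    return a


def fit_glm(
    y: RegionTimeSeries,
    x: ICDecomposition,
    include_intercept: bool = True,
    drop_constant_regions: bool = True,
) -> TValueTable:
    """OLS fit of every region course on the component courses.

    Returns the beta and t-value matrices (components × regions).  Regions
    with an exactly-zero residual variance get infinite t-values and are
    flagged; constant regions are dropped with a warning.  A rank-deficient
    design (collinear components) raises, naming the offending components.
    """
    if y.n_timepoints != x.n_timepoints:
        raise ValueError(
            f"time-point mismatch: Y has {y.n_timepoints}, X has {x.n_timepoints}"
        )
    n, p = x.n_components, x.n_timepoints
    if p <= n + 1:
        raise ValueError("need more time points than components + 1")

    values = y.values
    region_ids = np.asarray(y.region_ids)
    if drop_constant_regions:
        const = np.ptp(values, axis=1) == 0
        if const.any():
            dropped = region_ids[const].tolist()
            warnings.warn(
                f"dropping {const.sum()} constant region(s): {dropped}",
                stacklevel=2,
            )
            values = values[~const]
            region_ids = region_ids[~const]
            if values.shape[0] == 0:
                raise ValueError("all regions are constant")

    a = _design_matrix(x, include_intercept)
    gram = a.T @ a
    rank = np.linalg.matrix_rank(a)
    if rank < a.shape[1]:
        # name the components involved in the collinearity via tiny QR
        # diagonal entries of the component columns
        r_diag = np.abs(np.diag(np.linalg.qr(a, mode="r")))
        tol = np.finfo(float).eps * max(a.shape) * r_diag.max()
        bad = [
            x.component_ids[i] for i in range(n) if r_diag[i] <= tol
        ] or list(x.component_ids)
        raise ValueError(
            f"rank-deficient design: components {bad} are collinear"
        )
    gram_inv = np.linalg.inv(gram)

    beta_full = gram_inv @ a.T @ values.T  # (N[+1]) × R
    resid = values.T - a @ beta_full  # P × R
    dof = p - n - 1
    rss = np.einsum("ij,ij->j", resid, resid)
    # exact fits: residual variance is exactly 0 within numerical dust
    scale = np.einsum("ij,ij->j", values.T, values.T)
    zero_rv = rss <= np.maximum(scale, 1.0) * 1e-24
    rss = np.where(zero_rv, 0.0, rss)
    resid_var = rss / dof

    betas = beta_full[:n]
    se = np.sqrt(np.outer(np.diag(gram_inv)[:n], resid_var))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvalues = betas / se
    if zero_rv.any():
        warnings.warn(
            f"{int(zero_rv.sum())} region(s) fit exactly (zero residual "
            "variance); their t-values are flagged infinite and will be "
            "excluded from graphs",
            stacklevel=2,
        )
        tvalues[:, zero_rv] = np.sign(betas[:, zero_rv]) * np.inf

    return TValueTable(
        betas=betas,
        tvalues=tvalues,
        residual_variance=resid_var,
        dof=dof,
        n_volumes=p,
        n_components=n,
        component_ids=x.component_ids,
        region_ids=region_ids,
        flagged_regions=zero_rv,
    )


def compute_t_threshold(dof: int, p: float = 0.001) -> float:
    """Student-t quantile used as the node significance threshold.

    Returns the (1 - p) quantile of Student's t with ``dof`` degrees of
    freedom; during graph construction it is applied to |t|, and the edge
    rule keeps weights of at least twice this value.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    return float(stats.t.ppf(1.0 - p, dof))
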