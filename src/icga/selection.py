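"""Assignment of independent components to network templates, and filtering
of components to the "neuronal" subset.

Template matching scores each component spatial map against each binary
network template with a goodness-of-fit (mean z inside the template minus
mean z outside it) and then solves a maximum-weight one-to-one assignment
over all templates simultaneously, so that a component claimed by one
network is unavailable to the others.  Templates whose best attainable
goodness-of-fit is non-positive are reported absent.

Neuronality classification is pluggable: any callable scoring a component
time-course can stand in for a trained classifier.  The built-in default is
a spectral heuristic — a component is neuronal when more than half of its
time-course power lies in the canonical resting-state band (0.01–0.1 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import periodogram

from .types import ICDecomposition

ABSENT = "absent"


@dataclass
class TemplateSet:
    """Named binary masks on a common voxel grid."""

    masks: Mapping[str, np.ndarray]

    def __post_init__(self):
        masks = {}
        shape = None
        for name, m in self.masks.items():
            m = np.asarray(m).astype(bool)
            if m.ndim != 3:
                raise ValueError(f"template {name!r} must be a 3-D mask")
            if not m.any():
                raise ValueError(f"template {name!r} is empty")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError("templates do not share one voxel grid")
            masks[name] = m
        if not masks:
            raise ValueError("template set is empty")
        self.masks = masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)


@dataclass
class SelectionResult:
    """Outcome of template matching and neuronality filtering."""

    assignment: dict  # template name -> component id or ABSENT
    gof_matrix: np.ndarray  # components × templates
    component_ids: list
    template_names: list
    neuronal_ids: set = field(default_factory=set)

    def __post_init__(self):
        assigned = [c for c in self.assignment.values() if c != ABSENT]
        if len(assigned) != len(set(assigned)):
            raise ValueError("a component was assigned to two templates")


def goodness_of_fit(spatial_map: np.ndarray, mask: np.ndarray) -> float:
    """Mean of the map inside the mask minus the mean outside it.

    The standard template goodness-of-fit for z-scored component maps: a
    map that matches the template concentrates its weight inside the mask,
    driving the difference up; a spatially unrelated map scores near zero.
    """
    spatial_map = np.asarray(spatial_map, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if spatial_map.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: map {spatial_map.shape} vs mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("empty template mask")
    if mask.all():
        raise ValueError("template mask covers the whole volume")
    return float(spatial_map[mask].mean() - spatial_map[~mask].mean())


def gof_matrix(maps: np.ndarray, templates: TemplateSet) -> np.ndarray:
    """Goodness-of-fit of every component map against every template."""
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be 4-D (x, y, z, component)")
    names = templates.names
    out = np.empty((maps.shape[3], len(names)))
    for j, name in enumerate(names):
        mask = templates.masks[name]
        if mask.shape != maps.shape[:3]:
            raise ValueError(f"grid mismatch for template {name!r}")
        for i in range(maps.shape[3]):
            out[i, j] = goodness_of_fit(maps[..., i], mask)
    return out


def match_templates(
    maps: np.ndarray,
    templates: TemplateSet,
    component_ids=None,
) -> SelectionResult:
    """Assign components to templates by maximum-weight one-to-one matching.

    All networks are considered simultaneously: the assignment maximises the
    total goodness-of-fit over injective component→template matchings, with
    the option of leaving a template unmatched (gain 0).  Because unmatched
    templates cost nothing, a pairing with non-positive goodness-of-fit is
    never forced, and such templates come out ``"absent"``.
    """
    gof = gof_matrix(maps, templates)
    n, t = gof.shape
    if component_ids is None:
        component_ids = list(range(1, n + 1))
    component_ids = list(component_ids)

    # Pad with one zero-gain dummy row per template so every template can
    # decline all components; maximise by negating.
    padded = np.vstack([gof, np.zeros((t, t))])
    rows, cols = linear_sum_assignment(-padded)
    assignment = {name: ABSENT for name in templates.names}
    for r, c in zip(rows, cols):
        if r < n and padded[r, c] > 0:
            assignment[templates.names[c]] = component_ids[r]
    return SelectionResult(
        assignment=assignment,
        gof_matrix=gof,
        component_ids=component_ids,
        template_names=templates.names,
    )


def band_power_fraction(
    timecourse: np.ndarray, tr_seconds: float, band_hz=(0.01, 0.1)
) -> float:
    """Fraction of (non-DC) spectral power inside ``band_hz``."""
    freqs, power = periodogram(np.asarray(timecourse, float), fs=1.0 / tr_seconds)
    keep = freqs > 0
    freqs, power = freqs[keep], power[keep]
    total = power.sum()
    if total == 0:
        return 0.0
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return float(power[in_band].sum() / total)


def spectral_classifier(band_hz=(0.01, 0.1), cutoff: float = 0.5) -> Callable:
    """Build the default neuronality heuristic.

    Labels a component neuronal iff the fraction of its time-course power
    in ``band_hz`` exceeds ``cutoff``.  This is a documented stand-in for a
    trained spatiotemporal-fingerprint classifier, not a replication of one.
    """

    def classify(timecourse: np.ndarray, tr_seconds: float) -> bool:
        return band_power_fraction(timecourse, tr_seconds, band_hz) > cutoff

    return classify


def classify_neuronal(
    decomposition: ICDecomposition, classifier: Callable | None = None
) -> set:
    """Return the ids of components the classifier labels neuronal.

    ``classifier`` is any callable ``(timecourse, tr_seconds) -> bool``;
    when omitted the spectral heuristic with default settings is used.
    """
    if classifier is None:
        classifier = spectral_classifier()
    out = set()
    for cid, row in zip(decomposition.component_ids, decomposition.timecourses):
        if classifier(row, decomposition.tr_seconds):
            out.add(cid)
    return out
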