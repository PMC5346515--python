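"""Group-level comparison of component networks against the classical one.

Per-subject metric distributions are compared across networks with a
one-way ANOVA followed by Tukey's HSD post-hoc pairwise test (statsmodels
implementation, valid for unbalanced group sizes — group sizes differ
because a network only contributes a subject's record when it was detected
for that subject).  Pairs are flagged at the .05 and .01 tiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .types import MetricsRecord, SubjectGraph

COMPARABLE_METRICS = (
    "n_edges",
    "avg_degree",
    "triangles_normalized",
    "small_worldness",
)


@dataclass
class ComparisonReport:
    metric: str
    anova_f: float
    anova_p: float
    pairs: pd.DataFrame  # columns: group_a, group_b, mean_diff, p_adj, tier

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple]:
        sel = self.pairs[self.pairs["p_adj"] <= alpha]
        return list(zip(sel["group_a"], sel["group_b"]))

    def to_frame(self) -> pd.DataFrame:
        out = self.pairs.copy()
        out.insert(0, "metric", self.metric)
        return out


def _metric_values(records, metric: str) -> np.ndarray:
    vals = []
    for r in records:
        v = r.to_dict()[metric] if isinstance(r, MetricsRecord) else r[metric]
        vals.append(float(v))
    return np.asarray(vals)


def compare_networks(groups: dict, metric: str) -> ComparisonReport:
    """ANOVA + Tukey HSD across named groups of per-subject metric records.

    ``groups`` maps a network name to its list of MetricsRecord (or dict)
    entries, one per subject in which the network was detected.  NaN
    metric values are dropped per group.
    """
    if metric not in COMPARABLE_METRICS:
        raise ValueError(
            f"metric must be one of {COMPARABLE_METRICS}, got {metric!r}"
        )
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    clean = {}
    for name, records in groups.items():
        vals = _metric_values(records, metric)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError(
                f"group {name!r} has fewer than 2 usable records"
            )
        clean[name] = vals

    f_stat, p_val = f_oneway(*clean.values())

    values = np.concatenate(list(clean.values()))
    labels = np.concatenate(
        [np.full(v.size, name, dtype=object) for name, v in clean.items()]
    )
    if np.ptp(values) == 0:
        # all observations identical: Tukey is degenerate, no pair differs
        names = list(clean)
        rows = [
            (names[i], names[j], 0.0, 1.0, "")
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        pairs = pd.DataFrame(
            rows, columns=["group_a", "group_b", "mean_diff", "p_adj", "tier"]
        )
        return ComparisonReport(metric, float(f_stat), float(p_val), pairs)

    tukey = pairwise_tukeyhsd(values, labels, alpha=0.05)
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    pairs = pd.DataFrame(
        {
            "group_a": frame["group1"],
            "group_b": frame["group2"],
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": frame["p-adj"].astype(float),
        }
    )
    pairs["tier"] = np.select(
        [pairs["p_adj"] <= 0.01, pairs["p_adj"] <= 0.05],
        ["p<=.01", "p<=.05"],
        default="",
    )
    return ComparisonReport(metric, float(f_stat), float(p_val), pairs)


def mask_classical_to_network(
    classical: SubjectGraph, network_nodes
) -> SubjectGraph:
    """Induced subgraph of the classical network on a component's node set.

    Restricting both graphs to the same constellation removes the strong
    effect of node count on topology before metrics are compared.
    """
    network_nodes = list(network_nodes)
    if not network_nodes:
        raise ValueError("empty node set")
    ids = list(classical.region_ids)
    index = {rid: k for k, rid in enumerate(ids)}
    missing = [n for n in network_nodes if n not in index]
    if missing:
        raise ValueError(f"nodes not in classical graph: {missing}")
    sel = np.array([index[n] for n in network_nodes])
    return SubjectGraph(
        component_id=classical.component_id,
        flavor=classical.flavor,
        weights=classical.weights[np.ix_(sel, sel)],
        region_ids=[ids[k] for k in sel],
        threshold_applied=classical.threshold_applied,
    )
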