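"""Edge weighting, thresholding, group aggregation, classical network."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icga.graphs import (
    aggregate_group,
    build_classical_network,
    build_subject_graph,
    edge_weight,
    edge_weight_anticorr,
)
from icga.simulate import (
    SyntheticConfig,
    ground_truth_edges,
    signed_block_mixing,
    simulate_subject,
)
from icga.regression import compute_t_threshold, fit_glm
from icga.types import ICDecomposition, ParcellationVolume, SubjectGraph, TValueTable

finite_t = st.floats(min_value=-50, max_value=50, allow_nan=False)


def _table(t_row, region_ids=None):
    t_row = np.asarray(t_row, dtype=float)
    return TValueTable(
        betas=t_row[None, :], tvalues=t_row[None, :],
        residual_variance=np.ones(t_row.size), dof=100, n_volumes=102,
        n_components=1, component_ids=[1],
        region_ids=region_ids or list(range(1, t_row.size + 1)),
    )


class TestEdgeWeights:
    def test_same_sign_pair(self):
        assert edge_weight(5, 3) == 6  # 2*min(5,3)

    def test_opposite_sign_pair_is_zero(self):
        assert edge_weight(5, -3) == 0

    def test_equal_t_gives_twice_abs(self, rng):
        for t in rng.standard_normal(100) * 10:
            assert edge_weight(t, t) == pytest.approx(2 * abs(t))

    def test_anticorr_opposite_sign(self):
        assert edge_weight_anticorr(5, -3) == 6

    def test_anticorr_same_sign_is_zero(self):
        assert edge_weight_anticorr(5, 3) == 0

    @given(finite_t, finite_t)
    def test_flavors_partition_twice_min(self, ta, tb):
        w = edge_weight(ta, tb)
        wac = edge_weight_anticorr(ta, tb)
        assert w >= 0 and wac >= 0
        assert w + wac == pytest.approx(2 * min(abs(ta), abs(tb)), abs=1e-9)
        if ta * tb > 0:
            assert wac == 0
        if ta * tb < 0:
            assert w == 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            edge_weight(np.nan, 1.0)
        with pytest.raises(ValueError):
            edge_weight_anticorr(np.inf, 1.0)


class TestBuildSubjectGraph:
    def test_correlation_enumeration(self):
        g = build_subject_graph(_table([4, 4, -4, 1]), 1, "correlation", 3.0)
        assert g.edge_set() == {(1, 2)}
        assert g.weights[0, 1] == 8.0

    def test_anticorrelation_enumeration(self):
        g = build_subject_graph(_table([4, 4, -4, 1]), 1, "anticorrelation", 3.0)
        assert g.edge_set() == {(1, 3), (2, 3)}
        assert g.weights[0, 2] == 8.0 and g.weights[1, 2] == 8.0

    def test_all_subthreshold_gives_empty_graph(self):
        g = build_subject_graph(_table([2, 2, -1, 0.5]), 1, "correlation", 3.0)
        assert g.n_edges == 0

    def test_unknown_component_rejected(self):
        with pytest.raises(KeyError):
            build_subject_graph(_table([1, 2, 3]), 99, "correlation", 3.0)

    def test_edge_rule_equals_both_significant(self, rng):
        # edge set must equal the brute-force rule: both |t| >= threshold
        # and the flavor's sign condition, pair by pair
        thr = 2.5
        for _ in range(20):
            t = rng.standard_normal(15) * 4
            for flavor, cond in [
                ("correlation", lambda a, b: a * b > 0),
                ("anticorrelation", lambda a, b: a * b < 0),
            ]:
                g = build_subject_graph(_table(t), 1, flavor, thr)
                expected = {
                    (i + 1, j + 1)
                    for i, j in itertools.combinations(range(15), 2)
                    if abs(t[i]) >= thr and abs(t[j]) >= thr and cond(t[i], t[j])
                }
                assert g.edge_set() == expected

    def test_raising_threshold_only_removes_edges(self, rng):
        t = rng.standard_normal(20) * 4
        prev = build_subject_graph(_table(t), 1, "correlation", 1.0).edge_set()
        for thr in (1.5, 2.0, 3.0, 4.5):
            cur = build_subject_graph(_table(t), 1, "correlation", thr).edge_set()
            assert cur <= prev
            prev = cur

    def test_flagged_regions_excluded(self, rng):
        t = np.array([np.inf, 5.0, 5.0])
        table = TValueTable(
            betas=t[None, :], tvalues=t[None, :],
            residual_variance=np.array([0.0, 1.0, 1.0]), dof=100,
            n_volumes=102, n_components=1, component_ids=[1],
            region_ids=[1, 2, 3],
        )
        with pytest.warns(UserWarning, match="non-finite"):
            g = build_subject_graph(table, 1, "correlation", 3.0)
        assert g.edge_set() == {(2, 3)}


class TestAggregateGroup:
    def _graphs(self, presence, n_regions=4, weight=8.0):
        """presence: list of per-subject edge lists."""
        out = []
        for edges in presence:
            w = np.zeros((n_regions, n_regions))
            for a, b in edges:
                w[a, b] = w[b, a] = weight
            out.append(
                SubjectGraph(component_id=1, flavor="correlation", weights=w,
                             region_ids=list(range(1, n_regions + 1)),
                             threshold_applied=weight)
            )
        return out

    def test_quarter_rule_keeps_4_of_15(self):
        graphs = self._graphs([[(0, 1)]] * 4 + [[]] * 11)
        gg = aggregate_group(graphs, 0.25)
        assert gg.edge_set() == {(1, 2)}  # 4/15 ≈ .267 >= .25

    def test_quarter_rule_drops_3_of_15(self):
        graphs = self._graphs([[(0, 1)]] * 3 + [[]] * 12)
        gg = aggregate_group(graphs, 0.25)
        assert gg.edge_set() == set()  # 3/15 = .20 < .25

    def test_identical_graphs_idempotent(self):
        graphs = self._graphs([[(0, 1), (2, 3)]] * 5)
        gg = aggregate_group(graphs, 0.25)
        assert gg.edge_set() == graphs[0].edge_set()
        assert np.allclose(gg.mean_weights, graphs[0].weights)

    def test_union_and_intersection_limits(self):
        per_subject = [[(0, 1)], [(0, 1), (1, 2)], [(2, 3)], [(0, 1)], [(1, 2)]]
        graphs = self._graphs(per_subject)
        union = set().union(*(g.edge_set() for g in graphs))
        inter = set.intersection(*(g.edge_set() for g in graphs))
        assert aggregate_group(graphs, 1 / 5).edge_set() == union
        assert aggregate_group(graphs, 1.0).edge_set() == inter

    def test_mismatched_nodes_rejected(self):
        g1 = self._graphs([[(0, 1)]])[0]
        g2 = self._graphs([[(0, 1)]], n_regions=5)[0]
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_group([g1, g2], 0.25)


class TestClassicalNetwork:
    def _volume_subject(self, seed=3):
        cfg = SyntheticConfig(
            n_regions=20, n_components=2, n_timepoints=100,
            mixing=signed_block_mixing(2, 20), volume_shape=(6, 6, 4),
            seed=seed,
        )
        return simulate_subject(cfg, 0), cfg

    def test_constant_map_two_regions_perfectly_correlated(self):
        # one component, identical loading on both regions: the cleaned
        # courses are proportional, r = 1, t flagged infinite, edge kept
        p = 60
        course = np.sin(2 * np.pi * np.arange(p) / 25)[None, :]
        maps = np.ones((2, 2, 1, 1))
        decomp = ICDecomposition(timecourses=course, tr_seconds=2.0,
                                 spatial_maps=maps)
        labels = np.array([[[1], [1]], [[2], [2]]])
        parc = ParcellationVolume(labels=labels)
        g = build_classical_network(decomp, [1], parc, t_threshold=3.0)
        assert g.edge_set() == {(1, 2)}
        assert np.isinf(g.weights[0, 1])

    def test_orthogonal_loadings_give_no_edge(self):
        p = 120
        x = np.vstack([
            np.sin(2 * np.pi * np.arange(p) / 30),
            np.cos(2 * np.pi * np.arange(p) / 30),
        ])
        maps = np.zeros((2, 1, 1, 2))
        maps[0, 0, 0, 0] = 1.0  # region 1 loads only component 1
        maps[1, 0, 0, 1] = 1.0  # region 2 loads only component 2
        decomp = ICDecomposition(timecourses=x, tr_seconds=2.0, spatial_maps=maps)
        labels = np.array([[[1]], [[2]]])
        g = build_classical_network(
            decomp, [1, 2], ParcellationVolume(labels=labels), t_threshold=3.0
        )
        assert g.n_edges == 0

    def test_correlations_match_pairwise_oracle(self):
        subject, cfg = self._volume_subject()
        decomp = subject["decomposition"]
        parc = subject["parcellation"]
        thr = compute_t_threshold(cfg.n_timepoints - cfg.n_components - 1, 0.001)
        g = build_classical_network(decomp, [1, 2], parc, thr)
        # oracle: region-average the cleaned signal by explicit loops,
        # then np.corrcoef pair by pair
        from icga.graphs import reconstruct_clean_signal

        clean = reconstruct_clean_signal(decomp, [1, 2])
        r_regions = parc.n_regions
        courses = np.array([
            clean[parc.labels == rid].mean(axis=0) for rid in parc.region_ids
        ])
        dof = cfg.n_timepoints - 2 - 1
        for i in range(r_regions):
            for j in range(i + 1, r_regions):
                r = np.corrcoef(courses[i], courses[j])[0, 1]
                if np.isclose(abs(r), 1.0):
                    t = np.sign(r) * np.inf
                else:
                    t = r * np.sqrt(dof / (1 - r**2))
                expected = 2 * t if t >= thr else 0.0
                if np.isinf(expected):
                    assert np.isinf(g.weights[i, j])
                else:
                    assert g.weights[i, j] == pytest.approx(expected, abs=1e-10)

    def test_missing_maps_rejected(self):
        decomp = ICDecomposition(
            timecourses=np.random.default_rng(0).standard_normal((2, 50)),
            tr_seconds=2.0,
        )
        parc = ParcellationVolume(labels=np.array([[[1]], [[2]]]))
        with pytest.raises(ValueError, match="spatial maps"):
            build_classical_network(decomp, [1, 2], parc, 3.0)


class TestPlantedRecovery:
    def test_blocks_recovered(self):
        """Same-sign block loading: each component's correlation graph is the
        clique on its block.

        At high SNR no planted edge is ever missed in any subject.  Null
        regions cross the p=.001 node threshold at the nominal false-positive
        rate, so single-subject graphs carry a stray edge now and then (mean
        Jaccard stays near 1); the group presence rule removes them exactly.
        """
        mixing = np.zeros((3, 60))
        for i in range(3):
            mixing[i, i * 20 : (i + 1) * 20] = 1.0
        jaccards = []
        group_inputs = {c: [] for c in range(3)}
        for seed in range(10):
            cfg = SyntheticConfig(mixing=mixing, snr=10, seed=seed)
            s = simulate_subject(cfg, 0)
            table = fit_glm(s["series"], s["decomposition"])
            thr = compute_t_threshold(table.dof, 0.001)
            for comp in range(3):
                g = build_subject_graph(table, comp + 1, "correlation", thr)
                truth = ground_truth_edges(mixing, comp, "correlation")
                pred = g.weights > 0
                assert not np.any(truth & ~pred), "a planted edge was missed"
                inter = np.count_nonzero(pred & truth)
                union = np.count_nonzero(pred | truth)
                jaccards.append(inter / union)
                group_inputs[comp].append(g)
        assert np.mean(jaccards) > 0.99
        # the 25% presence rule removes every stray single-subject edge
        for comp in range(3):
            gg = aggregate_group(group_inputs[comp], 0.25)
            truth = ground_truth_edges(mixing, comp, "correlation")
            assert np.array_equal(gg.retained_mask(), truth)
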