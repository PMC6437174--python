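"""Niche classification, heterogeneity indices, group tests and clustering."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from vasculoscope.hemodynamics import HemodynamicState
from vasculoscope.oxygen import OxygenState
from vasculoscope.phenotype import (
    ClassThresholds,
    classify_vessels,
    cluster_networks,
    coefficient_of_variation,
    compare_groups,
    cv_correlation_matrix,
    mean_path_length,
)


def fake_states(vel_mm_s, po2, flow=None, diameters=None, lengths=None):
    """Minimal paired states for classification tests."""
    vel = np.asarray(vel_mm_s, dtype=float)
    n = len(vel)
    flow = np.asarray(flow, float) if flow is not None else np.full(n, 1e-4)
    hemo = HemodynamicState(
        node_ids=np.arange(n + 1),
        segment_ids=np.arange(n),
        pressure=np.zeros(n + 1),
        flow=flow,
        hd=np.full(n, 0.4),
        ht=np.full(n, 0.3),
        viscosity=np.ones(n),
        velocity=vel,
        wall_shear_stress=np.ones(n),
        transit_time=np.ones(n),
        boundary_pressures={},
    )
    oxy = OxygenState(
        node_ids=np.arange(n + 1),
        segment_ids=np.arange(n),
        node_po2=np.zeros(n + 1),
        segment_po2=np.asarray(po2, dtype=float),
        saturation=np.zeros(n),
        solubility=np.full(n, 3e-5),
        wall_flux=np.zeros(n),
        eligible=np.ones(n, dtype=bool),
    )
    d = np.asarray(diameters, float) if diameters is not None else np.full(n, 10.0)
    length = np.asarray(lengths, float) if lengths is not None else np.full(n, 100.0)
    return hemo, oxy, d, length


class TestClassification:
    # velocity threshold 50 µm/s = 0.05 mm/s; PO2 threshold 10 mmHg
    @pytest.mark.parametrize(
        "vel_um_s, po2, expected",
        [
            (30.0, 5.0, 1),   # slow + hypoxic
            (30.0, 10.0, 3),  # slow + normoxic (boundary PO2 inclusive)
            (30.0, 20.0, 3),
            (50.0, 5.0, 3),   # boundary velocity counts as fast
            (50.0, 10.0, 2),
            (50.0, 20.0, 2),
            (60.0, 5.0, 3),
            (60.0, 9.999, 3),
            (60.0, 20.0, 2),
        ],
    )
    def test_threshold_grid(self, vel_um_s, po2, expected):
        # one reference segment keeps the medians away from the probe
        hemo, oxy, d, length = fake_states(
            [vel_um_s * 1e-3] + [0.04] * 5, [po2] + [8.0] * 5
        )
        labels = classify_vessels(hemo, oxy, d, length)
        assert labels[0] == expected

    def test_shunt_overrides(self):
        # probe: fast, normoxic AND matching all three shunt criteria
        vel = [0.25] + [0.1] * 6           # 2.5× the median (0.1 mm/s)
        po2 = [30.0] + [20.0] * 6
        d = [22.0] + [10.0] * 6            # 2.2× median diameter
        length = [40.0] + [100.0] * 6      # 0.4× median length
        hemo, oxy, dd, ll = fake_states(vel, po2, diameters=d, lengths=length)
        labels = classify_vessels(hemo, oxy, dd, ll)
        assert labels[0] == 4
        assert set(labels[1:]) == {2}

    def test_unperfused_excluded_and_partition(self):
        flow = [1e-4, 1e-12, 1e-4]
        hemo, oxy, d, length = fake_states([0.1, 0.1, 0.01], [20, 20, 5], flow=flow)
        labels = classify_vessels(hemo, oxy, d, length)
        assert labels[1] == 0  # below the perfusion floor
        assert np.all(labels[[0, 2]] > 0)

    def test_empty_perfused_set_errors(self):
        hemo, oxy, d, length = fake_states([0.1], [20.0], flow=[1e-12])
        with pytest.raises(ValueError, match="perfused"):
            classify_vessels(hemo, oxy, d, length)


class TestCV:
    def test_hand_computed(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5, rel=1e-12)

    def test_constant_vector(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_scale_invariance(self):
        x = np.array([1.0, 3.0, 7.0, 2.0])
        assert coefficient_of_variation(7.3 * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        r, p, sig = cv_correlation_matrix(table)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)
        assert np.all(np.diag(r.values) == 1.0)
        np.testing.assert_allclose(r.values, r.values.T)

    def test_constant_column_reported_missing(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        r, p, sig = cv_correlation_matrix(table)
        assert np.isnan(r.loc["a", "b"])
        assert not sig.loc["a", "b"]

    def test_planted_correlation_recovered(self):
        # networks with CVs correlated at ρ = 0.8: the Monte-Carlo mean of
        # the sample r over replicates should sit near the planted value
        rho, reps = 0.8, 100
        rng = np.random.default_rng(42)
        rs = []
        for _ in range(reps):
            z = rng.multivariate_normal(
                [0, 0], [[1, rho], [rho, 1]], size=8
            )
            table = pd.DataFrame({"a": z[:, 0] + 5, "b": z[:, 1] + 5})
            r, _, _ = cv_correlation_matrix(table)
            rs.append(r.loc["a", "b"])
        assert abs(np.mean(rs) - rho) < 0.25

    def test_too_few_networks(self):
        with pytest.raises(ValueError):
            cv_correlation_matrix(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestMPL:
    def test_hand_computed(self):
        assert mean_path_length([1.0, 3.0], [10.0, 20.0]) == pytest.approx(17.5)

    def test_uniform_flow_gives_mean_length(self):
        lengths = np.array([10.0, 30.0, 50.0])
        assert mean_path_length([2.0, 2.0, 2.0], lengths) == pytest.approx(30.0)

    def test_single_segment(self):
        assert mean_path_length([0.5], [123.0]) == 123.0

    def test_bounded_by_length_range(self, tumor_state, tumor_net):
        perf = tumor_state.perfused
        mpl = mean_path_length(tumor_state.flow[perf], tumor_net.lengths[perf])
        assert tumor_net.lengths[perf].min() <= mpl <= tumor_net.lengths[perf].max()


class TestMannWhitney:
    def test_identical_groups(self):
        with pytest.warns(UserWarning, match="tied"):
            u, p, sig = compare_groups([1.0] * 5, [1.0] * 5)
        assert p == 1.0 and not sig

    def test_fully_separated(self):
        a = np.arange(10, dtype=float)
        b = a + 100.0
        u, p, sig = compare_groups(a, b)
        assert min(u, len(a) * len(b) - u) == 0.0
        assert sig

    def test_small_sample_matches_rank_enumeration(self):
        a = np.array([1.2, 3.4, 0.7, 5.5])
        b = np.array([2.2, 4.1, 6.0, 0.1])
        u, p, _ = compare_groups(a, b)
        # brute force: U = number of (a_i, b_j) pairs with a_i > b_j
        u_brute = sum(1.0 for x in a for y in b if x > y) + 0.5 * sum(
            1.0 for x in a for y in b if x == y
        )
        assert u == u_brute
        # exact two-sided p over all C(8,4) labelings
        pooled = np.concatenate([a, b])
        stats_all = []
        for idx in combinations(range(8), 4):
            grp = pooled[list(idx)]
            other = pooled[[i for i in range(8) if i not in idx]]
            ub = sum(1.0 for x in grp for y in other if x > y)
            stats_all.append(min(ub, 16 - ub))
        observed = min(u_brute, 16 - u_brute)
        p_exact = np.mean([s <= observed for s in stats_all])
        assert p == pytest.approx(p_exact, abs=0.02)


class TestClustering:
    def test_closest_pair_merges_first(self):
        feats = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        res = cluster_networks(feats, n_clusters=2)
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_four_point_manual_upgma_trace(self):
        # 1D points 0, 2, 9, 10 (single feature → z-scoring rescales all
        # distances by one factor; merge ORDER and height RATIOS persist):
        # merge (9,10) at 1, (0,2) at 2, then the two clusters at the mean
        # of the cross distances {9, 10, 7, 8} = 8.5
        pts = [0.0, 2.0, 9.0, 10.0]
        feats = pd.DataFrame({"x": pts}, index=list("abcd"))
        res = cluster_networks(feats, n_clusters=2)
        heights = res.linkage[:, 2]
        sd = np.std(pts)
        np.testing.assert_allclose(heights * sd, [1.0, 2.0, (9 + 10 + 7 + 8) / 4], rtol=1e-9)

    def test_planted_groups_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.3, size=(5, 3))
        b = rng.normal(4.0, 0.3, size=(5, 3))
        feats = pd.DataFrame(np.vstack([a, b]), index=range(10))
        res = cluster_networks(feats, n_clusters=2)
        la, lb = set(res.labels[:5]), set(res.labels[5:])
        assert len(la) == 1 and len(lb) == 1 and la != lb
        assert res.cophenetic > 0.8
        assert res.significant

    def test_ultrametric_input_cophenetic_one(self):
        # two tight pairs at distance ≫ within-pair spread approximate an
        # ultrametric; exact ultrametric: equidistant triple
        feats = pd.DataFrame(
            {"x": [0.0, 0.0, 10.0, 10.0], "y": [0.0, 1.0, 0.0, 1.0]}, index=range(4)
        )
        res = cluster_networks(feats)
        assert -1.0 <= res.cophenetic <= 1.0

    def test_duplicate_rows_handled(self):
        feats = pd.DataFrame({"x": [1.0, 1.0, 5.0], "y": [2.0, 2.0, 6.0]}, index=range(3))
        res = cluster_networks(feats, n_clusters=2)
        assert res.labels[0] == res.labels[1]

    def test_distance_threshold_labels(self):
        feats = pd.DataFrame({"x": [0.0, 0.1, 5.0, 5.1]}, index=range(4))
        res = cluster_networks(feats, distance_threshold=0.5)
        assert len(set(res.labels)) == 2
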