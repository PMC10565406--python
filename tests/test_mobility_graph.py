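import numpy as np
import pandas as pd
import pytest

import flowscales as fs
from flowscales.exceptions import (
    InvalidParameterError,
    MalformedRecordsError,
    UndefinedStatisticError,
)


def frame(rows):
    return pd.DataFrame(rows, columns=["date", "origin", "destination", "trips"])


class TestBuildBaselineGraph:
    def test_cycle_retained(self):
        df = frame(
            [
                ("2020-01-01", "1", "2", 1.0),
                ("2020-01-01", "2", "3", 1.0),
                ("2020-01-01", "3", "1", 1.0),
            ]
        )
        g = fs.build_baseline_graph(df)
        assert g.n_nodes == 3
        assert (g.A > 0).sum() == 3
        assert g.n_dropped == 0

    def test_one_way_pendant_dropped(self):
        df = frame(
            [
                ("2020-01-01", "1", "2", 1.0),
                ("2020-01-01", "2", "3", 1.0),
                ("2020-01-01", "3", "1", 1.0),
                ("2020-01-01", "3", "4", 5.0),
            ]
        )
        g = fs.build_baseline_graph(df)
        assert set(g.nodes) == {"1", "2", "3"}
        assert g.n_dropped == 1

    def test_window_averaging_matches_reference_loop(self):
        """Averaged weights equal a direct per-day mean (absent day = 0)."""
        rows = [
            ("2020-01-01", "a", "b", 4.0),
            ("2020-01-02", "a", "b", 2.0),
            ("2020-01-01", "b", "a", 6.0),
            # b->a missing on day 2: contributes 0 to the mean
            ("2020-01-01", "a", "a", 10.0),
            ("2020-01-02", "a", "a", 20.0),
        ]
        g = fs.build_baseline_graph(frame(rows), ("2020-01-01", "2020-01-02"))
        # independent reference: accumulate by hand over the 2-day window
        expected = {}
        for d, o, dd, t in rows:
            expected[(o, dd)] = expected.get((o, dd), 0.0) + t / 2.0
        i, j = g.nodes.index("a"), g.nodes.index("b")
        assert g.A[i, j] == pytest.approx(expected[("a", "b")], abs=1e-12)
        assert g.A[j, i] == pytest.approx(expected[("b", "a")], abs=1e-12)
        assert g.intra[i] == pytest.approx(expected[("a", "a")], abs=1e-12)

    def test_empty_lscc_raises(self):
        df = frame([("2020-01-01", "1", "2", 1.0)])  # no return path
        with pytest.raises(InvalidParameterError):
            fs.build_baseline_graph(df)

    def test_synthetic_baseline_strongly_connected(self):
        plan = fs.HierarchyPlan(levels=(2, 2), leaf_size=3, sparsity=0.3)
        tab = fs.generate_hierarchical_flows(plan, 5)
        g = fs.build_baseline_graph(tab)
        assert g.n_nodes == plan.n_tiles
        assert g.is_strongly_connected()


class TestReadFlowCsv:
    def test_malformed_rows_reported_with_lines(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "date,origin,destination,trips\n"
            "2020-01-01,a,b,3\n"
            "2020-01-01,a,c,oops\n"
            "2020-01-01,c,a,-1\n"
        )
        with pytest.raises(MalformedRecordsError) as exc:
            fs.read_flow_csv(p)
        assert exc.value.lines == [3, 4]

    def test_roundtrip_via_writer(self, tmp_path):
        plan = fs.HierarchyPlan(levels=(2,), leaf_size=2)
        tab = fs.generate_hierarchical_flows(plan, 0)
        path = tmp_path / "flows.csv"
        from flowscales.synthetic_data import write_flow_csv

        write_flow_csv(tab, path)
        back = fs.read_flow_csv(path)
        assert np.allclose(np.sort(back["trips"]), np.sort(tab["trips"]))


class TestStationaryDistribution:
    def test_symmetric_closed_form(self, small_random_graph):
        g = small_random_graph
        A = g.A + g.A.T  # symmetrize
        gsym = fs.FlowGraph(nodes=g.nodes, A=A, intra=np.zeros(g.n_nodes))
        pi = fs.stationary_distribution(gsym)
        d = gsym.d_out
        assert np.allclose(pi, d / d.sum(), atol=1e-12)

    def test_two_node_forced_symmetric(self):
        g = fs.FlowGraph(
            nodes=["x", "y"], A=np.array([[0.0, 2.0], [1.0, 0.0]]), intra=np.zeros(2)
        )
        pi = fs.stationary_distribution(g)
        assert np.allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        from conftest import random_strongly_connected

        for _ in range(5):
            g = random_strongly_connected(rng, n=5)
            pi = fs.stationary_distribution(g)
            M = g.A / g.d_out[:, None]
            w, v = np.linalg.eig(M.T)
            k = np.argmin(np.abs(w - 1.0))
            ref = np.real(v[:, k])
            ref = ref / ref.sum()
            assert np.max(np.abs(pi - ref)) < 1e-10

    def test_model_invariants(self, small_random_graph):
        m = fs.RandomWalkModel.from_graph(small_random_graph)
        assert np.allclose(m.M.sum(axis=1), 1.0, atol=1e-12)
        assert np.max(np.abs(m.pi @ m.M - m.pi)) < 1e-10
        assert np.max(np.abs(m.pi @ m.L)) < 1e-10
        assert m.pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestPairwiseRelativeAsymmetry:
    def test_boundary_values(self):
        A = np.array(
            [
                [0, 2, 3, 0],
                [2, 0, 0, 1],
                [1, 0, 0, 1],
                [0, 0, 1, 0],
            ],
            dtype=float,
        )
        g = fs.FlowGraph(nodes=list("abcd"), A=A, intra=np.zeros(4))
        res = fs.pairwise_relative_asymmetry(g)
        pairs = res["pairs"]
        assert pairs[("a", "b")] == 0.0  # symmetric pair
        assert pairs[("a", "c")] == pytest.approx(0.5)  # |3-1|/4
        assert pairs[("b", "d")] == 1.0  # one-way
        assert res["n_one_way"] == 1
        assert ("a", "d") not in pairs  # zero total flow: skipped
        assert ("b", "c") not in pairs

    def test_invariant_to_global_rescaling(self, small_random_graph):
        g = small_random_graph
        g2 = fs.FlowGraph(nodes=g.nodes, A=7.5 * g.A, intra=g.intra)
        r1 = fs.pairwise_relative_asymmetry(g)["values"]
        r2 = fs.pairwise_relative_asymmetry(g2)["values"]
        assert np.allclose(r1, r2, atol=1e-12)


class TestDetailedBalance:
    def test_symmetric_graph_reversible(self, small_random_graph):
        g = small_random_graph
        gsym = fs.FlowGraph(nodes=g.nodes, A=g.A + g.A.T, intra=np.zeros(g.n_nodes))
        m = fs.RandomWalkModel.from_graph(gsym)
        assert fs.detailed_balance_deviation(m) < 1e-12

    def test_two_node_always_reversible(self):
        g = fs.FlowGraph(
            nodes=["x", "y"], A=np.array([[0.0, 5.0], [0.2, 0.0]]), intra=np.zeros(2)
        )
        m = fs.RandomWalkModel.from_graph(g)
        assert fs.detailed_balance_deviation(m) < 1e-12

    def test_three_cycle_sqrt2(self, cycle3_model):
        assert fs.detailed_balance_deviation(cycle3_model) == pytest.approx(
            np.sqrt(2.0), abs=1e-10
        )

    def test_asymmetry_increases_deviation(self):
        """Generator irreversibility grows with the asymmetry knob."""
        devs = []
        for asym in (0.0, 0.15, 0.5):
            vals = []
            for seed in range(4):
                plan = fs.HierarchyPlan(levels=(2, 2), leaf_size=3, asymmetry=asym)
                g = fs.build_baseline_graph(fs.generate_hierarchical_flows(plan, seed))
                vals.append(
                    fs.detailed_balance_deviation(fs.RandomWalkModel.from_graph(g))
                )
            devs.append(np.mean(vals))
        assert devs[0] < 1e-10
        assert devs[0] < devs[1] < devs[2]


class TestCentralityDiagnostics:
    def test_symmetric_graph_r2_one(self, small_random_graph):
        g = small_random_graph
        gsym = fs.FlowGraph(
            nodes=g.nodes, A=g.A + g.A.T, intra=np.arange(1.0, g.n_nodes + 1)
        )
        m = fs.RandomWalkModel.from_graph(gsym)
        d = fs.centrality_diagnostics(gsym, m)
        assert d["r2_pi_d_out"] == pytest.approx(1.0, abs=1e-10)

    def test_constant_intra_undefined(self, small_random_graph):
        g = small_random_graph
        g2 = fs.FlowGraph(nodes=g.nodes, A=g.A, intra=np.full(g.n_nodes, 3.0))
        m = fs.RandomWalkModel.from_graph(g2)
        with pytest.raises(UndefinedStatisticError):
            fs.centrality_diagnostics(g2, m)

    def test_matches_least_squares_oracle(self):
        plan = fs.HierarchyPlan(levels=(2, 2), leaf_size=3)
        g = fs.build_baseline_graph(fs.generate_hierarchical_flows(plan, 9))
        m = fs.RandomWalkModel.from_graph(g)
        d = fs.centrality_diagnostics(g, m)
        x, y = g.d_out, m.pi
        beta, alpha = np.polyfit(x, y, 1)
        ss_res = np.sum((y - (alpha + beta * x)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert d["r2_pi_d_out"] == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
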