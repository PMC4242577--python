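
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cphylo.chrono import parse_newick
from cphylo.dec import (
    AreaSet,
    anagenetic_rate_matrix,
    branch_probability,
    build_state_space,
    cladogenesis_table,
    compare_hypotheses,
    fit_hypothesis,
    make_hypothesis,
    read_range_matrix,
    root_range_profile,
    tree_negloglik,
    write_range_matrix,
    DEFAULT_AREAS,
)
from cphylo.errors import ArgumentError
from oracles import brute_force_likelihood


class TestStateSpace:
    def test_six_areas_max_two_gives_21_living_states(self):
        space = build_state_space(DEFAULT_AREAS, 2)
        assert space.n_living == 21
        assert space.n_states == 22
        assert space.states[0] == frozenset()

    def test_single_area(self):
        space = build_state_space(("A",), 1)
        assert space.n_living == 1

    def test_two_areas_full(self):
        space = build_state_space(("A", "B"), 2)
        assert space.living_states == [frozenset("A"), frozenset("B"), frozenset("AB")]

    def test_empty_area_set_rejected(self):
        with pytest.raises(ArgumentError):
            AreaSet(())


class TestRateMatrix:
    def test_zero_rates_zero_matrix(self):
        space = build_state_space(("A", "B"), 2)
        Q = anagenetic_rate_matrix(space, np.ones((2, 2)), 0.0, 0.0)
        assert np.all(Q == 0)

    def test_single_source_dispersal_rate(self):
        space = build_state_space(("A", "B"), 2)
        d = 0.37
        Q = anagenetic_rate_matrix(space, np.ones((2, 2)), d, 0.0)
        iA = space.state_index({"A"})
        iAB = space.state_index({"A", "B"})
        assert Q[iA, iAB] == pytest.approx(d)

    def test_extinction_reaches_empty_state(self):
        space = build_state_space(("A", "B"), 2)
        e = 0.11
        Q = anagenetic_rate_matrix(space, np.ones((2, 2)), 0.0, e)
        assert Q[space.state_index({"A"}), 0] == pytest.approx(e)
        assert Q[space.state_index({"A", "B"}), space.state_index({"B"})] == pytest.approx(e)

    def test_row_sums_vanish_on_full_fixture(self):
        space = build_state_space(DEFAULT_AREAS, 2)
        hyp = make_hypothesis("northward_expansion", root_age_kya=500.0)
        Q = anagenetic_rate_matrix(space, hyp.epochs[2].multipliers, 0.013, 0.0012)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)


class TestBranchProbability:
    def test_zero_interval_is_identity(self):
        space = build_state_space(DEFAULT_AREAS, 2)
        hyp = make_hypothesis("multiple_refugia", root_age_kya=100.0)
        P = branch_probability(space, hyp, 0.01, 0.01, 50.0, 50.0)
        assert np.array_equal(P, np.eye(space.n_states))

    def test_zero_rates_identity(self):
        space = build_state_space(DEFAULT_AREAS, 2)
        hyp = make_hypothesis("multiple_refugia", root_age_kya=100.0)
        P = branch_probability(space, hyp, 0.0, 0.0, 90.0, 10.0)
        assert np.allclose(P, np.eye(space.n_states), atol=1e-12)

    def test_rows_stochastic(self):
        space = build_state_space(DEFAULT_AREAS, 2)
        hyp = make_hypothesis("southward_expansion", root_age_kya=1100.0)
        P = branch_probability(space, hyp, 0.005, 0.001, 1000.0, 3.0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= -1e-12)

    def test_multi_epoch_product_matches_ode_oracle(self):
        """A branch crossing several epochs must match direct numerical
        integration of the time-inhomogeneous forward equation."""
        space = build_state_space(DEFAULT_AREAS, 2)
        hyp = make_hypothesis("multiple_refugia", root_age_kya=300.0)
        d, e = 0.008, 0.002
        t_start, t_end = 260.0, 5.0
        Qs = [anagenetic_rate_matrix(space, ep.multipliers, d, e) for ep in hyp.epochs]

        def rhs(t, y):
            # t runs forward from 0 (branch start = t_start before present)
            kya = t_start - t
            idx = hyp.epoch_at(max(kya, 1e-9))
            return (y.reshape(space.n_states, space.n_states) @ Qs[idx]).ravel()

        sol = solve_ivp(
            rhs, (0.0, t_start - t_end), np.eye(space.n_states).ravel(),
            rtol=1e-10, atol=1e-12, method="DOP853",
        )
        expected = sol.y[:, -1].reshape(space.n_states, space.n_states)
        P = branch_probability(space, hyp, d, e, t_start, t_end)
        assert np.max(np.abs(P - expected)) < 1e-8


class TestCladogenesis:
    def test_single_area_inherited_identically(self):
        table = cladogenesis_table(frozenset({"A"}))
        assert table == [(frozenset({"A"}), frozenset({"A"}), 1.0)]

    def test_two_area_range_has_six_uniform_scenarios(self):
        table = cladogenesis_table(frozenset({"A", "B"}))
        assert len(table) == 6
        assert all(p == pytest.approx(1 / 6) for *_, p in table)
        pairs = {(l, r) for l, r, _ in table}
        A, B, AB = frozenset("A"), frozenset("B"), frozenset("AB")
        assert pairs == {(A, B), (B, A), (A, AB), (AB, A), (B, AB), (AB, B)}

    @pytest.mark.parametrize("rng", [{"A"}, {"A", "B"}, {"B", "C"}])
    def test_probabilities_normalized(self, rng):
        table = cladogenesis_table(frozenset(rng))
        assert sum(p for *_, p in table) == pytest.approx(1.0)

    def test_empty_range_rejected(self):
        with pytest.raises(ArgumentError):
            cladogenesis_table(frozenset())


class TestTreeLikelihood:
    def test_single_area_no_extinction_likelihood_one(self):
        hyp = make_hypothesis(
            "multiple_refugia", root_age_kya=10.0, areas=("A",), adjacency=(),
            latitudes={"A": 50.0},
        )
        tree = parse_newick("(t1:5,t2:5):0;")
        ranges = {"t1": frozenset("A"), "t2": frozenset("A")}
        nll = tree_negloglik(tree, ranges, hyp, 0.02, 0.0, max_range_size=1)
        assert nll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "newick,ranges",
        [
            ("(t1:40,t2:40):0;", {"t1": "A", "t2": "B"}),
            ("(t1:40,t2:40):0;", {"t1": "AB", "t2": "A"}),
            ("((t1:25,t2:25):30,t3:55):0;", {"t1": "A", "t2": "C", "t3": "AC"}),
            ("((t1:10,t2:10):45,t3:55):0;", {"t1": "AB", "t2": "B", "t3": "C"}),
        ],
    )
    def test_pruning_matches_brute_force_enumeration(self, newick, ranges):
        areas = ("A", "B", "C")
        lat = {"A": 60.0, "B": 50.0, "C": 40.0}
        adj = (("A", "B"), ("B", "C"))
        hyp = make_hypothesis("multiple_refugia", root_age_kya=60.0, areas=areas,
                              adjacency=adj, latitudes=lat)
        space = build_state_space(areas, 2)
        tree = parse_newick(newick)
        tips = {k: frozenset(v) for k, v in ranges.items()}
        d, e = 0.004, 0.0015
        fast = tree_negloglik(tree, tips, hyp, d, e, space=space)
        slow = brute_force_likelihood(tree, tips, hyp, d, e, space)
        assert fast == pytest.approx(slow, abs=1e-9)

    def test_impossible_data_gives_infinite_nll(self):
        hyp = make_hypothesis("multiple_refugia", root_age_kya=10.0,
                              areas=("A", "B"), adjacency=(("A", "B"),),
                              latitudes={"A": 60.0, "B": 40.0})
        tree = parse_newick("(t1:5,t2:5):0;")
        # every cladogenetic scenario leaves one daughter a single area,
        # so two widespread tips are unreachable without dispersal
        ranges = {"t1": frozenset("AB"), "t2": frozenset("AB")}
        assert tree_negloglik(tree, ranges, hyp, 0.0, 0.0) == np.inf


class TestFitting:
    def _fixture(self):
        from cphylo.datasets import synthetic_chronogram, synthetic_range_matrix

        return synthetic_chronogram(), synthetic_range_matrix()

    def test_no_dispersal_signal_drives_d_to_lower_bound(self):
        hyp = make_hypothesis("multiple_refugia", root_age_kya=60.0)
        tree = parse_newick("((t1:25,t2:25):30,t3:55):0;")
        ranges = {k: frozenset({"Olympics"}) for k in ("t1", "t2", "t3")}
        fit = fit_hypothesis(tree, ranges, hyp, starts=((0.01, 0.001),), tol=1e-6)
        assert fit.d < 1e-6

    def test_optimum_beats_probed_rate_grid(self):
        tree, ranges = self._fixture()
        hyp = make_hypothesis("multiple_refugia", root_age_kya=1100.0)
        fit = fit_hypothesis(tree, ranges, hyp, starts=((0.01, 0.01),), tol=1e-6)
        for d in (0.001, 0.005, 0.02):
            for e in (0.0005, 0.002, 0.01):
                assert fit.neg_log_lik <= tree_negloglik(tree, ranges, hyp, d, e) + 1e-6

    def test_root_profile_window(self):
        tree, ranges = self._fixture()
        hyp = make_hypothesis("multiple_refugia", root_age_kya=1100.0)
        full = root_range_profile(tree, ranges, hyp, 0.005, 0.001, window=np.inf)
        assert len(full) == 21
        assert all(b >= a for (_, a), (_, b) in zip(full, full[1:]))
        windowed = root_range_profile(tree, ranges, hyp, 0.005, 0.001, window=2.0)
        best = full[0][1]
        assert windowed == [ent for ent in full if ent[1] <= best + 2.0]

    def test_duplicate_hypotheses_tie(self):
        tree, ranges = self._fixture()
        hyp = make_hypothesis("multiple_refugia", root_age_kya=1100.0)
        table = compare_hypotheses(tree, ranges, [hyp, hyp],
                                   starts=((0.01, 0.01),), tol=1e-6)
        assert table["delta_neg_log_lik"].iloc[1] == pytest.approx(0.0, abs=1e-4)
        deltas = table["neg_log_lik"] - table["neg_log_lik"].iloc[0]
        assert np.allclose(deltas, table["delta_neg_log_lik"])


class TestRangeMatrixIO:
    def test_round_trip(self, tmp_path):
        from cphylo.datasets import synthetic_range_matrix

        ranges = synthetic_range_matrix()
        p = tmp_path / "ranges.csv"
        write_range_matrix(ranges, DEFAULT_AREAS, p)
        assert read_range_matrix(p) == ranges
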