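import itertools

import numpy as np
import pandas as pd
import pytest

from cphylo.enm import (
    LearnerModel,
    auc,
    bootstrap_gate,
    fit_learner,
    prune_predictors,
    refugia_map,
    run_ensemble,
    select_threshold,
    vote_map,
    weighted_background,
    LEARNER_REGISTRY,
    VoteMap,
)
from cphylo.errors import ArgumentError
from cphylo.raster import RasterGrid, stack_table
from cphylo.simulate import NicheSpec, make_climate_stack, sample_species_occurrences


def _rho(names, values):
    return pd.DataFrame(values, index=names, columns=names)


class TestPrunePredictors:
    def test_correlated_pair_keeps_more_important(self):
        rho = _rho(["a", "b"], [[1.0, 0.9], [0.9, 1.0]])
        assert prune_predictors({"a": 0.2, "b": 0.8}, rho) == ["b"]

    def test_uncorrelated_variables_all_kept(self):
        names = list("abcd")
        rho = _rho(names, np.eye(4))
        kept = prune_predictors({n: i for i, n in enumerate(names)}, rho)
        assert sorted(kept) == names

    def test_44_variable_block_structure_keeps_5(self):
        # five blocks of strongly inter-correlated variables: the greedy
        # rule keeps exactly the most important member of each block
        names = [f"v{i}" for i in range(44)]
        block = np.repeat(np.arange(5), [9, 9, 9, 9, 8])
        R = np.eye(44)
        for i, j in itertools.combinations(range(44), 2):
            if block[i] == block[j]:
                R[i, j] = R[j, i] = 0.85
        importance = {n: 44 - i for i, n in enumerate(names)}
        kept = prune_predictors(importance, _rho(names, R))
        assert len(kept) == 5
        # the first (most important) variable of each block is the survivor
        starts = np.searchsorted(block, np.arange(5))
        assert kept == [names[s] for s in starts]

    def test_asymmetric_rho_rejected(self):
        rho = _rho(["a", "b"], [[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ArgumentError):
            prune_predictors({"a": 1, "b": 2}, rho)


class TestWeightedBackground:
    def test_ratio_weights(self):
        wp, wb = weighted_background(100, 400)
        assert np.all(wp == 1.0)
        assert np.allclose(wb, 0.25)
        assert wp.sum() == pytest.approx(wb.sum())

    def test_equal_counts_unit_weights(self):
        wp, wb = weighted_background(50, 50)
        assert np.all(wp == 1.0) and np.all(wb == 1.0)

    def test_zero_counts_rejected(self):
        with pytest.raises(ArgumentError):
            weighted_background(0, 10)

    def test_logistic_intercept_reflects_balanced_prevalence(self):
        # with equalized weights the fitted intercept of the logistic
        # learner on exchangeable data sits near the 50% prevalence logit
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 1))
        model = fit_learner("logistic", X, np.vstack([X] * 4))
        mean_pred = model.predict(X).mean()
        assert abs(mean_pred - 0.5) < 0.1


class TestLearners:
    def test_envelope_point_mass(self):
        pres = np.full((30, 1), 2.0)
        model = fit_learner("envelope", pres, np.linspace(-5, 5, 50)[:, None])
        assert model.predict([[2.0]])[0] == pytest.approx(1.0)
        assert model.predict([[4.0]])[0] == 0.0

    def test_logistic_separable_training_auc_one(self):
        pres = np.linspace(1, 2, 40)[:, None]
        bg = np.linspace(-2, -1, 40)[:, None]
        model = fit_learner("logistic", pres, bg)
        assert auc(model.predict(pres), model.predict(bg)) == pytest.approx(1.0)

    def test_mahalanobis_maximal_at_centroid(self):
        rng = np.random.default_rng(1)
        pres = rng.normal(size=(100, 3))
        model = fit_learner("mahalanobis", pres, rng.normal(size=(100, 3)))
        at_centroid = model.predict(pres.mean(axis=0, keepdims=True))[0]
        assert at_centroid == pytest.approx(1.0, abs=1e-9)
        assert np.all(model.predict(pres) <= at_centroid + 1e-9)

    def test_mahalanobis_rank_deficiency(self):
        with pytest.raises(ArgumentError):
            fit_learner("mahalanobis", np.zeros((3, 5)), np.zeros((10, 5)))

    def test_unknown_learner(self):
        with pytest.raises(ArgumentError):
            fit_learner("maxent", np.zeros((5, 1)), np.zeros((5, 1)))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 1, 1], [0, 0]) == 1.0

    def test_identical_distributions(self):
        assert auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_hand_enumerated_case(self):
        assert auc([0.9, 0.8], [0.85, 0.1]) == pytest.approx(0.75)

    def test_matches_pairwise_oracle_on_small_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            pres = rng.integers(0, 6, size=rng.integers(1, 10)) / 5.0
            bg = rng.integers(0, 6, size=rng.integers(1, 10)) / 5.0
            wins = sum(p > b for p in pres for b in bg)
            ties = sum(p == b for p in pres for b in bg)
            oracle = (wins + 0.5 * ties) / (len(pres) * len(bg))
            assert auc(pres, bg) == pytest.approx(oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(ArgumentError):
            auc([], [0.1])


class TestBootstrapGate:
    def test_uninformative_learner_removed_informative_kept(self):
        def fit_noise(presences, background, weights):
            rng = np.random.default_rng(abs(int(presences.sum() * 1e6)) % 2**31)
            return lambda X: rng.random(len(X))

        LEARNER_REGISTRY["noise"] = fit_noise
        try:
            rng = np.random.default_rng(3)
            pres = rng.normal(2.0, 0.5, size=(80, 1))
            bg = rng.normal(-2.0, 0.5, size=(200, 1))
            retained, table = bootstrap_gate(["logistic", "noise"], pres, bg, seed=1)
            assert "logistic" in retained and "noise" not in retained
            row = table.set_index("learner")
            assert row.loc["noise", "mean_auc"] < 0.65
            assert row.loc["logistic", "mean_auc"] > 0.95
        finally:
            del LEARNER_REGISTRY["noise"]

    def test_zero_gate_keeps_everything(self):
        rng = np.random.default_rng(4)
        pres = rng.normal(size=(40, 2))
        bg = rng.normal(size=(80, 2))
        retained, _ = bootstrap_gate(
            ["envelope", "mahalanobis", "logistic"], pres, bg, auc_min=0.0, seed=2
        )
        assert set(retained) == {"envelope", "mahalanobis", "logistic"}


class TestSelectThreshold:
    @staticmethod
    def _identity_model():
        return LearnerModel(name="identity", _predict=lambda X: X[:, 0])

    def test_separated_scores_lowest_zero_gap_cutoff(self):
        model = self._identity_model()
        cut = select_threshold(model, [[0.9], [0.8]], [[0.2], [0.1]], "sens_eq_spec")
        assert cut == pytest.approx(0.8)

    def test_mean_probability_of_constant_map(self):
        model = self._identity_model()
        cut = select_threshold(model, [[0.9]], [[0.4]] * 10, "mean_probability")
        assert cut == pytest.approx(0.4)

    def test_symmetric_overlap_cuts_at_midpoint(self):
        rng = np.random.default_rng(5)
        model = LearnerModel(name="expit", _predict=lambda X: 1 / (1 + np.exp(-X[:, 0])))
        pres = rng.normal(1.0, 1.0, size=(2000, 1))
        bg = rng.normal(-1.0, 1.0, size=(2000, 1))
        cut = select_threshold(model, pres, bg, "sens_eq_spec")
        # midpoint of the score distributions is expit(0) = 0.5
        assert abs(cut - 0.5) < 0.05

    def test_constant_predictions_degenerate(self):
        model = LearnerModel(name="const", _predict=lambda X: np.full(len(X), 0.7))
        assert select_threshold(model, [[1.0]], [[0.0]], "sens_eq_spec") == 0.7


def _grid(values, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(
        n_rows=values.shape[0], n_cols=values.shape[1], x_origin=0.0, y_origin=0.0,
        cell_size=1.0, nodata_value=nodata, values=values,
    )


class TestVoteMap:
    def test_half_votes_is_50_percent(self):
        maps = [_grid([[1.0]])] * 8 + [_grid([[0.0]])] * 8
        vm = vote_map(maps)
        assert vm.grid.values[0, 0] == 50.0
        assert vm.total_votes == 16

    def test_unanimous_48_votes(self):
        vm = vote_map([_grid([[1.0]])] * 48)
        assert vm.grid.values[0, 0] == 100.0
        assert vm.total_votes == 48

    def test_single_map_percentages_binary(self):
        vm = vote_map([_grid([[1.0, 0.0]])])
        assert set(vm.grid.values.ravel()) == {0.0, 100.0}

    def test_order_invariance_and_nodata(self):
        a = _grid([[1.0, -9999.0]])
        b = _grid([[0.0, 1.0]])
        v1 = vote_map([a, b]).grid.values
        v2 = vote_map([b, a]).grid.values
        assert np.array_equal(v1, v2)
        assert v1[0, 1] == 100.0  # only one valid vote there

    def test_geometry_mismatch(self):
        with pytest.raises(ArgumentError):
            vote_map([_grid([[1.0]]), _grid([[1.0, 0.0]])])


class TestRefugiaMap:
    def _slices(self, percentages):
        return [VoteMap(grid=_grid([[p]]), total_votes=16) for p in percentages]

    def test_stable50_not_75(self):
        rmap = refugia_map(self._slices([60, 60, 60, 60]))
        assert rmap.grid.values[0, 0] == 1

    def test_ice_overrides_stability(self):
        rmap = refugia_map(self._slices([80, 80, 80, 80]), ice=_grid([[1.0]]))
        assert rmap.grid.values[0, 0] == 0

    def test_one_failing_slice_demotes(self):
        rmap = refugia_map(self._slices([80, 80, 80, 40]))
        assert rmap.grid.values[0, 0] == 0

    def test_needs_exactly_four_slices(self):
        with pytest.raises(ArgumentError):
            refugia_map(self._slices([80, 80, 80]))

    def test_monotone_in_slice_percentages(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0, 100, size=4)
        cat0 = refugia_map(self._slices(base)).grid.values[0, 0]
        for k in range(4):
            bumped = base.copy()
            bumped[k] = min(100.0, bumped[k] + 30)
            cat1 = refugia_map(self._slices(bumped)).grid.values[0, 0]
            assert cat1 >= cat0


class TestEnsembleRecovery:
    def test_synthetic_species_recovered(self):
        """The full ensemble on a species with a known niche: mean AUC
        above 0.9 and >= 90% of the truly suitable region voted in."""
        stack = make_climate_stack(21, 40, 50, 3)
        # a selective niche (suitable in ~4% of the landscape) so the
        # species occupies a coherent, learnable climate envelope
        niche = NicheSpec(coefficients=[20.0, -12.0, 0.0], intercept=-45.0)
        occ = sample_species_occurrences(stack, niche, n=150, seed=22)
        from cphylo.raster import extract_climate, thin_occurrences

        occ = thin_occurrences(occ, stack[0])
        pres = extract_climate(stack, occ.points)
        bg, flat = stack_table(stack)
        result = run_ensemble(pres, bg, {"current": [bg]}, stack[0], flat, seed=5)
        assert result.auc_table["mean_auc"].mean() > 0.9

        truth = niche.suitability(bg) > 0.8
        votes = result.vote_maps["current"].grid.values.ravel()[flat]
        assert np.mean(votes[truth] >= 50.0) >= 0.9
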