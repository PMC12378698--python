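"""Feature ranking, LOOCV ridge evaluation, selection and score emission."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge
from sklearn.preprocessing import StandardScaler

from cognav.errors import ConfigurationError, DataError
from cognav.prediction import (TrainedModel, backward_elimination,
                               compare_single_layer_models,
                               correlate_features, fit_final_model,
                               incremental_forward_selection, loocv_evaluate,
                               predict_scores, rank_features_boosting,
                               rank_features_cfs, select_and_train)


def _toy_table(n=60, p=4, seed=0, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"f{i}" for i in range(p)]
    data = rng.standard_normal((n, p))
    return pd.DataFrame(data, columns=names,
                        index=[f"p{i:03d}" for i in range(n)])


class TestCorrelate:
    def test_identity_and_negation(self):
        table = _toy_table(30, 2)
        target = table["f0"].rename("y")
        corr = correlate_features(table.assign(f1=-target), target)
        assert corr.loc["f0", "r"] == pytest.approx(1.0)
        assert corr.loc["f1", "r"] == pytest.approx(-1.0)

    def test_constant_feature_is_missing_with_warning(self, caplog):
        table = _toy_table(20, 2)
        table["f1"] = 5.0
        with caplog.at_level("WARNING"):
            corr = correlate_features(table, table["f0"].rename("y"))
        assert math.isnan(corr.loc["f1", "r"])

    def test_permutation_null_calibration(self):
        # With an independent target, |r| should exceed the theoretical 95%
        # bound in roughly 5% of permutations.
        rng = np.random.default_rng(1)
        n, reps = 40, 1000
        x = rng.standard_normal(n)
        crit = 2.0 / math.sqrt(n)  # approximate two-sided 95% bound
        hits = 0
        for _ in range(reps):
            y = rng.permutation(x)
            r = np.corrcoef(x, y)[0, 1]
            hits += abs(r) > crit
        assert 0.02 < hits / reps < 0.10


class TestRanking:
    def test_cfs_orders_signal_before_noise(self):
        table = _toy_table(80, 2)
        target = table["f0"].rename("y")
        ranked = rank_features_cfs(table, target)
        assert ranked.order[0] == "f0"
        assert ranked.method == "correlation"

    def test_cfs_tie_broken_by_name(self):
        table = _toy_table(30, 1, names=["b"])
        table["a"] = table["b"]
        ranked = rank_features_cfs(table, table["b"].rename("y"))
        assert ranked.order == ("a", "b")

    def test_cfs_matches_planted_coefficient_order(self):
        # Independent features, noiseless target: |r| ordering follows the
        # |standardized coefficient| ordering.
        table = _toy_table(400, 3, seed=3)
        target = (4.0 * table["f0"] + 2.0 * table["f1"]
                  + 1.0 * table["f2"]).rename("y")
        ranked = rank_features_cfs(table, target)
        assert ranked.order == ("f0", "f1", "f2")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_boosting_finds_the_informative_feature(self, seed):
        table = _toy_table(200, 5, seed=seed)
        target = table["f2"].rename("y")
        ranked = rank_features_boosting(table, target, seed=seed)
        assert ranked.order[0] == "f2"

    def test_boosting_deterministic_under_seed(self):
        table = _toy_table(50, 4, seed=9)
        target = (table["f0"] + 0.5 * table["f1"]).rename("y")
        r1 = rank_features_boosting(table, target, seed=5)
        r2 = rank_features_boosting(table, target, seed=5)
        assert r1.order == r2.order
        assert r1.scores == r2.scores

    def test_boosting_constant_target_degenerates_by_name(self, caplog):
        table = _toy_table(20, 3, seed=2)
        target = pd.Series(1.0, index=table.index, name="y")
        with caplog.at_level("WARNING"):
            ranked = rank_features_boosting(table, target)
        assert ranked.order == ("f0", "f1", "f2")
        assert all(v == 0 for v in ranked.scores.values())


class TestLoocv:
    def test_noiseless_linear_recovery(self):
        table = _toy_table(50, 1)
        target = (2.0 * table["f0"]).rename("y")
        report = loocv_evaluate(table, target, ["f0"], l2_strength=0.0)
        assert report.pearson_r > 0.999
        assert report.mse == pytest.approx(0.0, abs=1e-12)

    def test_each_row_held_out_exactly_once(self):
        table = _toy_table(5, 1)
        target = table["f0"].rename("y") + 0.1
        report = loocv_evaluate(table, target, ["f0"], l2_strength=1.0)
        assert list(report.per_fold_predictions.index) == list(table.index)
        assert report.per_fold_predictions.index.is_unique

    def test_no_leakage_from_held_out_row(self):
        # The held-out row must not influence its own fold's scaler or fit:
        # its prediction must equal what a scaler+ridge trained on the other
        # n-1 (unperturbed) rows produces for the perturbed inputs.
        table = _toy_table(30, 3, seed=4)
        target = (table["f0"] - table["f2"]).rename("y")
        held = table.index[7]
        corrupted = table.copy()
        corrupted.loc[held, :] = [7.5, -3.0, 12.0]
        pert = loocv_evaluate(corrupted, target, list(table.columns), 1.0)
        x_train = table.drop(index=held).to_numpy()
        y_train = target.drop(index=held).to_numpy()
        scaler = StandardScaler().fit(x_train)
        ref = Ridge(alpha=1.0).fit(scaler.transform(x_train), y_train)
        expected = ref.predict(
            scaler.transform(corrupted.loc[[held]].to_numpy()))[0]
        assert pert.per_fold_predictions[held] == pytest.approx(
            expected, abs=1e-10)

    def test_rejects_tiny_or_empty_inputs(self):
        table = _toy_table(4, 1)
        with pytest.raises(ConfigurationError):
            loocv_evaluate(table, table["f0"].rename("y"), ["f0"])
        with pytest.raises(ConfigurationError):
            loocv_evaluate(_toy_table(10, 1),
                           _toy_table(10, 1)["f0"].rename("y"), [])


class TestSelection:
    def test_forward_keeps_only_informative_feature(self):
        rng = np.random.default_rng(0)
        table = _toy_table(200, 4, seed=0)
        signal = table["f0"]
        target = (signal + rng.normal(0, 0.1 * signal.std(), len(table))
                  ).rename("y")
        ranked = rank_features_cfs(table, target)
        assert ranked.order[0] == "f0"
        subset, report = incremental_forward_selection(ranked, table, target,
                                                       l2_strength=1.0)
        assert subset == ["f0"]

    def test_forward_takes_full_ranking_when_all_informative(self):
        table = _toy_table(150, 3, seed=1)
        target = (table["f0"] + table["f1"] + table["f2"]).rename("y")
        ranked = rank_features_cfs(table, target)
        subset, _ = incremental_forward_selection(ranked, table, target,
                                                  l2_strength=0.0)
        assert sorted(subset) == ["f0", "f1", "f2"]

    def test_forward_single_feature_trivial(self):
        table = _toy_table(20, 1)
        target = table["f0"].rename("y")
        ranked = rank_features_cfs(table, target)
        subset, _ = incremental_forward_selection(ranked, table, target)
        assert subset == ["f0"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_backward_drops_pure_noise_first(self, seed):
        rng = np.random.default_rng(seed)
        table = _toy_table(120, 3, seed=seed)
        target = (table["f0"] + table["f1"]
                  + rng.normal(0, 0.05, len(table))).rename("y")
        _, _, trajectory = backward_elimination(
            table, target, ["f0", "f1", "f2"], l2_strength=0.1,
            return_trajectory=True)
        if len(trajectory) > 1:
            removed_first = set(trajectory[0][0]) - set(trajectory[1][0])
            assert removed_first == {"f2"}

    def test_backward_removes_redundant_copy(self):
        table = _toy_table(60, 1, names=["f0"])
        table["f1"] = table["f0"]
        target = table["f0"].rename("y")
        subset, report, trajectory = backward_elimination(
            table, target, ["f0", "f1"], l2_strength=0.0,
            return_trajectory=True)
        assert len(subset) == 1
        start_mse = trajectory[0][1].mse
        assert report.mse <= start_mse + 1e-9

    def test_backward_trajectory_bookkeeping(self):
        table = _toy_table(40, 4, seed=6)
        target = table["f0"].rename("y")
        _, _, trajectory = backward_elimination(
            table, target, list(table.columns), l2_strength=1.0,
            return_trajectory=True)
        start, final = trajectory[0][0], trajectory[-1][0]
        assert len(trajectory) == len(start) - len(final) + 1


class TestFinalModel:
    def test_exact_least_squares_on_standardized_feature(self):
        table = _toy_table(50, 1)
        zs = (table["f0"] - table["f0"].mean()) / table["f0"].std(ddof=0)
        target = (3.0 + 2.0 * zs).rename("y")
        model = fit_final_model(table, target, ["f0"], l2_strength=0.0)
        assert model.intercept == pytest.approx(3.0)
        assert model.coefficients[0] == pytest.approx(2.0)

    def test_ridge_limit_shrinks_to_target_mean(self):
        table = _toy_table(40, 2)
        target = (table["f0"] + 1.0).rename("y")
        model = fit_final_model(table, target, ["f0", "f1"],
                                l2_strength=1e9)
        assert max(abs(c) for c in model.coefficients) < 1e-6
        preds = predict_scores(model, table)["raw"]
        assert preds.std() < 1e-6
        assert preds.mean() == pytest.approx(target.mean(), abs=1e-4)

    def test_matches_closed_form_ridge(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.standard_normal((20, 3)),
                             columns=["f0", "f1", "f2"])
        target = pd.Series(rng.standard_normal(20), index=table.index,
                           name="y")
        lam = 2.5
        model = fit_final_model(table, target, list(table.columns),
                                l2_strength=lam)
        xs = StandardScaler().fit_transform(table.to_numpy())
        y = target.to_numpy()
        oracle = np.linalg.solve(xs.T @ xs + lam * np.eye(3),
                                 xs.T @ (y - y.mean()))
        assert np.allclose(model.coefficients, oracle, atol=1e-8)

    def test_agrees_with_sklearn_ridge(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.standard_normal((30, 2)),
                             columns=["f0", "f1"])
        target = pd.Series(rng.standard_normal(30), index=table.index,
                           name="y")
        model = fit_final_model(table, target, ["f0", "f1"], l2_strength=3.0)
        xs = StandardScaler().fit_transform(table.to_numpy())
        ref = Ridge(alpha=3.0).fit(xs, target.to_numpy())
        assert np.allclose(model.coefficients, ref.coef_, atol=1e-10)

    def test_shrinkage_monotone_in_l2(self):
        table = _toy_table(50, 3, seed=2)
        target = (table["f0"] + table["f1"]).rename("y")
        norms = []
        for lam in [0.0, 0.1, 1.0, 10.0, 100.0]:
            model = fit_final_model(table, target, list(table.columns),
                                    l2_strength=lam)
            norms.append(np.linalg.norm(model.coefficients))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_zero_variance_feature_rejected(self):
        table = _toy_table(20, 2)
        table["f1"] = 0.0
        with pytest.raises(DataError):
            fit_final_model(table, table["f0"].rename("y"), ["f0", "f1"])

    def test_singular_design_without_regularization_errors(self):
        table = _toy_table(20, 1, names=["f0"])
        table["f1"] = table["f0"] * 2
        with pytest.raises(DataError, match="nonzero"):
            fit_final_model(table, table["f0"].rename("y"), ["f0", "f1"],
                            l2_strength=0.0)


class TestPredictScores:
    def _model_and_table(self):
        table = _toy_table(30, 2, seed=5)
        target = (table["f0"] * 2 + 1).rename("y")
        model = fit_final_model(table, target, ["f0", "f1"],
                                l2_strength=0.5)
        return model, table

    def test_training_max_maps_to_100(self):
        model, table = self._model_and_table()
        scores = predict_scores(model, table)
        assert scores["display"].max() == pytest.approx(100.0)
        assert scores["display"].min() == pytest.approx(0.0)
        assert ((scores["unit"] >= 0) & (scores["unit"] <= 1)).all()

    def test_out_of_range_raw_clipped(self):
        model, table = self._model_and_table()
        low = table.iloc[[0]].copy()
        low["f0"] = -1e3
        assert predict_scores(model, low)["unit"].iloc[0] == 0.0

    def test_round_trip_serialization_bit_identical(self, tmp_path):
        model, table = self._model_and_table()
        model.save(tmp_path / "model.json")
        reloaded = TrainedModel.load(tmp_path / "model.json")
        s1 = predict_scores(model, table)
        s2 = predict_scores(reloaded, table)
        assert s1.equals(s2)

    def test_schema_mismatch_refused(self, tmp_path):
        model, _ = self._model_and_table()
        payload = model.to_dict()
        payload["schema"] = "something-else"
        with pytest.raises(DataError):
            TrainedModel.from_dict(payload)

    def test_missing_features_imputed_with_training_median(self):
        model, table = self._model_and_table()
        holed = table.copy()
        holed.iloc[0, 0] = np.nan
        scores = predict_scores(model, holed)
        assert np.isfinite(scores["raw"]).all()


class TestSelectAndTrain:
    def test_auto_never_beaten_by_single_method(self):
        rng = np.random.default_rng(3)
        table = _toy_table(60, 5, seed=3)
        target = (table["f0"] + rng.normal(0, 0.3, 60)).rename("y")
        _, auto_report, _ = select_and_train(table, target, method="auto",
                                             seed=0, backward=False)
        _, cfs_report, _ = select_and_train(table, target, method="cfs",
                                            seed=0, backward=False)
        assert auto_report.mse <= cfs_report.mse + 1e-12


class TestSingleLayerComparison:
    def test_identical_layers_give_identical_reports(self):
        from cognav.multiplex import Layer, build_multiplex
        from cognav.walks import FluencyList

        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")]
        mpx = build_multiplex([Layer("x", edges), Layer("y", edges)])
        rng = np.random.default_rng(0)
        nodes = sorted(mpx.node_universe)
        cohort = [FluencyList(f"p{i}",
                              list(rng.choice(nodes, size=6)))
                  for i in range(12)]
        target = pd.Series(rng.standard_normal(12),
                           index=[f"p{i}" for i in range(12)], name="y")
        reports = compare_single_layer_models(
            mpx, cohort, target, ["number_of_responses",
                                  "fraction_responses_in_lvc"],
            l2_strength=1.0, category="a")
        assert set(reports) == {"multiplex", "x", "y"}
        assert reports["x"].mse == pytest.approx(reports["multiplex"].mse)
        assert reports["y"].pearson_r == pytest.approx(
            reports["multiplex"].pearson_r)
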