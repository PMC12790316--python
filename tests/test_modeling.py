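"""MLR fitting, cross-validation, subset search, HOMO filter, benchmark."""

import numpy as np
import pandas as pd
import pytest

from co2screen.errors import (
    CollinearityError,
    DegenerateInputError,
    FeatureError,
    ModelingError,
    SplitError,
)
from co2screen.fixtures import SyntheticSpec, make_descriptor_table
from co2screen.modeling import (
    HOMO_THRESHOLD,
    MLRModel,
    best_subset_search,
    evaluate,
    fit_mlr,
    homo_filter,
    kfold_cv,
    loo_cv,
    make_split,
    nucleophilicity_correlation,
    predict,
)


class TestFitMLR:
    def test_noiseless_recovery_exact(self, linear_table):
        model = fit_mlr(linear_table, ["x1", "x2", "x3"])
        np.testing.assert_allclose(
            model.raw_coefficients, [2.0, -1.0, 0.5], atol=1e-10
        )
        yhat = model.predict_frame(linear_table)
        np.testing.assert_allclose(yhat, linear_table["co2a"], atol=1e-10)

    def test_constant_response_gives_zero_coefficients(self, linear_table):
        table = linear_table.copy()
        table["co2a"] = 4.2
        model = fit_mlr(table, ["x1", "x2"])
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-10)
        assert model.intercept == pytest.approx(4.2, abs=1e-10)

    def test_duplicate_feature_raises_collinearity_with_names(self, linear_table):
        table = linear_table.copy()
        table["x1_copy"] = table["x1"]
        with pytest.raises(CollinearityError) as err:
            fit_mlr(table, ["x1", "x1_copy", "x2"])
        assert {"x1", "x1_copy"} <= set(err.value.features)

    def test_zero_variance_feature_named(self, linear_table):
        table = linear_table.copy()
        table["flat"] = 1.0
        with pytest.raises(CollinearityError) as err:
            fit_mlr(table, ["x1", "flat"])
        assert err.value.features == ["flat"]

    def test_too_few_rows_rejected(self, linear_table):
        with pytest.raises(ModelingError):
            fit_mlr(linear_table.head(4), ["x1", "x2", "x3"])

    def test_coefficient_recovery_under_noise(self):
        # estimates fall within 3 standard errors of truth nearly always
        truth = np.array([2.0, -1.0, 0.5])
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(31, 3))
            y = x @ truth + rng.normal(scale=0.5257, size=31)
            table = pd.DataFrame(x, columns=["x1", "x2", "x3"])
            table["co2a"] = y
            model = fit_mlr(table, ["x1", "x2", "x3"])
            resid = y - model.predict_frame(table)
            sigma2 = resid @ resid / (31 - 4)
            xc = x - x.mean(axis=0)
            cov = sigma2 * np.linalg.inv(np.column_stack([np.ones(31), x]).T @ np.column_stack([np.ones(31), x]))
            se = np.sqrt(np.diag(cov)[1:])
            if np.all(np.abs(model.raw_coefficients - truth) <= 3 * se):
                hits += 1
        assert hits / n_seeds >= 0.99

    def test_train_r2_invariant_to_feature_rescaling(self, linear_table):
        table = linear_table.copy()
        table["co2a"] += np.random.default_rng(0).normal(size=len(table))
        split = make_split(table, seed=1)
        m1 = fit_mlr(table, ["x1", "x2"])
        r2_before = evaluate(m1, table, split).r2_train
        table["x1"] = table["x1"] * 250.0 + 17.0
        m2 = fit_mlr(table, ["x1", "x2"])
        r2_after = evaluate(m2, table, split).r2_train
        assert r2_after == pytest.approx(r2_before, abs=1e-10)

    def test_serialization_round_trip(self, tmp_path, linear_table):
        model = fit_mlr(linear_table, ["x1", "x2", "x3"])
        path = tmp_path / "model.json"
        model.save(path)
        back = MLRModel.load(path)
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        np.testing.assert_allclose(
            back.predict_frame(linear_table), model.predict_frame(linear_table)
        )


class TestEvaluate:
    def test_perfect_model_r2_one(self, linear_table):
        model = fit_mlr(linear_table, ["x1", "x2", "x3"])
        split = make_split(linear_table, seed=0)
        m = evaluate(model, linear_table, split)
        assert m.r2_test == pytest.approx(1.0, abs=1e-10)
        assert m.mae_test == pytest.approx(0.0, abs=1e-10)

    def test_predict_the_mean_model_r2_zero(self, linear_table):
        model = fit_mlr(linear_table, ["x1"])
        model.coefficients = np.array([0.0])
        split = pd.Series("train", index=linear_table.index)
        split.iloc[-5:] = "test"
        # predicting the train-split mean gives exactly zero train R2
        model.intercept = float(linear_table["co2a"][split == "train"].mean())
        m = evaluate(model, linear_table, split)
        assert m.r2_train == pytest.approx(0.0, abs=1e-10)

    def test_empty_test_split_rejected(self, linear_table):
        model = fit_mlr(linear_table, ["x1"])
        with pytest.raises(SplitError):
            evaluate(model, linear_table, ["train"] * len(linear_table))


class TestLOO:
    def test_noiseless_linear_data_q2_one(self, linear_table):
        assert loo_cv(linear_table, ["x1", "x2", "x3"]) == pytest.approx(1.0, abs=1e-10)

    def test_matches_hat_matrix_closed_form(self):
        # for OLS with intercept: e_(i) = e_i / (1 - h_ii)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 2))
        y = x @ [1.5, -0.7] + rng.normal(scale=0.3, size=12)
        table = pd.DataFrame(x, columns=["a", "b"])
        table["co2a"] = y
        q2 = loo_cv(table, ["a", "b"])

        design = np.column_stack([np.ones(12), x])
        hat = design @ np.linalg.inv(design.T @ design) @ design.T
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        resid = y - design @ beta
        press = float(((resid / (1 - np.diag(hat))) ** 2).sum())
        q2_closed = 1 - press / float(((y - y.mean()) ** 2).sum())
        assert q2 == pytest.approx(q2_closed, abs=1e-10)

    def test_pure_noise_q2_nonpositive_in_expectation(self):
        q2s = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
            table["co2a"] = rng.normal(size=25)
            q2s.append(loo_cv(table, ["a", "b", "c"]))
        assert np.mean(q2s) <= 0.0


class TestKFold:
    def test_fold_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(31, 3)), columns=["a", "b", "c"])
        table["co2a"] = table["a"] * 2 + rng.normal(size=31)
        m = kfold_cv(table, ["a", "b"], k=5, seed=0)
        assert sorted(m.kfold["fold_sizes"], reverse=True) == [7, 6, 6, 6, 6]

    def test_same_seed_identical_folds(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        table["co2a"] = table["a"] + rng.normal(size=20)
        m1 = kfold_cv(table, ["a"], k=5, seed=9)
        m2 = kfold_cv(table, ["a"], k=5, seed=9)
        assert m1.kfold == m2.kfold

    def test_k_exceeding_rows_rejected(self, linear_table):
        with pytest.raises(SplitError):
            kfold_cv(linear_table.head(3), ["x1"], k=5)


class TestBestSubset:
    def test_pool_of_six_evaluates_twenty_candidates(self):
        spec = SyntheticSpec(n_samples=31, n_decoys=3, seed=1)
        table = make_descriptor_table(spec)
        pool = [c for c in table.columns if c != "co2a"]
        assert len(pool) == 6
        leaderboard = best_subset_search(table, pool, subset_size=3)
        assert len(leaderboard) == 20

    def test_planted_subset_ranked_first(self):
        spec = SyntheticSpec(n_samples=31, n_decoys=5, seed=7)
        table = make_descriptor_table(spec)
        pool = [c for c in table.columns if c != "co2a"]
        leaderboard = best_subset_search(table, pool, subset_size=3)
        assert set(leaderboard[0]["features"]) == {"x1", "x2", "x3"}

    def test_duplicated_column_subsets_skipped_as_collinear(self):
        spec = SyntheticSpec(n_samples=20, n_decoys=2, seed=3)
        table = make_descriptor_table(spec)
        table["x1_dup"] = table["x1"]
        pool = ["x1", "x1_dup", "x2", "x3"]
        leaderboard = best_subset_search(table, pool, subset_size=2)
        skipped = [e for e in leaderboard if "skipped" in e]
        assert any({"x1", "x1_dup"} == set(e["features"]) for e in skipped)

    def test_candidate_cap_enforced_with_guidance(self):
        spec = SyntheticSpec(n_samples=20, n_decoys=7, seed=0)
        table = make_descriptor_table(spec)
        pool = [c for c in table.columns if c != "co2a"]
        with pytest.raises(ModelingError, match="greedy"):
            best_subset_search(table, pool, subset_size=3, max_candidates=10)

    def test_noise_feature_never_lowers_training_r2(self):
        worse = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(25, 2))
            y = x[:, 0] * 2 + rng.normal(scale=0.5, size=25)
            table = pd.DataFrame(x, columns=["a", "noise"])
            table["co2a"] = y
            m_small = fit_mlr(table, ["a"])
            m_big = fit_mlr(table, ["a", "noise"])
            r2 = lambda m, f: 1 - ((y - m.predict_frame(table)) ** 2).sum() / (
                (y - y.mean()) ** 2
            ).sum()
            if r2(m_big, None) < r2(m_small, None) - 1e-12:
                worse += 1
        assert worse == 0


class TestHomoFilter:
    def test_table_values_pass(self):
        assert homo_filter(-0.129)  # a reported stable candidate proceeds
        assert homo_filter(-0.137)

    def test_table_values_fail(self):
        assert not homo_filter(-0.153)  # a reported screened-out candidate
        assert not homo_filter(-0.150)

    def test_boundary_is_inclusive(self):
        assert homo_filter(-0.140)
        assert homo_filter(HOMO_THRESHOLD + 1e-12)
        assert not homo_filter(HOMO_THRESHOLD - 1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ModelingError):
            homo_filter(float("nan"))


class TestPredict:
    def test_mean_row_predicts_intercept(self, linear_table):
        model = fit_mlr(linear_table, ["x1", "x2", "x3"])
        row = {f: float(linear_table[f].mean()) for f in ["x1", "x2", "x3"]}
        p = predict(model, row, record_id="mean", epsilon_homo=-0.10)
        assert p.co2a_pred == pytest.approx(model.intercept, abs=1e-10)

    def test_screened_out_row_has_no_affinity(self, toy_model):
        p = predict(toy_model, {}, record_id="low", epsilon_homo=-0.155)
        assert not p.passed_homo_filter
        assert p.co2a_pred is None
        assert p.stability_call == "screened-out"

    def test_affinity_monotone_in_homo_coefficient_direction(self, linear_table):
        model = fit_mlr(linear_table, ["x1", "x2", "x3"])
        base = {"x1": 0.0, "x2": 0.0, "x3": 0.0}
        up = dict(base, x1=1.0)
        p0 = predict(model, base, epsilon_homo=-0.1)
        p1 = predict(model, up, epsilon_homo=-0.1)
        assert np.sign(p1.co2a_pred - p0.co2a_pred) == np.sign(model.coefficients[0])

    def test_missing_feature_raises(self, toy_model):
        with pytest.raises(FeatureError):
            predict(toy_model, {"epsilon_homo_boltz": -0.13}, epsilon_homo=-0.13)

    def test_stability_call_follows_sign(self, toy_model):
        row = {
            "epsilon_homo_boltz": -0.15,
            "site_dipole_boltz": 0.1,
            "buried_b1_boltz": 1.7,
        }
        p = predict(toy_model, row, epsilon_homo=-0.13)
        assert p.stability_call == ("stable" if p.co2a_pred > 0 else "unstable")


class TestNucleophilicityCorrelation:
    def test_perfectly_collinear_r2_one(self):
        n_values = {f"n{i}": float(i) for i in range(5)}
        affinities = {k: 2.0 * v - 1.0 for k, v in n_values.items()}
        result = nucleophilicity_correlation(affinities, n_values)
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)
        assert result.slope == pytest.approx(2.0, abs=1e-12)

    def test_constant_n_is_degenerate(self):
        n_values = {f"n{i}": 5.0 for i in range(4)}
        affinities = {f"n{i}": float(i) for i in range(4)}
        with pytest.raises(DegenerateInputError):
            nucleophilicity_correlation(affinities, n_values)

    def test_unpaired_ids_reported(self):
        with pytest.raises(ModelingError, match="unpaired"):
            nucleophilicity_correlation({"a": 1.0, "b": 2.0}, {"c": 1.0, "d": 2.0})

    def test_moderate_noise_gives_moderate_r2(self):
        rng = np.random.default_rng(8)
        n = rng.uniform(10, 30, size=31)
        co2a = 0.5 * n - 8 + rng.normal(scale=3.0, size=31)
        result = nucleophilicity_correlation(
            {f"m{i}": co2a[i] for i in range(31)},
            {f"m{i}": n[i] for i in range(31)},
        )
        assert 0.3 < result.r_squared < 1.0
        assert result.slope > 0
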