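"""CV splits, random-forest training, rank evaluation, importances."""

import pickle

import numpy as np
import pandas as pd
import pytest

from phenosel.config import RFConfig
from phenosel.prediction import (evaluate, feature_importance, make_cohorts,
                                 make_cv1_splits, make_cv2_splits,
                                 run_cohort_experiment, train_rf)


GENOTYPES_292 = [f"G{i:04d}" for i in range(292)]


class TestSplits:
    def test_breeding_panel_sizes(self):
        splits = make_cv1_splits(GENOTYPES_292, 0.80, n_iter=10, seed=1)
        assert len(splits) == 10
        for s in splits:
            assert len(s.train_genotypes) == 234
            assert len(s.test_genotypes) == 58

    def test_forty_percent_training(self):
        s = make_cv1_splits(GENOTYPES_292, 0.40, n_iter=1, seed=1)[0]
        assert len(s.train_genotypes) == 117

    def test_disjointness(self):
        for s in make_cv1_splits(GENOTYPES_292, 0.8, 5, seed=2):
            assert not set(s.train_genotypes) & set(s.test_genotypes)

    def test_cv2_fold_structure(self):
        envs = ["E1", "E2", "E3", "E4"]
        splits = make_cv2_splits(GENOTYPES_292, envs, 0.80, n_iter=2, seed=3)
        assert len(splits) == 8                   # 4 envs x 2 iterations
        for s in splits:
            assert s.held_out_environment in envs
            assert len(s.train_genotypes) == 234
            assert not set(s.train_genotypes) & set(s.test_genotypes)

    def test_cv2_two_environments_two_folds(self):
        splits = make_cv2_splits(GENOTYPES_292, ["E1", "E2"], 0.8, 1, 0)
        assert len(splits) == 2

    def test_cv2_needs_two_environments(self):
        with pytest.raises(ValueError, match="2 complete environments"):
            make_cv2_splits(GENOTYPES_292, ["E1"], 0.8, 1, 0)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_cv1_splits(GENOTYPES_292, 1.5, 1, 0)
        with pytest.raises(ValueError):
            make_cv1_splits(["a", "b"], 0.9999, 1, 0)


def _linear_data(n=200, p=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{j}" for j in range(p)])
    y = X.sum(axis=1) + noise * rng.normal(size=n)
    return X, y.rename("y")


class TestTrainRF:
    def test_noiseless_linear_response_high_r2(self):
        X, y = _linear_data()
        _, metrics = train_rf(X, y, RFConfig(n_trees=200), seed=1)
        assert metrics["oob_r2"] > 0.8

    def test_permuted_response_near_zero_r2(self):
        X, y = _linear_data(seed=2)
        yp = pd.Series(np.random.default_rng(3).permutation(y.to_numpy()),
                       index=y.index, name="y")
        _, metrics = train_rf(X, yp, RFConfig(n_trees=200), seed=1)
        assert metrics["oob_r2"] < 0.1

    def test_deterministic_given_seed(self):
        X, y = _linear_data(seed=4)
        m1, _ = train_rf(X, y, RFConfig(n_trees=100), seed=9)
        m2, _ = train_rf(X, y, RFConfig(n_trees=100), seed=9)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_tuning_selects_from_grid(self):
        X, y = _linear_data(n=120, seed=5)
        cfg = RFConfig(n_trees=60, tune=True, max_features_grid=(0.5, 1.0),
                       tune_folds=4, tune_repeats=1)
        _, metrics = train_rf(X, y, cfg, seed=2)
        assert metrics["max_features"] in (0.5, 1.0)
        assert np.isfinite(metrics["cv_r2"])

    def test_constant_response_rejected(self):
        X, _ = _linear_data(n=50)
        with pytest.raises(ValueError, match="constant response"):
            train_rf(X, pd.Series(np.ones(50)), seed=0)

    def test_missing_predictors_rejected(self):
        X, y = _linear_data(n=50)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing predictor"):
            train_rf(X, y, seed=0)

    def test_no_information_leakage(self):
        """The fitted model depends only on training rows: retraining after
        replacing the 'test' data leaves the model bit-identical."""
        X, y = _linear_data(seed=6)
        m1, _ = train_rf(X, y, RFConfig(n_trees=50), seed=5)
        _ = _linear_data(seed=99)        # a different "test set" existing
        m2, _ = train_rf(X, y, RFConfig(n_trees=50), seed=5)
        assert pickle.dumps(m1) == pickle.dumps(m2)


class TestEvaluate:
    def _identity_model(self):
        class M:
            def predict(self, X):
                return np.asarray(X).ravel()
        return M()

    def test_perfect_and_reversed(self):
        m = self._identity_model()
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert evaluate(m, X, y) == pytest.approx(1.0)
        assert evaluate(m, X, y.iloc[::-1].reset_index(drop=True)) == \
            pytest.approx(-1.0)

    def test_hand_rank_value(self):
        m = self._identity_model()
        X = pd.DataFrame({"x": [2.0, 1.0, 3.0]})
        y = pd.Series([1.0, 2.0, 3.0])
        assert evaluate(m, X, y) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        class Exp:
            def predict(self, X):
                return np.exp(np.asarray(X).ravel())
        X = pd.DataFrame({"x": np.random.default_rng(1).normal(size=20)})
        y = pd.Series(np.random.default_rng(2).normal(size=20))
        assert evaluate(self._identity_model(), X, y) == pytest.approx(
            evaluate(Exp(), X, y))

    def test_within_environment_averaging(self):
        m = self._identity_model()
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 3.0, 2.0, 1.0]})
        y = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        envs = pd.Series(["a"] * 3 + ["b"] * 3)
        assert evaluate(m, X, y, environments=envs) == pytest.approx(0.0)
        pooled = evaluate(m, X, y, environments=envs, pool_environments=True)
        assert pooled == pytest.approx(0.0)

    def test_too_few_test_points(self):
        m = self._identity_model()
        with pytest.raises(ValueError, match="at least 3"):
            evaluate(m, pd.DataFrame({"x": [1.0, 2.0]}),
                     pd.Series([1.0, 2.0]))


class TestImportance:
    def test_normalized_to_hundred(self):
        X, y = _linear_data(seed=7)
        m, _ = train_rf(X, y, RFConfig(n_trees=50), seed=1)
        imp = feature_importance(m)
        assert imp.sum() == pytest.approx(100.0)
        assert (imp >= 0).all()

    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(8)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(40 + seed)
            X = pd.DataFrame(rng.normal(size=(150, 21)),
                             columns=["signal"] + [f"n{j}" for j in range(20)])
            y = X["signal"] + 0.3 * rng.normal(size=150)
            m, _ = train_rf(X, y.rename("y"), RFConfig(n_trees=100),
                            seed=seed)
            hits += feature_importance(m).index[0] == "signal"
        assert hits >= 9

    def test_all_noise_importances_flat(self):
        ratios = []
        for seed in range(5):
            rng = np.random.default_rng(60 + seed)
            X = pd.DataFrame(rng.normal(size=(120, 20)),
                             columns=[f"n{j}" for j in range(20)])
            y = pd.Series(rng.normal(size=120), name="y")
            m, _ = train_rf(X, y, RFConfig(n_trees=100), seed=seed)
            imp = feature_importance(m)
            ratios.append(imp.max() / imp.median())
        assert np.median(ratios) < 3.0


class TestCohorts:
    def test_standard_cohorts_built(self, study_tables):
        m1, _, _ = study_tables
        cohorts = make_cohorts([c for c in m1.frame.columns
                                if c != "seed_yield"])
        assert set(cohorts) == {"canopy", "vi", "canopy+vi", "wavebands"}
        assert set(cohorts["canopy"].columns) == {
            "S1_CA", "S1_CT", "S2_CA", "S2_CT"}
        assert all(c.split("_")[1].startswith("R")
                   for c in cohorts["wavebands"].columns)

    def test_missing_cohort_columns_error(self, study_tables, fast_rf):
        from phenosel.prediction import CohortSpec
        m1, m2, _ = study_tables
        bad = {"canopy": CohortSpec("canopy", ("S9_CA",))}
        with pytest.raises(KeyError, match="S9_CA"):
            run_cohort_experiment(m1, m2, cohorts=bad, n_iter=1,
                                  rf_config=fast_rf, seed=0)

    def test_zero_signal_grid_near_zero(self, fast_rf):
        """With pure-noise predictors every mean rho stays near zero."""
        rng = np.random.default_rng(123)
        genos = [f"g{i:03d}" for i in range(80)]
        envs = ["E1", "E2"]
        idx = pd.MultiIndex.from_product([genos, envs],
                                         names=["genotype", "environment"])
        cols = {"seed_yield": rng.normal(size=len(idx))}
        for s in ("S1", "S2"):
            for t in ("CA", "CT", "R705", "R715"):
                cols[f"{s}_{t}"] = rng.normal(size=len(idx))
        from phenosel.datatypes import TraitTable
        m1 = TraitTable("genotype_env", pd.DataFrame(cols, index=idx))
        res = run_cohort_experiment(m1, None, methods=(1,),
                                    scenarios=("CV1",), n_iter=3,
                                    rf_config=fast_rf, seed=3)
        assert res.summary()["mean_rho"].abs().max() < 0.2
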