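import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from protomer import (
    ConfigurationError,
    FEATURE_NAMES,
    InputError,
    RankerModel,
    SyntheticSpec,
    TrainingError,
    TrainingTable,
    acceptance_capacity,
    enumerate_models,
    load_ranker,
    mir_feature_importance,
    predict_and_rank,
    save_ranker,
    select_models,
    synthetic_training_table,
    train,
)


class _StubEstimator:
    """Returns canned relative energies, one per featurized row."""

    def __init__(self, values):
        self.values = list(values)

    def predict(self, X):
        assert len(X) == len(self.values)
        return np.array(self.values, dtype=float)


def _stub_ranker(values, rmse=1.0):
    return RankerModel(
        estimator=_StubEstimator(values),
        training_rmse=rmse,
        feature_schema=FEATURE_NAMES,
        mode="[M+H]+",
        seed=0,
    )


class TestAcceptanceCapacity:
    def test_worked_example(self):
        stats = acceptance_capacity(3.0, [0.0, 2.0])
        assert stats.re_min == 0.0
        assert stats.sigma == 1.0
        assert stats.variance_s == 1.0
        assert stats.capacity == pytest.approx(0.5, abs=1e-15)

    def test_matches_direct_formula(self, rng):
        for _ in range(1000):
            rmse = float(rng.uniform(0, 10))
            res = rng.uniform(0, 20, size=int(rng.integers(2, 9)))
            res -= res.min()
            stats = acceptance_capacity(rmse, list(res))
            sigma = float(np.std(res))
            s = sigma**2
            if sigma + s < 1e-9:
                expected = 1.0
            else:
                expected = (rmse + res.min()) / (3.0 * (sigma + s))
            assert abs(stats.capacity - expected) <= 1e-12
            assert abs(stats.sigma**2 - stats.variance_s) < 1e-9

    def test_single_model_degeneracy_guard(self):
        assert acceptance_capacity(2.5, [4.2]).capacity == 1.0
        assert acceptance_capacity(2.5, [1.0, 1.0, 1.0]).capacity == 1.0

    @given(st.floats(0.01, 50.0), st.floats(0.01, 50.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_increasing_in_rmse(self, rmse, delta):
        res = [0.0, 2.0, 5.0]
        low = acceptance_capacity(rmse, res).capacity
        high = acceptance_capacity(rmse + delta, res).capacity
        assert high > low

    def test_empty_ensemble_rejected(self):
        with pytest.raises(InputError):
            acceptance_capacity(1.0, [])


class TestRanking:
    def _models(self, toy_lib):
        return enumerate_models(toy_lib["glycine"], "[M+H]+")

    def test_rank_order_follows_predicted_re(self, toy_lib):
        models = self._models(toy_lib)
        ranked = predict_and_rank(_stub_ranker([2.0, 0.5, 1.1]), models)
        by_original = sorted(ranked, key=lambda m: m.predicted_re)
        assert [m.initial_rank_r for m in by_original] == [1, 2, 3]
        assert [m.predicted_re for m in ranked] == [0.5, 1.1, 2.0]

    def test_ranks_are_a_permutation(self, toy_lib):
        models = self._models(toy_lib)
        ranked = predict_and_rank(_stub_ranker([5.0, 5.0, 0.1]), models)
        assert sorted(m.initial_rank_r for m in ranked) == [1, 2, 3]

    def test_tie_broken_by_lower_cba_index(self, toy_lib):
        models = self._models(toy_lib)
        ranked = predict_and_rank(_stub_ranker([1.0, 1.0, 1.0]), models)
        assert [m.cba_index for m in ranked] == sorted(m.cba_index for m in models)

    def test_single_model_gets_rank_one(self, toy_lib):
        models = enumerate_models(toy_lib["pyridine"], "[M+H]+")
        ranked = predict_and_rank(_stub_ranker([3.3]), models)
        assert ranked[0].initial_rank_r == 1

    def test_schema_mismatch_rejected(self, toy_lib):
        bad = _stub_ranker([1.0])
        bad.feature_schema = ("only", "three", "features")
        with pytest.raises(ConfigurationError):
            predict_and_rank(bad, self._models(toy_lib))


class TestSelection:
    def _ranked(self, toy_lib, n):
        lib = {3: "glycine", 2: "ethanolamine", 1: "pyridine"}
        models = enumerate_models(toy_lib[lib[n]], "[M+H]+")
        return predict_and_rank(_stub_ranker(range(n)), models)

    def test_fractional_capacity_forwards_only_leader(self, toy_lib):
        ranked = self._ranked(toy_lib, 3)
        stats = acceptance_capacity(0.4, [m.predicted_re for m in ranked])
        assert stats.capacity < 1
        selected = select_models(ranked, stats)
        assert [m.initial_rank_r for m in selected] == [1]

    def test_ceiling_rule(self, toy_lib):
        ranked = self._ranked(toy_lib, 3)
        stats = acceptance_capacity(0.0, [0.0, 0.2, 0.4])
        stats.capacity = 2.2
        assert len(select_models(ranked, stats)) == 3

    def test_capacity_clamped_to_ensemble_size(self, toy_lib):
        ranked = self._ranked(toy_lib, 3)
        stats = acceptance_capacity(1000.0, [m.predicted_re for m in ranked])
        assert len(select_models(ranked, stats)) == 3

    def test_never_empty_and_keeps_rank_one(self, toy_lib, rng):
        ranked = self._ranked(toy_lib, 3)
        for _ in range(50):
            stats = acceptance_capacity(
                float(rng.uniform(0, 5)), list(rng.uniform(0, 10, 3))
            )
            selected = select_models(ranked, stats)
            assert selected
            assert selected[0].initial_rank_r == 1


class TestTraining:
    def test_same_seed_bitwise_identical_predictions(self):
        table = synthetic_training_table(SyntheticSpec(n_systems=30, seed=3))
        a = train(table, seed=3)
        b = train(table, seed=3)
        np.testing.assert_array_equal(a.predict(table.X), b.predict(table.X))
        assert a.training_rmse == b.training_rmse

    def test_constant_labels_zero_rmse(self):
        frame = pd.DataFrame(
            {
                "f1": np.linspace(0, 1, 40),
                "f2": np.linspace(1, 0, 40),
                "re_label": np.zeros(40),
                "system_id": [f"s{i//4}" for i in range(40)],
            }
        )
        model = train(TrainingTable(frame), seed=0)
        assert model.training_rmse <= 1e-6

    def test_too_small_table_rejected(self):
        frame = pd.DataFrame(
            {"f1": [0.0, 1.0], "re_label": [0.0, 0.0], "system_id": ["a", "b"]}
        )
        with pytest.raises(TrainingError):
            train(TrainingTable(frame), seed=0)

    def test_constant_features_rejected(self):
        frame = pd.DataFrame(
            {
                "f1": np.ones(40),
                "re_label": np.abs(np.linspace(-1, 1, 40)) * 0,
                "system_id": [f"s{i//4}" for i in range(40)],
            }
        )
        with pytest.raises(TrainingError, match="constant"):
            train(TrainingTable(frame), seed=0)

    def test_recovers_planted_monotone_signal(self):
        table, truth = synthetic_training_table(
            SyntheticSpec(n_systems=60, seed=9), return_truth=True
        )
        model = train(table, seed=9)
        from scipy.stats import spearmanr

        pred = model.predict(table.X)
        assert spearmanr(pred, truth).statistic >= 0.8

    def test_label_invariants_enforced(self):
        with pytest.raises(InputError):
            TrainingTable(
                pd.DataFrame(
                    {"f1": [0.0, 1.0], "re_label": [-0.5, 0.5], "system_id": ["a", "a"]}
                )
            )
        with pytest.raises(InputError, match="min"):
            TrainingTable(
                pd.DataFrame(
                    {"f1": [0.0, 1.0], "re_label": [1.0, 2.0], "system_id": ["a", "a"]}
                )
            )


class TestFeatureImportance:
    def test_planted_feature_dominates_and_noise_is_null(self):
        table = synthetic_training_table(
            SyntheticSpec(n_systems=40, seed=13, extra_noise_features=("pure_noise",))
        )
        scores = mir_feature_importance(
            table, hyperparams={"n_estimators": 120}, seed=13, n_repeats=1
        )
        assert set(scores) == set(table.feature_names)
        planted = scores["dist_cba_coe"]
        assert max(scores, key=scores.get) == "dist_cba_coe"
        assert abs(scores["pure_noise"]) < 0.1 * planted


class TestPersistence:
    def test_round_trip(self, tmp_path):
        table = synthetic_training_table(SyntheticSpec(n_systems=30, seed=4))
        model = train(table, seed=4)
        path = tmp_path / "ranker.joblib"
        save_ranker(model, path)
        back = load_ranker(path)
        assert back.feature_schema == model.feature_schema
        assert back.training_rmse == model.training_rmse
        assert back.mode == model.mode
        np.testing.assert_array_equal(back.predict(table.X), model.predict(table.X))

    def test_version_tag_checked(self, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        joblib.dump({"format_version": 99}, path)
        with pytest.raises(ConfigurationError, match="version"):
            load_ranker(path)
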