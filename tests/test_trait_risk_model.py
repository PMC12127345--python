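import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.inspection import permutation_importance as sk_permutation_importance

from oasisrisk import importance_ranking as ir
from oasisrisk import trait_risk_model as trm
from oasisrisk.errors import ConfigurationError, ValidationError


def _balanced_matrix(n_per_class=25, seed=0, informative=True):
    """4-class toy data: two continuous features carry the class signal."""
    rng = np.random.default_rng(seed)
    classes = list(ir.RISK_LEVELS)
    rows, ys = [], []
    for k, cls in enumerate(classes):
        for _ in range(n_per_class):
            x1 = k + rng.normal(0, 0.15) if informative else rng.normal()
            x2 = -k + rng.normal(0, 0.15) if informative else rng.normal()
            rows.append({"sla": x1, "hundred_grain_weight": x2, "noise": rng.normal()})
            ys.append(cls)
    X = pd.DataFrame(rows)
    y = pd.Series(pd.Categorical(ys, categories=classes, ordered=True), name="risk_level")
    return trm.FeatureMatrix(X=X, y=y, groups={})


class TestEncodeFeatures:
    def test_column_arity_and_order(self, small_world):
        rk = ir.rank_and_classify(small_world["survey"])
        fm = trm.encode_features(small_world["traits"], rk)
        cont = [c for c in fm.X.columns if "=" not in c]
        assert cont == ["sla", "height", "hundred_grain_weight", "flowering_duration"]
        # one-hot columns sum to 1 per categorical variable
        for var, cols in fm.groups.items():
            assert np.allclose(fm.X[cols].sum(axis=1), 1.0)

    def test_deterministic_column_order(self, small_world):
        rk = ir.rank_and_classify(small_world["survey"])
        a = trm.encode_features(small_world["traits"], rk)
        b = trm.encode_features(small_world["traits"], rk)
        assert list(a.X.columns) == list(b.X.columns)

    def test_missing_species_error(self, small_world):
        rk = ir.rank_and_classify(small_world["survey"])
        rk.loc[0, "species"] = "unknown_sp"
        with pytest.raises(ValidationError, match="unknown_sp"):
            trm.encode_features(small_world["traits"], rk)


class TestSplit:
    def test_sizes_and_partition(self):
        fm = _balanced_matrix()
        train, test = trm.split_train_test(fm, 0.7, seed=0)
        assert len(train) == 70 and len(test) == 30
        # per-class train counts within rounding of 0.7 * 25
        counts = train.y.value_counts()
        assert set(counts.to_numpy()) <= {17, 18}

    def test_same_seed_same_split(self):
        fm = _balanced_matrix()
        a1, _ = trm.split_train_test(fm, 0.7, seed=3)
        a2, _ = trm.split_train_test(fm, 0.7, seed=3)
        pd.testing.assert_frame_equal(a1.X, a2.X)

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            trm.split_train_test(_balanced_matrix(), 1.5, seed=0)


class TestFitAndEvaluate:
    @pytest.mark.parametrize("algorithm", ["forest", "boosting"])
    def test_separable_data_perfect_fit(self, algorithm):
        fm = _balanced_matrix()
        hp = {"n_estimators": 50} if algorithm == "forest" else {"n_estimators": 50, "max_depth": 3, "learning_rate": 0.3}
        model = trm.fit_classifier(fm, algorithm, hyperparams=hp, seed=0)
        rep = trm.evaluate(model, fm)
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert np.allclose(rep.per_class["f1"], 1.0)

    def test_unknown_algorithm(self):
        with pytest.raises(ConfigurationError):
            trm.fit_classifier(_balanced_matrix(), "svm")

    def test_deterministic_given_seed(self):
        fm = _balanced_matrix(informative=False)
        m1 = trm.fit_classifier(fm, "forest", hyperparams={"n_estimators": 30}, seed=5)
        m2 = trm.fit_classifier(fm, "forest", hyperparams={"n_estimators": 30}, seed=5)
        assert (m1.predict(fm.X) == m2.predict(fm.X)).all()


class TestMetricIdentities:
    def test_hand_computed_binary_kappa(self):
        conf = pd.DataFrame(
            [[40, 10, 0, 0], [5, 45, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]],
            index=ir.RISK_LEVELS,
            columns=ir.RISK_LEVELS,
        )
        rep = trm.report_from_confusion(conf)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.kappa == pytest.approx(0.70)

    def test_single_class_prediction_on_balanced_test(self):
        y_true = np.repeat(list(ir.RISK_LEVELS), 10)
        conf = pd.DataFrame(0, index=ir.RISK_LEVELS, columns=ir.RISK_LEVELS)
        for c in ir.RISK_LEVELS:
            conf.loc[c, "High"] = 10
        rep = trm.report_from_confusion(conf)
        assert rep.accuracy == pytest.approx(0.25)
        assert rep.kappa == pytest.approx(0.0)
        assert len(y_true) == conf.to_numpy().sum()

    def test_absent_class_is_nan_not_zero(self):
        conf = pd.DataFrame(
            [[5, 0, 0, 0], [0, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 0]],
            index=ir.RISK_LEVELS,
            columns=ir.RISK_LEVELS,
        )
        rep = trm.report_from_confusion(conf)
        assert np.isnan(rep.per_class.loc["No", "recall"])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_identities_on_random_confusions(self, seed):
        """accuracy = trace/n; F1 = harmonic mean; kappa matches a literal
        chance-agreement computation."""
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 30, size=(4, 4))
        if m.sum() == 0:
            m[0, 0] = 1
        conf = pd.DataFrame(m, index=ir.RISK_LEVELS, columns=ir.RISK_LEVELS)
        rep = trm.report_from_confusion(conf)
        n = m.sum()
        assert rep.accuracy == pytest.approx(np.trace(m) / n, abs=1e-12)
        p_o = np.trace(m) / n
        p_e = sum(m[i, :].sum() * m[:, i].sum() for i in range(4)) / n**2
        if p_e < 1:
            assert rep.kappa == pytest.approx((p_o - p_e) / (1 - p_e), abs=1e-12)
        for cls in ir.RISK_LEVELS:
            p, r, f1 = rep.per_class.loc[cls, ["precision", "recall", "f1"]]
            if np.isfinite(p) and np.isfinite(r) and (p + r) > 0:
                assert f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)


class TestPermutationImportance:
    def test_null_feature_has_near_zero_drop(self):
        fm = _balanced_matrix(seed=2)
        model = trm.fit_classifier(fm, "forest", hyperparams={"n_estimators": 100}, seed=0)
        imp = trm.permutation_importance(model, fm, n_repeats=50, seed=0)
        row = imp.set_index("feature").loc["noise"]
        assert abs(row["mean_drop"]) < max(2 * row["sd_drop"], 0.02)

    def test_fully_determining_feature_drop_half(self):
        """A binary feature that fully determines a balanced binary label
        loses ~0.5 accuracy under permutation (analytic expectation)."""
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 400).astype(float)
        X = pd.DataFrame({"x": x})
        y = pd.Series(
            pd.Categorical(
                np.where(x > 0.5, "High", "No"), categories=list(ir.RISK_LEVELS), ordered=True
            )
        )
        fm = trm.FeatureMatrix(X=X, y=y, groups={})
        model = trm.fit_classifier(fm, "forest", hyperparams={"n_estimators": 20}, seed=0)
        imp = trm.permutation_importance(model, fm, n_repeats=50, seed=1)
        assert imp["mean_drop"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_xor_drops_are_not_additive(self):
        """On an XOR fixture, jointly permuting both inputs drops accuracy by
        ~0.5 while the single-feature drops already sum to ~1.0."""
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 600).astype(float)
        z = rng.integers(0, 2, 600).astype(float)
        label = np.where((x != z), "High", "No")
        X = pd.DataFrame({"x": x, "z": z})
        y = pd.Series(pd.Categorical(label, categories=list(ir.RISK_LEVELS), ordered=True))
        fm = trm.FeatureMatrix(X=X, y=y, groups={"both": ["x", "z"]})
        model = trm.fit_classifier(fm, "forest", hyperparams={"n_estimators": 50}, seed=0)
        per_col = trm.permutation_importance(model, fm, n_repeats=30, seed=0, grouping="column")
        joint = trm.permutation_importance(model, fm, n_repeats=30, seed=0, grouping="variable")
        sum_single = per_col["mean_drop"].sum()
        joint_drop = joint.set_index("feature").loc["both", "mean_drop"]
        assert sum_single > joint_drop + 0.3

    def test_matches_sklearn_oracle_on_columns(self):
        """Independent cross-check: sklearn's permutation_importance on the
        raw estimator agrees on the importance ranking."""
        fm = _balanced_matrix(seed=4)
        model = trm.fit_classifier(fm, "forest", hyperparams={"n_estimators": 100}, seed=0)
        ours = trm.permutation_importance(model, fm, n_repeats=30, seed=0)
        y_codes = pd.Categorical(fm.y, categories=model.classes).codes
        theirs = sk_permutation_importance(
            model.est, fm.X.to_numpy(), y_codes, n_repeats=30, random_state=0
        )
        their_order = fm.X.columns[np.argsort(-theirs.importances_mean)].tolist()
        assert ours["feature"].tolist()[:2] == their_order[:2]

    def test_repeats_floor(self):
        fm = _balanced_matrix()
        model = trm.fit_classifier(fm, "forest", hyperparams={"n_estimators": 10}, seed=0)
        with pytest.raises(ConfigurationError):
            trm.permutation_importance(model, fm, n_repeats=1)


class TestConcordance:
    def test_identical_tables(self):
        t = pd.DataFrame({"feature": list("abcde"), "mean_drop": [5, 4, 3, 2, 1.0]})
        out = trm.importance_concordance(t, t)
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["top_k_equal"]

    def test_reversed_ranking(self):
        a = pd.DataFrame({"feature": list("abcde"), "mean_drop": [5, 4, 3, 2, 1.0]})
        b = pd.DataFrame({"feature": list("abcde"), "mean_drop": [1, 2, 3, 4, 5.0]})
        assert trm.importance_concordance(a, b)["spearman_rho"] == pytest.approx(-1.0)

    def test_top2_set_semantics(self):
        a = pd.DataFrame({"feature": ["sla", "hgw", "c"], "mean_drop": [3, 2, 1.0]})
        b = pd.DataFrame({"feature": ["sla", "hgw", "c"], "mean_drop": [2, 3, 1.0]})
        assert trm.importance_concordance(a, b)["top_k_equal"]

    def test_mismatched_features(self):
        a = pd.DataFrame({"feature": ["x"], "mean_drop": [1.0]})
        b = pd.DataFrame({"feature": ["y"], "mean_drop": [1.0]})
        with pytest.raises(ValidationError):
            trm.importance_concordance(a, b)
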