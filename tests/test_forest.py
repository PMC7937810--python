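"""Random-forest validation: preprocessing, PFE, selection, evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from hippodx import (
    CohortSpec,
    ForestValidation,
    PFEConfig,
    evaluate,
    normalize_to_tiv,
    preprocess_features,
    run_pfe,
    select_optimal_n,
    simulate_cohort,
)
from hippodx.forest import PFECurve
from hippodx.io import FeatureTable

FAST = PFEConfig(n_splits_pfe=8, n_trees=60, n_splits_eval=25, seed=7)


def make_table():
    """2 global + 4 volume + 2 thickness features, 12 subjects."""
    rng = np.random.default_rng(0)
    idx = pd.Index([f"s{i}" for i in range(12)], name="subject_id")
    feats = {
        "BrainSegVol": rng.normal(1.1e6, 1e4, 12),
        "CortexVol": rng.normal(5e5, 1e4, 12),
        "Hippo_right": rng.normal(3400, 100, 12),
        "Hippo_left": rng.normal(3350, 100, 12),
        "Amygdala_right": rng.normal(1500, 60, 12),
        "Amygdala_left": rng.normal(1480, 60, 12),
        "ctx_thickness_a": rng.normal(2.5, 0.1, 12),
        "ctx_thickness_b": rng.normal(2.2, 0.1, 12),
        "Hippo_asym": rng.normal(0, 3, 12),
    }
    registry = {n: ("thickness" if "thickness" in n else "volume",
                    "global" if n in ("BrainSegVol", "CortexVol") else "bilateral")
                for n in feats}
    return FeatureTable(
        data=pd.DataFrame(feats, index=idx),
        groups=pd.Series(["HC"] * 6 + ["RHS"] * 3 + ["LHS"] * 3, index=idx),
        tiv=pd.Series(rng.normal(1.5e6, 1e5, 12), index=idx),
        registry=registry,
    )


class TestPreprocess:
    def test_drops_globals_and_asymmetry_keeps_six(self):
        X, y = preprocess_features(make_table())
        assert X.shape[1] == 6
        assert not any("BrainSeg" in c or "Cortex" in c or c.endswith("_asym")
                       for c in X.columns)

    def test_volume_columns_equal_normalize_to_tiv(self):
        table = make_table()
        X, _ = preprocess_features(table)
        expected = normalize_to_tiv(table.data["Hippo_right"].to_numpy(),
                                    table.tiv.to_numpy())
        assert np.allclose(X["Hippo_right_pct"], expected)

    def test_thickness_passes_through_unscaled(self):
        table = make_table()
        X, _ = preprocess_features(table)
        assert np.allclose(X["ctx_thickness_a"], table.data["ctx_thickness_a"])


def toy_xy(n=40, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    y = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2))
    sig = np.r_[rng.normal(0, 1, n // 2), rng.normal(6, 1, n // 2)] if informative \
        else rng.normal(size=n)
    X = pd.DataFrame({"signal": sig, "noise": rng.normal(size=n)})
    return X, y


class TestPFE:
    def test_noise_feature_eliminated_first(self):
        X, y = toy_xy()
        curve = run_pfe(X, y, FAST)
        assert curve.elimination_order[0] == "noise"
        # a single separating feature performs as well as both
        assert abs(curve.mean_accuracy[0] - curve.mean_accuracy[1]) < 0.1

    def test_single_feature_curve_has_one_point(self):
        X, y = toy_xy()
        curve = run_pfe(X[["signal"]], y, FAST)
        assert list(curve.n_features) == [1]
        assert curve.elimination_order == ["signal"]

    def test_class_below_two_members_errors(self):
        X, y = toy_xy()
        y = y.copy()
        y.iloc[:] = "a"
        y.iloc[0] = "b"
        with pytest.raises(ValueError, match=">= 2"):
            run_pfe(X, y, FAST)

    def test_permuted_labels_accuracy_near_chance(self):
        rng = np.random.default_rng(3)
        X, y = toy_xy(n=40, informative=True)
        y_perm = pd.Series(rng.permutation(y.to_numpy()))
        curve = run_pfe(X, y_perm, FAST)
        se = curve.sd_accuracy / np.sqrt(curve.n_splits)
        assert (np.abs(curve.mean_accuracy - 0.5) <= 3 * np.maximum(se, 0.05)).all()

    def test_deterministic_under_fixed_seed(self):
        X, y = toy_xy()
        c1, c2 = run_pfe(X, y, FAST), run_pfe(X, y, FAST)
        assert np.array_equal(c1.mean_accuracy, c2.mean_accuracy)
        assert c1.elimination_order == c2.elimination_order


class TestSelectOptimalN:
    def _curve(self, means, sds=None):
        n = len(means)
        return PFECurve(
            n_features=np.arange(1, n + 1),
            mean_accuracy=np.asarray(means, dtype=float),
            sd_accuracy=np.asarray(sds if sds is not None else [0.05] * n),
            elimination_order=[f"f{i}" for i in range(n)],
            n_splits=30,
        )

    def test_flat_curve_selects_one(self):
        assert select_optimal_n(self._curve([0.9, 0.9, 0.9, 0.9])) == 1

    def test_strictly_increasing_selects_all(self):
        assert select_optimal_n(self._curve([0.5, 0.6, 0.7, 0.9], sds=[0.01] * 4)) == 4

    def test_step_curve_selects_plateau_start(self):
        means = [0.50, 0.55, 0.60, 0.90, 0.905, 0.9, 0.91]
        # SE of the best point = 0.1/sqrt(30) ~ 0.018: plateau starts at N=4
        assert select_optimal_n(self._curve(means, sds=[0.1] * 7)) == 4


class TestEvaluate:
    def test_separable_toy_perfect(self):
        X, y = toy_xy(seed=5)
        rep = evaluate(X, y, ["signal"], FAST)
        assert rep.mean_accuracy == 1.0
        off_diag = rep.confusion.to_numpy()[~np.eye(2, dtype=bool)]
        assert (off_diag == 0).all()
        assert rep.macro_auc == 1.0

    def test_confusion_total_is_sum_of_fold_test_sizes(self):
        X, y = toy_xy(seed=6)
        rep = evaluate(X, y, ["signal", "noise"], FAST)
        test_size = len(y) - int(round(FAST.train_fraction * len(y)))
        assert rep.confusion.to_numpy().sum() == FAST.n_splits_eval * test_size

    def test_probability_vectors_sum_to_one(self):
        X, y = toy_xy(seed=8)
        rep = evaluate(X, y, ["signal", "noise"], FAST)
        sums = rep.per_subject_prob.dropna().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_uninformative_features_near_chance(self):
        X, y = toy_xy(seed=9, informative=False)
        rep = evaluate(X, y, list(X.columns), FAST)
        se = rep.accuracies.std(ddof=1) / np.sqrt(len(rep.accuracies))
        assert abs(rep.mean_accuracy - 0.5) <= 3 * max(se, 0.05)

    def test_unknown_feature_errors(self):
        X, y = toy_xy()
        with pytest.raises(KeyError):
            evaluate(X, y, ["nope"], FAST)

    def test_deterministic_under_fixed_seed(self):
        X, y = toy_xy(seed=10)
        r1 = evaluate(X, y, ["signal", "noise"], FAST)
        r2 = evaluate(X, y, ["signal", "noise"], FAST)
        assert np.array_equal(r1.accuracies, r2.accuracies)
        pd.testing.assert_frame_equal(r1.per_subject_prob, r2.per_subject_prob)


class TestGiniImportances:
    def test_single_forest_importances_sum_to_one(self):
        X, y = toy_xy(seed=12)
        rf = RandomForestClassifier(n_estimators=100, max_features="sqrt",
                                    random_state=0, n_jobs=1).fit(X, y)
        imp = rf.feature_importances_
        assert (imp >= 0).all()
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_normalized_importances_mean_is_one(self):
        # dividing by the trivial level 1/N makes the per-fold mean equal N/N = 1
        X, y = toy_xy(seed=13)
        rep = evaluate(X, y, ["signal", "noise"], FAST)
        assert np.allclose(rep.importances.sum(axis=1), 2.0, atol=1e-9)


class TestModelInterface:
    @pytest.fixture(scope="class")
    def cohort(self):
        table, _ = simulate_cohort(
            CohortSpec(n_hc=16, n_rhs=6, n_lhs=6, seed=21,
                       n_nuisance_volume=3, n_nuisance_thickness=3)
        )
        return table

    def test_missing_group_errors(self, cohort):
        with pytest.raises(ValueError, match="absent"):
            ForestValidation.from_table(cohort.subset(["HC", "RHS"]), "HC_vs_HS")

    def test_three_class_confusion_shape_and_summary(self, cohort):
        res = ForestValidation.from_table(cohort, "three_class", FAST).fit()
        assert res.report.confusion.shape == (3, 3)
        assert "Random-forest validation" in res.summary()
        d = res.to_dict()
        assert d["selected_n"] == res.selected_n
        assert len(d["pfe_curve"]["elimination_order"]) == res.pfe_curve.n_features.max()

    def test_hc_vs_hs_merges_patients(self, cohort):
        res = ForestValidation.from_table(cohort, "HC_vs_HS", FAST).fit()
        assert res.report.classes == ["HC", "HS"]
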