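"""ROC analysis: pair-counting AUC, step curves, Youden cutoffs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from hippodx import DiagnosticROC, auc, diagnostic_table, optimal_cutoff, roc_points


def brute_force_auc(scores, labels, direction="lower_is_positive"):
    """Independent oracle: enumerate all (positive, negative) pairs."""
    s = np.asarray(scores, dtype=float)
    if direction == "lower_is_positive":
        s = -s
    pos = s[np.asarray(labels) == 1]
    neg = s[np.asarray(labels) == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def random_instance(rng, tie_prone=True):
    n = int(rng.integers(4, 50))
    labels = np.zeros(n, dtype=int)
    labels[: int(rng.integers(1, n - 1))] = 1
    rng.shuffle(labels)
    scores = rng.integers(0, 8, n).astype(float) if tie_prone else rng.normal(size=n)
    return scores, labels


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 5, 6], [1, 1, 0, 0], "lower_is_positive") == 1.0

    def test_all_tied_is_half(self):
        assert auc([3, 3, 3, 3], [1, 1, 0, 0]) == 0.5

    def test_tied_pair_counts_half(self):
        # positives {1,2}, negatives {1,3}: wins 2, tie 1, loss 1 -> 2.5/4
        assert auc([1, 2, 1, 3], [1, 1, 0, 0], "lower_is_positive") == 0.625

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    @pytest.mark.parametrize("direction", ["lower_is_positive", "higher_is_positive"])
    def test_matches_brute_force_pair_counting(self, direction):
        rng = np.random.default_rng(42)
        for _ in range(40):
            scores, labels = random_instance(rng)
            assert auc(scores, labels, direction) == pytest.approx(
                brute_force_auc(scores, labels, direction), abs=1e-12
            )

    def test_matches_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores, labels = random_instance(rng)
            assert auc(scores, labels, "higher_is_positive") == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_direction_complement_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            scores, labels = random_instance(rng)
            total = auc(scores, labels, "lower_is_positive") + auc(
                scores, labels, "higher_is_positive"
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.integers(-500, 500), min_size=4, max_size=30, unique=True),
           st.integers(1, 3))
    def test_monotone_transform_invariance(self, raw, n_pos):
        scores = np.asarray(raw, dtype=float) / 100.0
        labels = np.zeros(len(scores), dtype=int)
        labels[:n_pos] = 1
        base = auc(scores, labels, "higher_is_positive")
        for f in (np.exp, lambda x: x**3, lambda x: 3 * x + 2):
            assert auc(f(scores), labels, "higher_is_positive") == \
                pytest.approx(base, abs=1e-12)


class TestROCPoints:
    def test_two_point_perfect_curve(self):
        r = roc_points([1.0, 5.0], [1, 0], "lower_is_positive")
        assert np.allclose(r.one_minus_spec, [0, 0, 1])
        assert np.allclose(r.sens, [0, 1, 1])
        assert r.auc == 1.0

    def test_trapezoid_area_equals_auc(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            scores, labels = random_instance(rng)
            r = roc_points(scores, labels)
            assert r.trapezoid_area() == pytest.approx(r.auc, abs=1e-12)

    def test_curve_monotone_to_corner(self):
        rng = np.random.default_rng(3)
        scores, labels = random_instance(rng)
        r = roc_points(scores, labels)
        assert (np.diff(r.sens) >= 0).all() and (np.diff(r.one_minus_spec) >= 0).all()
        assert (r.sens[0], r.one_minus_spec[0]) == (0.0, 0.0)
        assert (r.sens[-1], r.one_minus_spec[-1]) == (1.0, 1.0)

    def test_direction_reflection(self):
        rng = np.random.default_rng(23)
        scores, labels = random_instance(rng)
        a_lo = roc_points(scores, labels, "lower_is_positive").auc
        a_hi = roc_points(scores, labels, "higher_is_positive").auc
        assert a_lo == pytest.approx(1 - a_hi, abs=1e-12)


def brute_force_cutoff(scores, labels, direction):
    """Oracle: scan a dense threshold grid for the best Youden J."""
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == 1
    lo, hi = s.min() - 1, s.max() + 1
    grid = np.unique(np.r_[np.linspace(lo, hi, 4001), s])
    best = (-np.inf, -np.inf)
    for t in grid:
        pred = s <= t if direction == "lower_is_positive" else s >= t
        sens = (pred & pos).sum() / pos.sum()
        fpr = (pred & ~pos).sum() / (~pos).sum()
        best = max(best, (sens - fpr, sens))
    return best


class TestOptimalCutoff:
    def test_perfect_separation_corner(self):
        r = roc_points([1, 2, 8, 9], [1, 1, 0, 0], "lower_is_positive")
        c = optimal_cutoff(r)
        assert (c.sens, c.one_minus_spec) == (1.0, 0.0)
        assert 2 < c.ref_value < 8

    def test_forced_midpoint_between_singletons(self):
        r = roc_points([-47.0, 3.6], [1, 0], "lower_is_positive")
        c = optimal_cutoff(r)
        assert -47 < c.ref_value < 3.6
        assert c.ref_value == pytest.approx((-47 + 3.6) / 2)

    @pytest.mark.parametrize("direction", ["lower_is_positive", "higher_is_positive"])
    def test_six_point_instances_match_threshold_scan(self, direction):
        rng = np.random.default_rng(31)
        for _ in range(30):
            scores = rng.integers(0, 6, 6).astype(float)
            labels = np.array([1, 1, 1, 0, 0, 0])
            rng.shuffle(labels)
            r = roc_points(scores, labels, direction)
            c = optimal_cutoff(r)
            j_star, sens_star = brute_force_cutoff(scores, labels, direction)
            assert c.sens - c.one_minus_spec == pytest.approx(j_star, abs=1e-12)
            assert c.sens == pytest.approx(sens_star, abs=1e-12)
            # the reported threshold actually attains the optimum
            pred = scores <= c.ref_value if direction == "lower_is_positive" else scores >= c.ref_value
            sens = (pred & (labels == 1)).sum() / 3
            fpr = (pred & (labels == 0)).sum() / 3
            assert sens - fpr == pytest.approx(j_star, abs=1e-12)


class TestDiagnosticTable:
    @pytest.fixture()
    def frame(self):
        rng = np.random.default_rng(8)
        groups = pd.Series(["HC"] * 20 + ["RHS"] * 10 + ["LHS"] * 10)
        df = pd.DataFrame({
            "vol": np.r_[rng.normal(10, 1, 20), rng.normal(6, 1, 10), rng.normal(10, 1, 10)],
            "asym": np.r_[rng.normal(2, 3, 20), rng.normal(-40, 8, 10), rng.normal(45, 8, 10)],
        })
        return df, groups

    def test_auc_column_consistent_with_auc(self, frame):
        df, groups = frame
        tasks = [dict(column="vol", positive_group="RHS", direction="lower_is_positive"),
                 dict(column="asym", positive_group="LHS", direction="higher_is_positive")]
        out = diagnostic_table(df, groups, tasks)
        for _, row in out.iterrows():
            mask = groups.isin([row.task.split("_vs_")[0], "HC"])
            expected = auc(df.loc[mask, row.discriminator], groups[mask],
                           row.direction, positive_label=row.task.split("_vs_")[0])
            assert row.auc == pytest.approx(expected, abs=1e-12)

    def test_swapping_positive_group_complements_auc(self, frame):
        df, groups = frame
        mask = groups.isin(["RHS", "HC"])
        a = auc(df.loc[mask, "vol"], groups[mask], "lower_is_positive", positive_label="RHS")
        b = auc(df.loc[mask, "vol"], groups[mask], "lower_is_positive", positive_label="HC")
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_unknown_column_or_group_errors(self, frame):
        df, groups = frame
        with pytest.raises(KeyError):
            diagnostic_table(df, groups, [dict(column="nope", positive_group="RHS")])
        with pytest.raises(ValueError):
            diagnostic_table(df, groups, [dict(column="vol", positive_group="XXX")])

    def test_model_results_summary(self, frame):
        df, groups = frame
        mask = groups.isin(["RHS", "HC"])
        res = DiagnosticROC(df.loc[mask, "vol"], groups[mask], "lower_is_positive",
                            positive_label="RHS", name="vol", task="RHS_vs_HC").fit()
        text = res.summary()
        assert "AUC" in text and "ref. value" in text
        assert res.auc == res.roc.auc
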