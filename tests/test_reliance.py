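"""Grouped model reliance: score arithmetic, permutation engine, CV loop."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

import grouprely as g
from grouprely.reliance import DegenerateBaselineWarning, _two_stage_means


class TestRelianceValue:
    def test_ratio_arithmetic(self):
        # errors 0.75 vs 0.5, group of 2: (1/2)(0.75/0.5 - 1) = 0.25
        mr, deg = g.reliance_value(0.5, 0.25, 2, normalize=True, mode="ratio")
        assert mr == pytest.approx(0.25)
        assert not deg

    @pytest.mark.parametrize("mode", ["ratio", "difference"])
    def test_equal_accuracies_give_zero(self, mode):
        mr, _ = g.reliance_value(0.6, 0.6, 3, mode=mode)
        assert mr == 0.0

    @pytest.mark.parametrize("mode", ["ratio", "difference"])
    def test_permutation_helping_gives_negative(self, mode):
        mr, _ = g.reliance_value(0.5, 0.7, 2, mode=mode)
        assert mr < 0

    def test_perfect_baseline_degenerates_to_difference_with_warning(self):
        with pytest.warns(DegenerateBaselineWarning):
            mr, deg = g.reliance_value(1.0, 0.4, 2, mode="ratio")
        assert deg
        assert mr == pytest.approx((0.6 - 0.0) / 2)

    def test_singleton_group_normalization_is_identity(self):
        a, _ = g.reliance_value(0.5, 0.3, 1, normalize=True)
        b, _ = g.reliance_value(0.5, 0.3, 1, normalize=False)
        assert a == b


class TestPermuteGroup:
    def test_joint_preserves_row_multiset(self, rng):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        out = g.permute_group(X, [0, 1], rng, mode="joint")
        rows = {tuple(r) for r in out}
        assert rows == {(1.0, 10.0), (2.0, 20.0), (3.0, 30.0)}

    def test_single_row_is_identity(self, rng):
        X = np.array([[1.0, 2.0]])
        assert np.array_equal(g.permute_group(X, [0], rng), X)

    def test_untouched_columns_and_no_mutation(self, rng):
        X = np.arange(12.0).reshape(4, 3)
        X0 = X.copy()
        out = g.permute_group(X, [1], rng)
        assert np.array_equal(X, X0)
        assert np.array_equal(out[:, [0, 2]], X[:, [0, 2]])

    def test_independent_breaks_within_group_pairing(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.arange(30.0), np.arange(30.0)])
        out = g.permute_group(X, [0, 1], rng, mode="independent")
        assert not np.array_equal(out[:, 0], out[:, 1])  # pairing destroyed

    def test_joint_keeps_within_group_pairing(self, rng):
        X = np.column_stack([np.arange(30.0), np.arange(30.0)])
        out = g.permute_group(X, [0, 1], rng, mode="joint")
        assert np.array_equal(out[:, 0], out[:, 1])

    def test_empty_group_rejected(self, rng):
        with pytest.raises(g.ValidationError, match="empty"):
            g.permute_group(np.zeros((2, 2)), [], rng)

    def test_joint_orders_are_uniform(self):
        """Each of the 3! joint row orders appears with frequency 1/6 +- MC error."""
        rng = np.random.default_rng(42)
        X = np.array([[0.0], [1.0], [2.0]])
        n_draws = 1800
        counts = {}
        for _ in range(n_draws):
            order = tuple(g.permute_group(X, [0], rng)[:, 0].astype(int))
            counts[order] = counts.get(order, 0) + 1
        assert len(counts) == 6
        tol = 3 * np.sqrt((1 / 6) * (5 / 6) / n_draws)
        for c in counts.values():
            assert abs(c / n_draws - 1 / 6) < tol


class TestStratifiedFolds:
    def test_proportions_within_one_trial_per_class(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], [37, 41, 30])
        folds = g.stratified_folds(y, 10, rng)
        assert sorted(np.concatenate(folds).tolist()) == list(range(len(y)))
        for c, total in zip([0, 1, 2], [37, 41, 30]):
            per_fold = [np.sum(y[f] == c) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1
            # surplus goes to the lowest-indexed folds
            assert per_fold == sorted(per_fold, reverse=True)

    def test_seeded_shuffle_is_deterministic(self):
        y = np.repeat([0, 1], 20)
        f1 = g.stratified_folds(y, 4, np.random.default_rng(9))
        f2 = g.stratified_folds(y, 4, np.random.default_rng(9))
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_small_class_and_bad_k_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(g.ValidationError, match="fewer than k"):
            g.stratified_folds(np.array([0] * 20 + [1] * 3), 10, rng)
        with pytest.raises(g.ValidationError, match="k"):
            g.stratified_folds(np.repeat([0, 1], 10), 1, rng)


def _fitted_tree(seed=0, n_train=40, p=3):
    """A deterministic fitted model plus a validation fold it cannot ace."""
    rng = np.random.default_rng(seed)
    Xtr = rng.standard_normal((n_train, p))
    ytr = (Xtr[:, 0] + 0.5 * rng.standard_normal(n_train) > 0).astype(int)
    model = DecisionTreeClassifier(random_state=0, max_depth=3).fit(Xtr, ytr)
    Xv = rng.standard_normal((6, p))
    yv = (Xv[:, 0] > 0).astype(int)
    yv[:2] ^= 1  # guarantee an imperfect baseline on the validation fold
    return model, Xv, yv


class TestGroupReliance:
    def test_monte_carlo_matches_exact_enumeration(self):
        """Mean MR over seeded draws converges to the exact mean over all 6!
        joint row permutations of the validation fold."""
        model, Xv, yv = _fitted_tree()
        J = [0, 2]
        acc_bl = np.mean(model.predict(Xv) == yv)
        assert acc_bl < 1.0
        # brute-force oracle: every joint permutation, independent arithmetic
        exact_vals = []
        for order in itertools.permutations(range(len(yv))):
            Xp = Xv.copy()
            Xp[:, J] = Xv[np.asarray(order)][:, J]
            acc_p = np.mean(model.predict(Xp) == yv)
            exact_vals.append(
                (1 / len(J)) * ((1 - acc_p) / (1 - acc_bl) - 1)
            )
        exact = np.mean(exact_vals)

        n_perm = 600
        records = g.group_reliance(
            model, Xv, yv, J, n_perm=n_perm, rng=np.random.default_rng(1),
        )
        mrs = np.array([r.mr for r in records])
        se = mrs.std(ddof=1) / np.sqrt(n_perm)
        assert abs(mrs.mean() - exact) <= 3 * se + 1e-12

    def test_precomputed_baseline_is_respected(self):
        model, Xv, yv = _fitted_tree()
        recs = g.group_reliance(
            model, Xv, yv, [0], 3, np.random.default_rng(0), acc_bl=0.5
        )
        assert all(r.acc_bl == 0.5 for r in recs)


class TestCrossValidatedReliance:
    def test_determinism_bit_identical(self, planted_tabular, fast_rf):
        fm, groups = planted_tabular
        kwargs = dict(k=5, n_perm=3, seed=21)
        r1 = g.cross_validated_reliance(fast_rf, fm, groups, **kwargs)
        r2 = g.cross_validated_reliance(fast_rf, fm, groups, **kwargs)
        assert r1.records == r2.records
        assert r1.group_means == r2.group_means
        assert r1.fold_accuracies == r2.fold_accuracies

    def test_baseline_constant_within_fold(self, planted_tabular, fast_rf):
        fm, groups = planted_tabular
        res = g.cross_validated_reliance(fast_rf, fm, groups, k=5, n_perm=2, seed=0)
        for fold in range(5):
            accs = {r.acc_bl for r in res.records if r.fold == fold}
            assert len(accs) == 1

    def test_group_means_are_two_stage_average(self, planted_tabular, fast_rf):
        fm, groups = planted_tabular
        res = g.cross_validated_reliance(fast_rf, fm, groups, k=5, n_perm=3, seed=2)
        manual = _two_stage_means(res.records, groups.names, 5)
        assert res.group_means == manual

    def test_informative_group_ranks_first(self, planted_tabular, fast_rf):
        fm, groups = planted_tabular
        res = g.cross_validated_reliance(fast_rf, fm, groups, k=10, n_perm=3, seed=4)
        assert max(res.group_means, key=res.group_means.get) == "g1"
        assert res.mean_accuracy > 0.5

    def test_null_labels_give_chance_accuracy_and_zero_reliance(self, fast_rf):
        fm, groups = g.simulate_grouped_tabular(
            n=240, group_sizes=[4, 4], informative={"g0"}, effect=1.5, seed=8
        )
        null = g.shuffle_labels(fm, seed=99)
        res = g.cross_validated_reliance(fast_rf, null, groups, k=10, n_perm=4, seed=5)
        # binomial MC error on 240 predictions
        se = np.sqrt((1 / 3) * (2 / 3) / 240)
        assert abs(res.mean_accuracy - 1 / 3) < 3 * se
        for name in groups.names:
            fold_means = [
                np.mean([r.mr for r in res.records
                         if r.group == name and r.fold == f])
                for f in range(10)
            ]
            se_mr = np.std(fold_means, ddof=1) / np.sqrt(10)
            assert abs(res.group_means[name]) < 3 * se_mr + 1e-3

    def test_class_smaller_than_k_rejected(self, fast_rf):
        fm, groups = g.simulate_grouped_tabular(
            n=12, group_sizes=[2], informative=set(), effect=0.0, seed=0
        )
        with pytest.raises(g.ValidationError, match="fewer than k"):
            g.cross_validated_reliance(fast_rf, fm, groups, k=10, n_perm=1, seed=0)


class TestGroupOnly:
    def test_all_columns_group_equals_standard_cv(self, planted_tabular, fast_rf):
        fm, _ = planted_tabular
        whole = g.GroupSpec(
            groups={"all": np.arange(fm.n_predictors)},
            n_predictors=fm.n_predictors,
        )
        accs = g.group_only_accuracy(fast_rf, fm, whole, k=10, seed=31)
        mean_acc, _ = g.cv_accuracy(fast_rf, fm, k=10, seed=31)
        assert accs["all"] == mean_acc

    def test_signal_group_beats_chance_noise_group_does_not(
        self, planted_tabular, fast_rf
    ):
        fm, groups = planted_tabular
        accs = g.group_only_accuracy(fast_rf, fm, groups, k=10, seed=7)
        se = np.sqrt((1 / 3) * (2 / 3) / fm.n_trials)
        assert accs["g1"] > 1 / 3 + 3 * se
        assert abs(accs["g0"] - 1 / 3) < 3 * se


class TestLeaveOneSubjectOut:
    @staticmethod
    def _subject(seed, sign=1.0):
        fm, _ = g.simulate_grouped_tabular(
            n=120, group_sizes=[4, 4], informative={"g0"},
            effect=1.5 * sign if sign > 0 else 0.0, seed=seed,
        )
        if sign < 0:  # same layout, reversed association
            fm = g.FeatureMatrix(
                X=fm.X.copy(), y=fm.y.copy(), meta=list(fm.meta)
            )
            fm.X[:, :4] -= 3.0 * fm.y[:, None]
        return fm

    def test_shared_effect_generalizes_above_chance(self):
        fms = [self._subject(s) for s in range(3)]
        _, mean = g.leave_one_subject_out(g.svm_factory(), fms)
        assert mean > 1 / 3 + 3 * np.sqrt((1 / 3) * (2 / 3) / 360)

    def test_identical_subjects_reproduce_within_subject_accuracy(self):
        fm = self._subject(0)
        accs, _ = g.leave_one_subject_out(g.svm_factory(), [fm, fm])
        # deterministic estimator, identical data: both held-out accs equal
        # the fit-on-copy / test-on-original accuracy
        model = g.svm_factory()().fit(fm.X, fm.y)
        direct = float(np.mean(model.predict(fm.X) == fm.y))
        assert accs == [direct, direct]

    def test_mismatched_metadata_rejected(self):
        a = self._subject(0)
        b, _ = g.simulate_grouped_tabular(
            n=120, group_sizes=[8], informative=set(), effect=0.0, seed=1
        )
        with pytest.raises(g.ValidationError, match="metadata"):
            g.leave_one_subject_out(g.svm_factory(), [a, b])

    def test_single_subject_rejected(self):
        with pytest.raises(g.ValidationError, match="2 subjects"):
            g.leave_one_subject_out(g.svm_factory(), [self._subject(0)])
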