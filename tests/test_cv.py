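import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from phradiomics import models as mz
from phradiomics.cv import (
    CVResult,
    auc,
    compare_models,
    evaluate_pipeline,
    make_fold_plan,
    permutation_significance,
    run_cv,
)
from phradiomics.selection import SelectionSpec


def pairwise_auc_oracle(scores, labels):
    """Exhaustive mean over all case-control pairs of win/tie indicators."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    cases = scores[labels == "case"]
    controls = scores[labels == "control"]
    total = 0.0
    for s1 in cases:
        for s0 in controls:
            total += 1.0 if s1 > s0 else 0.5 if s1 == s0 else 0.0
    return total / (len(cases) * len(controls))


def _labels(n_case, n_control, seed=0, prefix="S"):
    ids = [f"{prefix}{i:03d}" for i in range(n_case + n_control)]
    lab = ["case"] * n_case + ["control"] * n_control
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return pd.Series(np.array(lab)[order], index=np.array(ids)[order])


class TestFoldPlan:
    def test_each_subject_tested_once_per_repeat(self):
        labels = _labels(42, 40)
        plan = make_fold_plan(labels, k=5, repeats=5, seed=1)
        assert len(plan.assignments) == 5
        n_sets = 0
        for r in range(5):
            seen = []
            for f in range(5):
                seen.extend(plan.test_subjects(r, f))
                n_sets += 1
            assert sorted(seen) == sorted(labels.index)
        assert n_sets == 25

    def test_small_cohort_fold_sizes(self):
        labels = _labels(5, 5)
        plan = make_fold_plan(labels, k=5, repeats=1, seed=0)
        sizes = [len(plan.test_subjects(0, f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_stratification_within_one(self):
        labels = _labels(42, 40)
        plan = make_fold_plan(labels, k=5, repeats=5, seed=3)
        for r in range(5):
            for f in range(5):
                sub = labels.loc[plan.test_subjects(r, f)]
                assert abs((sub == "case").sum() - 42 / 5) <= 1
                assert abs((sub == "control").sum() - 40 / 5) <= 1

    def test_seed_reproducibility(self):
        labels = _labels(20, 20)
        p1 = make_fold_plan(labels, seed=11)
        p2 = make_fold_plan(labels, seed=11)
        for a, b in zip(p1.assignments, p2.assignments):
            pd.testing.assert_series_equal(a, b)

    def test_single_class_rejected(self):
        labels = pd.Series(["case"] * 10, index=[f"S{i}" for i in range(10)])
        with pytest.raises(ValueError):
            make_fold_plan(labels)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([3, 4, 1, 2], ["case", "case", "control", "control"]) == 1.0

    def test_all_ties(self):
        assert auc([1, 1, 1, 1], ["case", "case", "control", "control"]) == 0.5

    def test_six_point_toy_matches_pair_oracle(self):
        scores = [0.9, 0.8, 0.8, 0.4, 0.3, 0.8]
        labels = ["case", "case", "control", "control", "control", "case"]
        assert auc(scores, labels) == pytest.approx(pairwise_auc_oracle(scores, labels))

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            scores = rng.normal(size=30)
            labels = rng.choice(["case", "control"], 30)
            if len(set(labels)) < 2:
                continue
            assert auc(scores, labels) == pytest.approx(
                roc_auc_score(labels == "case", scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], ["case", "case"])


def _pipeline_data(n_case=12, n_control=12, p=8, effect=2.5, seed=0):
    rng = np.random.default_rng(seed)
    labels = _labels(n_case, n_control, seed=seed + 1)
    shift = np.zeros(p)
    shift[: p // 2] = effect
    X = pd.DataFrame(
        rng.normal(size=(len(labels), p))
        + np.where(labels == "case", 1.0, 0.0)[:, None] * shift[None, :],
        index=labels.index,
        columns=[f"f{j}" for j in range(p)],
    )
    groups = pd.Series(labels.index, index=labels.index)
    return X, labels, groups


class TestRunCV:
    def test_strong_signal_rf_full(self):
        # oversized-signal sanity run: many stable informative features
        from phradiomics.cohort import CohortConfig
        from phradiomics.runner import build_cohort_data

        cfg = CohortConfig(
            n_features_per_mask=60, n_informative_stable=10,
            n_informative_unstable=10, effect_size=1.5, seed=5,
        )
        data = build_cohort_data(cfg)
        X = data.main["LV"].data
        labels = data.subjects["class_label"]
        groups = pd.Series(X.index, index=X.index)
        spec = mz.ModelSpec("rf", {"n_estimators": [100]})
        res = evaluate_pipeline(
            "Original", "LV", spec, SelectionSpec("full"), X, labels, groups,
            seed=5, tune=False,
        )
        assert len(res.auc_estimates) == 25
        assert res.summary["mean"] > 0.9

    def test_null_labels_give_chance_auc(self):
        X, labels, groups = _pipeline_data(effect=0.0, seed=6)
        res = evaluate_pipeline(
            "Original", "LV", mz.ModelSpec("ridge"), SelectionSpec("corr", corr_threshold=0.9),
            X, labels, groups, seed=6, tune=False,
        )
        assert abs(res.summary["mean"] - 0.5) < 0.15

    def test_summary_recomputable_from_estimates(self):
        est = np.array([0.8, 0.9, 1.0, 0.7, 0.85])
        res = CVResult("Original", "LV", "ridge", "full", est, plan_id=("x",))
        assert res.summary["mean"] == pytest.approx(est.mean())
        assert res.summary["sd"] == pytest.approx(est.std(ddof=1))
        assert res.summary["median"] == pytest.approx(np.median(est))
        assert res.summary["min"] == 0.7 and res.summary["max"] == 1.0

    def test_inapplicable_cell_rejected(self):
        X, labels, groups = _pipeline_data(seed=7)
        with pytest.raises(ValueError, match="excluded"):
            evaluate_pipeline(
                "Original", "LV", mz.ModelSpec("logistic"), SelectionSpec("full"),
                X, labels, groups, tune=False,
            )

    def test_augmented_groups_never_straddle_folds(self):
        X, labels, groups = _pipeline_data(seed=8)
        # fake augmentation: two sibling rows per subject
        X2 = pd.concat([X, X + 0.01])
        X2.index = [f"{sid}::aug{r}" for r in (1, 2) for sid in X.index]
        groups2 = pd.Series([sid for _ in (1, 2) for sid in X.index], index=X2.index)
        plan = make_fold_plan(labels, seed=9)
        y2 = groups2.map(labels)
        res = run_cv(
            "DAFIT", "LV", mz.ModelSpec("ridge"), SelectionSpec("full"),
            X2, y2, groups2, plan, seed=9, tune=False,
        )
        for s in res.splits:
            subs = {rid.split("::")[0] for rid in s.row_ids}
            # each tested subject contributes both siblings to the same fold
            assert all(
                sum(g == sid for g in groups2.loc[s.row_ids]) == 2 for sid in subs
            )


class TestCompareModels:
    def _result(self, estimates, plan_id=(5, 5, 0, (10,))):
        return CVResult("Original", "LV", "m", "full", np.asarray(estimates, float), plan_id)

    def test_identical_results_give_p_one(self):
        a = self._result(np.linspace(0.7, 0.9, 25))
        assert compare_models(a, self._result(a.auc_estimates.copy())) == 1.0

    def test_dominated_result_is_significant(self):
        rng = np.random.default_rng(10)
        base = 0.7 + rng.normal(0, 0.01, 25)
        a = self._result(base + 0.2)
        b = self._result(base)
        assert compare_models(a, b) < 0.05

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        a = self._result(0.8 + rng.normal(0, 0.05, 25))
        b = self._result(0.75 + rng.normal(0, 0.05, 25))
        assert compare_models(a, b) == pytest.approx(compare_models(b, a))

    def test_different_plans_rejected(self):
        a = self._result(np.full(25, 0.8))
        b = self._result(np.full(25, 0.7), plan_id=(5, 5, 1, (10,)))
        with pytest.raises(ValueError):
            compare_models(a, b)


class TestPermutation:
    def test_strong_signal_attains_floor(self):
        X, labels, groups = _pipeline_data(n_case=10, n_control=10, effect=3.0, seed=12)
        perm = permutation_significance(
            "Original", "LV", mz.ModelSpec("ridge"), SelectionSpec("full"),
            X, labels, groups, B=100, seed=12, tune=False,
        )
        assert perm.p_value == pytest.approx(1 / 101)
        assert round(perm.p_value, 4) == 0.0099
        assert abs(perm.null_aucs.mean() - 0.5) < 0.05

    def test_null_pipeline_p_value_in_range(self):
        X, labels, groups = _pipeline_data(effect=0.0, seed=13)
        perm = permutation_significance(
            "Original", "LV", mz.ModelSpec("ridge"), SelectionSpec("full"),
            X, labels, groups, B=19, seed=13, tune=False,
        )
        assert 1 / 20 <= perm.p_value <= 1.0
        assert perm.p_value > 0.05  # no real signal to detect
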