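"""Repeated stratified group-aware cross-validation with in-fold feature
selection, AUC scoring, model comparison and permutation significance.

Performance is estimated by fivefold cross-validation repeated five
times (25 estimates per pipeline cell).  Folds are assigned at the
*source-subject* level: under DAFIT every augmented sibling of a subject
shares its fold, so information never leaks between train and test
through the augmentation.  Standardization, feature selection and
hyperparameter tuning are all redone inside every split.

The permutation test recomputes the entire pipeline on label-permuted
data (labels permuted at the subject level, B=100 by default); with an
observed mean AUC above every null replicate the p-value attains its
floor (0 + 1) / (100 + 1) = 0.0099.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import models as mz
from .selection import SelectionSpec, fit_selection, standardize_fit_apply

__all__ = [
    "FoldPlan",
    "CVResult",
    "PermutationResult",
    "make_fold_plan",
    "auc",
    "run_cv",
    "evaluate_pipeline",
    "compare_models",
    "permutation_significance",
]


class DegenerateSplitError(RuntimeError):
    """More than 20% of CV splits had a single-class test set."""


@dataclass
class FoldPlan:
    """Subject-to-fold assignments for each repeat."""

    k: int
    repeats: int
    assignments: list[pd.Series]  # per repeat: subject id -> fold
    seed: int

    def test_subjects(self, repeat: int, fold: int) -> list[str]:
        a = self.assignments[repeat]
        return list(a.index[a == fold])

    @property
    def plan_id(self) -> tuple:
        return (self.k, self.repeats, self.seed, tuple(map(len, self.assignments)))


def make_fold_plan(
    labels: pd.Series, k: int = 5, repeats: int = 5, seed: int = 0
) -> FoldPlan:
    """Stratified fold assignment at the subject (group) level.

    ``labels`` is indexed by subject id; within every repeat each class is
    shuffled and dealt round-robin, so per-fold class counts differ by at
    most one from the stratified ideal.
    """
    classes = labels.unique()
    if classes.size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    assignments = []
    for _ in range(repeats):
        folds = pd.Series(-1, index=labels.index, dtype=int)
        for cls in sorted(map(str, classes)):
            ids = np.asarray(labels.index[labels.astype(str) == cls])
            rng.shuffle(ids)
            offset = int(rng.integers(k))
            folds.loc[ids] = (np.arange(ids.size) + offset) % k
        assignments.append(folds)
    return FoldPlan(k=k, repeats=repeats, assignments=assignments, seed=seed)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (ties counted 1/2): the probability that a random
    case scores above a random control."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == mz.positive_label(labels)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class SplitRecord:
    repeat: int
    fold: int
    row_ids: list[str]
    subjects: list[str]
    y_true: np.ndarray
    scores: np.ndarray
    auc: float  # NaN when degenerate


@dataclass
class CVResult:
    """25 per-split AUC estimates for one pipeline configuration."""

    approach: str
    mask: str
    model: str
    selection: str
    auc_estimates: np.ndarray  # NaN marks a degenerate split
    plan_id: tuple
    splits: list[SplitRecord] = field(default_factory=list, repr=False)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.auc_estimates).sum())

    @property
    def summary(self) -> dict[str, float]:
        est = self.auc_estimates[~np.isnan(self.auc_estimates)]
        return {
            "mean": float(est.mean()),
            "sd": float(est.std(ddof=1)) if est.size > 1 else 0.0,
            "median": float(np.median(est)),
            "min": float(est.min()),
            "max": float(est.max()),
        }


def run_cv(
    approach: str,
    mask: str,
    model_spec: mz.ModelSpec,
    selection_spec: SelectionSpec,
    X: pd.DataFrame,
    y: pd.Series,
    groups: pd.Series,
    plan: FoldPlan,
    seed: int = 0,
    tune: bool = True,
    keep_splits: bool = True,
) -> CVResult:
    """Evaluate one (approach, mask, model, selection) cell over the plan.

    ``X`` holds one row per observation (augmented or original), ``y`` the
    per-row labels, ``groups`` the per-row source-subject ids matching the
    plan's subjects.  Splits whose test set contains a single class are
    recorded as missing; the run fails if more than 20% are.
    """
    if not mz.applicable(model_spec.name, selection_spec.method, approach):
        raise ValueError(
            f"model {model_spec.name!r} with selection {selection_spec.method!r} "
            f"is excluded in the {approach} analysis"
        )
    names = list(X.columns)
    xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    gv = groups.astype(str).to_numpy()

    estimates = []
    splits: list[SplitRecord] = []
    for r in range(plan.repeats):
        for f in range(plan.k):
            test_subjects = set(plan.test_subjects(r, f))
            te = np.fromiter((g in test_subjects for g in gv), bool, len(gv))
            tr = ~te
            split_seed = int(
                np.random.SeedSequence([seed, 7919, r, f]).generate_state(1)[0] % (2**31)
            )
            y_te = yv[te]
            if np.unique(yv[tr]).size < 2 or np.unique(y_te).size < 2:
                estimates.append(np.nan)
                if keep_splits:
                    splits.append(SplitRecord(r, f, list(X.index[te]),
                                              sorted(test_subjects), y_te,
                                              np.full(y_te.size, np.nan), np.nan))
                continue
            x_tr, x_te, _ = standardize_fit_apply(xv[tr], xv[te])
            transform = fit_selection(selection_spec, x_tr, names)
            x_tr_sel, _ = transform.apply(x_tr, names)
            x_te_sel, _ = transform.apply(x_te, names)
            fitted = mz.fit(model_spec, x_tr_sel, yv[tr], seed=split_seed, tune=tune)
            scores = mz.predict_scores(fitted, x_te_sel)
            est = auc(scores, y_te)
            estimates.append(est)
            if keep_splits:
                splits.append(SplitRecord(r, f, list(X.index[te]),
                                          sorted(test_subjects), y_te, scores, est))

    estimates = np.asarray(estimates, dtype=float)
    n_nan = int(np.isnan(estimates).sum())
    if n_nan > 0.2 * estimates.size:
        raise DegenerateSplitError(
            f"{n_nan}/{estimates.size} splits had a single-class test set"
        )
    return CVResult(
        approach=approach,
        mask=mask,
        model=model_spec.name,
        selection=selection_spec.label,
        auc_estimates=estimates,
        plan_id=plan.plan_id,
        splits=splits,
    )


def evaluate_pipeline(
    approach: str,
    mask: str,
    model_spec: mz.ModelSpec,
    selection_spec: SelectionSpec,
    X: pd.DataFrame,
    subject_labels: pd.Series,
    groups: pd.Series,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    tune: bool = True,
    keep_splits: bool = True,
) -> CVResult:
    """Build a fold plan from subject-level labels and run the cell."""
    plan = make_fold_plan(subject_labels, k=k, repeats=repeats, seed=seed)
    y = groups.astype(str).map(subject_labels).rename("label")
    return run_cv(
        approach, mask, model_spec, selection_spec, X, y, groups, plan,
        seed=seed, tune=tune, keep_splits=keep_splits,
    )


def compare_models(a: CVResult, b: CVResult, method: str = "corrected_t") -> float:
    """Two-sided p-value for a paired comparison of two pipeline cells
    evaluated on the same fold plan.

    ``corrected_t`` is the corrected resampled paired t-test: the variance
    of the 25 paired AUC differences is inflated by the test/train size
    ratio (1/(k-1) for k-fold CV) to account for resampling overlap.
    ``permutation`` is a paired sign-flip permutation alternative.
    """
    if a.plan_id != b.plan_id:
        raise ValueError("results come from different fold plans")
    d = a.auc_estimates - b.auc_estimates
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("need at least 2 paired estimates")
    if np.allclose(d, 0.0):
        return 1.0
    if method == "corrected_t":
        k = a.plan_id[0]
        rho = 1.0 / (k - 1)  # n_test / n_train
        var = d.var(ddof=1)
        t = d.mean() / np.sqrt((1.0 / d.size + rho) * var)
        return float(2.0 * stats.t.sf(abs(t), df=d.size - 1))
    if method == "permutation":
        rng = np.random.default_rng(0)
        obs = abs(d.mean())
        B = 10000
        signs = rng.choice([-1.0, 1.0], size=(B, d.size))
        null = np.abs((signs * d).mean(axis=1))
        return float((np.sum(null >= obs) + 1) / (B + 1))
    raise ValueError("method must be 'corrected_t' or 'permutation'")


@dataclass
class PermutationResult:
    observed_auc: float
    null_aucs: np.ndarray
    p_value: float

    @property
    def B(self) -> int:
        return int(self.null_aucs.size)


def permutation_significance(
    approach: str,
    mask: str,
    model_spec: mz.ModelSpec,
    selection_spec: SelectionSpec,
    X: pd.DataFrame,
    subject_labels: pd.Series,
    groups: pd.Series,
    B: int = 100,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    tune: bool = True,
) -> PermutationResult:
    """Permutation significance of one pipeline's mean cross-validated AUC.

    Labels are permuted at the source-subject level (augmented siblings
    inherit the permuted label), the fold plan is re-stratified per
    permutation, and the full pipeline — selection inside splits included —
    is recomputed.  p = (#{null >= observed} + 1) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    observed = evaluate_pipeline(
        approach, mask, model_spec, selection_spec, X, subject_labels, groups,
        k=k, repeats=repeats, seed=seed, tune=tune, keep_splits=False,
    ).summary["mean"]

    rng = np.random.default_rng(np.random.SeedSequence([seed, 271]))
    null = np.empty(B)
    for b in range(B):
        permuted = pd.Series(
            rng.permutation(subject_labels.to_numpy()), index=subject_labels.index
        )
        rep_seed = int(rng.integers(2**31))
        null[b] = evaluate_pipeline(
            approach, mask, model_spec, selection_spec, X, permuted, groups,
            k=k, repeats=repeats, seed=rep_seed, tune=tune, keep_splits=False,
        ).summary["mean"]
    p = float((np.sum(null >= observed) + 1) / (B + 1))
    return PermutationResult(observed_auc=float(observed), null_aucs=null, p_value=p)
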