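"""Confounder deviance partitioning for classifier predictions.

For each confounder (age, BMI, BSA, hypertension) and each classifier,
three logistic regressions of the observed class are fit within every
cross-validated test set: confounder only, out-of-fold model predictions
only, and both combined.  The McFadden pseudo-R^2 of each fit gives the
fraction of binomial deviance explained; the likelihood-ratio statistic
LRT = deviance(confounder-only) - deviance(combined) measures what the
predictions add beyond the confounder.  Because CV test sets are not
independent, significance is assessed non-parametrically: outcomes are
permuted (B=100), the per-split median LRT is recomputed each time, and
p = (#{null >= observed} + 1) / (B + 1).  Components are combined across
the 25 splits by their median.

Logistic fits use Newton/IRLS with a tiny ridge stabilizer; under
(quasi-)perfect separation the ridge is raised and the fit flagged, so a
deviance is always defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import positive_label

__all__ = [
    "DevianceDecomposition",
    "logistic_deviance",
    "decompose",
    "permutation_lrt",
    "permutation_lrt_over_splits",
    "aggregate_over_splits",
]

_RIDGE = 1e-9
_RIDGE_STABILIZED = 1e-4


def _as01(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("outcome must contain both classes")
    return (y == positive_label(classes)).astype(float)


def _irls(y01: np.ndarray, X: np.ndarray, ridge: float, max_iter: int = 200) -> tuple[np.ndarray, float, bool]:
    """Ridge-stabilized Newton fit.  Returns (beta, deviance, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    dev_prev = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X.T @ (y01 - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:  # pragma: no cover - ridge keeps hess PD
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        dev = _deviance_at(y01, np.clip(X @ beta, -30.0, 30.0))
        if abs(dev_prev - dev) < 1e-10:
            converged = True
            break
        dev_prev = dev
    eta = np.clip(X @ beta, -30.0, 30.0)
    return beta, _deviance_at(y01, eta), converged


def _deviance_at(y01: np.ndarray, eta: np.ndarray) -> float:
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = np.sum(y01 * np.log(mu) + (1 - y01) * np.log(1 - mu))
    return float(-2.0 * ll)


def _null_deviance(y01: np.ndarray) -> float:
    p = y01.mean()
    if p in (0.0, 1.0):  # single class is rejected upstream
        return 0.0
    n1 = y01.sum()
    n0 = y01.size - n1
    return float(-2.0 * (n1 * math.log(p) + n0 * math.log(1 - p)))


def logistic_deviance(
    y: np.ndarray, X: np.ndarray | None, pseudo_r2: str = "mcfadden"
) -> tuple[float, float]:
    """Maximum-likelihood logistic deviance and pseudo-R^2.

    ``X`` is the covariate matrix without intercept (an intercept column
    is added); ``X=None`` fits the intercept-only model, whose pseudo-R^2
    is 0 by construction.  Perfect separation is handled with a small
    ridge stabilizer.  McFadden: 1 - D(model)/D(null); Nagelkerke rescales
    the Cox-Snell form to a [0, 1] range.
    """
    y01 = _as01(y)
    n = y01.size
    d_null = _null_deviance(y01)
    if X is None or (np.asarray(X).size == 0):
        return d_null, 0.0
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("y and X must be aligned")
    # standardize covariates for numerical conditioning (deviance invariant)
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    design = np.column_stack([np.ones(n), Xs])
    beta, dev, converged = _irls(y01, design, _RIDGE)
    separated = (not converged) or dev < 1e-6 or np.abs(beta).max() > 1e3
    if separated:
        beta, dev, _ = _irls(y01, design, _RIDGE_STABILIZED)
    dev = min(dev, d_null)  # numerical guard: nested in the saturated family
    if pseudo_r2 == "mcfadden":
        r2 = 1.0 - dev / d_null if d_null > 0 else 0.0
    elif pseudo_r2 == "nagelkerke":
        cox_snell = 1.0 - math.exp((dev - d_null) / n)
        r2_max = 1.0 - math.exp(-d_null / n)
        r2 = cox_snell / r2_max if r2_max > 0 else 0.0
    else:
        raise ValueError("pseudo_r2 must be 'mcfadden' or 'nagelkerke'")
    return float(dev), float(r2)


@dataclass
class DevianceDecomposition:
    """Deviance explained by confounder, predictions, and both combined."""

    confounder_name: str
    r2_confounder: float
    r2_predictions: float
    r2_both: float
    lrt_statistic: float
    p_value: float | None = None


def decompose(
    y: np.ndarray,
    confounder: np.ndarray,
    predictions: np.ndarray,
    confounder_name: str = "confounder",
    pseudo_r2: str = "mcfadden",
) -> DevianceDecomposition:
    """Three nested logistic fits of the outcome: confounder only,
    predictions only, and combined; LRT = D(confounder) - D(combined)."""
    y = np.asarray(y)
    c = np.asarray(confounder, dtype=float)
    s = np.asarray(predictions, dtype=float)
    if not (y.size == c.size == s.size):
        raise ValueError("y, confounder and predictions must be aligned")
    d_conf, r2_conf = logistic_deviance(y, c, pseudo_r2)
    _, r2_pred = logistic_deviance(y, s, pseudo_r2)
    d_both, r2_both = logistic_deviance(y, np.column_stack([c, s]), pseudo_r2)
    lrt = max(d_conf - d_both, 0.0)
    return DevianceDecomposition(
        confounder_name=confounder_name,
        r2_confounder=r2_conf,
        r2_predictions=r2_pred,
        r2_both=max(r2_both, r2_conf, r2_pred),
        lrt_statistic=lrt,
    )


def permutation_lrt(
    y: np.ndarray,
    confounder: np.ndarray,
    predictions: np.ndarray,
    B: int = 100,
    seed: int = 0,
) -> float:
    """Permutation p-value for the added value of the predictions.

    The outcome is permuted B times; both nested models are refit per
    permutation with the predictions and confounder held fixed.
    p = (#{null LRT >= observed} + 1) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = decompose(y, confounder, predictions).lrt_statistic
    rng = np.random.default_rng(np.random.SeedSequence([seed, 733]))
    y = np.asarray(y)
    count = 0
    for _ in range(B):
        yp = rng.permutation(y)
        if np.unique(yp).size < 2:  # pragma: no cover - permutation keeps counts
            continue
        null = decompose(yp, confounder, predictions).lrt_statistic
        if null >= obs:
            count += 1
    return float((count + 1) / (B + 1))


def permutation_lrt_over_splits(
    splits: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    B: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test on the median per-split LRT.

    ``splits`` holds (y, confounder, predictions) per CV test set.  Each
    permutation replicate permutes the outcome within every split,
    recomputes every per-split LRT and takes the median; the observed
    median is compared against that null.  Returns (observed median LRT, p).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    usable = [s for s in splits if np.unique(np.asarray(s[0])).size == 2]
    if not usable:
        raise ValueError("no split with both classes present")
    obs = float(np.median([decompose(y, c, s).lrt_statistic for y, c, s in usable]))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 997]))
    count = 0
    for _ in range(B):
        null_lrts = []
        for y, c, s in usable:
            yp = rng.permutation(np.asarray(y))
            if np.unique(yp).size < 2:
                continue
            null_lrts.append(decompose(yp, c, s).lrt_statistic)
        if null_lrts and np.median(null_lrts) >= obs:
            count += 1
    return obs, float((count + 1) / (B + 1))


def aggregate_over_splits(
    decompositions: list[DevianceDecomposition | None],
) -> dict[str, float]:
    """Median of each deviance component and of the LRT over CV splits.

    ``None`` entries (degenerate splits) are excluded; their count is
    reported under ``n_missing``.
    """
    usable = [d for d in decompositions if d is not None]
    if not usable:
        raise ValueError("no usable splits")
    return {
        "r2_confounder": float(np.median([d.r2_confounder for d in usable])),
        "r2_predictions": float(np.median([d.r2_predictions for d in usable])),
        "r2_both": float(np.median([d.r2_both for d in usable])),
        "lrt_statistic": float(np.median([d.lrt_statistic for d in usable])),
        "n_splits": len(usable),
        "n_missing": len(decompositions) - len(usable),
    }
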