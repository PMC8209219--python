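"""In-fold feature selection: standardization, high-correlation filter,
linear-combinations filter and PCA by variance fraction.

All transforms are fit on the training fold only and then applied,
frozen, to the held-out fold — feature selection inside each
cross-validated split is what keeps the resulting AUC estimate unbiased.

Per-approach thresholds (single mask / combined masks):

============  =======  ===========  ==========
approach      lincomb  corr         PCA
============  =======  ===========  ==========
Original      yes      0.6 / 0.5    0.9 / 0.85
ICC2          no       0.9 / 0.9    0.9 / 0.9
ICC3          no       (full only)  --
DAFIT         yes      0.6 / 0.4    0.9 / 0.85
DAFIT_Filt2   no       -- / 0.8     -- / 0.85
DAFIT_Filt3   no       -- / 0.8     -- / 0.85
============  =======  ===========  ==========

DAFIT_Filt analyses are only fit to the combined masks.  The full
(unselected) feature set is always evaluated as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "SelectionSpec",
    "FittedTransform",
    "StandardizeParams",
    "standardize_fit_apply",
    "corr_filter",
    "lincomb_filter",
    "pca_fit",
    "fit_selection",
    "resolve_selection",
    "APPROACHES",
]

APPROACHES = ("Original", "ICC2", "ICC3", "DAFIT", "DAFIT_Filt2", "DAFIT_Filt3")

_LINCOMB_TOL = 1e-8


@dataclass(frozen=True)
class SelectionSpec:
    """One feature-selection strategy with its threshold, if any."""

    method: str  # full | corr | lincomb | pca
    corr_threshold: float | None = None
    pca_variance_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("full", "corr", "lincomb", "pca"):
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.method == "corr" and not (self.corr_threshold and 0 < self.corr_threshold <= 1):
            raise ValueError("corr requires corr_threshold in (0, 1]")
        if self.method == "pca" and not (
            self.pca_variance_fraction and 0 < self.pca_variance_fraction <= 1
        ):
            raise ValueError("pca requires pca_variance_fraction in (0, 1]")

    @property
    def label(self) -> str:
        if self.method == "corr":
            return f"corr@{self.corr_threshold:g}"
        if self.method == "pca":
            return f"pca@{self.pca_variance_fraction:g}"
        return self.method


@dataclass
class StandardizeParams:
    mean: np.ndarray
    scale: np.ndarray  # 0 marks a zero-variance training column


def standardize_fit_apply(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, StandardizeParams]:
    """Center/scale columns by training statistics; apply the same
    parameters to the test rows.  Zero-variance training columns map to 0
    everywhere (including in the test rows)."""
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix is empty")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1) if train.shape[0] > 1 else np.zeros(train.shape[1])
    params = StandardizeParams(mean=mean, scale=sd)
    train_out = apply_standardize(train, params)
    test_out = apply_standardize(test, params) if test is not None else None
    return train_out, test_out, params


def apply_standardize(x: np.ndarray, params: StandardizeParams) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    safe = np.where(params.scale > 0, params.scale, 1.0)
    out = (x - params.mean) / safe
    out[:, params.scale == 0] = 0.0
    return out


def corr_filter(matrix: np.ndarray, names: list[str], threshold: float) -> list[str]:
    """Greedy high-correlation filter.

    While any remaining pair of columns has absolute Pearson correlation
    strictly above ``threshold``, the member of the worst pair with the
    larger mean absolute correlation to all remaining columns is removed
    (the classic findCorrelation heuristic).  Deterministic given column
    order; constant columns correlate 0 with everything.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] != len(names):
        raise ValueError("names length must match column count")
    if x.shape[1] < 2:
        return list(names)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(x, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)

    alive = np.ones(len(names), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        alive_idx = np.flatnonzero(alive)
        i_s, j_s = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive_idx[i_s], alive_idx[j_s]
        mean_i = corr[i, alive].mean()
        mean_j = corr[j, alive].mean()
        drop = i if mean_i > mean_j else j if mean_j > mean_i else max(i, j)
        alive[drop] = False
    return [names[i] for i in np.flatnonzero(alive)]


def lincomb_filter(
    matrix: np.ndarray, names: list[str], tol: float = _LINCOMB_TOL
) -> list[str]:
    """Linear-combinations filter: drop columns that are (numerically)
    exact linear combinations of earlier retained columns, until the
    retained set is full column rank.

    Implemented as an incremental Gram–Schmidt sweep in column order; a
    column is kept iff its residual after projection onto the retained
    orthonormal basis exceeds ``tol`` relative to the largest column norm.
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if p != len(names):
        raise ValueError("names length must match column count")
    norms = np.linalg.norm(x, axis=0)
    scale = norms.max() if norms.size else 0.0
    if scale == 0.0:
        return [names[0]] if p else []
    cutoff = tol * scale

    basis = np.empty((n, 0))
    kept: list[int] = []
    for j in range(p):
        v = x[:, j].copy()
        if basis.shape[1]:
            v -= basis @ (basis.T @ v)
            v -= basis @ (basis.T @ v)  # re-orthogonalize for stability
        r = np.linalg.norm(v)
        if r > cutoff:
            kept.append(j)
            basis = np.hstack([basis, (v / r)[:, None]])
    return [names[j] for j in kept]


@dataclass
class FittedTransform:
    """A frozen feature-selection transform.

    For name-based methods (full/corr/lincomb) applying the transform
    subsets columns; for PCA it projects onto the retained components.
    """

    spec: SelectionSpec
    retained_names: list[str] | None = None
    pca: PCA | None = None
    n_components: int | None = None
    input_names: list[str] = field(default_factory=list)

    def apply(self, x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
        if names != self.input_names:
            raise ValueError("feature names differ from those seen at fit time")
        x = np.asarray(x, dtype=float)
        if self.spec.method == "pca":
            scores = self.pca.transform(x)[:, : self.n_components]
            return scores, [f"PC{i + 1}" for i in range(self.n_components)]
        idx = [self.input_names.index(n) for n in self.retained_names]
        return x[:, idx], list(self.retained_names)

    def to_dict(self) -> dict:
        out = {"method": self.spec.method}
        if self.spec.method == "pca":
            out.update(
                n_components=self.n_components,
                components=self.pca.components_[: self.n_components].tolist(),
                mean=self.pca.mean_.tolist(),
            )
        else:
            out["retained"] = list(self.retained_names)
        return out


def pca_fit(matrix: np.ndarray, variance_fraction: float, names: list[str] | None = None) -> FittedTransform:
    """PCA keeping the smallest component count whose cumulative explained
    variance reaches ``variance_fraction``.  Input is expected to be
    standardized already."""
    if not (0 < variance_fraction <= 1):
        raise ValueError("variance_fraction must lie in (0, 1]")
    x = np.asarray(matrix, dtype=float)
    names = names if names is not None else [f"x{i}" for i in range(x.shape[1])]
    pca = PCA(n_components=min(x.shape), svd_solver="full")
    pca.fit(x)
    evr = pca.explained_variance_ratio_
    # components with numerically-zero variance never count toward rank
    nonzero = evr > 1e-12
    cum = np.cumsum(evr)
    if variance_fraction >= 1.0 - 1e-12:
        k = int(nonzero.sum())
    else:
        k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        k = min(k, int(nonzero.sum()) or 1)
    k = max(k, 1)
    spec = SelectionSpec("pca", pca_variance_fraction=variance_fraction)
    return FittedTransform(spec=spec, pca=pca, n_components=k, input_names=list(names))


def fit_selection(spec: SelectionSpec, matrix: np.ndarray, names: list[str]) -> FittedTransform:
    """Fit any SelectionSpec on (standardized) training data."""
    if spec.method == "full":
        return FittedTransform(spec=spec, retained_names=list(names), input_names=list(names))
    if spec.method == "corr":
        kept = corr_filter(matrix, names, spec.corr_threshold)
        return FittedTransform(spec=spec, retained_names=kept, input_names=list(names))
    if spec.method == "lincomb":
        kept = lincomb_filter(matrix, names)
        return FittedTransform(spec=spec, retained_names=kept, input_names=list(names))
    if spec.method == "pca":
        return pca_fit(matrix, spec.pca_variance_fraction, names)
    raise ValueError(f"unknown selection method {spec.method!r}")  # pragma: no cover


_TABLE = {
    # approach: (lincomb?, corr single, corr combined, pca single, pca combined)
    "Original": (True, 0.6, 0.5, 0.9, 0.85),
    "ICC2": (False, 0.9, 0.9, 0.9, 0.9),
    "ICC3": (False, None, None, None, None),
    "DAFIT": (True, 0.6, 0.4, 0.9, 0.85),
    "DAFIT_Filt2": (False, None, 0.8, None, 0.85),
    "DAFIT_Filt3": (False, None, 0.8, None, 0.85),
}


def resolve_selection(approach: str, mask_scope: str) -> list[SelectionSpec]:
    """Feature-selection strategies (with thresholds) for one analysis
    approach and mask scope (``single`` or ``combined``)."""
    if approach not in _TABLE:
        raise ValueError(f"unknown approach {approach!r}")
    if mask_scope not in ("single", "combined"):
        raise ValueError("mask_scope must be 'single' or 'combined'")
    lincomb, corr_s, corr_c, pca_s, pca_c = _TABLE[approach]
    if approach.startswith("DAFIT_Filt") and mask_scope == "single":
        raise ValueError(f"{approach} analyses are only fit to the combined masks")
    specs = [SelectionSpec("full")]
    if lincomb:
        specs.append(SelectionSpec("lincomb"))
    corr = corr_s if mask_scope == "single" else corr_c
    if corr is not None:
        specs.append(SelectionSpec("corr", corr_threshold=corr))
    pca = pca_s if mask_scope == "single" else pca_c
    if pca is not None:
        specs.append(SelectionSpec("pca", pca_variance_fraction=pca))
    return specs
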