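"""Intraclass correlation for radiomic feature repeatability.

Repeat feature extractions on the same subjects are scored with a two-way
mixed-effects single-rater ICC.  The consistency form ICC(3,1) is the
default because re-annotation by the same readers is a fixed-rater design;
the absolute-agreement form is available behind a flag.  Agreement bands:
poor (< 0.40), fair (0.40-0.59), good (0.60-0.75), excellent (> 0.75).
The printed bands leave (0.74, 0.75] ambiguous; such values are assigned
``good`` and flagged in the report.

Two feature filters are derived from a three-extraction side study:

* ICC2 — features with excellent ICC between extractions 1 and 2;
* ICC3 — features with excellent ICC between all three pairwise
  extraction combinations (a strict subset of ICC2's constraint set).
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

from .cohort import SideStudyBundle

__all__ = [
    "compute_icc",
    "icc_per_feature",
    "classify_agreement",
    "select_icc2",
    "select_icc3",
    "icc_report",
    "PAIRS",
]

PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (2, 3))

_EXCELLENT = 0.75


def _two_way_mean_squares(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row (subject), column (rater) and residual mean squares of a
    two-way ANOVA without replication.

    ``m`` has shape (n_subjects, k_raters) or (n, k, f) for f features
    stacked along the last axis.
    """
    n, k = m.shape[0], m.shape[1]
    grand = m.mean(axis=(0, 1))
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_means - grand) ** 2).sum(axis=0)
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def compute_icc(measurements: np.ndarray, form: str = "consistency") -> float:
    """Two-way mixed-effects single-rater ICC of a subjects x raters matrix.

    ``consistency`` is ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE), which
    ignores systematic rater offsets; ``agreement`` additionally charges
    the rater variance component.  A matrix with zero total variance has
    trivially perfect agreement and returns 1.0 with a warning.  Negative
    values are retained as computed.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects x raters matrix")
    n, k = m.shape
    if n < 2:
        raise ValueError("ICC requires at least 2 subjects")
    if k < 2:
        raise ValueError("ICC requires at least 2 raters")
    if np.isnan(m).any():
        raise ValueError("measurements must not contain missing values")
    if np.ptp(m) == 0.0:
        warnings.warn("zero total variance: returning ICC = 1.0", stacklevel=2)
        return 1.0
    msr, msc, mse = _two_way_mean_squares(m)
    if form == "consistency":
        denom = msr + (k - 1) * mse
    elif form == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError("form must be 'consistency' or 'agreement'")
    if denom == 0.0:
        return 1.0
    return float((msr - mse) / denom)


def icc_per_feature(
    a: pd.DataFrame, b: pd.DataFrame, form: str = "consistency"
) -> pd.Series:
    """Vectorized two-rater ICC per feature for two aligned extractions."""
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("extractions must be subject- and feature-aligned")
    m = np.stack([a.to_numpy(dtype=float), b.to_numpy(dtype=float)], axis=1)  # (n, 2, f)
    n, k = m.shape[0], 2
    msr, msc, mse = _two_way_mean_squares(m)
    if form == "consistency":
        denom = msr + (k - 1) * mse
    elif form == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError("form must be 'consistency' or 'agreement'")
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    total_var = m.reshape(-1, m.shape[-1]).var(axis=0)
    icc = np.where(total_var == 0.0, 1.0, icc)
    icc = np.where(denom == 0.0, 1.0, icc)
    return pd.Series(icc, index=a.columns, name="icc")


def classify_agreement(icc: float) -> str:
    """Map an ICC value onto the poor/fair/good/excellent bands."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc <= _EXCELLENT:
        return "good"
    return "excellent"


def _pair_icc(bundle: SideStudyBundle, pair: tuple[int, int], form: str) -> pd.Series:
    a = bundle.extractions[pair[0] - 1].data
    b = bundle.extractions[pair[1] - 1].data
    return icc_per_feature(a, b, form=form)


def select_icc2(bundle: SideStudyBundle, form: str = "consistency") -> list[str]:
    """Features with excellent ICC between the first two extractions."""
    icc = _pair_icc(bundle, (1, 2), form)
    return [name for name, v in icc.items() if v > _EXCELLENT]


def select_icc3(bundle: SideStudyBundle, form: str = "consistency") -> list[str]:
    """Features with excellent ICC on all three pairwise extraction pairs."""
    keep = pd.Series(True, index=bundle.feature_names)
    for pair in PAIRS:
        keep &= _pair_icc(bundle, pair, form) > _EXCELLENT
    return [name for name, v in keep.items() if v]


def icc_report(bundle: SideStudyBundle, form: str = "consistency") -> pd.DataFrame:
    """Long-format ICC report: feature, pair, icc, agreement, band-gap flag.

    The ``band_gap`` flag marks values in (0.74, 0.75], which the printed
    agreement bands do not unambiguously cover.
    """
    rows = []
    for pair in PAIRS:
        icc = _pair_icc(bundle, pair, form)
        for name, v in icc.items():
            rows.append(
                {
                    "feature": name,
                    "pair": f"{pair[0]}-{pair[1]}",
                    "icc": float(v),
                    "agreement": classify_agreement(float(v)),
                    "band_gap": bool(0.74 < v <= 0.75),
                }
            )
    return pd.DataFrame(rows)
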