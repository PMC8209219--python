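"""Data augmentation for information transfer (DAFIT).

Instead of discarding radiomic features that are unstable across repeat
extractions, DAFIT folds the extraction variability back into the main
study.  For each feature, the three sets of pairwise differences between
side-study extractions (1-2, 1-3, 2-3) are pooled; their sample mean mu
and variance sigma^2 define a per-feature Gaussian noise model of the
extraction process.  Each main-study observation x^M then spawns
``m_per_obs`` augmented observations x^A = x^M + Normal(mu, sigma^2),
drawn independently per feature.  With the study's 82 subjects and the
default two augmentations per subject the modelling set has 164 rows.

The augmented rows are grouped by their source subject for
cross-validation fold assignment so that siblings of one subject never
straddle a train/test split.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AlignmentError, FeatureMatrix, SideStudyBundle
from .icc import PAIRS

__all__ = [
    "NoiseProfile",
    "AugmentedMatrix",
    "pooled_pairwise_differences",
    "estimate_noise_profile",
    "augment",
]


@dataclass
class NoiseProfile:
    """Per-feature mean and variance of pooled pairwise extraction
    differences."""

    feature_names: list[str]
    mu: np.ndarray
    sigma2: np.ndarray
    n_pairs_pooled: int

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if not (len(self.feature_names) == self.mu.size == self.sigma2.size):
            raise ValueError("feature_names, mu and sigma2 must have equal length")
        if (self.sigma2 < 0).any():
            raise ValueError("sigma2 must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"feature": self.feature_names, "mu": self.mu, "sigma2": self.sigma2}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, n_pairs_pooled: int = 0) -> "NoiseProfile":
        df = pd.read_csv(path)
        return cls(list(df["feature"]), df["mu"].to_numpy(), df["sigma2"].to_numpy(), n_pairs_pooled)


@dataclass
class AugmentedMatrix:
    """Augmented feature rows, each traceable to one main-study subject."""

    data: pd.DataFrame  # index: augmented row ids
    mask: str
    source_subject_id: pd.Series  # per augmented row
    replicate_index: pd.Series  # per augmented row (0 = original row, if kept)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def labels_from(self, subjects: pd.DataFrame, column: str = "class_label") -> pd.Series:
        """Per-row labels inherited from the source subject."""
        return self.source_subject_id.map(subjects[column]).rename(column)


def pooled_pairwise_differences(bundle: SideStudyBundle) -> pd.DataFrame:
    """Concatenated pairwise extraction differences (1-2, 1-3, 2-3).

    Returns a DataFrame of shape (3 * n_side, n_features): one difference
    row per side-study subject per ordered pair, in pair order.  With the
    study's 40 side-study subjects this yields 120 differences per feature.
    """
    frames = []
    for i, j in PAIRS:
        a = bundle.extractions[i - 1].data
        b = bundle.extractions[j - 1].data
        d = a.to_numpy(dtype=float) - b.to_numpy(dtype=float)
        frames.append(
            pd.DataFrame(d, columns=bundle.feature_names,
                         index=[f"{sid}::d{i}{j}" for sid in bundle.subject_ids])
        )
    return pd.concat(frames, axis=0)


def estimate_noise_profile(differences: pd.DataFrame) -> NoiseProfile:
    """Per-feature sample mean and variance (ddof=1) of pooled differences."""
    if len(differences) < 2:
        raise ValueError("need at least 2 pooled differences per feature")
    mu = differences.mean(axis=0).to_numpy()
    sigma2 = differences.var(axis=0, ddof=1).to_numpy()
    return NoiseProfile(list(differences.columns), mu, sigma2, len(differences))


def augment(
    main: FeatureMatrix,
    profile: NoiseProfile,
    m_per_obs: int = 2,
    seed: int = 0,
    include_original: bool = False,
) -> AugmentedMatrix:
    """Generate ``m_per_obs`` augmented observations per main-study row.

    Each augmented value is the original value plus an independent draw
    from Normal(mu_f, sigma2_f).  By default the modelling set consists of
    the augmented rows only (2 x 82 = 164 under the study defaults);
    ``include_original`` additionally keeps the unperturbed rows for
    sensitivity analysis.
    """
    if m_per_obs < 1:
        raise ValueError("m_per_obs must be >= 1")
    if main.feature_names != profile.feature_names:
        raise AlignmentError("feature names of main table and noise profile differ")

    x = main.data.to_numpy(dtype=float)
    n, p = x.shape
    sd = np.sqrt(profile.sigma2)

    # noise streams are keyed by feature name so augmentation commutes
    # exactly with column permutation of the feature matrix
    noise = np.empty((m_per_obs * n, p))
    for j, name in enumerate(profile.feature_names):
        key = zlib.crc32(name.encode())
        rng_f = np.random.default_rng(np.random.SeedSequence([seed, key]))
        noise[:, j] = rng_f.normal(loc=profile.mu[j], scale=sd[j], size=m_per_obs * n)

    rows, sources, reps, ids = [], [], [], []
    if include_original:
        rows.append(x)
        sources.extend(main.subject_ids)
        reps.extend([0] * n)
        ids.extend([f"{sid}::orig" for sid in main.subject_ids])
    for r in range(1, m_per_obs + 1):
        rows.append(x + noise[(r - 1) * n : r * n])
        sources.extend(main.subject_ids)
        reps.extend([r] * n)
        ids.extend([f"{sid}::aug{r}" for sid in main.subject_ids])

    data = pd.DataFrame(np.vstack(rows), index=ids, columns=main.feature_names)
    return AugmentedMatrix(
        data=data,
        mask=main.mask,
        source_subject_id=pd.Series(sources, index=ids, name="source_subject_id"),
        replicate_index=pd.Series(reps, index=ids, name="replicate_index"),
    )
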