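"""Synthetic cohort generator for the PH-vs-control radiomics pipeline.

The real study population (82 subjects: 42 pulmonary-hypertension cases,
40 normal controls; 348 radiomic features per myocardial mask; a 40-subject
side study with three repeat feature extractions) is not publicly
deposited.  This module generates cohorts with the same statistical
structure so that every downstream stage — ICC stability filtering, DAFIT
augmentation, in-fold feature selection, cross-validated modelling and
confounder decomposition — can be exercised and tested end to end.

Generative model
----------------
Each subject carries a latent feature vector: ``class mean + subject
effect`` with unit between-subject SD.  Informative features shift the
class means apart by ``effect_size`` (a standardized mean difference);
the rest are noise.  An extraction replicate observes the latent value
plus independent extraction noise whose SD depends on whether the
feature is *stable* or *unstable*, plus a systematic ``extraction_bias``
for replicates 2 and 3.  Main-study values of side-study subjects equal
their first-extraction values; the differences between replicates are
therefore solely a product of the extraction process, which is exactly
the assumption the DAFIT augmentation rests on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "FeatureMatrix",
    "SideStudyBundle",
    "FEATURE_FAMILIES",
    "feature_family_counts",
    "feature_layout",
    "generate_cohort",
    "generate_feature_tables",
    "combine_masks",
    "combine_bundles",
    "write_cohort",
]

# Canonical per-family feature counts of the 348-feature texture layout:
# histogram, co-occurrence, run-length, gradient, autoregressive,
# geometrical and wavelet families.
FEATURE_FAMILIES: dict[str, int] = {
    "hist": 9,
    "glcm": 220,
    "rlm": 20,
    "grad": 5,
    "ar": 5,
    "geom": 73,
    "wav": 16,
}


def feature_family_counts() -> dict[str, int]:
    """Per-family feature counts of the canonical 348-feature layout."""
    return dict(FEATURE_FAMILIES)


def feature_layout(n_features: int) -> list[str]:
    """Feature names for a mask with ``n_features`` columns.

    When ``n_features`` equals the canonical total (348) the names follow
    the family layout (``hist_000`` ... ``wav_015``) and the family counts
    are schema-checked; otherwise generic ``f000`` ... names are used.
    """
    total = sum(FEATURE_FAMILIES.values())
    if n_features == total:
        if total != 348:  # pragma: no cover - schema guard
            raise AssertionError("feature family schema does not sum to 348")
        names = [
            f"{fam}_{i:03d}" for fam, cnt in FEATURE_FAMILIES.items() for i in range(cnt)
        ]
        return names
    width = max(3, len(str(n_features)))
    return [f"f{i:0{width}d}" for i in range(n_features)]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


class AlignmentError(ValueError):
    """Subject-alignment mismatch between feature tables."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: 42 cases vs 40 controls, 348
    features per mask, a side study of 20 subjects per class with three
    paired repeat extractions, a minority of stable features, and
    confounders (age, BMI, BSA, hypertension) shifted between classes.
    """

    n_cases: int = 42
    n_controls: int = 40
    n_features_per_mask: int = 348
    n_informative_stable: int = 1
    n_informative_unstable: int = 19
    frac_side_study: float = 0.4878  # -> round(.4878*42)=20, round(.4878*40)=20
    effect_size: float = 1.5
    extraction_noise_sd_stable: float = 0.15
    extraction_noise_sd_unstable: float = 1.5
    extraction_bias: float = 0.05
    confounder_strength: float = 1.0
    frac_stable_noise: float = 0.1
    corr_block_size: int = 5
    corr_within: float = 0.7
    seed: int = 0
    mode: str = "tabular"

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("n_cases and n_controls must be >= 1")
        if self.n_features_per_mask < 1:
            raise ConfigurationError("n_features_per_mask must be >= 1")
        if self.n_informative_stable + self.n_informative_unstable > self.n_features_per_mask:
            raise ConfigurationError("informative feature counts exceed n_features_per_mask")
        if not (0.0 < self.frac_side_study <= 1.0):
            raise ConfigurationError("frac_side_study must lie in (0, 1]")
        for name in ("extraction_noise_sd_stable", "extraction_noise_sd_unstable"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.mode not in ("tabular", "image"):
            raise ConfigurationError("mode must be 'tabular' or 'image'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class FeatureMatrix:
    """A subjects x features table for one mask and one extraction.

    ``data`` is indexed by subject id; columns are unique feature names.
    """

    data: pd.DataFrame
    mask: str  # LV, RV or combined
    extraction_id: str = "main"  # "1", "2", "3" or "main"
    # generator bookkeeping (per-feature 'informative'/'stable' flags);
    # None for tables read from disk
    roles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("FeatureMatrix must not contain missing values")
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_features(self, names: list[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        roles = self.roles.loc[list(names)] if self.roles is not None else None
        return FeatureMatrix(
            self.data.loc[:, list(names)].copy(), self.mask, self.extraction_id, roles
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, mask: str, extraction_id: str = "main") -> "FeatureMatrix":
        df = pd.read_csv(path)
        df = df.set_index("subject_id")
        return cls(df, mask, extraction_id)


@dataclass
class SideStudyBundle:
    """Three subject-aligned repeat extractions of the side-study subset."""

    extractions: tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix]

    def __post_init__(self) -> None:
        e1, e2, e3 = self.extractions
        ids = e1.subject_ids
        names = e1.feature_names
        for e in (e2, e3):
            if e.subject_ids != ids:
                raise AlignmentError("side-study extractions are not subject-aligned")
            if e.feature_names != names:
                raise AlignmentError("side-study extractions have different feature sets")
        if tuple(e.extraction_id for e in self.extractions) != ("1", "2", "3"):
            raise AlignmentError("extraction ids must be ('1', '2', '3')")

    @property
    def subject_ids(self) -> list[str]:
        return self.extractions[0].subject_ids

    @property
    def feature_names(self) -> list[str]:
        return self.extractions[0].feature_names

    @property
    def mask(self) -> str:
        return self.extractions[0].mask

    def select_features(self, names: list[str]) -> "SideStudyBundle":
        return SideStudyBundle(tuple(e.select_features(names) for e in self.extractions))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the subject table: labels, confounders and LVEF.

    Returns a DataFrame with one row per subject and columns
    ``subject_id, class_label, age, bmi, bsa, hypertension, lvef``.
    Confounder class shifts scale linearly with ``confounder_strength``;
    at strength 0 the two classes share identical distributions.
    Controls always have preserved ejection fraction; cases are a mixture
    of reduced and preserved EF so the preserved-EF subgroup is non-empty.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    cs = config.confounder_strength
    n_ca, n_co = config.n_cases, config.n_controls
    n = n_ca + n_co

    labels = np.array(["case"] * n_ca + ["control"] * n_co)
    age = np.concatenate([
        rng.normal(52.0 + 10.0 * cs, 12.0, n_ca),
        rng.normal(52.0, 12.0, n_co),
    ]).clip(18.0, 95.0)
    bmi = np.concatenate([
        rng.normal(27.0 + 2.5 * cs, 4.0, n_ca),
        rng.normal(27.0, 4.0, n_co),
    ]).clip(15.0, 55.0)
    bsa = np.concatenate([
        rng.normal(1.85 + 0.12 * cs, 0.2, n_ca),
        rng.normal(1.85, 0.2, n_co),
    ]).clip(1.2, 2.8)

    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    base_logit = np.log(0.25 / 0.75)
    p_htn = np.concatenate([
        np.full(n_ca, _sigmoid(base_logit + 1.2 * cs)),
        np.full(n_co, _sigmoid(base_logit)),
    ])
    hypertension = (rng.random(n) < p_htn).astype(int)

    # EF: controls normal; roughly half the cases preserved (>= 50%).
    lvef = np.empty(n)
    reduced = rng.random(n_ca) < 0.5
    lvef[:n_ca] = np.where(
        reduced,
        rng.normal(40.0, 6.0, n_ca),
        rng.normal(58.0, 5.0, n_ca),
    )
    lvef[n_ca:] = rng.normal(62.0, 4.0, n_co)
    lvef = lvef.clip(15.0, 80.0)

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "class_label": labels,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "bsa": np.round(bsa, 2),
            "hypertension": hypertension,
            "lvef": np.round(lvef, 1),
        }
    ).set_index("subject_id", drop=False)


def _feature_roles(config: CohortConfig, rng: np.random.Generator):
    """Assign informative/noise and stable/unstable roles per feature."""
    p = config.n_features_per_mask
    idx = rng.permutation(p)
    ns, nu = config.n_informative_stable, config.n_informative_unstable
    informative = np.zeros(p, bool)
    informative[idx[: ns + nu]] = True
    stable = np.zeros(p, bool)
    stable[idx[:ns]] = True  # informative-stable
    noise_idx = idx[ns + nu:]
    n_stable_noise = int(round(config.frac_stable_noise * noise_idx.size))
    stable[noise_idx[:n_stable_noise]] = True
    sign = np.where(rng.random(p) < 0.5, -1.0, 1.0)
    return informative, stable, sign


def _latent_matrix(config: CohortConfig, labels: np.ndarray,
                   informative: np.ndarray, sign: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Latent subject-level feature values with unit between-subject SD."""
    n, p = labels.size, config.n_features_per_mask
    is_case = (labels == "case").astype(float)[:, None]
    shift = np.where(informative, config.effect_size, 0.0) * sign
    mean = is_case * shift[None, :]

    # Correlated blocks among the noise features keep the corr and lincomb
    # filters honest; informative features stay mutually independent.
    eps = rng.normal(size=(n, p))
    latent = mean + eps
    rho = config.corr_within
    bs = config.corr_block_size
    if bs >= 2 and 0.0 < rho < 1.0:
        noise_cols = np.flatnonzero(~informative)
        for start in range(0, noise_cols.size - bs + 1, bs):
            block = noise_cols[start:start + bs]
            g = rng.normal(size=(n, 1))
            latent[:, block] = mean[:, block] + np.sqrt(rho) * g + np.sqrt(1 - rho) * eps[:, block]
    return latent


def _apply_exact_redundancy(values: np.ndarray, informative: np.ndarray) -> None:
    """Overwrite two noise columns with an exact duplicate and an exact
    linear combination of other noise columns (in place)."""
    noise_cols = np.flatnonzero(~informative)
    if noise_cols.size < 5:
        return
    a, b, c, dup, lin = noise_cols[-5:]
    values[:, dup] = values[:, a]
    values[:, lin] = values[:, b] + values[:, c]


def generate_feature_tables(
    config: CohortConfig, subjects: pd.DataFrame
) -> tuple[FeatureMatrix, FeatureMatrix, SideStudyBundle, SideStudyBundle]:
    """Generate main-study LV/RV feature tables and side-study bundles.

    The side study is a stratified subset of ``round(frac_side_study * n)``
    subjects per class with three repeat extractions.  Main-study values of
    side-study subjects equal their first-extraction values.

    Tabular mode only; image-mode side studies are built from toy images
    with :func:`phradiomics.texture.texture_side_bundle`.
    """
    config.validate()
    if config.mode != "tabular":
        raise ConfigurationError(
            "generate_feature_tables is tabular-mode only; use "
            "phradiomics.texture.texture_side_bundle for image mode"
        )
    ss = np.random.SeedSequence([config.seed, 23])
    rng_lv, rng_rv, rng_pick = (np.random.default_rng(s) for s in ss.spawn(3))

    labels = subjects["class_label"].to_numpy()
    ids = np.asarray(subjects.index)

    side_ids: list[str] = []
    for cls in ("case", "control"):
        cls_ids = ids[labels == cls]
        k = int(round(config.frac_side_study * cls_ids.size))
        if k < 1:
            raise ConfigurationError("frac_side_study selects no subjects for a class")
        side_ids.extend(rng_pick.choice(cls_ids, size=k, replace=False))
    side_set = set(side_ids)
    side_order = [sid for sid in ids if sid in side_set]

    names = feature_layout(config.n_features_per_mask)

    def _one_mask(mask: str, rng: np.random.Generator):
        informative, stable, sign = _feature_roles(config, rng)
        roles = pd.DataFrame(
            {"informative": informative, "stable": stable, "sign": sign}, index=names
        )
        latent = _latent_matrix(config, labels, informative, sign, rng)
        noise_sd = np.where(
            stable, config.extraction_noise_sd_stable, config.extraction_noise_sd_unstable
        )
        side_pos = np.array([np.flatnonzero(ids == sid)[0] for sid in side_order])

        extractions = []
        for e in (1, 2, 3):
            vals = latent[side_pos] + rng.normal(size=(side_pos.size, latent.shape[1])) * noise_sd
            if e >= 2:
                vals = vals + config.extraction_bias
            _apply_exact_redundancy(vals, informative)
            extractions.append(
                FeatureMatrix(
                    pd.DataFrame(vals, index=side_order, columns=names), mask, str(e), roles
                )
            )
        bundle = SideStudyBundle(tuple(extractions))

        main_vals = latent + rng.normal(size=latent.shape) * noise_sd
        _apply_exact_redundancy(main_vals, informative)
        # first extraction IS the original data for side-study subjects
        main_df = pd.DataFrame(main_vals, index=list(ids), columns=names)
        main_df.loc[side_order, :] = bundle.extractions[0].data.to_numpy()
        main = FeatureMatrix(main_df, mask, "main", roles)
        return main, bundle

    main_lv, side_lv = _one_mask("LV", rng_lv)
    main_rv, side_rv = _one_mask("RV", rng_rv)
    return main_lv, main_rv, side_lv, side_rv


def combine_masks(lv: FeatureMatrix, rv: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of LV and RV tables, aligned by subject id.

    Feature names are prefixed with their mask so the combined table has
    unique columns; RV rows are aligned to the LV subject order by id, not
    by position.
    """
    if set(lv.subject_ids) != set(rv.subject_ids):
        raise AlignmentError("LV and RV tables cover different subjects")
    if lv.extraction_id != rv.extraction_id:
        raise AlignmentError("LV and RV tables come from different extractions")
    rv_aligned = rv.data.loc[lv.subject_ids]
    left = lv.data.add_prefix(f"{lv.mask}__")
    right = rv_aligned.add_prefix(f"{rv.mask}__")
    roles = None
    if lv.roles is not None and rv.roles is not None:
        roles = pd.concat(
            [
                lv.roles.set_axis([f"{lv.mask}__{n}" for n in lv.roles.index]),
                rv.roles.set_axis([f"{rv.mask}__{n}" for n in rv.roles.index]),
            ]
        )
    return FeatureMatrix(pd.concat([left, right], axis=1), "combined", lv.extraction_id, roles)


def combine_bundles(lv: SideStudyBundle, rv: SideStudyBundle) -> SideStudyBundle:
    """Combined-mask side-study bundle (per-extraction mask concatenation)."""
    return SideStudyBundle(
        tuple(
            combine_masks(le, re)
            for le, re in zip(lv.extractions, rv.extractions)
        )
    )


def write_cohort(
    out_dir: str | Path,
    config: CohortConfig,
    subjects: pd.DataFrame,
    tables: tuple[FeatureMatrix, FeatureMatrix, SideStudyBundle, SideStudyBundle],
) -> None:
    """Write subject table, feature tables and a manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / "subjects.csv", index=False)
    main_lv, main_rv, side_lv, side_rv = tables
    main_lv.to_csv(out / "main_LV.csv")
    main_rv.to_csv(out / "main_RV.csv")
    for bundle, mask in ((side_lv, "LV"), (side_rv, "RV")):
        for e in bundle.extractions:
            e.to_csv(out / f"side_{mask}_extraction{e.extraction_id}.csv")
    manifest = {"seed": config.seed, "config": asdict(config), "config_hash": config.config_hash()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
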