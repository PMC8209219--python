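"""Experiment orchestration: the six-approach analysis grid.

Approaches: Original (no side-study information), ICC2 / ICC3 (keep only
features with excellent ICC across two / all three extractions), DAFIT
(augment the main study with the side-study noise model), and
DAFIT_Filt2 / DAFIT_Filt3 (ICC filtering first, then DAFIT — combined
masks only).  For each admissible (approach, mask, model, selection)
cell the repeated-CV harness produces 25 AUC estimates; reports list the
top models per approach by mean AUC, the permutation significance of
each approach's best cell, and the confounder deviance decomposition of
its out-of-fold predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as mz
from .cohort import (
    CohortConfig,
    FeatureMatrix,
    SideStudyBundle,
    combine_bundles,
    combine_masks,
    generate_cohort,
    generate_feature_tables,
)
from .confounders import aggregate_over_splits, decompose, permutation_lrt_over_splits
from .cv import CVResult, evaluate_pipeline, permutation_significance
from .dafit import augment, estimate_noise_profile, pooled_pairwise_differences
from .icc import select_icc2, select_icc3
from .selection import APPROACHES, SelectionSpec, resolve_selection

__all__ = [
    "ExperimentConfig",
    "CohortData",
    "build_cohort_data",
    "prepare_approach_data",
    "run_experiment",
    "report_tables",
    "CONFOUNDER_COLUMNS",
]

CONFOUNDER_COLUMNS = ("age", "bmi", "bsa", "hypertension")

_MASKS_BY_APPROACH = {
    "Original": ("LV", "RV", "combined"),
    "ICC2": ("LV", "RV", "combined"),
    "ICC3": ("LV", "RV", "combined"),
    "DAFIT": ("LV", "RV", "combined"),
    "DAFIT_Filt2": ("combined",),
    "DAFIT_Filt3": ("combined",),
}


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    approaches: tuple[str, ...] = APPROACHES
    masks: tuple[str, ...] = ("LV", "RV", "combined")
    models: tuple[str, ...] = mz.MODEL_NAMES
    selections: tuple[str, ...] | None = None  # None -> all from the threshold table
    subgroup: str = "all"  # all | preserved_EF
    k: int = 5
    repeats: int = 5
    tune: bool = True
    B_permutation: int = 0  # 0 skips the permutation test
    run_confounders: bool = False
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        for a in self.approaches:
            if a not in APPROACHES:
                raise ValueError(f"unknown approach {a!r}")
            if a.startswith("DAFIT_Filt") and "combined" not in self.masks:
                raise ValueError(f"{a} requires the combined mask")
        if self.subgroup not in ("all", "preserved_EF"):
            raise ValueError("subgroup must be 'all' or 'preserved_EF'")
        for m in self.models:
            if m not in mz.MODEL_NAMES:
                raise ValueError(f"unknown model {m!r}")


@dataclass
class CohortData:
    subjects: pd.DataFrame
    main: dict[str, FeatureMatrix]  # LV, RV, combined
    side: dict[str, SideStudyBundle]


def build_cohort_data(config: CohortConfig) -> CohortData:
    subjects = generate_cohort(config)
    main_lv, main_rv, side_lv, side_rv = generate_feature_tables(config, subjects)
    return CohortData(
        subjects=subjects,
        main={
            "LV": main_lv,
            "RV": main_rv,
            "combined": combine_masks(main_lv, main_rv),
        },
        side={
            "LV": side_lv,
            "RV": side_rv,
            "combined": combine_bundles(side_lv, side_rv),
        },
    )


def subgroup_subjects(subjects: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    """Primary analysis keeps everyone; the preserved-EF subgroup keeps
    cases with LVEF >= 50% and all controls."""
    if subgroup == "all":
        return subjects
    if subgroup == "preserved_EF":
        if "lvef" not in subjects.columns:
            raise ValueError("preserved_EF subgroup requires an 'lvef' column")
        keep = (subjects["class_label"] == "control") | (subjects["lvef"] >= 50.0)
        return subjects.loc[keep]
    raise ValueError(f"unknown subgroup {subgroup!r}")


def prepare_approach_data(
    approach: str,
    mask: str,
    data: CohortData,
    subjects: pd.DataFrame,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Modelling matrix, per-row source subjects and subject labels for
    one (approach, mask) cell.

    ICC filters and DAFIT noise profiles are computed from the side-study
    bundle; the modelling rows are restricted to ``subjects`` (which may
    be the preserved-EF subgroup).
    """
    if mask not in _MASKS_BY_APPROACH[approach]:
        raise ValueError(f"{approach} analyses are only fit to the combined masks")
    labels = subjects["class_label"]
    main = data.main[mask]
    main = FeatureMatrix(main.data.loc[list(subjects.index)], main.mask, main.extraction_id)
    bundle = data.side[mask]

    if approach in ("ICC2", "ICC3", "DAFIT_Filt2", "DAFIT_Filt3"):
        selector = select_icc2 if approach.endswith("2") else select_icc3
        kept = selector(bundle)
        if not kept:
            raise RuntimeError(f"{approach}: no feature has excellent ICC")
        main = main.select_features(kept)
        bundle = bundle.select_features(kept)

    if approach in ("DAFIT", "DAFIT_Filt2", "DAFIT_Filt3"):
        profile = estimate_noise_profile(pooled_pairwise_differences(bundle))
        aug_seed = int(np.random.SeedSequence([seed, 131]).generate_state(1)[0] % (2**31))
        augmented = augment(main, profile, m_per_obs=2, seed=aug_seed)
        return augmented.data, augmented.source_subject_id, labels

    groups = pd.Series(main.subject_ids, index=main.subject_ids, name="source_subject_id")
    return main.data, groups, labels


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full grid; returns a bundle with the tidy results table,
    per-approach top-3 tables, permutation and confounder results, and a
    manifest.  Writes CSV/JSON files when ``output_dir`` is set."""
    config.validate()
    data = build_cohort_data(config.cohort)
    subjects = subgroup_subjects(data.subjects, config.subgroup)

    rows = []
    cell_results: dict[tuple, CVResult] = {}
    for approach in config.approaches:
        for mask in _MASKS_BY_APPROACH[approach]:
            if mask not in config.masks:
                continue
            X, groups, labels = prepare_approach_data(
                approach, mask, data, subjects, seed=config.seed
            )
            scope = "combined" if mask == "combined" else "single"
            for sel in resolve_selection(approach, scope):
                if config.selections is not None and sel.method not in config.selections:
                    continue
                for model_name in config.models:
                    if not mz.applicable(model_name, sel.method, approach):
                        continue
                    spec = mz.ModelSpec.with_default_grid(model_name)
                    result = evaluate_pipeline(
                        approach, mask, spec, sel, X, labels, groups,
                        k=config.k, repeats=config.repeats, seed=config.seed,
                        tune=config.tune,
                    )
                    cell_results[(approach, mask, model_name, sel.label)] = result
                    rows.append(
                        {
                            "approach": approach,
                            "mask": mask,
                            "model": model_name,
                            "selection": sel.label,
                            **result.summary,
                            "n_missing": result.n_missing,
                        }
                    )
    results_df = pd.DataFrame(rows)
    top3 = report_tables(results_df)

    permutation: dict[str, dict] = {}
    confounder_rows = []
    for approach in config.approaches:
        sub = results_df[results_df["approach"] == approach]
        if sub.empty:
            continue
        best = sub.sort_values(
            ["mean", "sd", "mask", "model", "selection"],
            ascending=[False, True, True, True, True],
        ).iloc[0]
        key = (approach, best["mask"], best["model"], best["selection"])
        best_result = cell_results[key]

        if config.B_permutation > 0:
            X, groups, labels = prepare_approach_data(
                approach, best["mask"], data, subjects, seed=config.seed
            )
            sel = _spec_from_label(best["selection"])
            perm = permutation_significance(
                approach, best["mask"], mz.ModelSpec.with_default_grid(best["model"]),
                sel, X, labels, groups, B=config.B_permutation,
                k=config.k, repeats=config.repeats, seed=config.seed, tune=config.tune,
            )
            permutation[approach] = {
                "mask": best["mask"],
                "model": best["model"],
                "selection": best["selection"],
                "observed_auc": perm.observed_auc,
                "p_value": perm.p_value,
            }

        if config.run_confounders:
            confounder_rows.extend(
                _confounder_analysis(approach, best, best_result, subjects, seed=config.seed)
            )
    confounders_df = pd.DataFrame(confounder_rows)

    manifest = {
        "seed": config.seed,
        "subgroup": config.subgroup,
        "cohort_config_hash": config.cohort.config_hash(),
        "n_subjects": int(len(subjects)),
        "n_cells": int(len(results_df)),
    }
    bundle = {
        "results": results_df,
        "top3": top3,
        "permutation": permutation,
        "confounders": confounders_df,
        "manifest": manifest,
    }
    if config.output_dir:
        _write_bundle(Path(config.output_dir), bundle)
    return bundle


def _spec_from_label(label: str) -> SelectionSpec:
    if label.startswith("corr@"):
        return SelectionSpec("corr", corr_threshold=float(label.split("@")[1]))
    if label.startswith("pca@"):
        return SelectionSpec("pca", pca_variance_fraction=float(label.split("@")[1]))
    return SelectionSpec(label)


def _confounder_analysis(
    approach: str, best: pd.Series, result: CVResult, subjects: pd.DataFrame, seed: int
) -> list[dict]:
    rows = []
    for conf in CONFOUNDER_COLUMNS:
        decomps, triples = [], []
        for s in result.splits:
            if np.isnan(s.auc):
                decomps.append(None)
                continue
            # one observation per test subject; augmented siblings reuse
            # their subject's confounder value
            subj_of_row = [rid.split("::")[0] for rid in s.row_ids]
            c = subjects.loc[subj_of_row, conf].to_numpy(dtype=float)
            decomps.append(decompose(s.y_true, c, s.scores, confounder_name=conf))
            triples.append((s.y_true, c, s.scores))
        summary = aggregate_over_splits(decomps)
        obs_lrt, p = permutation_lrt_over_splits(triples, B=100, seed=seed)
        rows.append(
            {
                "approach": approach,
                "mask": best["mask"],
                "model": best["model"],
                "selection": best["selection"],
                "confounder": conf,
                **{k: v for k, v in summary.items()},
                "median_lrt": obs_lrt,
                "p_value": p,
            }
        )
    return rows


def report_tables(results: pd.DataFrame, top_n: int = 3) -> dict[str, pd.DataFrame]:
    """Per-approach top-``top_n`` tables sorted by mean AUC (ties broken
    by SD ascending, then by mask/model/selection name)."""
    if results.empty:
        raise ValueError("no results to report")
    tables = {}
    for approach, sub in results.groupby("approach", sort=False):
        ordered = sub.sort_values(
            ["mean", "sd", "mask", "model", "selection"],
            ascending=[False, True, True, True, True],
        )
        cols = ["mask", "model", "selection", "mean", "sd", "median", "min", "max"]
        tables[approach] = ordered.head(top_n)[cols].reset_index(drop=True)
    return tables


def _write_bundle(out: Path, bundle: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["results"].to_csv(out / "results.csv", index=False)
    for approach, table in bundle["top3"].items():
        table.to_csv(out / f"top3_{approach}.csv", index=False)
    (out / "permutation.json").write_text(json.dumps(bundle["permutation"], indent=2))
    if len(bundle["confounders"]):
        bundle["confounders"].to_csv(out / "confounders.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
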