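"""End-to-end run: generate -> rule-classify -> train/tune/evaluate -> reclassify -> prognosis.

Every stage persists its outputs (CSV for tables, JSON for summaries) under
the run's output directory, together with a manifest recording all seeds, the
configuration hash and record counts per stage, so a run is reproducible and
auditable stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ccs import classify_cohort
from .classifier import (
    DEFAULT_ALPHA_GRID,
    SubtypeClassifier,
    apply_to_undetermined,
    build_feature_frame,
    evaluate,
    split_cohort,
)
from .config import GeneratorConfig, default_config
from .generator import generate_cohort, write_cohort_csv
from .prognosis import compare_groups


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=default_config)
    n_cases: int = 20000
    seed_generation: int = 1
    seed_split: int = 2
    seed_cv: int = 3
    seed_bootstrap: int = 4
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    n_bootstrap: int = 2000
    horizon_years: float = 5.0
    include_silent_infarcts: bool = True
    train_fraction: float = 0.85
    output_dir: str = "run_output"

    def validate(self) -> None:
        self.generator.validate()
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")

    def manifest(self) -> dict:
        cfg_hash = hashlib.sha256(self.generator.to_json_str().encode()).hexdigest()[:16]
        return {
            "package_version": __version__,
            "n_cases": self.n_cases,
            "seeds": {
                "generation": self.seed_generation, "split": self.seed_split,
                "cv": self.seed_cv, "bootstrap": self.seed_bootstrap,
            },
            "alpha_grid": [float(a) for a in self.alpha_grid],
            "n_bootstrap": self.n_bootstrap,
            "horizon_years": self.horizon_years,
            "include_silent_infarcts": self.include_silent_infarcts,
            "train_fraction": self.train_fraction,
            "generator_config_sha256": cfg_hash,
        }


def filter_silent_infarcts(cohort: pd.DataFrame, include: bool) -> pd.DataFrame:
    """Drop imaging-only (silent) infarcts when ``include`` is False."""
    if include:
        return cohort
    return cohort[~cohort["silent_infarct"]].reset_index(drop=True)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True) + "\n")


def _rates_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def baseline_table(cohort: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by evident+probable assigned subtype."""
    merged = cohort.merge(assignments, on="case_id")
    truth = merged[merged["confidence"].isin(["EVIDENT", "PROBABLE"])]
    rows = []
    for sub, g in truth.groupby("subtype"):
        rows.append({
            "subtype": sub, "n": len(g),
            "age_mean": g["age"].mean(), "age_sd": g["age"].std(),
            "female_pct": 100 * (g["sex"] == "female").mean(),
            "urban_pct": 100 * g["urban"].mean(),
            "diabetes_pct": 100 * g["diabetes"].mean(),
            "chd_pct": 100 * g["chd"].mean(),
            "hypertension_pct": 100 * g["hypertension"].mean(),
            "cardioaortic_source_pct": 100 * g["cardioaortic_source"].isin(["low_risk", "high_risk"]).mean(),
            "sbp_mean": g["sbp"].mean(), "sbp_sd": g["sbp"].std(),
            "dbp_mean": g["dbp"].mean(), "dbp_sd": g["dbp"].std(),
            "bmi_mean": g["bmi"].mean(), "bmi_sd": g["bmi"].std(),
        })
    return pd.DataFrame(rows).sort_values("subtype").reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also persisted as JSON files).

    A stage failure writes a FAILED marker naming the stage and re-raises, so
    partial outputs stay on disk for inspection.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"manifest": config.manifest()}
    stage = "generate"
    try:
        cohort = generate_cohort(config.generator, config.n_cases, seed=config.seed_generation)
        cohort = filter_silent_infarcts(cohort, config.include_silent_infarcts)
        write_cohort_csv(cohort, outdir / "cohort.csv")
        report["n_after_silent_filter"] = int(len(cohort))

        stage = "classify-ccs"
        assignments, summary = classify_cohort(cohort)
        assignments.to_csv(outdir / "assignments.csv", index=False)
        _write_json(outdir / "ccs_summary.json", summary)
        report["ccs_summary"] = summary

        stage = "train"
        merged = cohort.merge(assignments, on="case_id")
        truth = merged[merged["confidence"].isin(["EVIDENT", "PROBABLE"])]
        y = truth["subtype"].to_numpy()
        train, test, y_train, y_test = split_cohort(
            truth, y, fraction=config.train_fraction, seed=config.seed_split
        )
        model = SubtypeClassifier(alpha_grid=config.alpha_grid, cv=5,
                                  random_state=config.seed_cv)
        model.fit(build_feature_frame(train), y_train)
        model.to_json(outdir / "model.json")
        ev_report = evaluate(model, build_feature_frame(test), y_test,
                             n_bootstrap=config.n_bootstrap, seed=config.seed_bootstrap)
        _write_json(outdir / "evaluation.json", ev_report.to_dict())
        report["evaluation"] = ev_report.to_dict()
        report["tuned_alpha"] = model.alpha_

        stage = "reclassify"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            predictions = apply_to_undetermined(model, cohort, assignments)
        predictions.to_csv(outdir / "undetermined_predictions.csv", index=False)
        report["n_reclassified"] = int(len(predictions))

        stage = "baseline-table"
        table = baseline_table(cohort, assignments)
        _rates_csv(table, outdir / "baseline_table.csv")

        stage = "prognosis"
        ep = merged["confidence"].isin(["EVIDENT", "PROBABLE"])
        truth_groups = np.where(ep, merged["subtype"], None)
        truth_rates = compare_groups(merged, truth_groups, horizon=config.horizon_years)
        _rates_csv(truth_rates, outdir / "rates_truth.csv")
        report["rates_truth"] = truth_rates.to_dict(orient="records")
        if len(predictions):
            pred_map = predictions.set_index("case_id")["predicted"]
            ml_groups = merged["case_id"].map(pred_map).to_numpy()
            ml_rates = compare_groups(merged, ml_groups, horizon=config.horizon_years)
        else:
            ml_rates = truth_rates.iloc[0:0]
        _rates_csv(ml_rates, outdir / "rates_ml.csv")
        report["rates_ml"] = ml_rates.to_dict(orient="records")

        _write_json(outdir / "manifest.json", report["manifest"])
        _write_json(outdir / "report.json", report)
    except Exception as exc:  # persist the failure point, keep partial outputs
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    return report
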