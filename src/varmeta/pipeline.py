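"""End-to-end orchestration: ingest, normalise, fit all models, report.

`run_full_analysis` is the single entry point behind the command-line
`fit`/`reproduce` subcommands: it reads one arm-level table per outcome
track, normalises every arm, fits the base treatment-contrast model, one
interaction model per predictor, the drug-class model, the GLP-1 subgroup
interaction with baseline HbA1c, and the corridor-effect variance
comparison, then writes JSON plus aligned-text reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import meta_regression as mr
from . import summary_conversion as sc

__all__ = ["RunConfig", "run_descriptives", "run_full_analysis", "DEFAULT_PREDICTORS"]

log = logging.getLogger("varmeta")

#: The eight predictors screened for treatment-by-covariate interaction.
DEFAULT_PREDICTORS = (
    "age_years",
    "male_pct",
    "bmi",
    "disease_duration_years",
    "baseline_hba1c_pct",
    "trial_duration_weeks",
    "year",
    "drug_class",
)

#: Variables summarised in the descriptive table, with display units.
_DESCRIPTIVE_VARS = (
    ("age_years", "Mean age at baseline (years)"),
    ("male_pct", "Proportion male (%)"),
    ("bmi", "Mean BMI (kg/m2)"),
    ("disease_duration_years", "Mean disease duration (years)"),
    ("baseline_hba1c_pct", "Mean HbA1c at baseline (%)"),
    ("year", "Year"),
    ("trial_duration_weeks", "Duration of treatment (weeks)"),
    ("n", "Number of treated individuals"),
    ("mean_pct", "Mean HbA1c after treatment (%)"),
    ("log_mean", "Log(mean) HbA1c after treatment (%)"),
    ("sd_pct", "SD of HbA1c after treatment (%)"),
    ("lnsd", "Log(SD) of HbA1c after treatment (%)"),
)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    inputs: dict[str, str | Path]  # track -> path
    column_map: Mapping[str, str] | None = None
    ci_level: float = 0.95
    estimation: str = "REML"
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    subgroup_class: str = "GLP-1 receptor agonists"
    subgroup_predictor: str = "baseline_hba1c_pct"
    output_dir: str | Path = "varmeta-results"
    seed: int = 0
    weight_scheme: str = "2n-1"

    def __post_init__(self) -> None:
        known = set(sc.COVARIATE_NAMES) | {"drug_class"}
        unknown = set(self.predictors) - known
        if unknown:
            raise mr.ModelError(f"unknown predictors {sorted(unknown)}")
        for track in self.inputs:
            sc.Track(track)


def _quantiles(values: np.ndarray) -> dict[str, float]:
    """Median/min/Q1/Q3/max with linear interpolation between order
    statistics (the documented quantile convention for all summaries)."""
    v = values[~np.isnan(values)]
    if len(v) == 0:
        return {k: float("nan") for k in ("median", "min", "q1", "q3", "max")}
    q = np.quantile(v, [0.5, 0.0, 0.25, 0.75, 1.0], method="linear")
    return {
        "median": float(q[0]),
        "min": float(q[1]),
        "q1": float(q[2]),
        "q3": float(q[3]),
        "max": float(q[4]),
    }


def run_descriptives(dataset: mr.MetaDataset) -> dict:
    """Descriptive table per treatment group: five-number summaries of
    every analysis variable, missing-arm counts, and drug-class counts."""
    if dataset.n_arms == 0:
        raise mr.ModelError("dataset is empty")
    df = dataset.frame.copy()
    # uncorrected log(SD): the descriptive quantity, before bias correction
    df["lnsd"] = np.log(df["sd_pct"].astype(float))
    out: dict = {"n_trials": dataset.n_trials, "groups": {}}
    for grp, sub in df.groupby(df["treatment"].astype(str)):
        variables = {}
        for col, label in _DESCRIPTIVE_VARS:
            if col in sub.columns:
                vals = sub[col].to_numpy(dtype=float)
            else:  # covariate never recorded: all arms missing
                vals = np.full(len(sub), np.nan)
            variables[col] = {
                "label": label,
                "n_missing": int(np.isnan(vals).sum()),
                **_quantiles(vals),
            }
        entry = {"n_arms": int(len(sub)), "variables": variables}
        if grp == "verum":
            counts = sub["drug_class"].astype(str).value_counts()
            entry["drug_class_counts"] = {str(k): int(v) for k, v in counts.items()}
        out["groups"][grp] = entry
    return out


def _descriptives_text(desc: dict) -> str:
    lines = [f"{'variable':<42}{'group':<10}{'miss':>5}{'median':>10}{'min':>9}{'q1':>9}{'q3':>9}{'max':>10}"]
    for grp, entry in desc["groups"].items():
        for col, v in entry["variables"].items():
            lines.append(
                f"{v['label']:<42}{grp:<10}{v['n_missing']:>5}"
                f"{v['median']:>10.2f}{v['min']:>9.2f}{v['q1']:>9.2f}"
                f"{v['q3']:>9.2f}{v['max']:>10.2f}"
            )
    return "\n".join(lines)


def _interactions_text(rows: Sequence[dict]) -> str:
    head = (
        f"{'predictor':<26}{'miss':>5}  {'verum slope (CI)':<28}"
        f"{'placebo slope (CI)':<28}{'difference (CI)':<28}"
    )
    lines = [head]
    for r in rows:
        def fmt(est, ci):
            return f"{est:.4f} ({ci[0]:.4f}, {ci[1]:.4f})"
        lines.append(
            f"{r['predictor']:<26}{r['n_missing_arms']:>5}  "
            f"{fmt(r['slope_verum'], r['slope_verum_ci']):<28}"
            f"{fmt(r['slope_placebo'], r['slope_placebo_ci']):<28}"
            f"{fmt(r['slope_difference'], r['slope_difference_ci']):<28}"
        )
    return "\n".join(lines)


def _drugclass_text(contrasts: dict) -> str:
    lines = [f"{'drug class':<34}{'n_arms':>7}  {'contrast vs placebo (CI)':<32}"]
    for cls, row in contrasts.items():
        if cls.startswith("_"):
            continue
        flag = "  [unstable: <2 arms]" if row["unstable"] else ""
        lines.append(
            f"{cls:<34}{row['n_arms']:>7}  "
            f"{row['contrast']:.4f} ({row['ci'][0]:.4f}, {row['ci'][1]:.4f}){flag}"
        )
    return "\n".join(lines)


def analyse_track(dataset: mr.MetaDataset, config: RunConfig) -> dict:
    """All models for one outcome track; returns a JSON-serialisable bundle."""
    spec = mr.ModelSpec(
        estimation=config.estimation,
        ci_level=config.ci_level,
        weight_scheme=config.weight_scheme,
    )
    bundle: dict = {
        "track": dataset.track.value,
        "n_arms": dataset.n_arms,
        "n_trials": dataset.n_trials,
    }
    bundle["descriptives"] = run_descriptives(dataset)

    base = mr.fit_base_model(dataset, spec)
    log.info(
        "base model: n_arms_used=%d n_trials_used=%d converged=%s",
        base.n_arms_used, base.n_trials_used, base.converged,
    )
    bundle["base_model"] = base.to_dict()
    median_lnsd_placebo = bundle["descriptives"]["groups"]["placebo"]["variables"][
        "lnsd"
    ]["median"]
    bundle["backtransform"] = {
        "median_lnsd_placebo": median_lnsd_placebo,
        "placebo_sd_pct": mr.backtransform_sd(median_lnsd_placebo),
        "verum_sd_pct": mr.backtransform_sd(
            median_lnsd_placebo, base.coefficients["treatment[verum]"]
        ),
    }

    interactions = []
    for predictor in config.predictors:
        if predictor == "drug_class":
            continue
        res = mr.fit_interaction_model(dataset, predictor, spec)
        log.info(
            "interaction %s: n_missing=%d", predictor, res.n_missing_arms
        )
        interactions.append(res.to_dict())
    bundle["interactions"] = interactions

    if "drug_class" in config.predictors:
        bundle["drug_class"] = mr.fit_drugclass_model(dataset, spec)

    try:
        sub = mr.fit_subgroup(
            dataset, config.subgroup_class, config.subgroup_predictor, spec
        )
        bundle["subgroup"] = {
            "drug_class": config.subgroup_class,
            **sub.to_dict(),
        }
    except mr.ModelError as err:
        bundle["subgroup"] = {"drug_class": config.subgroup_class, "error": str(err)}

    bundle["variance_of_means"] = mr.variance_of_means(dataset, config.ci_level)
    return bundle


def _bundle_text(bundle: dict) -> str:
    base = bundle["base_model"]
    bt = bundle["backtransform"]
    t = base["coefficients"]["treatment[verum]"]
    t_ci = base["ci"]["treatment[verum]"]
    m = base["coefficients"]["log_mean"]
    m_ci = base["ci"]["log_mean"]
    vom = bundle["variance_of_means"]
    parts = [
        f"track: {bundle['track']}   arms: {bundle['n_arms']}   trials: {bundle['n_trials']}",
        "",
        "Base model (treatment-heterogeneity contrast)",
        f"  treatment (verum - placebo) log(SD): {t:.3f} ({t_ci[0]:.3f}, {t_ci[1]:.3f})",
        f"  log(mean) effect:                    {m:.3f} ({m_ci[0]:.3f}, {m_ci[1]:.3f})",
        f"  random-intercept variance tau2:      {base['tau2']:.3f}"
        f" ({base['tau2_ci'][0]:.3f}, {base['tau2_ci'][1]:.3f})",
        f"  residual scale sigma2:               {base['sigma2']:.3f}",
        f"  back-transformed placebo median SD:  {bt['placebo_sd_pct']:.3f}%"
        f"  -> verum: {bt['verum_sd_pct']:.3f}%",
        "",
        "Predictor-by-treatment interactions",
        _interactions_text(bundle["interactions"]),
        "",
    ]
    if "drug_class" in bundle:
        parts += ["Drug-class contrasts vs placebo", _drugclass_text(bundle["drug_class"]), ""]
    parts += [
        "Variance of arm mean HbA1c (corridor-effect check)",
        *(
            f"  {grp}: {row['variance']:.3f} ({row['ci'][0]:.3f}, {row['ci'][1]:.3f})"
            f"  [{row['n_arms']} arms]"
            for grp, row in vom.items()
        ),
        "",
        "Descriptives",
        _descriptives_text(bundle["descriptives"]),
    ]
    return "\n".join(parts)


def run_full_analysis(config: RunConfig) -> dict:
    """Ingest, normalise and analyse every requested track; write outputs.

    Returns the result bundle keyed by track.  Raises on unreadable input
    or model failure (callers exit nonzero)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for track, path in config.inputs.items():
        reports = sc.read_arm_reports(path, config.column_map, track=track)
        records, exclusions = sc.normalise_reports(reports)
        log.info(
            "track %s: %d arms read, %d normalised, %d excluded",
            track, len(reports), len(records), len(exclusions),
        )
        dataset = mr.MetaDataset.from_records(records, track=track)
        bundle = analyse_track(dataset, config)
        bundle["exclusions"] = {
            "n_input_arms": len(reports),
            "n_analysed_arms": len(records),
            "n_excluded_arms": len(exclusions),
            "reasons": pd.Series([e.reason for e in exclusions])
            .value_counts()
            .to_dict()
            if exclusions
            else {},
        }
        results[track] = bundle

        stem = outdir / f"analysis_{track}"
        sc.write_records(records, stem.with_suffix(".records.csv"))
        sc.write_exclusions(exclusions, stem.with_suffix(".exclusions.jsonl"))
        with open(stem.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        with open(stem.with_suffix(".txt"), "w", encoding="utf-8") as fh:
            fh.write(_bundle_text(bundle) + "\n")
    return results
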