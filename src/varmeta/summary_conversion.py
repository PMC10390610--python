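"""Normalisation of heterogeneous arm-level summary statistics.

Randomised-trial publications report the post-treatment HbA1c of an arm in
many forms: mean and SD, mean and SE, mean with a confidence interval, or
medians with quartiles and/or extrema, on the percent (NGSP) or mmol/mol
(IFCC) scale.  This module converts every such report into one canonical
analysis row: percent-scale mean and SD, the bias-corrected log-SD outcome
``ln(SD) + 1/(2n-1)``, its inverse-variance weight ``2n-1``, and the
log-mean covariate.

Arms that cannot be normalised (no resolvable variability statistic, no
sample size, no mean) are excluded, never imputed; each exclusion carries a
machine-readable reason code.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Unit",
    "Treatment",
    "Track",
    "DRUG_CLASSES",
    "COVARIATE_NAMES",
    "ConversionConstants",
    "ArmReport",
    "ArmRecord",
    "Exclusion",
    "ConversionError",
    "convert_location",
    "convert_dispersion",
    "sd_from_se",
    "sd_from_ci",
    "mean_sd_from_quantiles",
    "make_arm_record",
    "normalise_reports",
    "read_arm_reports",
    "records_to_frame",
    "write_records",
    "write_exclusions",
]


class ConversionError(ValueError):
    """Raised when a reported statistic violates its preconditions."""


class Unit(str, enum.Enum):
    PERCENT = "percent"
    MMOL_PER_MOL = "mmol_per_mol"


class Treatment(str, enum.Enum):
    PLACEBO = "placebo"
    VERUM = "verum"


class Track(str, enum.Enum):
    RAW = "raw"
    BASELINE_CORRECTED = "baseline_corrected"


DRUG_CLASSES = (
    "alpha-glucosidase inhibitors",
    "DPP-4 inhibitors",
    "GLP-1 receptor agonists",
    "metformin",
    "SGLT-2 inhibitors",
    "sulfonylureas",
    "thiazolidinediones",
    "combination",
    "other",
    "placebo",
)

#: Canonical baseline / design covariates carried on each arm.
COVARIATE_NAMES = (
    "age_years",
    "male_pct",
    "bmi",
    "disease_duration_years",
    "baseline_hba1c_pct",
    "trial_duration_weeks",
    "year",
)


@dataclass(frozen=True)
class ConversionConstants:
    """IFCC (mmol/mol) to NGSP (%) affine map for HbA1c.

    A location statistic transforms with slope and intercept; a dispersion
    statistic is translation-invariant, so only the slope applies.
    """

    slope: float = 0.0915
    intercept: float = 2.15


CONSTANTS = ConversionConstants()


def convert_location(value: float, unit: Unit | str) -> float:
    """Map an HbA1c location statistic (mean, median, quartile, CI bound)
    to the percent scale."""
    unit = Unit(unit)
    if unit is Unit.PERCENT:
        return float(value)
    return float(value) * CONSTANTS.slope + CONSTANTS.intercept


def convert_dispersion(value: float, unit: Unit | str) -> float:
    """Map an HbA1c dispersion statistic (SD, SE, CI half-width) to the
    percent scale: slope only, no intercept."""
    if value < 0:
        raise ConversionError(f"dispersion statistic must be >= 0, got {value}")
    unit = Unit(unit)
    if unit is Unit.PERCENT:
        return float(value)
    return float(value) * CONSTANTS.slope


def invert_location(value_pct: float) -> float:
    """Percent → mmol/mol inverse of :func:`convert_location`."""
    return (value_pct - CONSTANTS.intercept) / CONSTANTS.slope


def sd_from_se(se: float, n: int) -> float:
    """SD from a standard error of the mean: ``se * sqrt(n)``."""
    if se <= 0:
        raise ConversionError(f"standard error must be > 0, got {se}")
    if n < 2:
        raise ConversionError(f"need n >= 2 to convert an SE, got n={n}")
    return float(se) * math.sqrt(n)


def sd_from_ci(ci_low: float, ci_high: float, n: int, ci_level: float = 0.95) -> float:
    """SD from a normal-theory confidence interval for the mean.

    ``sd = sqrt(n) * (ci_high - ci_low) / (2 * z)`` with ``z`` the standard
    normal quantile at ``(1 + ci_level) / 2``.
    """
    if not ci_low < ci_high:
        raise ConversionError(f"degenerate interval ({ci_low}, {ci_high})")
    if not 0.0 < ci_level < 1.0:
        raise ConversionError(f"ci_level must be in (0, 1), got {ci_level}")
    if n < 2:
        raise ConversionError(f"need n >= 2 to convert a CI, got n={n}")
    z = norm.ppf(0.5 * (1.0 + ci_level))
    return math.sqrt(n) * (ci_high - ci_low) / (2.0 * z)


def _check_ordered(values: Sequence[float], labels: Sequence[str]) -> None:
    for (a, la), (b, lb) in zip(zip(values, labels), list(zip(values, labels))[1:]):
        if a > b:
            raise ConversionError(f"quantiles out of order: {la}={a} > {lb}={b}")


def mean_sd_from_quantiles(
    scenario: str,
    values: Sequence[float],
    n: int,
) -> tuple[float, float]:
    """Estimate (mean, SD) from reported order statistics.

    Three reporting scenarios are supported, with the sample-size-dependent
    weighted means of Luo et al. and the closed-form Wan-type SD estimators
    (normal order-statistic spacings):

    ``min_med_max``
        values = (min, median, max)
    ``q1_med_q3``
        values = (q1, median, q3)
    ``five_number``
        values = (min, q1, median, q3, max)
    """
    if n < 2:
        raise ConversionError(f"need n >= 2, got n={n}")
    v = [float(x) for x in values]

    if scenario == "min_med_max":
        if len(v) != 3:
            raise ConversionError("min_med_max needs (min, median, max)")
        lo, med, hi = v
        _check_ordered(v, ("min", "median", "max"))
        if hi == lo:
            raise ConversionError("degenerate range: min == max")
        w = 4.0 / (4.0 + n**0.75)
        mean = w * (lo + hi) / 2.0 + (1.0 - w) * med
        sd = (hi - lo) / (2.0 * norm.ppf((n - 0.375) / (n + 0.25)))
        return mean, sd

    if scenario == "q1_med_q3":
        if len(v) != 3:
            raise ConversionError("q1_med_q3 needs (q1, median, q3)")
        q1, med, q3 = v
        _check_ordered(v, ("q1", "median", "q3"))
        if q3 == q1:
            raise ConversionError("degenerate IQR: q1 == q3")
        w = 0.7 + 0.39 / n
        mean = w * (q1 + q3) / 2.0 + (1.0 - w) * med
        sd = (q3 - q1) / (2.0 * norm.ppf((0.75 * n - 0.125) / (n + 0.25)))
        return mean, sd

    if scenario == "five_number":
        if len(v) != 5:
            raise ConversionError("five_number needs (min, q1, median, q3, max)")
        lo, q1, med, q3, hi = v
        _check_ordered(v, ("min", "q1", "median", "q3", "max"))
        if hi == lo:
            raise ConversionError("degenerate range: min == max")
        w1 = 2.2 / (2.2 + n)
        w2 = 0.7 - 0.72 / n**0.55
        mean = (
            w1 * (lo + hi) / 2.0
            + w2 * (q1 + q3) / 2.0
            + (1.0 - w1 - w2) * med
        )
        sd = 0.5 * (
            (hi - lo) / (2.0 * norm.ppf((n - 0.375) / (n + 0.25)))
            + (q3 - q1) / (2.0 * norm.ppf((0.75 * n - 0.125) / (n + 0.25)))
        )
        return mean, sd

    raise ConversionError(f"unknown quantile scenario {scenario!r}")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class ArmReport:
    """One trial arm's raw reported summaries, in whatever form published."""

    trial_id: str
    arm_id: str
    treatment: Treatment
    n: int | None = None
    drug_class: str = "other"
    unit: Unit = Unit.PERCENT
    mean: float | None = None
    sd: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float = 0.95
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    min: float | None = None
    max: float | None = None
    covariates: dict[str, float | None] = field(default_factory=dict)
    track: Track = Track.RAW

    def __post_init__(self) -> None:
        self.treatment = Treatment(self.treatment)
        self.unit = Unit(self.unit)
        self.track = Track(self.track)
        if self.drug_class not in DRUG_CLASSES:
            raise ConversionError(
                f"unknown drug class {self.drug_class!r}; expected one of {DRUG_CLASSES}"
            )
        if self.treatment is Treatment.PLACEBO:
            self.drug_class = "placebo"
        unknown = set(self.covariates) - set(COVARIATE_NAMES)
        if unknown:
            raise ConversionError(f"unknown covariates {sorted(unknown)}")


@dataclass(frozen=True)
class ArmRecord:
    """The normalised analysis row derived from one :class:`ArmReport`."""

    trial_id: str
    arm_id: str
    treatment: Treatment
    drug_class: str
    n: int
    mean_pct: float
    sd_pct: float
    lnsd_bc: float
    weight: float
    log_mean: float
    covariates: dict[str, float | None]
    track: Track


@dataclass(frozen=True)
class Exclusion:
    """Record of an arm dropped during normalisation, with the reason."""

    trial_id: str
    arm_id: str
    reason: str
    detail: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "trial_id": self.trial_id,
                "arm_id": self.arm_id,
                "reason": self.reason,
                "detail": self.detail,
            }
        )


def _resolve_sd_pct(report: ArmReport) -> tuple[float, float | None]:
    """Resolve the percent-scale SD (and, for quantile scenarios, a mean
    estimate) using the least-derived statistic available.

    Priority: reported SD > SE > CI > quantiles.
    """
    u = report.unit
    if report.sd is not None:
        return convert_dispersion(report.sd, u), None
    if report.se is not None:
        if report.n is None:
            raise ConversionError("SE reported without sample size")
        return convert_dispersion(sd_from_se(report.se, report.n), u), None
    if report.ci_low is not None and report.ci_high is not None:
        if report.n is None:
            raise ConversionError("CI reported without sample size")
        lo = convert_location(report.ci_low, u)
        hi = convert_location(report.ci_high, u)
        return sd_from_ci(lo, hi, report.n, report.ci_level), None
    if report.median is not None:
        if report.n is None:
            raise ConversionError("quantiles reported without sample size")
        med = convert_location(report.median, u)
        if report.q1 is not None and report.q3 is not None:
            q1 = convert_location(report.q1, u)
            q3 = convert_location(report.q3, u)
            if report.min is not None and report.max is not None:
                lo = convert_location(report.min, u)
                hi = convert_location(report.max, u)
                mean, sd = mean_sd_from_quantiles(
                    "five_number", (lo, q1, med, q3, hi), report.n
                )
            else:
                mean, sd = mean_sd_from_quantiles("q1_med_q3", (q1, med, q3), report.n)
            return sd, mean
        if report.min is not None and report.max is not None:
            lo = convert_location(report.min, u)
            hi = convert_location(report.max, u)
            mean, sd = mean_sd_from_quantiles("min_med_max", (lo, med, hi), report.n)
            return sd, mean
    raise ConversionError("no variability statistic (SD, SE, CI or quantiles)")


def make_arm_record(report: ArmReport) -> ArmRecord:
    """Normalise one arm report into the canonical analysis row.

    Sets the bias-corrected outcome ``lnsd_bc = ln(sd_pct) + 1/(2n-1)``,
    the inverse-variance weight ``2n-1`` and ``log_mean = ln(mean_pct)``.

    Raises :class:`ConversionError` when the arm cannot be normalised;
    callers that process batches should use :func:`normalise_reports`,
    which turns these into logged exclusions.
    """
    if report.n is None:
        raise ConversionError("no sample size reported")
    if report.n < 2:
        raise ConversionError(f"sample size must be >= 2, got {report.n}")

    sd_pct, mean_from_quantiles = _resolve_sd_pct(report)
    if report.mean is not None:
        mean_pct = convert_location(report.mean, report.unit)
    elif mean_from_quantiles is not None:
        mean_pct = mean_from_quantiles
    else:
        raise ConversionError("no mean HbA1c reported")

    if sd_pct <= 0:
        raise ConversionError(f"resolved SD must be > 0, got {sd_pct}")
    if mean_pct <= 0:
        raise ConversionError(f"resolved mean must be > 0, got {mean_pct}")

    n = int(report.n)
    covs = {k: report.covariates.get(k) for k in COVARIATE_NAMES}
    return ArmRecord(
        trial_id=str(report.trial_id),
        arm_id=str(report.arm_id),
        treatment=report.treatment,
        drug_class=report.drug_class,
        n=n,
        mean_pct=mean_pct,
        sd_pct=sd_pct,
        lnsd_bc=math.log(sd_pct) + 1.0 / (2.0 * n - 1.0),
        weight=float(2 * n - 1),
        log_mean=math.log(mean_pct),
        covariates=covs,
        track=report.track,
    )


_REASON_CODES = {
    "no variability": "no_sd",
    "no sample size": "no_n",
    "sample size": "no_n",
    "no mean": "no_mean",
    "without sample size": "no_n",
}


def _reason_code(message: str) -> str:
    for needle, code in _REASON_CODES.items():
        if needle in message:
            return code
    return "invalid"


def normalise_reports(
    reports: Iterable[ArmReport],
) -> tuple[list[ArmRecord], list[Exclusion]]:
    """Normalise a batch of arm reports, excluding (and logging) failures."""
    records: list[ArmRecord] = []
    exclusions: list[Exclusion] = []
    for report in reports:
        try:
            records.append(make_arm_record(report))
        except ConversionError as err:
            exclusions.append(
                Exclusion(
                    trial_id=str(report.trial_id),
                    arm_id=str(report.arm_id),
                    reason=_reason_code(str(err)),
                    detail=str(err),
                )
            )
    return records, exclusions


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = (
    "trial_id", "arm_id", "treatment", "drug_class", "n", "unit",
    "mean", "sd", "se", "ci_low", "ci_high", "ci_level",
    "median", "q1", "q3", "min", "max", "track",
) + COVARIATE_NAMES


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_arm_reports(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    track: Track | str = Track.RAW,
) -> list[ArmReport]:
    """Read arm reports from a delimited text file (one row per arm).

    ``column_map`` maps canonical field names to the file's native headers,
    so externally deposited tables can be ingested without renaming.
    Missing canonical columns are treated as absent statistics.
    """
    df = _read_table(path)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ConversionError(f"mapped columns not found in {path}: {missing}")
        df = df.rename(columns=rename)

    def get(row: pd.Series, col: str):
        if col not in df.columns:
            return None
        val = row[col]
        if pd.isna(val):
            return None
        return val

    reports = []
    for _, row in df.iterrows():
        n = get(row, "n")
        reports.append(
            ArmReport(
                trial_id=str(get(row, "trial_id")),
                arm_id=str(get(row, "arm_id")),
                treatment=Treatment(get(row, "treatment")),
                drug_class=get(row, "drug_class") or "other",
                n=None if n is None else int(n),
                unit=Unit(get(row, "unit") or "percent"),
                mean=get(row, "mean"),
                sd=get(row, "sd"),
                se=get(row, "se"),
                ci_low=get(row, "ci_low"),
                ci_high=get(row, "ci_high"),
                ci_level=float(get(row, "ci_level") or 0.95),
                median=get(row, "median"),
                q1=get(row, "q1"),
                q3=get(row, "q3"),
                min=get(row, "min"),
                max=get(row, "max"),
                covariates={k: get(row, k) for k in COVARIATE_NAMES},
                track=Track(get(row, "track") or track),
            )
        )
    return reports


def records_to_frame(records: Sequence[ArmRecord]) -> pd.DataFrame:
    """Flatten normalised records into the canonical analysis table."""
    rows = []
    for r in records:
        row = {
            "trial_id": r.trial_id,
            "arm_id": r.arm_id,
            "treatment": r.treatment.value,
            "drug_class": r.drug_class,
            "n": r.n,
            "mean_pct": r.mean_pct,
            "sd_pct": r.sd_pct,
            "lnsd_bc": r.lnsd_bc,
            "weight": r.weight,
            "log_mean": r.log_mean,
            "track": r.track.value,
        }
        row.update({k: r.covariates.get(k) for k in COVARIATE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def write_records(records: Sequence[ArmRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def write_exclusions(exclusions: Sequence[Exclusion], path: str | Path) -> None:
    """One JSON object per excluded arm, one per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in exclusions:
            fh.write(e.to_json() + "\n")
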