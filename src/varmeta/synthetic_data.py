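"""Synthetic trial generators with known ground truth.

Two levels of simulation mirror the two levels of the analysis:

* :func:`simulate_individual_trial` draws person-level HbA1c trajectories
  (baseline, change, post value) for one two-arm placebo-controlled trial.
  Treatment heterogeneity is injected as a responder mixture: a fraction
  ``p`` of treated individuals do not respond while the rest get an extra
  change ``d``, inflating the verum arm's post-treatment variance by
  exactly ``p (1-p) d^2`` on top of the propagated baseline and residual
  variance.  A crossover-style flag produces the pathological case where
  person-level heterogeneity leaves arm SDs equal.

* :func:`simulate_meta_dataset` draws an arm-level meta-analysis dataset
  directly from the meta-regression model (trial random intercepts,
  treatment and log-mean fixed effects, optional covariate-by-treatment
  interactions, weight-scaled residuals), for parameter-recovery studies.

All randomness flows through one integer seed per config; identical
configs and seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .meta_regression import MetaDataset, fit_base_model, ModelSpec
from .summary_conversion import COVARIATE_NAMES, ArmReport, Track, Treatment, Unit

__all__ = [
    "IndividualTrialConfig",
    "ArmLevelSimConfig",
    "SimulationError",
    "simulate_individual_trial",
    "simulate_meta_dataset",
    "parameter_recovery",
]


class SimulationError(ValueError):
    """Raised for invalid generative configurations."""


# ---------------------------------------------------------------------------
# Individual-level simulation
# ---------------------------------------------------------------------------

@dataclass
class IndividualTrialConfig:
    """Generative parameters for one two-arm trial at the person level.

    Units are mmol/mol (IFCC), the scale trial publications most often
    report; the emitted arm summaries carry that unit tag so the normal
    conversion path applies.  Defaults describe a typical glucose-lowering
    trial: baseline 66 +/- 10 mmol/mol, a small placebo drift, a clear mean
    treatment effect, and residual change noise chosen so the no-mixture
    post-treatment SD is 12 mmol/mol.
    """

    n_per_arm: int = 200
    baseline_mean: float = 66.0
    baseline_sd: float = 10.0
    placebo_change_mean: float = -2.0
    verum_effect: float = -11.0
    nonresponder_fraction: float = 0.0
    responder_extra_effect: float = 0.0
    residual_change_sd: float = math.sqrt(44.0)  # -> post SD 12 when baseline SD 10
    crossover_negative_dependence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise SimulationError("need at least 2 participants per arm")
        if self.baseline_sd <= 0 or self.residual_change_sd <= 0:
            raise SimulationError("SD parameters must be positive")
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise SimulationError("nonresponder_fraction must lie in [0, 1]")

    def expected_verum_post_sd(self) -> float:
        """Closed-form post-treatment SD in the verum arm under the
        additive model: sqrt(baseline^2 + residual^2 + p(1-p) d^2)."""
        p, d = self.nonresponder_fraction, self.responder_extra_effect
        return math.sqrt(
            self.baseline_sd**2 + self.residual_change_sd**2 + p * (1.0 - p) * d**2
        )


def _summarise_arm(
    trial_id: str,
    arm_id: str,
    treatment: Treatment,
    values: np.ndarray,
    track: Track,
) -> ArmReport:
    return ArmReport(
        trial_id=trial_id,
        arm_id=arm_id,
        treatment=treatment,
        drug_class="other" if treatment is Treatment.VERUM else "placebo",
        n=len(values),
        unit=Unit.MMOL_PER_MOL,
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        track=track,
    )


def simulate_individual_trial(
    config: IndividualTrialConfig,
) -> tuple[pd.DataFrame, tuple[ArmReport, ArmReport], tuple[ArmReport, ArmReport]]:
    """Simulate person-level trajectories for one placebo-controlled trial.

    Returns the individual records plus two pairs of arm summaries:
    (placebo, verum) for the raw post-treatment values and (placebo, verum)
    for the change scores (the baseline-corrected track).
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    raw_reports, change_reports = [], []
    for treatment in (Treatment.PLACEBO, Treatment.VERUM):
        n = config.n_per_arm
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, n)
        eps = rng.normal(0.0, config.residual_change_sd, n)
        change = config.placebo_change_mean + eps
        responder = np.zeros(n, dtype=bool)
        if treatment is Treatment.VERUM:
            change = change + config.verum_effect
            if config.crossover_negative_dependence:
                # The person-level treatment effect is perfectly anti-
                # correlated with the placebo response: individuals who
                # would drift least under placebo respond most.  Arm SDs
                # stay equal although every individual effect differs.
                change = change - 2.0 * eps
            else:
                responder = rng.random(n) >= config.nonresponder_fraction
                change = change + config.responder_extra_effect * responder
        post = baseline + change
        arm_id = treatment.value
        frames.append(
            pd.DataFrame(
                {
                    "arm": arm_id,
                    "treatment": treatment.value,
                    "baseline": baseline,
                    "change": change,
                    "post": post,
                    "responder": responder,
                }
            )
        )
        raw_reports.append(
            _summarise_arm("sim-trial", arm_id, treatment, post, Track.RAW)
        )
        change_reports.append(
            _summarise_arm(
                "sim-trial", arm_id, treatment, change, Track.BASELINE_CORRECTED
            )
        )
    individuals = pd.concat(frames, ignore_index=True)
    return individuals, tuple(raw_reports), tuple(change_reports)


# ---------------------------------------------------------------------------
# Arm-level simulation
# ---------------------------------------------------------------------------

#: Default trial-level covariate generators; location/scale follow the
#: descriptive distribution of published placebo-controlled T2D trials.
_DEFAULT_COVARIATE_GENS: dict[str, dict] = {
    "age_years": {"dist": "normal", "mu": 56.7, "sd": 4.5},
    "male_pct": {"dist": "normal", "mu": 55.0, "sd": 10.0, "lo": 0.0, "hi": 100.0},
    "bmi": {"dist": "normal", "mu": 30.7, "sd": 3.0},
    "disease_duration_years": {"dist": "normal", "mu": 7.6, "sd": 3.5, "lo": 0.0},
    "baseline_hba1c_pct": {"dist": "normal", "mu": 8.2, "sd": 0.7},
    "trial_duration_weeks": {"dist": "lognormal", "mu": math.log(26.0), "sd": 0.35},
    "year": {"dist": "uniform_int", "lo": 1987, "hi": 2020},
}

#: Default drug-class mix for verum arms (share of arms per class).
_DEFAULT_CLASS_MIX: dict[str, float] = {
    "DPP-4 inhibitors": 0.21,
    "GLP-1 receptor agonists": 0.21,
    "thiazolidinediones": 0.17,
    "SGLT-2 inhibitors": 0.15,
    "alpha-glucosidase inhibitors": 0.08,
    "metformin": 0.08,
    "combination": 0.04,
    "sulfonylureas": 0.03,
    "other": 0.03,
}


def _draw(spec: Mapping, rng: np.random.Generator, size: int) -> np.ndarray:
    dist = spec.get("dist", "normal")
    if dist == "normal":
        x = rng.normal(spec["mu"], spec["sd"], size)
    elif dist == "lognormal":
        x = np.exp(rng.normal(spec["mu"], spec["sd"], size))
    elif dist == "uniform":
        x = rng.uniform(spec["lo"], spec["hi"], size)
    elif dist == "uniform_int":
        x = rng.integers(spec["lo"], spec["hi"] + 1, size).astype(float)
    elif dist == "constant":
        x = np.full(size, float(spec["value"]))
    else:
        raise SimulationError(f"unknown distribution {dist!r}")
    if "lo" in spec and dist not in {"uniform", "uniform_int"}:
        x = np.clip(x, spec["lo"], None)
    if "hi" in spec and dist not in {"uniform", "uniform_int"}:
        x = np.clip(x, None, spec["hi"])
    return x


@dataclass
class ArmLevelSimConfig:
    """Generative twin of the meta-regression model.

    Defaults reproduce the design of the published trial corpus this
    package was built around: 174 trials, one placebo arm plus one to
    three verum arms each, arm sizes log-uniform on [5, 8078], placebo /
    verum post-treatment mean HbA1c centred at 8.0% / 7.3%, and the
    arm-level model
    ``lnsd_bc = beta0 + beta_t T + beta_m log_mean + sum_p beta_int[p] P T
    + u_trial + eps`` with ``u ~ N(0, tau2)`` and
    ``eps ~ N(0, sigma2 / (2n-1))``.
    """

    n_trials: int = 174
    verum_arm_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1, 2, 3 verum arms)
    n_range: tuple[int, int] = (5, 8078)
    beta0: float = -2.97
    beta_t: float = 0.037
    beta_m: float = 1.476
    tau2: float = 0.112
    sigma2: float = 1.0
    placebo_logmean_mu: float = math.log(8.0)
    verum_logmean_mu: float = math.log(7.3)
    logmean_sd: float = 0.08
    covariate_gens: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COVARIATE_GENS.items()}
    )
    interaction_betas: dict[str, float] = field(default_factory=dict)
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_MIX)
    )
    class_effects: dict[str, float] = field(default_factory=dict)
    track: Track = Track.RAW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise SimulationError("need at least one trial")
        if self.tau2 < 0 or self.sigma2 < 0:
            raise SimulationError("variance components must be >= 0")
        if self.n_range[0] < 2:
            raise SimulationError("minimum arm size must be >= 2")
        if abs(sum(self.verum_arm_probs) - 1.0) > 1e-9:
            raise SimulationError("verum_arm_probs must sum to 1")
        unknown = set(self.interaction_betas) - set(COVARIATE_NAMES)
        if unknown:
            raise SimulationError(f"interaction on unknown covariates {sorted(unknown)}")


def simulate_meta_dataset(
    config: ArmLevelSimConfig, rng: np.random.Generator | None = None
) -> MetaDataset:
    """Draw one arm-level meta-analysis dataset from the generative model."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_verum = 1 + rng.choice(
        len(config.verum_arm_probs), size=config.n_trials, p=config.verum_arm_probs
    )
    n_arms_per_trial = n_verum + 1
    total = int(n_arms_per_trial.sum())

    trial_idx = np.repeat(np.arange(config.n_trials), n_arms_per_trial)
    # first arm of each trial is the placebo arm
    first = np.r_[0, np.cumsum(n_arms_per_trial)[:-1]]
    is_placebo = np.zeros(total, dtype=bool)
    is_placebo[first] = True
    T = (~is_placebo).astype(float)

    lo, hi = config.n_range
    n_arm = np.exp(rng.uniform(math.log(lo), math.log(hi), total))
    n_arm = np.clip(np.round(n_arm), lo, hi).astype(int)
    weight = 2.0 * n_arm - 1.0

    log_mean = rng.normal(
        np.where(is_placebo, config.placebo_logmean_mu, config.verum_logmean_mu),
        config.logmean_sd,
    )

    covs = {
        name: np.repeat(_draw(spec, rng, config.n_trials), n_arms_per_trial)
        for name, spec in config.covariate_gens.items()
    }

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    trial_class = rng.choice(len(classes), size=config.n_trials, p=probs)
    drug_class = np.where(
        is_placebo, "placebo", np.array(classes, dtype=object)[trial_class[trial_idx]]
    )

    u = rng.normal(0.0, math.sqrt(config.tau2), config.n_trials)
    eps = rng.normal(0.0, np.sqrt(config.sigma2 / weight))
    lnsd_bc = (
        config.beta0
        + config.beta_t * T
        + config.beta_m * log_mean
        + u[trial_idx]
        + eps
    )
    for name, b in config.interaction_betas.items():
        lnsd_bc = lnsd_bc + b * covs[name] * T
    for cls, extra in config.class_effects.items():
        lnsd_bc = lnsd_bc + extra * (drug_class == cls).astype(float)

    arm_counter = np.concatenate([np.arange(k) for k in n_arms_per_trial])
    frame = pd.DataFrame(
        {
            "trial_id": [f"T{j:05d}" for j in trial_idx],
            "arm_id": [f"T{j:05d}a{a}" for j, a in zip(trial_idx, arm_counter)],
            "treatment": np.where(is_placebo, "placebo", "verum"),
            "drug_class": drug_class,
            "n": n_arm,
            "mean_pct": np.exp(log_mean),
            "sd_pct": np.exp(lnsd_bc - 1.0 / weight),
            "lnsd_bc": lnsd_bc,
            "weight": weight,
            "log_mean": log_mean,
            "track": config.track.value,
        }
    )
    for name in COVARIATE_NAMES:
        frame[name] = covs.get(name, np.full(total, np.nan))
    return MetaDataset(frame=frame, track=config.track)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def parameter_recovery(
    config: ArmLevelSimConfig,
    n_reps: int,
    *,
    estimation: str = "REML",
    tau2_ci: bool = True,
) -> dict:
    """Repeated simulate-then-fit validation of the base model.

    For each replicate a fresh dataset is drawn from ``config`` and the
    base model refitted; the table reports mean bias, RMSE, Monte-Carlo
    standard errors and 95% CI coverage for the treatment coefficient, the
    log-mean coefficient and the random-intercept variance.  Replicates
    whose optimiser fails to converge are counted, never dropped silently.
    """
    if n_reps < 2:
        raise SimulationError("need n_reps >= 2 for Monte-Carlo error estimates")
    truth = {"beta_t": config.beta_t, "beta_m": config.beta_m, "tau2": config.tau2}
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n_reps)]
    spec = ModelSpec(estimation=estimation)
    est: dict[str, list[float]] = {k: [] for k in truth}
    cover: dict[str, list[bool]] = {k: [] for k in truth}
    n_nonconverged = 0
    for rng in rngs:
        data = simulate_meta_dataset(config, rng=rng)
        fit = fit_base_model(data, spec, tau2_ci=tau2_ci)
        if not fit.converged:
            n_nonconverged += 1
        est["beta_t"].append(fit.coefficients["treatment[verum]"])
        est["beta_m"].append(fit.coefficients["log_mean"])
        est["tau2"].append(fit.tau2)
        lo, hi = fit.ci["treatment[verum]"]
        cover["beta_t"].append(lo <= truth["beta_t"] <= hi)
        lo, hi = fit.ci["log_mean"]
        cover["beta_m"].append(lo <= truth["beta_m"] <= hi)
        if tau2_ci:
            lo, hi = fit.tau2_ci
            cover["tau2"].append(lo <= truth["tau2"] <= hi)
    table: dict[str, dict] = {}
    for name, values in est.items():
        arr = np.asarray(values)
        bias = arr - truth[name]
        cov_arr = np.asarray(cover[name], dtype=float) if cover[name] else None
        table[name] = {
            "truth": truth[name],
            "mean_estimate": float(arr.mean()),
            "bias": float(bias.mean()),
            "mcse_bias": float(arr.std(ddof=1) / math.sqrt(n_reps)),
            "rmse": float(np.sqrt(np.mean(bias**2))),
            "coverage": None if cov_arr is None else float(cov_arr.mean()),
            "coverage_mcse": (
                None
                if cov_arr is None
                else float(cov_arr.std(ddof=1) / math.sqrt(n_reps))
            ),
        }
    return {
        "n_reps": n_reps,
        "n_nonconverged": n_nonconverged,
        "parameters": table,
    }
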