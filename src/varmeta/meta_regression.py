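"""Weighted random-intercept meta-regression of log-SD outcomes.

The model treats each trial arm as one observation ("arm-based"
formulation).  For arm ``a`` of trial ``j`` with bias-corrected outcome
``y_ja = ln(SD_ja) + 1/(2 n_ja - 1)``:

.. math::

    y_{ja} = x_{ja}^T \\beta + u_j + \\varepsilon_{ja},
    \\qquad u_j \\sim N(0, \\tau^2),
    \\qquad \\varepsilon_{ja} \\sim N(0, \\sigma^2 / w_{ja}),

with inverse-variance weights ``w_ja = 2 n_ja - 1`` and a trial-level
random intercept ``u_j`` absorbing within-trial correlation.  The fixed
part always contains an intercept, a treatment contrast (verum vs placebo,
or a drug-class factor with placebo as reference) and the log of the arm's
mean outcome; interaction models add one predictor and its product with
treatment.

Estimation is restricted maximum likelihood (ML optional).  Writing
``lambda = tau^2 / sigma^2`` and ``G_j = lambda 1 1' + diag(1/w)``, both
``beta`` and ``sigma^2`` have closed-form profile solutions given
``lambda``, and all quantities reduce to per-trial sufficient statistics
via the Sherman-Morrison identity, so one criterion evaluation costs
O(J p^2) regardless of the number of arms.  ``lambda`` is optimised on the
log scale with an explicit check of the tau^2 = 0 boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from .summary_conversion import (
    COVARIATE_NAMES,
    ArmRecord,
    Track,
    records_to_frame,
)

__all__ = [
    "MetaDataset",
    "ModelSpec",
    "FitResult",
    "InteractionResult",
    "ModelError",
    "fit_weighted_lmm",
    "fit_base_model",
    "fit_interaction_model",
    "fit_drugclass_model",
    "fit_subgroup",
    "variance_of_means",
    "backtransform_sd",
]

_CHI2_95_1DF_HALF = chi2.ppf(0.95, 1) / 2.0  # profile-likelihood CI cutoff


class ModelError(ValueError):
    """Raised for invalid model specifications or non-estimable fits."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class MetaDataset:
    """A collection of normalised trial arms ready for meta-regression."""

    frame: pd.DataFrame
    track: Track = Track.RAW

    def __post_init__(self) -> None:
        self.track = Track(self.track)
        required = {"trial_id", "treatment", "n", "lnsd_bc", "weight", "log_mean"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ModelError(f"dataset is missing columns {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Sequence[ArmRecord], track: Track | str = Track.RAW
    ) -> "MetaDataset":
        return cls(frame=records_to_frame(records), track=Track(track))

    @property
    def n_arms(self) -> int:
        return len(self.frame)

    @property
    def n_trials(self) -> int:
        return self.frame["trial_id"].nunique()

    def subset(self, mask) -> "MetaDataset":
        return MetaDataset(frame=self.frame.loc[mask].copy(), track=self.track)


@dataclass
class ModelSpec:
    """Fixed-effect terms, estimation method and weighting convention.

    ``fixed_terms`` is an ordered list over {"intercept", "treatment",
    "drug_class", "log_mean", a covariate name, "<covariate>:treatment"}.
    The random part is always a trial-level intercept.
    """

    fixed_terms: tuple[str, ...] = ("intercept", "treatment", "log_mean")
    estimation: str = "REML"
    ci_level: float = 0.95
    weight_scheme: str = "2n-1"  # or "2(n-1)": large-sample lnSD variance

    def __post_init__(self) -> None:
        if "intercept" not in self.fixed_terms:
            raise ModelError("the intercept term is mandatory")
        if not ({"treatment", "drug_class"} & set(self.fixed_terms)):
            raise ModelError("a treatment or drug_class term is mandatory")
        if "log_mean" not in self.fixed_terms:
            raise ModelError("the log_mean adjustment term is mandatory")
        if self.estimation not in {"REML", "ML"}:
            raise ModelError(f"unknown estimation method {self.estimation!r}")
        if self.weight_scheme not in {"2n-1", "2(n-1)"}:
            raise ModelError(f"unknown weight scheme {self.weight_scheme!r}")


@dataclass
class FitResult:
    """Point estimates, uncertainty and bookkeeping from one model fit."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    ci: dict[str, tuple[float, float]]
    tau2: float
    tau2_ci: tuple[float, float]
    sigma2: float
    loglik: float
    n_arms_used: int
    n_trials_used: int
    n_arms_dropped: int
    converged: bool
    estimation: str
    ci_level: float
    terms: tuple[str, ...] = ()
    cov: np.ndarray | None = field(default=None, repr=False)
    warnings: tuple[str, ...] = ()

    def contrast(self, weights: Mapping[str, float]) -> tuple[float, float, tuple[float, float]]:
        """Estimate, SE and Wald CI of a linear combination of coefficients."""
        c = np.array([weights.get(t, 0.0) for t in self.terms])
        est = float(c @ np.array([self.coefficients[t] for t in self.terms]))
        var = float(c @ self.cov @ c)
        se = math.sqrt(max(var, 0.0))
        z = norm.ppf(0.5 * (1.0 + self.ci_level))
        return est, se, (est - z * se, est + z * se)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "tau2": self.tau2,
            "tau2_ci": list(self.tau2_ci),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n_arms_used": self.n_arms_used,
            "n_trials_used": self.n_trials_used,
            "n_arms_dropped": self.n_arms_dropped,
            "converged": self.converged,
            "estimation": self.estimation,
            "ci_level": self.ci_level,
            "warnings": list(self.warnings),
        }


@dataclass
class InteractionResult:
    """Treatment-specific slopes of one predictor and their difference.

    The difference of slopes (verum minus placebo) is the predictor-by-
    treatment interaction coefficient; a nonzero value means outcome
    variability changes with the predictor at a different rate under
    active treatment than under placebo.
    """

    predictor: str
    slope_verum: float
    slope_verum_ci: tuple[float, float]
    slope_placebo: float
    slope_placebo_ci: tuple[float, float]
    slope_difference: float
    slope_difference_ci: tuple[float, float]
    n_missing_arms: int
    fit: FitResult = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "slope_verum": self.slope_verum,
            "slope_verum_ci": list(self.slope_verum_ci),
            "slope_placebo": self.slope_placebo,
            "slope_placebo_ci": list(self.slope_placebo_ci),
            "slope_difference": self.slope_difference,
            "slope_difference_ci": list(self.slope_difference_ci),
            "n_missing_arms": self.n_missing_arms,
        }


# ---------------------------------------------------------------------------
# Design matrix construction
# ---------------------------------------------------------------------------

def _build_design(
    df: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Expand the term list into columns; returns (X, column names, mask of
    complete cases over the required source columns)."""
    verum = (df["treatment"].astype(str) == "verum").to_numpy(dtype=float)
    columns: list[np.ndarray] = []
    names: list[str] = []
    needed: list[str] = []
    for term in terms:
        if term == "intercept":
            columns.append(np.ones(len(df)))
            names.append("intercept")
        elif term == "treatment":
            columns.append(verum)
            names.append("treatment[verum]")
        elif term == "drug_class":
            classes = sorted(
                c for c in df["drug_class"].astype(str).unique() if c != "placebo"
            )
            if not classes:
                raise ModelError("drug_class term requires at least one verum class")
            for cls in classes:
                columns.append((df["drug_class"].astype(str) == cls).to_numpy(float))
                names.append(f"drug_class[{cls}]")
        elif term == "log_mean":
            columns.append(df["log_mean"].to_numpy(dtype=float))
            names.append("log_mean")
            needed.append("log_mean")
        elif term.endswith(":treatment"):
            cov = term[: -len(":treatment")]
            if cov not in df.columns:
                raise ModelError(f"interaction term on unknown covariate {cov!r}")
            columns.append(df[cov].to_numpy(dtype=float) * verum)
            names.append(f"{cov}:treatment[verum]")
            needed.append(cov)
        else:
            if term not in df.columns:
                raise ModelError(f"unknown model term {term!r}")
            columns.append(df[term].to_numpy(dtype=float))
            names.append(term)
            needed.append(term)
    X = np.column_stack(columns)
    mask = np.ones(len(df), dtype=bool)
    for col in set(needed):
        mask &= df[col].notna().to_numpy()
    return X, names, mask


# ---------------------------------------------------------------------------
# Profile REML machinery
# ---------------------------------------------------------------------------

class _SuffStats:
    """Per-trial sufficient statistics for the profiled criterion.

    With ``W_j = diag(w)`` inside trial j and the Sherman-Morrison identity
    ``G_j^{-1} = W_j - c_j w_j w_j'`` where ``c_j = lambda/(1+lambda S_j)``
    and ``S_j = sum(w_j)``, every term of the (restricted) likelihood is a
    function of {S_j, X_j'w_j, w_j'y_j} plus the global weighted cross
    products, independent of the number of arms.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        X, y, w, groups = X[order], y[order], w[order], groups[order]
        _, starts = np.unique(groups, return_index=True)
        starts = np.sort(starts)
        Xw = X * w[:, None]
        self.N, self.p = X.shape
        self.J = len(starts)
        self.S = np.add.reduceat(w, starts)                  # (J,)
        self.s = np.add.reduceat(Xw, starts, axis=0)         # (J, p)
        self.t = np.add.reduceat(w * y, starts)              # (J,)
        self.XtWX = X.T @ Xw
        self.XtWy = Xw.T @ y
        self.ytWy = float(w @ (y * y))
        self.sum_log_w = float(np.sum(np.log(w)))

    def profiled(self, lam: float) -> tuple[np.ndarray, np.ndarray, float, float]:
        """GLS beta, its unscaled information A = X'G^{-1}X, the residual
        quadratic form RSS_G, and sum_j log|G_j|, all at a given lambda."""
        c = lam / (1.0 + lam * self.S)
        A = self.XtWX - (self.s.T * c) @ self.s
        b = self.XtWy - (self.s.T * c) @ self.t
        beta = np.linalg.solve(A, b)
        quad = self.ytWy - float(c @ (self.t * self.t))
        rss = max(quad - float(b @ beta), 1e-300)
        sum_log_G = -self.sum_log_w + float(np.sum(np.log1p(lam * self.S)))
        return beta, A, rss, sum_log_G

    def neg2_profile(self, lam: float, reml: bool) -> float:
        _, A, rss, sum_log_G = self.profiled(lam)
        if reml:
            dof = self.N - self.p
            sigma2 = rss / dof
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            return (
                dof * math.log(sigma2)
                + sum_log_G
                + logdetA
                + dof * (1.0 + math.log(2.0 * math.pi))
            )
        sigma2 = rss / self.N
        return (
            self.N * math.log(sigma2)
            + sum_log_G
            + self.N * (1.0 + math.log(2.0 * math.pi))
        )

    def neg2_at(self, tau2: float, sigma2: float, reml: bool) -> float:
        """The (restricted) deviance at an explicit (tau2, sigma2) point;
        used for profile-likelihood intervals on tau2."""
        lam = tau2 / sigma2
        _, A, rss, sum_log_G = self.profiled(lam)
        val = (
            self.N * math.log(sigma2)
            + sum_log_G
            + rss / sigma2
            + self.N * math.log(2.0 * math.pi)
        )
        if reml:
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            val += logdetA - self.p * math.log(sigma2) - self.p * math.log(2.0 * math.pi)
        return val


_LOGLAM_GRID = np.linspace(-22.0, 10.0, 45)


def _optimise_lambda(stats: _SuffStats, reml: bool) -> tuple[float, bool]:
    """Grid scan plus local refinement of lambda = tau2/sigma2 >= 0."""
    crit0 = stats.neg2_profile(0.0, reml)
    grid_vals = np.array([stats.neg2_profile(math.exp(g), reml) for g in _LOGLAM_GRID])
    k = int(np.argmin(grid_vals))
    lo = _LOGLAM_GRID[max(k - 1, 0)]
    hi = _LOGLAM_GRID[min(k + 1, len(_LOGLAM_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda g: stats.neg2_profile(math.exp(g), reml),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    converged = bool(res.success)
    if crit0 <= res.fun:
        return 0.0, True
    return float(math.exp(res.x)), converged


def _profile_ci_tau2(
    stats: _SuffStats, tau2_hat: float, sigma2_hat: float, reml: bool, level: float
) -> tuple[float, float]:
    """Profile-likelihood interval for the trial random-intercept variance."""
    cutoff = chi2.ppf(level, 1) / 2.0

    def prof(tau2: float) -> float:
        # maximise over sigma2 at fixed tau2 (1-D, log scale)
        res = optimize.minimize_scalar(
            lambda ls: stats.neg2_at(tau2, math.exp(ls), reml),
            bounds=(math.log(sigma2_hat) - 12.0, math.log(sigma2_hat) + 12.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return -0.5 * res.fun

    l_max = prof(tau2_hat)
    target = l_max - cutoff

    # lower bound
    if tau2_hat <= 0 or prof(0.0) >= target:
        lower = 0.0
    else:
        lower = optimize.brentq(
            lambda t: prof(t) - target, 0.0, tau2_hat, xtol=1e-10, rtol=1e-10
        )

    # upper bound: expand a bracket geometrically
    hi = max(tau2_hat, 1e-6) * 2.0
    for _ in range(200):
        if prof(hi) < target:
            break
        hi *= 2.0
    else:
        return lower, math.inf
    upper = optimize.brentq(
        lambda t: prof(t) - target, max(tau2_hat, 1e-12), hi, xtol=1e-10, rtol=1e-10
    )
    return lower, upper


def fit_weighted_lmm(
    dataset: MetaDataset,
    spec: ModelSpec | None = None,
    *,
    fix_lambda: float | None = None,
    tau2_ci: bool = True,
) -> FitResult:
    """Fit the weighted random-intercept model by (restricted) maximum
    likelihood.

    Parameters
    ----------
    dataset
        Normalised arm-level data.
    spec
        Fixed-effect terms, estimation method, CI level and weight scheme.
    fix_lambda
        When given, the variance ratio ``tau2/sigma2`` is held fixed instead
        of optimised (``0.0`` reduces the fit to weighted least squares).
    tau2_ci
        Compute the profile-likelihood interval for ``tau2`` (skipped in
        tight simulation loops where only point estimates are needed).
    """
    spec = spec or ModelSpec()
    df = dataset.frame

    X_full, names, mask = _build_design(df, spec.fixed_terms)
    n_dropped = int((~mask).sum())
    X = X_full[mask]
    y = df.loc[mask, "lnsd_bc"].to_numpy(dtype=float)
    n_arm = df.loc[mask, "n"].to_numpy(dtype=float)
    # Weights are defined only up to a constant: rescaling them rescales
    # sigma2 by the same factor and leaves beta and tau2/sigma2-structure
    # estimable quantities unchanged.  The stored weight column (2n-1 for
    # normalised records) is used as-is; the large-sample alternative
    # 2(n-1) is recomputed from n on request.
    if spec.weight_scheme == "2n-1":
        w = df.loc[mask, "weight"].to_numpy(dtype=float)
    else:
        w = 2.0 * (n_arm - 1.0)
    groups = df.loc[mask, "trial_id"].to_numpy()

    n_trials_used = len(np.unique(groups))
    if n_trials_used < 2:
        raise ModelError("need at least 2 trials with usable arms")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ModelError(f"design matrix is rank deficient; check terms {bad}")

    stats = _SuffStats(X, y, w, groups)
    reml = spec.estimation == "REML"

    if fix_lambda is not None:
        lam, converged = float(fix_lambda), True
    else:
        lam, converged = _optimise_lambda(stats, reml)

    beta, A, rss, _ = stats.profiled(lam)
    dof = stats.N - stats.p if reml else stats.N
    sigma2 = rss / dof
    tau2 = lam * sigma2
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    z = norm.ppf(0.5 * (1.0 + spec.ci_level))
    loglik = -0.5 * stats.neg2_profile(lam, reml)

    if tau2_ci and fix_lambda is None:
        t_ci = _profile_ci_tau2(stats, tau2, sigma2, reml, spec.ci_level)
    else:
        t_ci = (math.nan, math.nan)

    return FitResult(
        coefficients={t: float(b) for t, b in zip(names, beta)},
        standard_errors={t: float(s) for t, s in zip(names, se)},
        ci={
            t: (float(b - z * s), float(b + z * s))
            for t, b, s in zip(names, beta, se)
        },
        tau2=float(tau2),
        tau2_ci=t_ci,
        sigma2=float(sigma2),
        loglik=float(loglik),
        n_arms_used=int(stats.N),
        n_trials_used=int(n_trials_used),
        n_arms_dropped=n_dropped,
        converged=converged,
        estimation=spec.estimation,
        ci_level=spec.ci_level,
        terms=tuple(names),
        cov=cov,
    )


# ---------------------------------------------------------------------------
# Named analyses
# ---------------------------------------------------------------------------

def fit_base_model(dataset: MetaDataset, spec: ModelSpec | None = None, **kw) -> FitResult:
    """The treatment-heterogeneity contrast: intercept + treatment +
    log_mean with a trial random intercept.  The treatment coefficient
    estimates the verum-minus-placebo difference in log(SD)."""
    spec = spec or ModelSpec()
    base = ModelSpec(
        fixed_terms=("intercept", "treatment", "log_mean"),
        estimation=spec.estimation,
        ci_level=spec.ci_level,
        weight_scheme=spec.weight_scheme,
    )
    return fit_weighted_lmm(dataset, base, **kw)


def fit_interaction_model(
    dataset: MetaDataset,
    predictor: str,
    spec: ModelSpec | None = None,
    **kw,
) -> InteractionResult:
    """Base model extended by one predictor and its treatment interaction.

    Returns the predictor's slope in placebo arms (the main effect), in
    verum arms (main effect plus interaction) and their difference (the
    interaction itself), each with a Wald CI from the fitted covariance.
    """
    if predictor not in dataset.frame.columns:
        raise ModelError(f"predictor {predictor!r} not in dataset")
    if dataset.frame[predictor].notna().sum() == 0:
        raise ModelError(f"predictor {predictor!r} is missing on every arm")
    spec = spec or ModelSpec()
    full = ModelSpec(
        fixed_terms=(
            "intercept", "treatment", "log_mean", predictor, f"{predictor}:treatment",
        ),
        estimation=spec.estimation,
        ci_level=spec.ci_level,
        weight_scheme=spec.weight_scheme,
    )
    fit = fit_weighted_lmm(dataset, full, **kw)
    p_term = predictor
    i_term = f"{predictor}:treatment[verum]"
    slope_placebo, _, ci_placebo = fit.contrast({p_term: 1.0})
    slope_verum, _, ci_verum = fit.contrast({p_term: 1.0, i_term: 1.0})
    slope_diff, _, ci_diff = fit.contrast({i_term: 1.0})
    return InteractionResult(
        predictor=predictor,
        slope_verum=slope_verum,
        slope_verum_ci=ci_verum,
        slope_placebo=slope_placebo,
        slope_placebo_ci=ci_placebo,
        slope_difference=slope_diff,
        slope_difference_ci=ci_diff,
        n_missing_arms=fit.n_arms_dropped,
        fit=fit,
    )


def fit_drugclass_model(
    dataset: MetaDataset, spec: ModelSpec | None = None, **kw
) -> dict[str, dict]:
    """Per-drug-class contrasts of log(SD) against placebo.

    The binary treatment indicator is replaced by a drug-class factor with
    placebo as the reference level; log_mean, weights and the trial random
    intercept are kept.  Classes contributing fewer than two arms are
    returned but flagged as unstable.
    """
    classes = [
        c for c in dataset.frame["drug_class"].astype(str).unique() if c != "placebo"
    ]
    if len(classes) < 1:
        raise ModelError("no verum drug classes present")
    spec = spec or ModelSpec()
    full = ModelSpec(
        fixed_terms=("intercept", "drug_class", "log_mean"),
        estimation=spec.estimation,
        ci_level=spec.ci_level,
        weight_scheme=spec.weight_scheme,
    )
    fit = fit_weighted_lmm(dataset, full, **kw)
    counts = dataset.frame["drug_class"].astype(str).value_counts()
    out: dict[str, dict] = {}
    for cls in sorted(classes):
        term = f"drug_class[{cls}]"
        est = fit.coefficients[term]
        out[cls] = {
            "contrast": est,
            "se": fit.standard_errors[term],
            "ci": list(fit.ci[term]),
            "n_arms": int(counts.get(cls, 0)),
            "unstable": bool(counts.get(cls, 0) < 2),
        }
    out["_fit"] = fit.to_dict()
    return out


def subgroup_dataset(dataset: MetaDataset, drug_class: str) -> MetaDataset:
    """Trials containing at least one arm of the class, restricted to that
    class's verum arms plus the placebo arms of those trials."""
    df = dataset.frame
    trials = df.loc[df["drug_class"].astype(str) == drug_class, "trial_id"].unique()
    if len(trials) == 0:
        raise ModelError(f"no trials contain drug class {drug_class!r}")
    mask = df["trial_id"].isin(trials) & (
        (df["drug_class"].astype(str) == drug_class)
        | (df["treatment"].astype(str) == "placebo")
    )
    return dataset.subset(mask)


def fit_subgroup(
    dataset: MetaDataset,
    drug_class: str,
    predictor: str,
    spec: ModelSpec | None = None,
    **kw,
) -> InteractionResult:
    """Predictor-by-treatment interaction within one drug class's trials."""
    return fit_interaction_model(
        subgroup_dataset(dataset, drug_class), predictor, spec, **kw
    )


def variance_of_means(
    dataset: MetaDataset, ci_level: float = 0.95
) -> dict[str, dict]:
    """Sample variance of arm mean HbA1c within each treatment group.

    A markedly smaller variance of means in verum arms signals a corridor
    effect: treatment compressing outcomes toward a target range, which can
    mask person-level heterogeneity.  CIs are chi-square intervals under
    normality.
    """
    out = {}
    for grp, sub in dataset.frame.groupby(dataset.frame["treatment"].astype(str)):
        vals = sub["mean_pct"].to_numpy(dtype=float)
        k = len(vals)
        if k < 2:
            raise ModelError(f"treatment group {grp!r} has fewer than 2 arms")
        s2 = float(np.var(vals, ddof=1))
        alpha = 1.0 - ci_level
        lo = (k - 1) * s2 / chi2.ppf(1.0 - alpha / 2.0, k - 1)
        hi = (k - 1) * s2 / chi2.ppf(alpha / 2.0, k - 1)
        out[grp] = {"variance": s2, "ci": [lo, hi], "n_arms": k}
    return out


def backtransform_sd(median_lnsd: float, delta: float = 0.0) -> float:
    """Back-transform a log(SD) value, optionally shifted by a model
    coefficient, to an SD on the percent scale: ``exp(median_lnsd + delta)``."""
    return math.exp(median_lnsd + delta)
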