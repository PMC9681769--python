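"""Screening and assay statistics.

Covers the statistical layer of the screening platform: the binomial GLM
used to characterise sorter efficiency (fitted here by iteratively
reweighted least squares, written out in full because the fitted surface
and its P = 0.5 inflection are central to the sorter characterisation),
Poisson single-cell encapsulation arithmetic, confusion-matrix metrics,
fluorogenic enzymatic-activity quantification, hyphal-exit rates, and
population-distribution comparisons (Brown-Forsythe variance test and the
Pearson second skewness coefficient).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln, xlogy

__all__ = [
    "EfficiencyModel",
    "ConfusionMatrix",
    "EncapsulationDesign",
    "SeparationWarning",
    "fit_binomial_glm",
    "inflection_point",
    "poisson_occupancy",
    "enzymatic_activity",
    "fold_change",
    "hyphal_exit_rate",
    "compare_populations",
    "binomial_lower_bound",
]


class SeparationWarning(UserWarning):
    """Complete or quasi-complete separation detected in a GLM fit."""


@dataclass
class ConfusionMatrix:
    """Sorting confusion matrix; positives are droplets routed for collection."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        """TP / (TP + FN): recovered fraction of truly positive droplets."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        """TN / (TN + FP): correctly rejected fraction of negative droplets."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")


@dataclass
class EfficiencyModel:
    """Fitted binomial-GLM characterisation of sorter efficiency."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    deviance: float
    aic: float
    log_likelihood: float
    n_obs: int
    converged: bool
    separation: bool
    feature_names: list[str] = field(default_factory=list)

    def linear_predictor(self, voltage: float, flow: float) -> float:
        c = self.coefficients
        eta = c["intercept"] + c["v"] * voltage + c["q"] * flow + c["vq"] * voltage * flow
        return eta

    def predict_prob(self, voltage: float, flow: float) -> float:
        return float(expit(self.linear_predictor(voltage, flow)))


def _design_matrix(table: pd.DataFrame, include_volume: bool) -> tuple[np.ndarray, list[str]]:
    v = table["v_rms"].to_numpy(dtype=float)
    q = table["q_nl_s"].to_numpy(dtype=float)
    cols = [np.ones_like(v), v, q, v * q]
    names = ["intercept", "v", "q", "vq"]
    if include_volume:
        cols.append(table["volume_nl"].to_numpy(dtype=float) - 1.0)
        names.append("vol")
    return np.column_stack(cols), names


def fit_binomial_glm(
    table: pd.DataFrame,
    include_volume: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> EfficiencyModel:
    """Fit the logit-link binomial GLM successes/n ~ V + Q + V:Q by IRLS.

    ``table`` needs columns ``v_rms, q_nl_s, successes, n`` (per-cell
    binomial response; per-attempt Bernoulli coding gives the same
    coefficients but a different AIC).  Iterations stop when the deviance
    changes by less than ``tol``.  Standard errors come from the inverse
    Fisher information and p-values are two-sided Wald tests.  AIC is
    -2*loglik + 2k with the full binomial likelihood, combinatorial term
    included; the deviance is reported against the saturated model.
    Complete separation is detected (diverging linear predictor) and
    flagged rather than silently returned.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 cells to fit the efficiency GLM")
    y = table["successes"].to_numpy(dtype=float)
    m = table["n"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y > m):
        raise ValueError("successes must satisfy 0 <= successes <= n")
    X, names = _design_matrix(table, include_volume)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design: predictor columns are collinear")

    beta = np.zeros(X.shape[1])
    p_obs = np.clip(y.sum() / m.sum(), 1e-6, 1 - 1e-6)
    beta[0] = math.log(p_obs / (1 - p_obs))
    eps = 1e-10
    deviance = np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), eps, 1 - eps)
        w = m * mu * (1 - mu)
        z = eta + (y / m - mu) / (mu * (1 - mu))
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        eta = X @ beta_new
        mu = np.clip(expit(eta), eps, 1 - eps)
        dev_new = 2.0 * float(
            np.sum(xlogy(y, y / (m * mu)) + xlogy(m - y, (m - y) / (m * (1 - mu))))
        )
        beta = beta_new
        if abs(deviance - dev_new) < tol:
            deviance = dev_new
            converged = True
            break
        deviance = dev_new

    eta = X @ beta
    separation = bool(np.max(np.abs(eta)) > 30.0) or not converged
    mu = np.clip(expit(eta), eps, 1 - eps)
    w = m * mu * (1 - mu)
    fisher = X.T @ (X * w[:, None])
    cov = np.linalg.inv(fisher)
    se = np.sqrt(np.diag(cov))
    zscores = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zscores))
    loglik = float(
        np.sum(
            gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)
            + y * np.log(mu) + (m - y) * np.log(1 - mu)
        )
    )
    k = X.shape[1]
    if separation:
        warnings.warn(
            "separation detected: some fitted probabilities are numerically 0/1",
            SeparationWarning,
            stacklevel=2,
        )
    return EfficiencyModel(
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        p_values=dict(zip(names, pvals)),
        deviance=float(deviance),
        aic=-2.0 * loglik + 2.0 * k,
        log_likelihood=loglik,
        n_obs=len(table),
        converged=converged,
        separation=separation,
        feature_names=names,
    )


def inflection_point(
    coefficients,
    fixed_voltage: float | None = None,
    fixed_flow: float | None = None,
) -> float:
    """Solve the P = 0.5 contour of a logistic surface for one predictor.

    ``coefficients`` is a mapping with keys ``intercept, v, q, vq`` (an
    ``EfficiencyModel`` or ``RoutingModel`` may be passed directly).  With
    ``fixed_voltage`` given, returns the flow at which P crosses 0.5, and
    vice versa.  Raises if the effective slope of the free predictor is
    zero at the fixed value.
    """
    c = _as_coeff_dict(coefficients)
    if (fixed_voltage is None) == (fixed_flow is None):
        raise ValueError("fix exactly one of voltage or flow")
    if fixed_voltage is not None:
        slope = c["q"] + c["vq"] * fixed_voltage
        offset = c["intercept"] + c["v"] * fixed_voltage
    else:
        slope = c["v"] + c["vq"] * fixed_flow
        offset = c["intercept"] + c["q"] * fixed_flow
    if slope == 0.0:
        raise ValueError("effective slope of the free predictor is zero")
    return float(-offset / slope)


def _as_coeff_dict(obj) -> dict[str, float]:
    if isinstance(obj, EfficiencyModel):
        return obj.coefficients
    if isinstance(obj, dict):
        return obj
    # duck-typed RoutingModel
    return {
        "intercept": obj.beta0,
        "v": obj.beta_v,
        "q": obj.beta_q,
        "vq": obj.beta_vq,
    }


@dataclass
class EncapsulationDesign:
    """Poisson encapsulation summary for a spore dilution."""

    lam: float
    p0: float
    p1: float
    p_ge1: float
    p_ge2: float
    concentration_per_ml: float | None = None
    droplet_volume_nl: float | None = None

    def expected_counts(self, n_droplets: int) -> dict[str, float]:
        return {
            "empty": n_droplets * self.p0,
            "single": n_droplets * self.p1,
            "occupied": n_droplets * self.p_ge1,
            "multiple": n_droplets * self.p_ge2,
        }


def poisson_occupancy(
    lam: float | None = None,
    concentration_per_ml: float | None = None,
    droplet_volume_nl: float | None = None,
) -> EncapsulationDesign:
    """Poisson occupancy summary from lambda or (concentration, volume).

    lambda = concentration [spores/mL] x droplet volume [nL] x 1e-6 mL/nL;
    P(k) = exp(-lambda) lambda^k / k!.
    """
    if lam is None:
        if concentration_per_ml is None or droplet_volume_nl is None:
            raise ValueError("give lam, or concentration and droplet volume")
        if concentration_per_ml < 0 or droplet_volume_nl < 0:
            raise ValueError("concentration and volume must be >= 0")
        lam = concentration_per_ml * droplet_volume_nl * 1e-6
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    dist = stats.poisson(lam)
    p0 = float(dist.pmf(0))
    p1 = float(dist.pmf(1))
    return EncapsulationDesign(
        lam=float(lam),
        p0=p0,
        p1=p1,
        p_ge1=float(1.0 - p0),
        p_ge2=float(1.0 - p0 - p1),
        concentration_per_ml=concentration_per_ml,
        droplet_volume_nl=droplet_volume_nl,
    )


def enzymatic_activity(
    flu: float,
    flu_blank: float,
    flu_std: float,
    v_f_ml: float,
    dilution_factor: float,
    t_min: float,
    v_sample_ml: float,
    standard_amount: float = 1.9,
) -> float:
    """Enzymatic activity (U/mL) from a 4-MU endpoint plate assay.

    activity = standard_amount * V_F * DF * (FLU - FLU_blank)
               / (FLU_std * t * V_sample)

    where the standard amount is 1.9 nmol/mL of released 4-MU, FLU_std is
    the blank-corrected fluorescence of that standard, and one unit
    releases 1 umol of 4-MU per minute.  A negative blank-corrected
    fluorescence clamps to zero activity with a warning (an assay cannot
    show negative release).
    """
    if flu_std <= 0:
        raise ValueError("FLU_std must be > 0")
    if t_min <= 0 or v_sample_ml <= 0 or v_f_ml <= 0:
        raise ValueError("time and volumes must be > 0")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    delta = flu - flu_blank
    if delta < 0:
        warnings.warn(
            "blank-corrected fluorescence is negative; clamping activity to 0",
            stacklevel=2,
        )
        return 0.0
    return standard_amount * v_f_ml * dilution_factor * delta / (
        flu_std * t_min * v_sample_ml
    )


def fold_change(sample_activity: float, reference_activity: float) -> float:
    """Activity fold change relative to a reference (e.g. wild type)."""
    if reference_activity <= 0:
        raise ValueError("reference activity must be > 0")
    return sample_activity / reference_activity


def hyphal_exit_rate(exited: int, total_including_empty: int) -> float:
    """Percentage of droplets with hyphae exiting, out of all droplets."""
    if total_including_empty <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= exited <= total_including_empty:
        raise ValueError("need 0 <= exited <= total")
    return 100.0 * exited / total_including_empty


def compare_populations(parent, mutant) -> dict[str, float]:
    """Compare parent and mutant intensity populations.

    Performs the Brown-Forsythe variance test (Levene's test on absolute
    deviations from the group median, robust for skewed fluorescence
    data) and reports each group's Pearson second skewness coefficient
    3*(mean - median)/sd.
    """
    parent = np.asarray(parent, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    if parent.size < 3 or mutant.size < 3:
        raise ValueError("each group needs at least 3 values")
    stat, p = stats.levene(parent, mutant, center="median")
    return {
        "levene_statistic": float(stat),
        "levene_p": float(p),
        "skewness_parent": _pearson_skew(parent),
        "skewness_mutant": _pearson_skew(mutant),
    }


def _pearson_skew(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0.0
    return 3.0 * (float(np.mean(x)) - float(np.median(x))) / sd


def binomial_lower_bound(successes: int, n: int, confidence: float = 0.999) -> float:
    """One-sided exact (Clopper-Pearson) lower bound for a proportion.

    The bound is the probability p at which observing ``successes`` or
    more has tail probability 1 - confidence; equivalently the
    Beta(successes, n - successes + 1) quantile at 1 - confidence.
    """
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    if successes == 0:
        return 0.0
    return float(stats.beta.ppf(1.0 - confidence, successes, n - successes + 1))
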