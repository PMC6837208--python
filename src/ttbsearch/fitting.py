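"""Parameter estimation for the search models.

Four estimators cover the model's free parameters:

* ``fit_epsilon`` — grid search for the decision-noise level by matching
  simulated best-so-far pay-off curves to observed ones (least squares).
* ``fit_stop_slope`` / ``fit_ignore_slope`` — linear-probability fits of
  the stop (``S = 0``) and ignore (never returned) indicators on
  ``X_best`` across peak-discovery episodes, giving ``k`` and ``l``.
* ``fit_s0`` — maximum likelihood for the safety-propensity distribution,
  a normal truncated to (0, 1], on the realized safety levels in that range.
* ``fit_probabilistic_logistic`` — logistic regression of pay-off-cue use
  on the best neighbouring pay-off, giving ``beta0`` and ``beta1``.

The observed fitted values ship as defaults on :class:`~ttbsearch.agents.
AgentParams`; these estimators exist to refit on simulated or user-supplied
trajectories and for parameter-recovery checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import truncnorm

from .agents import AgentParams
from .metrics import SafetyRecord, dist_payoff, payoff_curve
from .simulate import PhaseConfig, run_batch

__all__ = [
    "FitResult",
    "fit_epsilon",
    "fit_stop_slope",
    "fit_ignore_slope",
    "fit_s0",
    "fit_probabilistic_logistic",
]


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """An estimate with its uncertainty and optimizer/grid metadata."""

    name: str
    estimate: float | dict
    std_error: float | dict | None = None
    objective: float | None = None
    meta: dict | None = None


# ---------------------------------------------------------------------------
# epsilon: grid search against observed pay-off curves

def fit_epsilon(
    observed_curves: dict[str, np.ndarray],
    grid: Sequence[float],
    *,
    n_sim: int = 8000,
    master_seed: int = 0,
    landscape_seed: int | None = None,
    phase: str = "exploration",
    params: AgentParams | None = None,
    trials_per_landscape: int = 10,
) -> FitResult:
    """Grid-search the noise level epsilon against best-so-far curves.

    ``observed_curves`` maps landscape kind ("poor"/"rich") to a length-30
    mean best-so-far normalized pay-off curve.  For every grid value,
    ``n_sim`` trajectories are simulated (split equally across the kinds)
    and the summed squared curve difference is evaluated; the minimizing
    grid value is returned.  The same master seed (hence the same
    landscapes and decision streams) is used for every grid value, so
    objective differences reflect epsilon alone.  When the observed curves
    come from trajectories on a known landscape population, pass that
    population's seed as ``landscape_seed``: evaluating the grid on the
    same environments removes landscape sampling noise from the objective.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("epsilon grid must be non-empty")
    if any(not 0.0 <= e <= 1.0 for e in grid):
        raise ValueError("epsilon grid values must lie in [0, 1]")
    base = params if params is not None else AgentParams()
    kinds = sorted(observed_curves)
    n_per_kind = max(1, n_sim // len(kinds))
    n_landscapes = max(1, math.ceil(n_per_kind / trials_per_landscape))
    objectives = []
    for eps in grid:
        agent = replace(base, epsilon=eps)
        total = 0.0
        for kind in kinds:
            cfg = PhaseConfig.preset(phase, landscape_kind=kind)
            batch = run_batch(cfg, agent, n_landscapes, trials_per_landscape, master_seed,
                              landscape_seed=landscape_seed)
            total += dist_payoff(observed_curves[kind], payoff_curve(batch, "best_so_far"))
        objectives.append(total)
    best = int(np.argmin(objectives))
    return FitResult(
        name="epsilon",
        estimate=float(grid[best]),
        objective=float(objectives[best]),
        meta={"grid": [float(g) for g in grid], "objectives": [float(o) for o in objectives],
              "n_sim": n_per_kind * len(kinds), "master_seed": master_seed},
    )


# ---------------------------------------------------------------------------
# k and l: linear-probability fits on discovery episodes

def _usable(records: Sequence[SafetyRecord]) -> list[SafetyRecord]:
    return [r for r in records if r.censored != "superseded"]


def fit_stop_slope(records: Sequence[SafetyRecord]) -> FitResult:
    """Through-origin linear-probability fit of P(stop) = k * X_best.

    "Stop" episodes are those where the agent settled immediately on the
    discovered peak (returned with zero excursion, S = 0).
    """
    usable = _usable(records)
    x = np.array([r.x_best for r in usable], dtype=float)
    if len(set(x)) < 2:
        raise FitError("need at least two distinct x_best values to fit k")
    y = np.array([1.0 if (r.returned and r.realized_R == 0) else 0.0 for r in usable])
    fit = sm.OLS(y, x[:, None]).fit()
    return FitResult(
        name="k",
        estimate=float(fit.params[0]),
        std_error=float(fit.bse[0]),
        objective=float(fit.ssr),
        meta={"n_episodes": len(usable)},
    )


def fit_ignore_slope(records: Sequence[SafetyRecord]) -> FitResult:
    """Linear-probability fit of P(never return) = intercept + l * X_best."""
    usable = _usable(records)
    x = np.array([r.x_best for r in usable], dtype=float)
    if len(set(x)) < 2:
        raise FitError("need at least two distinct x_best values to fit l")
    y = np.array([0.0 if r.returned else 1.0 for r in usable])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return FitResult(
        name="l",
        estimate=float(fit.params[1]),
        std_error=float(fit.bse[1]),
        objective=float(fit.ssr),
        meta={"intercept": float(fit.params[0]), "n_episodes": len(usable)},
    )


# ---------------------------------------------------------------------------
# S0: truncated-normal maximum likelihood

def _truncnorm_nll(theta: np.ndarray, s: np.ndarray) -> float:
    mu, log_sigma = theta
    sigma = math.exp(log_sigma)
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    return -float(np.sum(truncnorm.logpdf(s, a, b, loc=mu, scale=sigma)))


def fit_s0(records: Sequence[SafetyRecord] | np.ndarray) -> FitResult:
    """MLE of the safety-propensity distribution N(mu, sigma2) on (0, 1].

    Accepts either :class:`SafetyRecord` lists (the S values with
    ``0 < S <= 1`` are used) or a raw array of safety levels.  Standard
    errors come from the inverse observed information (finite-difference
    Hessian at the optimum).
    """
    if len(records) and isinstance(records[0], SafetyRecord):
        s = np.array([r.S for r in records if r.returned and 0.0 < r.S <= 1.0])
    else:
        s = np.asarray(records, dtype=float)
        s = s[(s > 0.0) & (s <= 1.0)]
    if len(s) < 10:
        raise FitError(f"need at least 10 safety levels in (0, 1], got {len(s)}")
    if np.ptp(s) < 1e-12:
        raise FitError("degenerate sample: all safety levels identical (sigma -> 0)")
    theta0 = np.array([float(np.mean(s)), math.log(max(float(np.std(s)), 1e-3))])
    res = minimize(_truncnorm_nll, theta0, args=(s,), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    if not res.success:
        raise FitError(f"truncated-normal MLE did not converge: {res.message}")
    mu, sigma = res.x[0], math.exp(res.x[1])
    se = _se_from_hessian(res.x, s)
    return FitResult(
        name="s0",
        estimate={"mu": float(mu), "sigma2": float(sigma**2)},
        std_error=se,
        objective=float(res.fun),
        meta={"n": int(len(s))},
    )


def _se_from_hessian(theta: np.ndarray, s: np.ndarray, h: float = 1e-4) -> dict | None:
    """Delta-method standard errors for (mu, sigma2) from the (mu, log sigma) Hessian."""
    n = len(theta)
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ei, ej = np.eye(n)[i] * h, np.eye(n)[j] * h
            hess[i, j] = (
                _truncnorm_nll(theta + ei + ej, s)
                - _truncnorm_nll(theta + ei - ej, s)
                - _truncnorm_nll(theta - ei + ej, s)
                + _truncnorm_nll(theta - ei - ej, s)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) <= 0):
        return None
    sigma = math.exp(theta[1])
    se_mu = math.sqrt(cov[0, 0])
    # var(sigma2) via delta method: sigma2 = exp(2 * log_sigma)
    se_sigma2 = 2.0 * sigma**2 * math.sqrt(cov[1, 1])
    return {"mu": se_mu, "sigma2": se_sigma2}


# ---------------------------------------------------------------------------
# beta0, beta1: logistic regression for the probabilistic model

def fit_probabilistic_logistic(
    pn_max: np.ndarray,
    used_payoff_cue: np.ndarray,
) -> FitResult:
    """Logistic regression of pay-off-cue use on the best neighbour pay-off.

    ``used_payoff_cue`` is the binary outcome (1 = the choice followed the
    pay-off cue rather than the novelty cue); ``pn_max`` the pay-off of the
    most-rewarding neighbouring cell at the decision.  Perfect separation is
    flagged and handled with an L2-penalized refit (no standard errors).
    """
    x = np.asarray(pn_max, dtype=float)
    y = np.asarray(used_payoff_cue, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise FitError("used_payoff_cue must be binary")
    if len(np.unique(y)) < 2:
        raise FitError("both outcome classes must be present")
    design = sm.add_constant(x)
    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0)
        converged = bool(fit.mle_retvals.get("converged", True))
        if (not converged or np.any(~np.isfinite(fit.bse))
                or np.any(np.abs(fit.bse) > 1e3)):
            raise FitError("separation suspected")
        return FitResult(
            name="logistic",
            estimate={"beta0": float(fit.params[0]), "beta1": float(fit.params[1])},
            std_error={"beta0": float(fit.bse[0]), "beta1": float(fit.bse[1])},
            objective=float(-fit.llf),
            meta={"n": int(len(y)), "separation": False},
        )
    except Exception:
        fit = model.fit_regularized(alpha=1.0, disp=0)
        return FitResult(
            name="logistic",
            estimate={"beta0": float(fit.params[0]), "beta1": float(fit.params[1])},
            std_error=None,
            objective=None,
            meta={"n": int(len(y)), "separation": True},
        )
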