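"""Weighted maximum-likelihood calibration of the kinetic model.

Under independent Gaussian measurement errors the maximum-likelihood
estimate minimizes the weighted sum of squared residuals

    J_llk(theta) = sum_d (y_d - y_m(theta))^2 / sigma_d^2,

with sigma_d computed from the experimental replicates (floored at a
fraction of each observable's maximum, since replicate spread can
degenerate to zero at single sampling times). The global search is a
seeded multistart (Latin hypercube over the parameter bounds) with local
trust-region refinement — a scatter-search-style hybrid. Parameter
uncertainty comes from the Cramér–Rao bound: the covariance is
approximated by the inverse Fisher information matrix built from residual
sensitivities, giving ± t_{alpha/2,gamma} sqrt(C_ii) confidence
half-widths with gamma = N_d - n_params degrees of freedom.

Calibration never touches the FBA layer: the kinetic fit alone determines
the dFBA constraints (the architectural point of the continuous model).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .config import ModelConfiguration
from .kinetics import (
    IntegrationError,
    KineticParameters,
    STATE_INDEX,
    simulate,
)

__all__ = [
    "TimeSeriesDataset",
    "OptimizerSettings",
    "FitResult",
    "weighted_llk_cost",
    "fit",
    "confidence_intervals",
    "r_squared",
    "select_product_model",
]

logger = logging.getLogger(__name__)

#: penalty residual assigned to every data point when integration fails at
#: a candidate parameter vector, so global search can continue.
_PENALTY_RESIDUAL = 1e3


@dataclass
class TimeSeriesDataset:
    """Replicate-resolved fermentation measurements.

    ``data`` is tidy with columns (time, observable, replicate, value);
    observables name kinetic states directly, or "X" for total dry-weight
    biomass, or map through ``mapping``. Per-point means and replicate
    standard deviations are precomputed; sigma is floored at
    ``sigma_floor_frac`` times the observable's maximum mean.
    """

    data: pd.DataFrame
    initial_state: np.ndarray
    mapping: dict[str, str] = field(default_factory=dict)
    sigma_floor_frac: float = 0.05
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"time", "observable", "replicate", "value"}
        if not required <= set(self.data.columns):
            raise ValueError(f"dataset must have columns {sorted(required)}")
        self.data = self.data[~self.data.observable.isin(self.exclude)]
        for obs in self.data.observable.unique():
            target = self.mapping.get(obs, obs)
            if target != "X" and target not in STATE_INDEX:
                raise KeyError(f"observable {obs!r} maps to unknown state "
                               f"{target!r}")
        grouped = (self.data.groupby(["observable", "time"])["value"]
                   .agg(["mean", "std", "count"]).reset_index()
                   .sort_values(["observable", "time"], kind="stable"))
        grouped["std"] = grouped["std"].fillna(0.0)
        floors = (grouped.groupby("observable")["mean"].transform(
            lambda s: self.sigma_floor_frac * max(float(s.abs().max()), 1e-12)))
        grouped["sigma"] = np.maximum(grouped["std"], floors)
        self.points = grouped
        if np.any(self.points["sigma"] <= 0):
            raise ValueError("sigma must be > 0 after flooring")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time"].unique())

    def observable_state(self, obs: str) -> str:
        return self.mapping.get(obs, obs)


def _predict_points(
    params: KineticParameters,
    dataset: TimeSeriesDataset,
    config: ModelConfiguration,
) -> np.ndarray:
    """Model predictions aligned with dataset.points rows."""
    t_obs = dataset.times
    t_grid = t_obs if t_obs[0] == 0.0 else np.concatenate([[0.0], t_obs])
    traj = simulate(params, dataset.initial_state, t_grid,
                    rtol=config.rtol, atol=config.atol)
    t_index = {t: i for i, t in enumerate(t_grid)}
    preds = np.empty(dataset.n_points)
    x_total = traj.total_biomass
    for k, row in enumerate(dataset.points.itertuples(index=False)):
        i = t_index[row.time]
        target = dataset.observable_state(row.observable)
        preds[k] = x_total[i] if target == "X" else traj.states[i, STATE_INDEX[target]]
    return preds


def _weighted_residuals(
    params: KineticParameters,
    dataset: TimeSeriesDataset,
    config: ModelConfiguration,
) -> np.ndarray:
    try:
        preds = _predict_points(params, dataset, config)
    except IntegrationError as err:
        logger.warning("integration failed during calibration: %s", err)
        return np.full(dataset.n_points, _PENALTY_RESIDUAL)
    return ((dataset.points["mean"].to_numpy() - preds)
            / dataset.points["sigma"].to_numpy())


def weighted_llk_cost(
    params: KineticParameters,
    dataset: TimeSeriesDataset,
    config: ModelConfiguration,
) -> float:
    """Weighted sum of squared residuals over all data points."""
    r = _weighted_residuals(params, dataset, config)
    return float(r @ r)


@dataclass(frozen=True)
class OptimizerSettings:
    """Multistart + local-refinement budget. ``seed`` is mandatory."""

    seed: int
    n_starts: int = 8
    include_default_start: bool = True
    max_nfev: int = 200
    xtol: float = 1e-10
    ftol: float = 1e-10
    free: tuple[str, ...] | None = None  # subset of config.estimable


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    theta_hat: KineticParameters
    free_names: tuple[str, ...]
    cost: float
    trace: tuple[float, ...]
    seed: int
    n_points: int
    config: ModelConfiguration
    ci_half_widths: dict[str, float] = field(default_factory=dict)
    r2: dict[str, float] = field(default_factory=dict)

    def values(self) -> dict[str, float]:
        return {name: self.theta_hat.get(name) for name in self.free_names}

    def report(self) -> dict:
        return {
            "cost": self.cost,
            "seed": self.seed,
            "n_points": self.n_points,
            "theta_hat": self.values(),
            "ci_half_widths": dict(self.ci_half_widths),
            "r_squared": dict(self.r2),
            "trace": list(self.trace),
        }


def fit(
    dataset: TimeSeriesDataset,
    config: ModelConfiguration,
    settings: OptimizerSettings,
) -> FitResult:
    """Hybrid global/local weighted-least-squares fit.

    Starts are drawn from a seeded Latin hypercube over the configured
    bounds (plus the configuration's own values when
    ``include_default_start``); each is refined with a bounded
    trust-region least-squares solve in unit-normalized parameter space.
    Deterministic given the seed.
    """
    free = tuple(settings.free) if settings.free else config.estimable
    unknown = set(free) - set(config.estimable)
    if unknown:
        raise ValueError(f"free parameters not estimable in config: {sorted(unknown)}")
    lo = np.array([config.bounds[n][0] for n in free])
    hi = np.array([config.bounds[n][1] for n in free])
    span = np.where(hi > lo, hi - lo, 1.0)

    def to_params(x_norm: np.ndarray) -> KineticParameters:
        values = dict(zip(free, lo + np.clip(x_norm, 0, 1) * span))
        return config.params.with_values(values)

    def residuals(x_norm: np.ndarray) -> np.ndarray:
        return _weighted_residuals(to_params(x_norm), dataset, config)

    sampler = qmc.LatinHypercube(d=len(free), seed=settings.seed)
    starts = [sampler.random(1)[0] for _ in range(settings.n_starts)]
    if settings.include_default_start:
        x_default = (np.array([config.params.get(n) for n in free]) - lo) / span
        starts.insert(0, np.clip(x_default, 0.0, 1.0))

    best_x, best_cost, trace = None, np.inf, []
    n_failed = 0
    for x0 in starts:
        r0 = residuals(x0)
        if np.all(r0 == _PENALTY_RESIDUAL):
            n_failed += 1
            trace.append(float(r0 @ r0))
            continue
        sol = least_squares(
            residuals, x0, bounds=(np.zeros(len(free)), np.ones(len(free))),
            max_nfev=settings.max_nfev, xtol=settings.xtol, ftol=settings.ftol)
        cost = float(2.0 * sol.cost)  # least_squares cost is 0.5 * sum r^2
        trace.append(cost)
        if cost < best_cost:
            best_cost, best_x = cost, sol.x
    if best_x is None:
        raise RuntimeError(
            f"all {len(starts)} starts failed to integrate; check bounds "
            f"({n_failed} integration failures)")

    return FitResult(
        theta_hat=to_params(best_x),
        free_names=free,
        cost=best_cost,
        trace=tuple(trace),
        seed=settings.seed,
        n_points=dataset.n_points,
        config=config,
    )


def confidence_intervals(
    fit_result: FitResult,
    dataset: TimeSeriesDataset,
    alpha: float = 0.05,
    rel_step: float = 1e-5,
) -> dict[str, float]:
    """Cramér–Rao confidence half-widths at the fitted parameters.

    Residual sensitivities are computed by central finite differences with
    relative step ``rel_step``; F = J^T J, C = F^{-1} (Moore–Penrose
    pseudo-inverse with a warning when F is numerically singular), and the
    half-width of parameter i is t_{alpha/2,gamma} * sqrt(C_ii) with
    gamma = N_d - n_params. The result is also stored on ``fit_result``.
    """
    free = fit_result.free_names
    gamma = dataset.n_points - len(free)
    if gamma <= 0:
        raise ValueError(
            f"degrees of freedom must be positive, got {gamma} "
            f"({dataset.n_points} points, {len(free)} parameters)")
    config = fit_result.config
    theta = np.array([fit_result.theta_hat.get(n) for n in free])

    def residuals_at(values: np.ndarray) -> np.ndarray:
        return _weighted_residuals(
            fit_result.theta_hat.with_values(dict(zip(free, values))),
            dataset, config)

    jac = np.empty((dataset.n_points, len(free)))
    for i in range(len(free)):
        h = rel_step * max(abs(theta[i]), 1e-8)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        jac[:, i] = (residuals_at(up) - residuals_at(dn)) / (2.0 * h)

    fim = jac.T @ jac
    cond = np.linalg.cond(fim)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            f"Fisher information matrix is numerically singular "
            f"(cond = {cond:.2e}); using pseudo-inverse — some parameters "
            f"are likely structurally non-identifiable", stacklevel=2)
        cov = np.linalg.pinv(fim)
    else:
        cov = np.linalg.inv(fim)
    t_val = stats.t.ppf(1.0 - alpha / 2.0, gamma)
    half = {n: float(t_val * np.sqrt(max(cov[i, i], 0.0)))
            for i, n in enumerate(free)}
    fit_result.ci_half_widths = half
    return half


def r_squared(
    fit_result: FitResult, dataset: TimeSeriesDataset
) -> dict[str, float]:
    """Per-observable R^2 = 1 - SSres/SStot on replicate means.

    Observables with zero variance across sampling times are undefined and
    omitted from the result. Also stored on ``fit_result``.
    """
    preds = _predict_points(fit_result.theta_hat, dataset, fit_result.config)
    pts = dataset.points.assign(pred=preds)
    out: dict[str, float] = {}
    for obs, grp in pts.groupby("observable"):
        y = grp["mean"].to_numpy()
        if len(y) < 2:
            continue
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            continue
        ss_res = float(np.sum((y - grp["pred"].to_numpy()) ** 2))
        out[str(obs)] = 1.0 - ss_res / ss_tot
    fit_result.r2 = out
    return out


def select_product_model(
    dataset: TimeSeriesDataset,
    metabolite: str,
    config: ModelConfiguration,
    settings: OptimizerSettings | None = None,
    candidates: Sequence[str] = ("nitrogen_delayed", "nitrogen_delayed_repressed"),
    criterion: str = "aic",
) -> str:
    """Choose the production-law variant for one secondary metabolite.

    Fits each candidate variant (the metabolite's yield free, everything
    else at the configuration values) and returns the variant with the
    lower information criterion (AIC by default; "cost" compares raw
    weighted costs). Ties go to the first — simpler, un-repressed —
    candidate.
    """
    if metabolite not in config.params.variants:
        raise KeyError(f"{metabolite!r} has no production-variant switch")
    if criterion not in ("aic", "cost"):
        raise ValueError(f"unknown criterion {criterion!r}")
    settings = settings or OptimizerSettings(seed=0, n_starts=2)
    yield_name = f"y_products.{metabolite}"

    best_variant, best_score = None, np.inf
    failures = []
    for variant in candidates:
        variants = dict(config.params.variants)
        variants[metabolite] = variant
        trial = ModelConfiguration(
            name=f"{config.name}:{metabolite}={variant}",
            params=config.params.with_values({}),
            estimable=config.estimable,
            bounds=dict(config.bounds),
            phase_thresholds=config.phase_thresholds,
            rtol=config.rtol, atol=config.atol)
        trial.params.variants = variants
        try:
            res = fit(dataset, trial,
                      OptimizerSettings(seed=settings.seed,
                                        n_starts=settings.n_starts,
                                        max_nfev=settings.max_nfev,
                                        free=(yield_name,)))
        except RuntimeError as err:
            failures.append((variant, str(err)))
            continue
        score = res.cost + (2.0 if criterion == "aic" else 0.0)
        if score < best_score - 1e-12:
            best_score, best_variant = score, variant
    if best_variant is None:
        raise RuntimeError(f"all candidate variants failed to fit: {failures}")
    return best_variant
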