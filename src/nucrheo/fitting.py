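"""Nonlinear least-squares fitting of creep curves to viscoelastic models.

The central objects follow the Model/Results idiom: :class:`CreepModel`
binds a creep-compliance curve to a model family and ``fit()`` returns a
:class:`CreepFitResult` carrying the estimates, 95% confidence bounds,
R-square goodness of fit, residuals and derived physical parameters
(tau, k_ST, alpha for the Burgers family).

The objective is (optionally weighted) least squares on J(t) within
positivity bounds [1e-4, 1e4] in natural units (kPa, kPa*s).  Confidence
bounds are linearized: the parameter covariance is s^2 * (JᵀJ)^-1 at the
optimum, with t-based 95% intervals (n - p degrees of freedom), the
conventional reading of nonlinear-regression "fitting confidence
bounds".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import (
    MODEL_REGISTRY,
    BurgersParams,
    DerivedParams,
    ModelSpec,
    derive_params,
)
from .rheometry import CreepCurve

logger = logging.getLogger(__name__)

__all__ = [
    "CreepModel",
    "CreepFitResult",
    "initial_guess",
    "fit_curve",
    "select_model",
    "batch_fit",
    "PARAM_BOUNDS",
]

# positivity box spanning the physiological values by >= 3 orders of magnitude
PARAM_BOUNDS = (1e-4, 1e4)


def initial_guess(curve: CreepCurve) -> BurgersParams:
    """Heuristic starting values for a Burgers fit.

    k_M from the first compliance sample; the terminal slope of the last
    30% of points gives mu_M and, via the intercept J_inf, k_ST and
    k_KV; tau from the time at which J crosses 63% of the rise from J_0
    to J_inf.  Degenerate curves (flat, non-monotone trend) fall back to
    unit-magnitude defaults with a logged warning.
    """
    t, J = curve.t[curve.valid], curve.J[curve.valid]
    if t.size < 8 or t[-1] - t[0] < 3.0:
        raise ValueError("initial guess requires >= 8 points spanning >= 3 s")
    lo, hi = PARAM_BOUNDS

    def fallback(reason: str) -> BurgersParams:
        logger.warning("initial_guess fallback (%s); using unit-magnitude defaults", reason)
        return BurgersParams(k_M=1.0, k_KV=1.0, mu_M=10.0, mu_KV=1.0)

    J0 = J[0]
    if J0 <= 0 or np.ptp(J) <= 0:
        return fallback("flat or nonpositive curve")
    k_M = np.clip(1.0 / J0, lo, hi)

    tail = slice(int(np.floor(0.7 * t.size)), None)
    slope, intercept = np.polyfit(t[tail], J[tail], 1)
    if slope <= 0 or intercept <= J0:
        if intercept <= J0:
            return fallback("terminal intercept below instantaneous compliance")
        slope = 0.0
    mu_M = np.clip(1.0 / slope if slope > 0 else hi, lo, hi)

    J_inf = intercept
    k_ST = 1.0 / J_inf
    if k_ST >= k_M:
        return fallback("steady-state stiffness above instantaneous stiffness")
    k_KV = np.clip(k_M * k_ST / (k_M - k_ST), lo, hi)

    # time of 63% rise toward the extrapolated plateau approximates tau
    target = J0 + 0.63 * (J_inf - J0)
    crossing = np.flatnonzero(J >= target)
    tau = t[crossing[0]] if crossing.size and t[crossing[0]] > 0 else (t[-1] - t[0]) / 4
    mu_KV = np.clip(tau * k_KV, lo, hi)

    return BurgersParams(k_M=float(k_M), k_KV=float(k_KV), mu_M=float(mu_M), mu_KV=float(mu_KV))


def _init_vector(spec: ModelSpec, curve: CreepCurve) -> np.ndarray:
    """Map the Burgers heuristic onto each family's parameter vector."""
    try:
        g = initial_guess(curve)
    except ValueError:
        g = BurgersParams(1.0, 1.0, 10.0, 1.0)
    d = derive_params(g)
    if spec.model_id == "burgers":
        return g.as_array()
    if spec.model_id == "maxwell":
        return np.array([g.k_M, g.mu_M])
    if spec.model_id == "kelvin_voigt":
        return np.array([d.k_ST, d.tau * d.k_ST])
    if spec.model_id == "sls_kelvin":
        return np.array([g.k_M, g.k_KV, g.mu_KV])
    if spec.model_id == "sls_maxwell":
        return np.array([d.k_ST, max(g.k_M - d.k_ST, PARAM_BOUNDS[0]), g.mu_KV])
    raise KeyError(spec.model_id)


@dataclass
class CreepFitResult:
    """Results of fitting one creep curve to one viscoelastic model."""

    model_id: str
    params: Mapping[str, float]            # natural units (kPa, kPa*s)
    ci95: Mapping[str, tuple[float, float]]
    r_squared: float
    residuals: np.ndarray                  # J_obs - J_fit
    converged: bool
    n_points: int
    aic: float
    curve: CreepCurve = field(repr=False)
    derived: DerivedParams | None = None
    stderr: Mapping[str, float] | None = None

    @property
    def param_values(self) -> np.ndarray:
        return np.array(list(self.params.values()))

    def predict(self, t=None) -> np.ndarray:
        """Model compliance on ``t`` (defaults to the fitted grid)."""
        if t is None:
            t = self.curve.t
        return MODEL_REGISTRY[self.model_id].creep(t, self.param_values)

    def summary(self) -> str:
        """Plain-text summary table in the regression-results style."""
        lines = [
            f"Creep-compliance fit: {self.model_id}",
            "=" * 58,
            f"No. observations: {self.n_points:>6d}    R-squared: {self.r_squared:.6f}",
            f"Converged:        {str(self.converged):>6s}    AIC:       {self.aic:.2f}",
            "-" * 58,
            f"{'param':<10s} {'estimate':>12s} {'[0.025':>12s} {'0.975]':>12s}",
        ]
        for name, value in self.params.items():
            lo, hi = self.ci95[name]
            lines.append(f"{name:<10s} {value:>12.5g} {lo:>12.5g} {hi:>12.5g}")
        if self.derived is not None:
            d = self.derived
            lines += [
                "-" * 58,
                f"tau = {d.tau:.4g} s    k_ST = {d.k_ST:.4g} kPa    "
                f"alpha = {d.alpha:.4g} (kPa s)^-1",
            ]
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the data (with SEM band if available) and the fit."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.plot(c.t, c.J, ".", ms=4, alpha=0.6, label="data")
        if c.sem is not None:
            ax.fill_between(c.t, c.J - c.sem, c.J + c.sem, alpha=0.2, lw=0)
        tt = np.linspace(c.t[0], c.t[-1], 300)
        ax.plot(tt, self.predict(tt), "-", label=f"{self.model_id} fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel(r"creep compliance $J(t)$ (kPa$^{-1}$)")
        ax.legend()
        return ax


class CreepModel:
    """A viscoelastic creep model bound to one compliance curve.

    Parameters
    ----------
    curve : CreepCurve
        The observed compliance series; hard-flagged points are excluded.
    model : str
        Registered family id: burgers, sls_kelvin, sls_maxwell,
        maxwell or kelvin_voigt.
    weights : array-like, optional
        Per-point least-squares weights (default: unweighted).
    """

    def __init__(self, curve: CreepCurve, model: str = "burgers", weights=None):
        if model not in MODEL_REGISTRY:
            valid = ", ".join(sorted(MODEL_REGISTRY))
            raise KeyError(f"unknown model {model!r}; valid ids: {valid}")
        self.curve = curve
        self.spec = MODEL_REGISTRY[model]
        mask = curve.valid
        self.t = curve.t[mask]
        self.J = curve.J[mask]
        if weights is None:
            self.w = np.ones_like(self.J)
        else:
            self.w = np.asarray(weights, dtype=float)[mask]
        if self.t.size <= self.spec.n_params + 2:
            raise ValueError(
                f"need more than {self.spec.n_params + 2} points to fit "
                f"{model}; got {self.t.size}"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "burgers", **kwargs) -> "CreepModel":
        """Build from a tidy frame with columns ``t`` and ``J`` (kPa^-1)."""
        curve = CreepCurve(t=df["t"].to_numpy(), J=df["J"].to_numpy())
        return cls(curve, model=model, **kwargs)

    def fit(self, init: Sequence[float] | None = None,
            bounds: tuple[float, float] = PARAM_BOUNDS) -> CreepFitResult:
        """Minimize the weighted sum of squared compliance residuals.

        Never raises on non-convergence: the result carries
        ``converged=False`` and the best parameters found.  Deterministic
        given (curve, init, bounds).
        """
        spec = self.spec
        x0 = np.asarray(init, dtype=float) if init is not None else _init_vector(spec, self.curve)
        x0 = np.clip(x0, bounds[0], bounds[1])
        sw = np.sqrt(self.w)

        def resid(x):
            return sw * (spec.creep_fn(self.t, *x) - self.J)

        sol = optimize.least_squares(
            resid, x0, bounds=(bounds[0], bounds[1]), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        converged = bool(sol.success)
        if not converged:
            logger.warning("fit of %s did not converge: %s", spec.model_id, sol.message)

        x = sol.x
        fitted = spec.creep_fn(self.t, *x)
        residuals = self.J - fitted
        ss_res = float(np.sum(self.w * residuals**2))
        ss_tot = float(np.sum(self.w * (self.J - np.average(self.J, weights=self.w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

        n, p = self.t.size, spec.n_params
        # Gaussian log-likelihood AIC on the residuals
        aic = n * np.log(max(ss_res, 1e-300) / n) + 2 * p

        stderr, ci = self._linearized_ci(sol.jac, ss_res, n, p, x)
        params = dict(zip(spec.param_names, map(float, x)))
        derived = None
        if spec.model_id == "burgers":
            derived = derive_params(BurgersParams(*x))

        return CreepFitResult(
            model_id=spec.model_id,
            params=params,
            ci95={name: ci[i] for i, name in enumerate(spec.param_names)},
            r_squared=r2,
            residuals=residuals,
            converged=converged,
            n_points=n,
            aic=float(aic),
            curve=self.curve,
            derived=derived,
            stderr={name: stderr[i] for i, name in enumerate(spec.param_names)},
        )

    @staticmethod
    def _linearized_ci(jac, ss_res, n, p, x):
        dof = max(n - p, 1)
        s2 = ss_res / dof
        try:
            jtj = jac.T @ jac
            cov = s2 * np.linalg.inv(jtj)
            var = np.diag(cov)
            if np.any(var < 0) or not np.all(np.isfinite(var)):
                raise np.linalg.LinAlgError("negative or non-finite variance")
            se = np.sqrt(var)
        except np.linalg.LinAlgError:
            logger.warning("singular covariance at the optimum; confidence bounds unbounded")
            se = np.full(p, np.inf)
        tcrit = stats.t.ppf(0.975, dof)
        ci = [(float(xi - tcrit * s), float(xi + tcrit * s)) for xi, s in zip(x, se)]
        return se, ci


def fit_curve(
    curve: CreepCurve,
    model_id: str = "burgers",
    init: Sequence[float] | None = None,
    bounds: tuple[float, float] = PARAM_BOUNDS,
    weights=None,
) -> CreepFitResult:
    """Functional wrapper: fit ``curve`` with one model family."""
    return CreepModel(curve, model=model_id, weights=weights).fit(init=init, bounds=bounds)


def select_model(
    curve: CreepCurve,
    candidates: Sequence[str] = ("burgers", "sls_kelvin", "sls_maxwell"),
) -> list[CreepFitResult]:
    """Fit each candidate family and rank by goodness of fit.

    Primary criterion is R-square (descending); fits whose R² agree
    within 1e-6 are tied and the tie is broken in favour of fewer
    parameters (parsimony).  AIC is reported on every result.  A
    non-converged fit ranks below all converged ones.
    """
    if len(candidates) < 2:
        raise ValueError("model selection requires at least two candidates")
    results = [fit_curve(curve, model_id=m) for m in candidates]

    def sort_key(r: CreepFitResult):
        r2 = r.r_squared if np.isfinite(r.r_squared) else -np.inf
        # quantize R^2 so near-identical fits tie and parsimony decides
        return (not r.converged, -round(r2 / 1e-6) * 1e-6, MODEL_REGISTRY[r.model_id].n_params)

    return sorted(results, key=sort_key)


def batch_fit(
    curves_by_condition: Mapping[str, Sequence[CreepCurve]],
    model_id: str = "burgers",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every curve, tabulate per-condition statistics.

    Returns ``(fits, stats)``: one row per curve with the fitted and
    derived parameters, and a per-condition mean table.  The cross-
    condition coefficient of variation (sample sd over mean of the
    condition means) of each derived parameter is attached as
    ``stats.attrs['cv']``.
    """
    rows = []
    for condition, curves in curves_by_condition.items():
        n_ok = 0
        for curve in curves:
            res = fit_curve(curve, model_id=model_id)
            if not res.converged:
                continue
            n_ok += 1
            row = {"condition": condition, "replicate": curve.replicate,
                   "model": model_id, "r_squared": res.r_squared}
            row.update(res.params)
            if res.derived is not None:
                d = res.derived
                row.update(tau=d.tau, k_ST=d.k_ST, alpha=d.alpha, J_0=d.J_0, J_inf=d.J_inf)
            rows.append(row)
        if n_ok == 0:
            logger.warning("condition %r excluded: no converged fits", condition)
    fits = pd.DataFrame(rows)
    if fits.empty:
        return fits, pd.DataFrame()
    numeric = fits.select_dtypes("number").columns
    stats_table = fits.groupby("condition", sort=False)[list(numeric)].mean()
    means = stats_table
    cv = means.std(axis=0, ddof=1) / means.mean(axis=0)
    stats_table.attrs["cv"] = cv
    return fits, stats_table
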