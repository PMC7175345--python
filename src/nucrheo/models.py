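"""Linear viscoelastic creep-compliance models of the cell nucleus.

The nucleus responds to a step stress like a viscoelastic solid at short
times and a viscoelastic fluid at long times.  The minimal linear model
that captures both regimes is the four-element Burgers material: a
Maxwell arm (spring ``k_M`` in series with dashpot ``mu_M``) in series
with a Kelvin-Voigt arm (spring ``k_KV`` in parallel with dashpot
``mu_KV``).  Its creep compliance is

    J(t) = 1/k_M + (1/k_KV) * (1 - exp(-t/tau)) + t/mu_M,
    tau  = mu_KV / k_KV

with stiffnesses in kPa, viscosities in kPa*s, time in s and J in
kPa^-1 (the unit convention used throughout the package).

Three-element alternatives (Maxwell fluid, Kelvin-Voigt solid, and the
two equivalent representations of the standard linear solid) are
registered alongside for model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BurgersParams",
    "DerivedParams",
    "ModelSpec",
    "MODEL_REGISTRY",
    "creep_burgers",
    "creep_model",
    "derive_params",
    "approx_regimes",
    "sls_maxwell_to_kelvin",
    "sls_kelvin_to_maxwell",
]

# exp() underflows silently below ~ -745; clamp well before that so the
# optimizer can explore degenerate tau without FP warnings
_EXP_CLAMP = -700.0


def _safe_exp(x: np.ndarray | float) -> np.ndarray | float:
    return np.exp(np.maximum(x, _EXP_CLAMP))


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


def _require_nonneg_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time values must be nonnegative")
    return t


@dataclass(frozen=True)
class BurgersParams:
    """Element values of the four-element Burgers material.

    Parameters
    ----------
    k_M : float
        Instantaneous (Maxwell-spring) stiffness, kPa.
    k_KV : float
        Kelvin-Voigt spring stiffness, kPa.
    mu_M : float
        Maxwell dashpot viscosity (steady-state flow), kPa*s.
    mu_KV : float
        Kelvin-Voigt dashpot viscosity, kPa*s.
    """

    k_M: float
    k_KV: float
    mu_M: float
    mu_KV: float

    def __post_init__(self) -> None:
        _require_positive(k_M=self.k_M, k_KV=self.k_KV, mu_M=self.mu_M, mu_KV=self.mu_KV)

    @property
    def tau(self) -> float:
        """Viscoelastic response time mu_KV / k_KV, s."""
        return self.mu_KV / self.k_KV

    def as_array(self) -> np.ndarray:
        return np.array([self.k_M, self.k_KV, self.mu_M, self.mu_KV])


@dataclass(frozen=True)
class DerivedParams:
    """Physical parameters derived from the Burgers elements.

    tau = mu_KV/k_KV separates the dominantly elastic from the
    dominantly viscous regime; k_ST = k_M*k_KV/(k_M+k_KV) is the
    steady-state stiffness (series combination of the two springs);
    alpha = 1/mu_M is the steady-state compliance slope.  E_0 and E_ST
    are the effective instantaneous and steady-state moduli (equal to
    k_M and k_ST for this model); J_0 and J_inf their compliances.
    """

    tau: float          # s
    k_ST: float         # kPa
    alpha: float        # (kPa*s)^-1
    J_0: float          # kPa^-1
    J_inf: float        # kPa^-1
    E_0: float          # kPa
    E_ST: float         # kPa


def derive_params(p: BurgersParams) -> DerivedParams:
    """Compute the derived physical parameters of a Burgers material."""
    tau = p.mu_KV / p.k_KV
    k_st = p.k_M * p.k_KV / (p.k_M + p.k_KV)
    return DerivedParams(
        tau=tau,
        k_ST=k_st,
        alpha=1.0 / p.mu_M,
        J_0=1.0 / p.k_M,
        J_inf=1.0 / k_st,
        E_0=p.k_M,
        E_ST=k_st,
    )


def creep_burgers(t, p: BurgersParams) -> np.ndarray:
    """Burgers creep compliance J(t), kPa^-1, vectorized over ``t`` (s)."""
    t = _require_nonneg_time(t)
    tau = p.mu_KV / p.k_KV
    return 1.0 / p.k_M + (1.0 / p.k_KV) * (1.0 - _safe_exp(-t / tau)) + t / p.mu_M


def approx_regimes(p: BurgersParams, t) -> tuple[np.ndarray, np.ndarray]:
    """Short- and long-time approximations of the Burgers creep curve.

    Returns ``(short_time_J, long_time_J)``: the elastic plateau
    J_0 = 1/k_M valid for t << tau, and the affine steady-state creep
    J_inf + alpha*t = 1/k_ST + t/mu_M valid for t >> tau.
    """
    t = _require_nonneg_time(t)
    d = derive_params(p)
    short = np.full_like(t, d.J_0, dtype=float)
    long = d.J_inf + d.alpha * t
    return short, long


# ---------------------------------------------------------------------------
# model registry


def _creep_maxwell(t, k, mu):
    _require_positive(k=k, mu=mu)
    t = _require_nonneg_time(t)
    return 1.0 / k + t / mu


def _creep_kelvin_voigt(t, k, mu):
    _require_positive(k=k, mu=mu)
    t = _require_nonneg_time(t)
    return (1.0 / k) * (1.0 - _safe_exp(-t * k / mu))


def _creep_sls_kelvin(t, k0, k1, mu1):
    # free spring k0 in series with a Kelvin-Voigt arm (k1 || mu1):
    # finite instantaneous compliance 1/k0, finite plateau 1/k0 + 1/k1
    _require_positive(k0=k0, k1=k1, mu1=mu1)
    t = _require_nonneg_time(t)
    return 1.0 / k0 + (1.0 / k1) * (1.0 - _safe_exp(-t * k1 / mu1))


def _creep_sls_maxwell(t, ke, k1, mu1):
    # equilibrium spring ke in parallel with a Maxwell arm (k1 -- mu1):
    # J(0) = 1/(ke + k1), plateau 1/ke, retardation time
    # tau_ret = mu1*(ke + k1)/(ke*k1)
    _require_positive(ke=ke, k1=k1, mu1=mu1)
    t = _require_nonneg_time(t)
    tau_ret = mu1 * (ke + k1) / (ke * k1)
    return (1.0 / ke) * (1.0 - (k1 / (ke + k1)) * _safe_exp(-t / tau_ret))


def _creep_burgers_tuple(t, k_M, k_KV, mu_M, mu_KV):
    return creep_burgers(t, BurgersParams(k_M, k_KV, mu_M, mu_KV))


@dataclass(frozen=True)
class ModelSpec:
    """A registered creep-compliance model family."""

    model_id: str
    n_params: int
    param_names: tuple[str, ...]
    creep_fn: Callable[..., np.ndarray]

    def creep(self, t, params: Sequence[float]) -> np.ndarray:
        params = tuple(params)
        if len(params) != self.n_params:
            raise ValueError(
                f"{self.model_id} expects {self.n_params} parameters "
                f"{self.param_names}, got {len(params)}"
            )
        return self.creep_fn(t, *params)


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "maxwell": ModelSpec("maxwell", 2, ("k", "mu"), _creep_maxwell),
    "kelvin_voigt": ModelSpec("kelvin_voigt", 2, ("k", "mu"), _creep_kelvin_voigt),
    "sls_kelvin": ModelSpec("sls_kelvin", 3, ("k0", "k1", "mu1"), _creep_sls_kelvin),
    "sls_maxwell": ModelSpec("sls_maxwell", 3, ("ke", "k1", "mu1"), _creep_sls_maxwell),
    "burgers": ModelSpec("burgers", 4, ("k_M", "k_KV", "mu_M", "mu_KV"), _creep_burgers_tuple),
}


def creep_model(model_id: str, t, params: Sequence[float]) -> np.ndarray:
    """Evaluate the creep compliance of a registered model family."""
    try:
        spec = MODEL_REGISTRY[model_id]
    except KeyError:
        valid = ", ".join(sorted(MODEL_REGISTRY))
        raise KeyError(f"unknown model_id {model_id!r}; valid ids: {valid}") from None
    return spec.creep(t, params)


def sls_maxwell_to_kelvin(ke: float, k1: float, mu1: float) -> tuple[float, float, float]:
    """Convert SLS Maxwell-representation parameters to the Kelvin form.

    Both parameterizations describe the same three-element solid; the
    Kelvin form (k0, kv, muv) satisfies k0 = ke + k1,
    kv = ke*(ke + k1)/k1 and muv = mu1*(ke + k1)^2/k1^2, preserving
    J(0), the plateau and the retardation time.
    """
    _require_positive(ke=ke, k1=k1, mu1=mu1)
    k0 = ke + k1
    kv = ke * (ke + k1) / k1
    muv = mu1 * (ke + k1) ** 2 / k1**2
    return k0, kv, muv


def sls_kelvin_to_maxwell(k0: float, kv: float, muv: float) -> tuple[float, float, float]:
    """Inverse of :func:`sls_maxwell_to_kelvin`."""
    _require_positive(k0=k0, kv=kv, muv=muv)
    ke = k0 * kv / (k0 + kv)
    k1 = k0 - ke  # = k0^2/(k0 + kv)
    mu1 = muv * k1**2 / k0**2
    return ke, k1, mu1
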