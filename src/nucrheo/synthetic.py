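"""Synthetic creep traces and expression profiles with known ground truth.

The generator emulates the study conditions of the nucleus creep
experiments: a ~1 kPa step stress held for ~12 s, sampled at 10 Hz,
producing a Burgers response with an instantaneous elastic jump, an
exponential viscoelastic transition (tau ~ 1-2.5 s) and linear
steady-state flow, measured on 10-20 nuclei per condition.

Condition presets carry Burgers ground truth assembled from the
reported fibroblast values:

* ``WT``  — k_M = 0.5 kPa, k_ST = 0.25 kPa (hence k_KV = 0.5 kPa),
  tau = 1.8 s (hence mu_KV = 0.9 kPa*s), mu_M = 9.5 kPa*s.
* ``TKO`` (triple lamin knockout) — k_M = 0.27 kPa, k_ST = 0.15 kPa
  (hence k_KV = 0.3375 kPa), mu_M = 2.3 kPa*s; tau fixed at 1.5 s, the
  midpoint of the reported 1-2.5 s range (hence mu_KV = 0.50625 kPa*s).

Measurement noise is multiplicative Gaussian on the measured length
(aspirated length or indentation depth), default CV 5%: it preserves
positivity and scales with deformation, as camera/contact tracking
errors do.  Identical seeds yield bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .models import BurgersParams, creep_burgers, derive_params
from .rheometry import (
    AspirationTrace,
    CreepCurve,
    IndentationTrace,
    hertz_compliance,
    thin_sample_factor,
)

__all__ = [
    "ConditionPreset",
    "NoiseModel",
    "make_preset",
    "simulate_aspiration",
    "simulate_indentation",
    "simulate_profiles",
    "default_time_grid",
]


@dataclass(frozen=True)
class ConditionPreset:
    """Named Burgers ground truth for a simulated condition."""

    name: str
    burgers: BurgersParams
    note: str = ""


def _wt_params() -> BurgersParams:
    # k_KV from k_ST = k_M*k_KV/(k_M + k_KV) with k_M = 0.5, k_ST = 0.25
    # mu_KV from tau = mu_KV/k_KV with tau = 1.8 s
    return BurgersParams(k_M=0.5, k_KV=0.5, mu_M=9.5, mu_KV=0.9)


def _tko_params() -> BurgersParams:
    k_M, k_ST, tau = 0.27, 0.15, 1.5
    k_KV = k_M * k_ST / (k_M - k_ST)  # invert the series-stiffness identity
    return BurgersParams(k_M=k_M, k_KV=k_KV, mu_M=2.3, mu_KV=tau * k_KV)


def make_preset(name: str, params: BurgersParams | None = None) -> ConditionPreset:
    """Return a named condition preset (``WT``, ``TKO`` or ``custom``)."""
    key = name.lower()
    if key == "wt":
        return ConditionPreset("WT", _wt_params(),
                               "wild-type fibroblast creep response")
    if key == "tko":
        return ConditionPreset("TKO", _tko_params(),
                               "triple lamin-knockout fibroblast; tau fixed at 1.5 s")
    if key == "custom":
        if params is None:
            raise ValueError("custom preset requires explicit BurgersParams")
        return ConditionPreset("custom", params)
    raise ValueError(f"unknown preset {name!r}; expected WT, TKO or custom")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise on the deformation signal."""

    cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("noise cv must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_time_grid(fs: float = 10.0, duration: float = 12.0) -> np.ndarray:
    """Sampling grid from the first post-step frame to ``duration`` s."""
    n = int(round(duration * fs))
    return np.arange(1, n + 1) / fs


def _replicate_params(
    base: BurgersParams, rng: np.random.Generator, biological_cv: float
) -> BurgersParams:
    """Per-replicate ground truth; optional log-normal biological spread.

    ``biological_cv = 0`` (the default) makes every replicate share the
    preset's parameters exactly; a positive value scales each element by
    an independent log-normal factor with that coefficient of variation.
    """
    if biological_cv <= 0:
        return base
    sigma = np.sqrt(np.log1p(biological_cv**2))
    factors = rng.lognormal(-(sigma**2) / 2, sigma, size=4)
    k_M, k_KV, mu_M, mu_KV = base.as_array() * factors
    return BurgersParams(k_M, k_KV, mu_M, mu_KV)


def simulate_aspiration(
    preset: ConditionPreset,
    delta_P: float = 1.0,
    R_p: float = 3.0,
    phi: float = 2.0,
    fs: float = 10.0,
    duration: float = 12.0,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 15,
    phi_convention: str = "numerator",
    biological_cv: float = 0.0,
) -> list[AspirationTrace]:
    """Simulate micropipette-aspiration traces of a Burgers material.

    The aspirated length inverts the half-space relation,
    L_p(t) = J(t) * 3*R_p*delta_P / (2*pi*phi) under the active phi
    convention, and each sample is perturbed by independent
    multiplicative Gaussian noise.  ``biological_cv`` optionally adds a
    per-replicate log-normal spread of the ground-truth elements
    (default off: replicates differ by measurement noise only).
    """
    t = default_time_grid(fs, duration)
    if phi_convention == "numerator":
        factor = 3.0 * R_p * delta_P / (2.0 * np.pi * phi)
    elif phi_convention == "denominator":
        factor = 3.0 * phi * R_p * delta_P / (2.0 * np.pi)
    else:
        raise ValueError(f"unknown phi_convention {phi_convention!r}")
    rng = noise.rng()
    traces = []
    for rep in range(n_replicates):
        params = _replicate_params(preset.burgers, rng, biological_cv)
        L_clean = creep_burgers(t, params) * factor
        eps = rng.normal(0.0, noise.cv, size=t.size) if noise.cv > 0 else 0.0
        traces.append(
            AspirationTrace(
                t=t,
                L_p=L_clean * (1.0 + eps),
                delta_P=delta_P,
                R_p=R_p,
                phi=phi,
                condition=preset.name,
                replicate=rep,
            )
        )
    return traces


def _invert_indentation(J: float, f: float, R: float, h: float) -> float:
    """Solve J = J_hertz(delta) * thin_sample_factor(chi(delta)) for delta.

    The right-hand side is strictly increasing in delta, so the root is
    bracketed and unique.
    """

    def g(delta):
        chi = np.sqrt(R * delta) / h
        return hertz_compliance(delta, f, R) * thin_sample_factor(chi) - J

    hi = 1.0
    for _ in range(80):
        if g(hi) > 0:
            break
        hi *= 2.0
    else:
        raise ValueError(f"could not bracket indentation depth for J = {J} kPa^-1")
    return brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-12)


def simulate_indentation(
    preset: ConditionPreset,
    f: float = 1.0,
    R: float = 41.0,
    h: float = 3.0,
    ramp: float = 1.0,
    fs: float = 10.0,
    duration: float = 10.0,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 15,
) -> list[IndentationTrace]:
    """Simulate spherical nanoindentation creep traces.

    Depths are obtained by inverting the thin-sample-corrected
    compliance at each hold-phase time; the force-ramp interval is
    prepended with linearly ramped depth so converters can discard it.
    """
    t_hold = default_time_grid(fs, duration)
    J = creep_burgers(t_hold, preset.burgers)
    delta_clean = np.array([_invert_indentation(j, f, R, h) for j in J])
    # ramp prefix: depth rises toward the first hold-phase value
    n_ramp = max(int(round(ramp * fs)) - 1, 0)
    t_ramp = (np.arange(n_ramp) + 1) / fs if ramp > 0 else np.empty(0)
    delta_ramp = delta_clean[0] * t_ramp / ramp if ramp > 0 else np.empty(0)
    t_all = np.concatenate([t_ramp, t_hold + ramp])
    rng = noise.rng()
    traces = []
    for rep in range(n_replicates):
        delta_all = np.concatenate([delta_ramp, delta_clean])
        if noise.cv > 0:
            delta_all = delta_all * (1.0 + rng.normal(0.0, noise.cv, size=delta_all.size))
        traces.append(
            IndentationTrace(
                t=t_all,
                delta=np.maximum(delta_all, 0.0),
                f=f,
                R=R,
                h=h,
                ramp=ramp,
                condition=preset.name,
                replicate=rep,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# expression / mechanics profiles

# latent (lamin-A, lamin-B1) levels per condition, relative to WT;
# rescues restore roughly half the WT lamin-A level
_CONDITION_LAMINS: dict[str, tuple[float, float]] = {
    "WT": (1.0, 1.0),
    "TKO": (0.0, 0.0),
    "A-rescue": (0.5, 0.0),
    "B1-rescue": (0.0, 1.0),
    "AB1-rescue": (0.5, 1.0),
}

DEFAULT_PROFILE_CONDITIONS = tuple(_CONDITION_LAMINS)


def simulate_profiles(
    conditions: tuple[str, ...] = DEFAULT_PROFILE_CONDITIONS,
    slope_a: float = 1.0,
    slope_b1: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
):
    """Generate a conditions x features profile matrix with lamin coupling.

    Latent lamin levels are set per condition (knockouts at 0, rescues
    at the reported fractions of wild type).  Lamin-A couples linearly
    to the Maxwell elements (k_M, mu_M) and lamin-B1 to the
    Kelvin-Voigt elements (k_KV, mu_KV).  Every observed feature —
    expression and mechanics alike — carries independent Gaussian
    measurement noise with standard deviation ``noise_sd`` times the
    feature's dynamic range across conditions (default 20%).  Returns a
    :class:`nucrheo.association.ProfileMatrix`.
    """
    from .association import ProfileMatrix  # deferred: avoids import cycle

    import pandas as pd

    unknown = [c for c in conditions if c not in _CONDITION_LAMINS]
    if unknown:
        raise ValueError(f"no latent lamin levels defined for conditions {unknown}")
    if len(conditions) < 4:
        raise ValueError("need >= 4 conditions for meaningful correlation structure")
    rng = np.random.default_rng(seed)
    lam_a = np.array([_CONDITION_LAMINS[c][0] for c in conditions])
    lam_b1 = np.array([_CONDITION_LAMINS[c][1] for c in conditions])

    def noisy(base):
        scale = noise_sd * np.ptp(base)
        return base + (rng.normal(0.0, scale, size=base.size) if scale > 0 else 0.0)

    data = {
        "lamin_A": (noisy(lam_a), "protein"),
        "lamin_B1": (noisy(lam_b1), "protein"),
        "k_M": (noisy(0.27 + slope_a * 0.23 * lam_a), "mechanics"),
        "mu_M": (noisy(2.3 + slope_a * 7.2 * lam_a), "mechanics"),
        "k_KV": (noisy(0.3375 + slope_b1 * 0.1625 * lam_b1), "mechanics"),
        "mu_KV": (noisy(0.506 + slope_b1 * 0.394 * lam_b1), "mechanics"),
    }
    values = pd.DataFrame(
        {c: [data[f][0][i] for f in data] for i, c in enumerate(conditions)},
        index=list(data),
    )
    classes = pd.Series({f: data[f][1] for f in data}, name="class")
    return ProfileMatrix(values=values, classes=classes)


def true_curve(preset: ConditionPreset, fs: float = 10.0, duration: float = 12.0) -> CreepCurve:
    """Noise-free Burgers compliance of a preset on the default grid."""
    t = default_time_grid(fs, duration)
    return CreepCurve(t=t, J=creep_burgers(t, preset.burgers),
                      provenance="synthetic", condition=preset.name)


def preset_truth_table(preset: ConditionPreset) -> dict[str, float]:
    """Ground-truth element and derived values of a preset, for manifests."""
    p, d = preset.burgers, derive_params(preset.burgers)
    return {
        "k_M": p.k_M, "k_KV": p.k_KV, "mu_M": p.mu_M, "mu_KV": p.mu_KV,
        "tau": d.tau, "k_ST": d.k_ST, "alpha": d.alpha,
    }
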