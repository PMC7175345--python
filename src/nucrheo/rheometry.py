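"""Conversion of raw creep-test traces into creep-compliance curves.

Two instrument geometries are supported:

* **Micropipette aspiration (MPA)** — a step suction ``delta_P`` applied
  through a pipette of inner radius ``R_p`` draws the nucleus in by
  ``L_p(t)``.  The half-space punch model gives

      J(t) = 2*pi*phi * L_p(t) / (3 * R_p * delta_P)

  with geometrical wall factor ``phi`` (approximately 2).  The
  ``phi_convention`` switch moves phi to the denominator for users who
  prefer the classical punch normalisation; absolute moduli then differ
  by phi**2 but all within-convention comparisons are unchanged.

* **Spherical nanoindentation** — a constant force ``f`` applied through
  a bead of radius ``R`` onto a sample of thickness ``h`` produces depth
  ``delta(t)``.  The Hertz compliance is corrected for finite thickness
  by a polynomial in the dimensionless deformation chi = sqrt(R*delta)/h:

      J(t) = 16*sqrt(R)*delta^(3/2)/(9*f)
             * (1 + 1.133*chi + 1.283*chi^2 + 0.769*chi^3 + 0.0975*chi^4)

  assuming incompressibility (Poisson ratio 0.5).  The correction is a
  series in chi; points are soft-flagged above ``chi_warn`` (default 1)
  and hard-flagged (excluded from fitting by default) above ``chi_max``
  (default 3).

Internal units: s, um, kPa, uN; compliances are kPa^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AspirationTrace",
    "IndentationTrace",
    "CreepCurve",
    "mpa_to_creep",
    "indentation_to_creep",
    "average_curves",
    "hertz_compliance",
    "thin_sample_factor",
    "CHI_WARN_DEFAULT",
    "CHI_MAX_DEFAULT",
]

# thin-sample correction polynomial (non-bonded spherical indentation)
THIN_SAMPLE_COEFFS = (1.133, 1.283, 0.769, 0.0975)

CHI_WARN_DEFAULT = 1.0
CHI_MAX_DEFAULT = 3.0

# 16*sqrt(R[um])*delta[um]^1.5/(9*f[uN]) has units um^2/uN = MPa^-1
_UM2_PER_UN_TO_KPA_INV = 1e-3

PhiConvention = Literal["numerator", "denominator"]


def _check_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time must be a 1-D array with at least two samples")
    if t[0] < 0:
        raise ValueError("time must start at or after the stress step (t[0] >= 0)")
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise ValueError(f"time must be strictly increasing (violation at row {bad})")
    return t


@dataclass(frozen=True)
class AspirationTrace:
    """One micropipette-aspiration creep measurement of a single nucleus."""

    t: np.ndarray          # s, strictly increasing, from the pressure step
    L_p: np.ndarray        # aspirated length, um
    delta_P: float         # step suction, kPa
    R_p: float             # inner pipette radius, um
    phi: float = 2.0       # geometrical wall factor
    condition: str = ""
    replicate: str | int = 0

    def __post_init__(self) -> None:
        t = _check_time(self.t)
        L_p = np.asarray(self.L_p, dtype=float)
        if L_p.shape != t.shape:
            raise ValueError("t and L_p must have the same length")
        if np.any(L_p < 0):
            raise ValueError("aspirated length must be nonnegative")
        if self.delta_P <= 0:
            raise ValueError("delta_P must be positive")
        if self.R_p <= 0:
            raise ValueError("R_p must be positive")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "L_p", L_p)


@dataclass(frozen=True)
class IndentationTrace:
    """One spherical-probe nanoindentation creep measurement."""

    t: np.ndarray          # s
    delta: np.ndarray      # indentation depth, um
    f: float               # held force, uN
    R: float               # probe radius, um
    h: float               # sample (nucleus) thickness, um
    nu: float = 0.5        # Poisson ratio; incompressible
    ramp: float = 0.0      # force-ramp duration, s (samples before it are discarded)
    condition: str = ""
    replicate: str | int = 0

    def __post_init__(self) -> None:
        t = _check_time(self.t)
        delta = np.asarray(self.delta, dtype=float)
        if delta.shape != t.shape:
            raise ValueError("t and delta must have the same length")
        if np.any(delta < 0):
            raise ValueError("indentation depth must be nonnegative")
        if self.f <= 0:
            raise ValueError("force f must be positive")
        if self.R <= 0:
            raise ValueError("probe radius R must be positive")
        if self.h <= 0:
            raise ValueError("sample thickness h must be positive")
        if self.ramp < 0:
            raise ValueError("ramp duration must be nonnegative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "delta", delta)

    @property
    def chi(self) -> np.ndarray:
        """Dimensionless deformation coefficient sqrt(R*delta)/h per point."""
        return np.sqrt(self.R * self.delta) / self.h


@dataclass
class CreepCurve:
    """A creep-compliance series J(t) with provenance.

    ``flags`` marks points excluded from fitting (e.g. thin-sample
    correction outside its validity range); ``sem`` carries the
    per-point standard error when the curve is a replicate average.
    """

    t: np.ndarray                  # s
    J: np.ndarray                  # kPa^-1
    sem: np.ndarray | None = None  # kPa^-1
    provenance: str = "mpa"        # mpa | indentation | synthetic | averaged
    n_replicates: int = 1
    condition: str = ""
    replicate: str | int = 0
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = _check_time(self.t)
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != self.t.shape:
            raise ValueError("t and J must have the same length")
        if np.any(self.J < 0):
            raise ValueError("creep compliance must be nonnegative")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.t.shape:
                raise ValueError("sem must match t in length")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.t.shape:
                raise ValueError("flags must match t in length")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of points usable for fitting."""
        if self.flags is None:
            return np.ones_like(self.t, dtype=bool)
        return ~self.flags

    def __len__(self) -> int:
        return self.t.size


def mpa_to_creep(
    trace: AspirationTrace, phi_convention: PhiConvention = "numerator"
) -> CreepCurve:
    """Convert an aspiration trace to creep compliance by the half-space model."""
    if phi_convention == "numerator":
        factor = 2.0 * np.pi * trace.phi / (3.0 * trace.R_p * trace.delta_P)
    elif phi_convention == "denominator":
        factor = 2.0 * np.pi / (3.0 * trace.phi * trace.R_p * trace.delta_P)
    else:
        raise ValueError(
            f"phi_convention must be 'numerator' or 'denominator', got {phi_convention!r}"
        )
    return CreepCurve(
        t=trace.t,
        J=factor * trace.L_p,
        provenance="mpa",
        condition=trace.condition,
        replicate=trace.replicate,
    )


def thin_sample_factor(chi: np.ndarray | float) -> np.ndarray | float:
    """Finite-thickness correction polynomial in chi = sqrt(R*delta)/h."""
    c1, c2, c3, c4 = THIN_SAMPLE_COEFFS
    return 1.0 + c1 * chi + c2 * chi**2 + c3 * chi**3 + c4 * chi**4


def hertz_compliance(delta, f: float, R: float) -> np.ndarray:
    """Half-space (Hertz) spherical-indentation compliance, kPa^-1."""
    delta = np.asarray(delta, dtype=float)
    return 16.0 * np.sqrt(R) * delta**1.5 / (9.0 * f) * _UM2_PER_UN_TO_KPA_INV


def indentation_to_creep(
    trace: IndentationTrace,
    chi_warn: float = CHI_WARN_DEFAULT,
    chi_max: float = CHI_MAX_DEFAULT,
) -> CreepCurve:
    """Convert an indentation trace to creep compliance.

    Samples during the force ramp (t < ramp) are discarded and time is
    re-zeroed at ramp end.  Points whose thin-sample deformation
    coefficient chi exceeds ``chi_max`` are hard-flagged (excluded from
    fitting by default); chi in (chi_warn, chi_max] only logs a warning.
    """
    keep = trace.t >= trace.ramp
    if keep.sum() < 2:
        raise ValueError("fewer than two samples after the force ramp")
    t = trace.t[keep] - trace.ramp
    delta = trace.delta[keep]
    chi = np.sqrt(trace.R * delta) / trace.h
    J = hertz_compliance(delta, trace.f, trace.R) * thin_sample_factor(chi)
    hard = chi > chi_max
    soft = (chi > chi_warn) & ~hard
    if soft.any():
        logger.warning(
            "%d indentation points have chi in (%g, %g]; thin-sample correction "
            "is extrapolating",
            int(soft.sum()), chi_warn, chi_max,
        )
    if hard.any():
        logger.warning(
            "%d indentation points flagged with chi > %g and excluded from fitting",
            int(hard.sum()), chi_max,
        )
    return CreepCurve(
        t=t,
        J=J,
        provenance="indentation",
        condition=trace.condition,
        replicate=trace.replicate,
        flags=hard if hard.any() else None,
    )


def average_curves(curves: Sequence[CreepCurve], grid: np.ndarray) -> CreepCurve:
    """Average replicate creep curves on a common time grid.

    Each curve is linearly interpolated onto ``grid`` (no
    extrapolation); the result carries the per-point mean and standard
    error of the mean across replicates.
    """
    if len(curves) < 2:
        raise ValueError("averaging requires at least two replicate curves")
    grid = _check_time(np.asarray(grid, dtype=float))
    stack = np.empty((len(curves), grid.size))
    for i, c in enumerate(curves):
        if grid[0] < c.t[0] - 1e-12 or grid[-1] > c.t[-1] + 1e-12:
            rep = c.replicate if c.replicate != 0 else i
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] extends outside the time support "
                f"[{c.t[0]}, {c.t[-1]}] of replicate {rep!r}"
            )
        stack[i] = np.interp(grid, c.t, c.J)
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
    condition = curves[0].condition if len({c.condition for c in curves}) == 1 else ""
    return CreepCurve(
        t=grid,
        J=mean,
        sem=sem,
        provenance="averaged",
        n_replicates=len(curves),
        condition=condition,
    )
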