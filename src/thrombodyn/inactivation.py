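"""Kinetics of thrombin inactivation by antithrombin and α2-macroglobulin.

In plasma, free thrombin (T) is removed mainly by antithrombin (AT) and,
to a smaller extent, by α2-macroglobulin (α2M), forming stable T-AT and
T-α2M complexes.  Both reactions are second order::

    d(T-AT)/dt  = k_AT  * [AT]_t  * [T]_t
    d(T-α2M)/dt = k_α2M * [α2M]_t * [T]_t
    -d(T)/dt    = k_AT  * [AT]_t  * [T]_t  +  k_α2M * [α2M]_t * [T]_t

Fibrin(ogen) binds thrombin and shields it from its inhibitors, so the
effective rate constants decrease with the plasma fibrinogen level.
Because both inhibitors are in large molar excess over thrombin, decay is
pseudo-first order with rate constant

    TDC = k_AT(fib) * [AT]_0 + k_α2M(fib) * [α2M]_0        (min^-1)

the thrombin decay capacity — a conversion-independent measure of the
anticoagulant side of the haemostatic balance.

The published calibration of k_AT, k_α2M and their fibrinogen dependence
is external to this package; :class:`RateModel` therefore treats them as
pluggable parameters with physiologically plausible defaults (see
docs/methods.md).  Integration is a deterministic fixed-step classical
Runge-Kutta scheme with automatic sub-stepping; the system is non-stiff
at physiological constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "PlasmaFactors",
    "RateModel",
    "InactivationTrajectory",
    "rate_constants",
    "thrombin_decay_capacity",
    "simulate_inactivation",
    "fit_decay_rate",
]

#: sub-step so that (fastest pseudo-first-order rate) * h stays below this
MAX_RATE_PER_STEP = 0.05

FIB_FORMS = ("constant", "saturating")


@dataclass(frozen=True)
class PlasmaFactors:
    """Per-sample inhibitor and fibrinogen levels.

    at_pct : antithrombin activity, % of normal plasma.
    a2m_uM : α2-macroglobulin, μM.
    fib_gL : functional (Clauss) fibrinogen, g/L.
    """

    at_pct: float
    a2m_uM: float
    fib_gL: float

    def __post_init__(self) -> None:
        for name in ("at_pct", "a2m_uM", "fib_gL"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.at_pct > 250:
            raise ValueError(f"at_pct={self.at_pct:g} outside plausible range [0, 250]")


@dataclass(frozen=True)
class RateModel:
    """Rate constants for thrombin inactivation and their fibrinogen dependence.

    ``k_at_ref`` and ``k_a2m_ref`` are second-order constants (nM^-1 min^-1)
    at the reference fibrinogen level ``fib_ref_gL``.  The fibrinogen factor
    g(fib) in (0, 1] multiplies both constants:

    * ``constant`` — g = 1 (no fibrinogen effect),
    * ``saturating`` — g = 1 / (1 + beta * (fib - fib_ref)) above the
      reference, clipped to (0, 1]; monotone non-increasing.

    ``at_nM_per_pct`` converts AT % activity to nM (normal plasma AT is
    approximately 2.4 μM, i.e. 24 nM per %).  All values are calibration
    placeholders, never hard-coded in the algorithms.
    """

    k_at_ref: float = 3.5e-4
    k_a2m_ref: float = 1.0e-5
    fib_form: str = "saturating"
    fib_beta: float = 0.15  # per g/L
    fib_ref_gL: float = 2.9
    at_nM_per_pct: float = 24.0
    stoichiometric_depletion: bool = True

    def __post_init__(self) -> None:
        if self.k_at_ref < 0 or self.k_a2m_ref < 0:
            raise ValueError("rate constants must be >= 0")
        if self.fib_form not in FIB_FORMS:
            raise ValueError(f"fib_form must be one of {FIB_FORMS}")
        if self.fib_beta < 0:
            raise ValueError("fib_beta must be >= 0")
        if self.at_nM_per_pct <= 0:
            raise ValueError("at_nM_per_pct must be > 0")

    def g(self, fib_gL: float) -> float:
        """Fibrinogen protection factor, in (0, 1], g(fib_ref) = 1."""
        if fib_gL < 0:
            raise ValueError(f"fibrinogen must be >= 0, got {fib_gL:g}")
        if self.fib_form == "constant":
            return 1.0
        x = 1.0 + self.fib_beta * (fib_gL - self.fib_ref_gL)
        return float(min(1.0, 1.0 / max(x, 1e-12)))

    def at_nM(self, factors: PlasmaFactors) -> float:
        return factors.at_pct * self.at_nM_per_pct

    def a2m_nM(self, factors: PlasmaFactors) -> float:
        return factors.a2m_uM * 1e3

    @classmethod
    def from_dict(cls, d: dict) -> "RateModel":
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "k_at_ref": self.k_at_ref,
            "k_a2m_ref": self.k_a2m_ref,
            "fib_form": self.fib_form,
            "fib_beta": self.fib_beta,
            "fib_ref_gL": self.fib_ref_gL,
            "at_nM_per_pct": self.at_nM_per_pct,
            "stoichiometric_depletion": self.stoichiometric_depletion,
        }


def rate_constants(model: RateModel, fib_gL: float) -> tuple[float, float]:
    """Fibrinogen-adjusted (k_AT, k_α2M) in nM^-1 min^-1."""
    g = model.g(fib_gL)
    return model.k_at_ref * g, model.k_a2m_ref * g


def thrombin_decay_capacity(factors: PlasmaFactors, model: RateModel) -> float:
    """Pseudo-first-order thrombin decay constant TDC (min^-1).

    TDC = k_AT(fib)·[AT]_0 + k_α2M(fib)·[α2M]_0; independent of any
    thrombin concentration.
    """
    k_at, k_a2m = rate_constants(model, factors.fib_gL)
    return k_at * model.at_nM(factors) + k_a2m * model.a2m_nM(factors)


@dataclass
class InactivationTrajectory:
    """Coupled time courses of free thrombin, cumulative complexes and
    residual inhibitors on a uniform grid (minutes / nM)."""

    time: np.ndarray
    t_free: np.ndarray
    t_at: np.ndarray  # cumulative T-AT
    t_a2m: np.ndarray  # cumulative T-α2M
    at_remaining: np.ndarray
    a2m_remaining: np.ndarray
    source_integral: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def mass_balance_gap(self, bolus: float = 0.0) -> np.ndarray:
        """|T + T-AT + T-α2M - (bolus + ∫source)| at every step (nM)."""
        total_in = bolus + (self.source_integral if self.source_integral.size else 0.0)
        return np.abs(self.t_free + self.t_at + self.t_a2m - total_in)


def simulate_inactivation(
    factors: PlasmaFactors,
    model: RateModel,
    grid: np.ndarray,
    bolus: float = 0.0,
    source: Callable[[float], float] | None = None,
) -> InactivationTrajectory:
    """Integrate the inactivation system on a uniform time grid.

    Thrombin enters either as an initial ``bolus`` (nM) or continuously via
    ``source`` (a callable t -> nM/min, e.g. a prothrombin-conversion
    pulse), or both.  With ``stoichiometric_depletion`` the inhibitors are
    consumed 1:1 with complex formation; otherwise they stay at their
    initial (excess) levels and decay is exactly exponential at the TDC.

    Classical RK4 with sub-stepping keeps the per-step pseudo-first-order
    increment below ``MAX_RATE_PER_STEP``; mass balance
    bolus + ∫source = T + T-AT + T-α2M holds to rounding error because the
    stage derivatives sum to the source term identically.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D array with >= 2 points")
    steps = np.diff(grid)
    dt = float(steps[0])
    if not np.allclose(steps, dt, rtol=1e-8, atol=1e-12):
        raise ValueError("grid must be uniform")
    if bolus < 0:
        raise ValueError("bolus must be >= 0")

    k_at, k_a2m = rate_constants(model, factors.fib_gL)
    at0 = model.at_nM(factors)
    a2m0 = model.a2m_nM(factors)
    deplete = model.stoichiometric_depletion

    rate_max = k_at * at0 + k_a2m * a2m0
    n_sub = max(1, math.ceil(rate_max * dt / MAX_RATE_PER_STEP))
    h = dt / n_sub

    n = grid.size
    T = np.empty(n)
    TAT = np.empty(n)
    TA2M = np.empty(n)
    AT = np.empty(n)
    A2M = np.empty(n)
    SRC = np.zeros(n)

    src = source if source is not None else (lambda t: 0.0)

    def deriv(t: float, y: tuple) -> tuple:
        T_, AT_, A2M_, *_ = y
        f1 = k_at * AT_ * T_
        f2 = k_a2m * A2M_ * T_
        s = src(t)
        dT = s - f1 - f2
        dAT = -f1 if deplete else 0.0
        dA2M = -f2 if deplete else 0.0
        return (dT, dAT, dA2M, f1, f2, s)

    y = (float(bolus), at0, a2m0, 0.0, 0.0, 0.0)
    T[0], AT[0], A2M[0], TAT[0], TA2M[0], SRC[0] = y
    scale = max(bolus, 1.0)

    for i in range(1, n):
        t = grid[i - 1]
        for _ in range(n_sub):
            k1 = deriv(t, y)
            y2 = tuple(y[j] + 0.5 * h * k1[j] for j in range(6))
            k2 = deriv(t + 0.5 * h, y2)
            y3 = tuple(y[j] + 0.5 * h * k2[j] for j in range(6))
            k3 = deriv(t + 0.5 * h, y3)
            y4 = tuple(y[j] + h * k3[j] for j in range(6))
            k4 = deriv(t + h, y4)
            y = tuple(
                y[j] + (h / 6.0) * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
                for j in range(6)
            )
            t += h
        if y[0] < -1e-7 * scale or y[1] < -1e-7 * at0 - 1e-12 or y[2] < -1e-7 * a2m0 - 1e-12:
            raise RuntimeError(
                f"negative state at t={grid[i]:.3f} min (T={y[0]:.3e}); "
                "time step too large for the rate constants"
            )
        # clamp rounding-level negatives
        y = (max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0), y[3], y[4], y[5])
        T[i], AT[i], A2M[i], TAT[i], TA2M[i], SRC[i] = y

    return InactivationTrajectory(
        time=grid,
        t_free=T,
        t_at=TAT,
        t_a2m=TA2M,
        at_remaining=AT,
        a2m_remaining=A2M,
        source_integral=SRC,
    )


def fit_decay_rate(traj: InactivationTrajectory, tmin: float = 0.0, tmax: float | None = None) -> float:
    """Log-linear least-squares estimate of the thrombin decay rate (min^-1).

    Fits log T_free against time over [tmin, tmax]; only points with
    T_free > 0 are used.  On an excess-inhibitor bolus decay this recovers
    the TDC.
    """
    t = traj.time
    y = traj.t_free
    mask = (t >= tmin) & (y > 0)
    if tmax is not None:
        mask &= t <= tmax
    if mask.sum() < 3:
        raise ValueError("not enough positive samples for a decay fit")
    slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
    return float(-slope)
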