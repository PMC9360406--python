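"""Prothrombin conversion extracted from thrombin-generation curves.

The measured TG curve is the net of two opposing processes: prothrombin
conversion feeding free thrombin in, and inactivation by AT and α2M
taking it out::

    d(T)/dt = -d(P)/dt - d(T-inh)/dt

Since the inactivation flux at any instant is computable from the kinetic
model and the measured thrombin concentration itself, the conversion rate
follows directly::

    -d(P)/dt = d(T)/dt + k_AT·[AT]_t·[T]_t + k_α2M·[α2M]_t·[T]_t

This module marches the measured curve through the inactivation
equations (depleting the inhibitors stoichiometrically when the rate
model says so), differentiates the curve with a Savitzky-Golay local
polynomial filter, and summarizes the resulting conversion curve as

* PCtot — total prothrombin converted (area under -dP/dt, nM),
* PCmax — maximum conversion rate (peak of the curve, nM/min),
* T-AT, T-α2M — end-point complex totals (nM),
* TDC — the plasma's thrombin decay capacity (min^-1).

If the record ends with residual free thrombin the complex totals would
be biased low, so the curve is optionally extended with the exponential
tail implied by the remaining inhibitor levels before accumulating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .curve_model import ThrombinCurve, replace_curve
from .inactivation import (
    MAX_RATE_PER_STEP,
    PlasmaFactors,
    RateModel,
    InactivationTrajectory,
    rate_constants,
    thrombin_decay_capacity,
)

__all__ = [
    "ConversionCurve",
    "TDResult",
    "ExtractionOptions",
    "differentiate_curve",
    "extrapolate_tail",
    "extract_conversion",
    "summarize_td",
    "analyze_curve",
]


@dataclass
class ConversionCurve:
    """The computed prothrombin-conversion rate -d(P)/dt (nM/min) on the
    source grid, possibly extended with an exponential tail; negative
    excursions from noise are retained here and only clipped in the
    scalar summaries."""

    time: np.ndarray
    rate: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TDResult:
    """Scalar thrombin-dynamics summary of one curve."""

    pc_tot: float  # nM
    pc_max: float  # nM/min
    t_at: float  # nM
    t_a2m: float  # nM
    tdc: float  # min^-1
    residual_free_nM: float = 0.0  # free thrombin at record end
    tail_added_nM: float = 0.0  # complexes accumulated on the extrapolated tail
    conservation_gap_nM: float = 0.0  # pc_tot - (t_at + t_a2m + residual)
    clipped_mass_frac: float = 0.0  # |negative rate area| / pc_tot
    noisy_flag: bool = False  # >5% of rate mass was negative

    def to_dict(self) -> dict:
        return {
            "pc_tot": self.pc_tot,
            "pc_max": self.pc_max,
            "t_at": self.t_at,
            "t_a2m": self.t_a2m,
            "tdc": self.tdc,
            "residual_free_nM": self.residual_free_nM,
            "tail_added_nM": self.tail_added_nM,
            "conservation_gap_nM": self.conservation_gap_nM,
            "clipped_mass_frac": self.clipped_mass_frac,
            "noisy_flag": self.noisy_flag,
        }


@dataclass(frozen=True)
class ExtractionOptions:
    """Numerical knobs of the extraction, recorded into provenance.

    smooth_window_min : minimum Savitzky-Golay window length in minutes
        (an odd sample count >= 5 is derived from the grid spacing).
    polyorder : local polynomial degree (3 keeps cubic features unbiased).
    adaptive_smoothing : widen the window on noisy records so that the
        propagated derivative noise stays near ``deriv_noise_target``
        (nM/min, about 2% of a typical low-trigger conversion peak),
        capped at ``window_max_min``.  The record's noise level is
        estimated from second differences, so clean records keep the
        minimum window.
    tail_extend / tail_halflives / tail_threshold_frac : append an
        exponential tail of ``tail_halflives`` half-lives whenever the
        final thrombin exceeds ``tail_threshold_frac`` of the peak.
    """

    smooth_window_min: float = 0.5
    polyorder: int = 3
    adaptive_smoothing: bool = True
    deriv_noise_target: float = 3.5  # nM/min
    window_max_min: float = 2.5  # min
    tail_extend: bool = True
    tail_halflives: float = 10.0
    tail_threshold_frac: float = 0.01


#: empirical constant of the Savitzky-Golay (degree-3) first-derivative
#: noise law  sd_deriv ~= C * sigma / (sqrt(dt) * W^1.5)  for window W min
_SG_DERIV_NOISE_C = 0.47


def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust noise estimate from second differences.

    For i.i.d. additive noise the second difference has sd sigma*sqrt(6);
    the smooth signal contributes only O(curvature * dt^2).  Uses the
    median absolute value for outlier robustness.
    """
    if y.size < 4:
        return 0.0
    d2 = np.diff(y, n=2)
    return float(np.median(np.abs(d2)) / (0.6745 * math.sqrt(6.0)))


def _adaptive_window_min(sigma: float, dt: float, opts: ExtractionOptions) -> float:
    """Window length (minutes) keeping derivative noise near target."""
    if not opts.adaptive_smoothing or sigma <= 0:
        return opts.smooth_window_min
    w = (_SG_DERIV_NOISE_C * sigma / (opts.deriv_noise_target * math.sqrt(dt))) ** (2.0 / 3.0)
    return float(min(max(w, opts.smooth_window_min), opts.window_max_min))


def _window_samples(window_min: float, dt: float, n: int) -> int:
    w = max(5, int(round(window_min / dt)))
    if w % 2 == 0:
        w += 1
    if w >= n // 2:
        raise ValueError(
            f"smoothing window of {w} samples too large for a {n}-sample record"
        )
    return w


def differentiate_curve(
    curve: ThrombinCurve,
    window: int | None = None,
    polyorder: int = 3,
    smooth_window_min: float = 0.5,
) -> np.ndarray:
    """Smoothed first derivative dT/dt (nM/min) on a uniform grid.

    Local polynomial least squares (Savitzky-Golay): exact for any
    polynomial up to ``polyorder``, one-sided fits at the endpoints.
    ``window`` is an odd sample count; when omitted it is derived from
    ``smooth_window_min`` (never below 5 samples).
    """
    if not curve.is_uniform:
        raise ValueError("differentiation requires a uniform grid; resample first")
    n = curve.time.size
    dt = float(curve.time[1] - curve.time[0])
    if window is None:
        window = _window_samples(smooth_window_min, dt, n)
    else:
        if window % 2 == 0 or window < 5:
            raise ValueError(f"window must be odd and >= 5, got {window}")
        if window >= n // 2:
            raise ValueError(f"window {window} too large for {n} samples")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    return savgol_filter(
        curve.thrombin, window, polyorder, deriv=1, delta=dt, mode="interp"
    )


def extrapolate_tail(
    curve: ThrombinCurve, tdc: float, horizon_halflives: float = 10.0
) -> ThrombinCurve:
    """Append the exponential decay T_end·e^(-tdc·(t-t_end)) for
    ``horizon_halflives`` half-lives on the same grid spacing.

    Completes complex formation when the record ends with residual free
    thrombin.  A zero residual returns the curve unchanged.
    """
    residual = float(curve.thrombin[-1])
    if residual <= 0:
        return curve
    if tdc <= 0:
        raise ValueError("tdc must be > 0 to extrapolate a nonzero residual")
    dt = float(curve.time[1] - curve.time[0])
    horizon = horizon_halflives * math.log(2.0) / tdc
    n_ext = int(math.ceil(horizon / dt))
    t_end = curve.time[-1]
    t_ext = t_end + dt * np.arange(1, n_ext + 1)
    y_ext = residual * np.exp(-tdc * (t_ext - t_end))
    out = replace_curve(
        curve,
        np.concatenate([curve.time, t_ext]),
        np.concatenate([curve.thrombin, y_ext]),
    )
    out.truncated = False
    return out


def extract_conversion(
    curve: ThrombinCurve,
    factors: PlasmaFactors,
    model: RateModel,
    options: ExtractionOptions = ExtractionOptions(),
) -> tuple[ConversionCurve, InactivationTrajectory]:
    """Invert a TG curve into its prothrombin-conversion curve.

    The measured thrombin course (baseline-clipped to >= 0, lightly
    smoothed when the record is noisy) drives the inhibitor odes;
    cumulative T-AT / T-α2M and, in stoichiometric mode, the remaining
    inhibitor levels are integrated with RK4 against a monotone cubic
    interpolant of the record.  The conversion rate is the smoothed dT/dt
    plus the instantaneous inactivation flux; on noisy records the scalar
    summaries integrate over the active conversion support only, since
    clipping rectified derivative noise over a long zero-conversion
    baseline would otherwise bias PCtot upward.
    """
    if not curve.is_uniform:
        raise ValueError("extraction requires a uniform grid; resample first")
    dt = float(curve.time[1] - curve.time[0])
    n_rec = curve.time.size

    sigma = estimate_noise_sd(curve.thrombin)
    window_min = _adaptive_window_min(sigma, dt, options)
    w = _window_samples(window_min, dt, n_rec)

    if sigma > 0.25:  # denoise the thrombin course before it drives the odes
        y = np.clip(
            savgol_filter(curve.thrombin, w, options.polyorder, mode="interp"), 0.0, None
        )
    else:
        y = np.clip(curve.thrombin, 0.0, None)
    peak = float(y.max())

    work = replace_curve(curve, curve.time, curve.thrombin)
    dTdt = differentiate_curve(work, window=w, polyorder=options.polyorder)

    k_at, k_a2m = rate_constants(model, factors.fib_gL)
    at0 = model.at_nM(factors)
    a2m0 = model.a2m_nM(factors)
    deplete = model.stoichiometric_depletion

    # -- march inhibitors through the record --------------------------------
    AT, A2M, TAT, TA2M = _march(
        curve.time, y, k_at, k_a2m, at0, a2m0, deplete
    )

    residual = float(y[-1])
    tail_added = 0.0
    time_full, rate_full = curve.time, None
    tdc_end = k_at * AT[-1] + k_a2m * A2M[-1]

    flux = (k_at * AT + k_a2m * A2M) * y
    rate_rec = dTdt + flux

    tail_used = False
    if (
        options.tail_extend
        and peak > 0
        and residual > options.tail_threshold_frac * peak
        and tdc_end > 0
    ):
        tail_used = True
        ext = extrapolate_tail(
            replace_curve(curve, curve.time, y), tdc_end, options.tail_halflives
        )
        t_tail = ext.time[n_rec:]
        y_tail = ext.thrombin[n_rec:]
        AT2, A2M2, TAT2, TA2M2 = _march(
            np.concatenate([[curve.time[-1]], t_tail]),
            np.concatenate([[y[-1]], y_tail]),
            k_at,
            k_a2m,
            AT[-1],
            A2M[-1],
            deplete,
            tat0=TAT[-1],
            ta2m0=TA2M[-1],
        )
        tail_added = (TAT2[-1] + TA2M2[-1]) - (TAT[-1] + TA2M[-1])
        AT = np.concatenate([AT, AT2[1:]])
        A2M = np.concatenate([A2M, A2M2[1:]])
        TAT = np.concatenate([TAT, TAT2[1:]])
        TA2M = np.concatenate([TA2M, TA2M2[1:]])
        # on the tail the curve decays at exactly tdc_end, so the
        # conversion rate is the (small) flux imbalance from depletion
        dTdt_tail = -tdc_end * y_tail
        rate_tail = dTdt_tail + (k_at * AT2[1:] + k_a2m * A2M2[1:]) * y_tail
        time_full = np.concatenate([curve.time, t_tail])
        rate_full = np.concatenate([rate_rec, rate_tail])
        y_full = np.concatenate([y, y_tail])
    else:
        rate_full = rate_rec
        y_full = y

    i_lo, i_hi = _active_support(rate_full, sigma, w, dt, options)
    sub_t = time_full[i_lo : i_hi + 1]
    sub_r = rate_full[i_lo : i_hi + 1]
    neg_mass = float(-np.trapezoid(np.clip(sub_r, None, 0.0), sub_t))
    pos_mass = float(np.trapezoid(np.clip(sub_r, 0.0, None), sub_t))
    noisy = pos_mass > 0 and neg_mass > 0.05 * pos_mass
    if noisy:
        warnings.warn(
            f"curve {curve.sample_id!r}: {100 * neg_mass / pos_mass:.1f}% of the "
            "conversion-rate mass is negative (noise or rate-model mismatch)",
            stacklevel=2,
        )

    conv = ConversionCurve(
        time=time_full,
        rate=rate_full,
        provenance={
            "smooth_window_min": window_min,
            "window_samples": w,
            "noise_sd_est": sigma,
            "support": (int(i_lo), int(i_hi)),
            "polyorder": options.polyorder,
            "tail_extended": tail_used,
            "tail_halflives": options.tail_halflives if tail_used else 0.0,
            "tail_added_nM": tail_added,
            "residual_free_nM": residual,
            "negative_mass_frac": neg_mass / pos_mass if pos_mass > 0 else 0.0,
            "noisy_flag": noisy,
        },
    )
    traj = InactivationTrajectory(
        time=time_full,
        t_free=y_full,
        t_at=TAT,
        t_a2m=TA2M,
        at_remaining=AT,
        a2m_remaining=A2M,
    )
    return conv, traj


def _active_support(
    rate: np.ndarray, sigma: float, w: int, dt: float, opts: ExtractionOptions
) -> tuple[int, int]:
    """Index range of the active conversion pulse.

    The contiguous region around the rate maximum where the rate stays
    above max(0.5% of peak, 2x the propagated derivative noise), padded
    by one window on the left and two on the right so genuine low-rate
    shoulders are kept.  On a clean record this is nearly the whole
    positive-rate span; on a noisy one it excludes the long flat baseline
    whose rectified noise would bias the clipped area.
    """
    n = rate.size
    rmax = float(rate.max(initial=0.0))
    if rmax <= 0:
        return 0, n - 1
    sd_deriv = _SG_DERIV_NOISE_C * sigma / (math.sqrt(dt) * max(w * dt, dt) ** 1.5)
    thr = max(0.005 * rmax, 2.0 * sd_deriv)
    if thr >= rmax:
        return 0, n - 1
    ipk = int(np.argmax(rate))
    lo = ipk
    while lo > 0 and rate[lo - 1] > thr:
        lo -= 1
    hi = ipk
    while hi < n - 1 and rate[hi + 1] > thr:
        hi += 1
    lo = max(0, lo - w)
    hi = min(n - 1, hi + 2 * w)
    return lo, hi


def _march(
    t: np.ndarray,
    y: np.ndarray,
    k_at: float,
    k_a2m: float,
    at0: float,
    a2m0: float,
    deplete: bool,
    tat0: float = 0.0,
    ta2m0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """RK4 of the inhibitor/complex odes driven by the measured thrombin.

    The thrombin course enters through a monotone cubic (PCHIP)
    interpolant so stage evaluations at sub-step midpoints are consistent
    with the record.
    """
    n = t.size
    dt = float(t[1] - t[0])
    rate_max = k_at * at0 + k_a2m * a2m0
    n_sub = max(1, math.ceil(rate_max * dt / MAX_RATE_PER_STEP))
    h = dt / n_sub

    # thrombin at every half-sub-step, evaluated once
    n_fine = 2 * (n - 1) * n_sub + 1
    t_fine = t[0] + (h / 2.0) * np.arange(n_fine)
    y_fine = PchipInterpolator(t, y, extrapolate=True)(t_fine)
    y_fine = np.clip(y_fine, 0.0, None)

    AT = np.empty(n)
    A2M = np.empty(n)
    TAT = np.empty(n)
    TA2M = np.empty(n)
    at, a2m, tat, ta2m = float(at0), float(a2m0), float(tat0), float(ta2m0)
    AT[0], A2M[0], TAT[0], TA2M[0] = at, a2m, tat, ta2m

    idx = 0  # index into t_fine (step h/2)
    for i in range(1, n):
        for _ in range(n_sub):
            T0 = y_fine[idx]
            Tm = y_fine[idx + 1]
            T1 = y_fine[idx + 2]
            if deplete:
                # stages for d(at)/dt = -k_at*at*T(t), d(a2m)/dt analogous
                a1 = -k_at * at * T0
                b1 = -k_a2m * a2m * T0
                a2 = -k_at * (at + 0.5 * h * a1) * Tm
                b2 = -k_a2m * (a2m + 0.5 * h * b1) * Tm
                a3 = -k_at * (at + 0.5 * h * a2) * Tm
                b3 = -k_a2m * (a2m + 0.5 * h * b2) * Tm
                a4 = -k_at * (at + h * a3) * T1
                b4 = -k_a2m * (a2m + h * b3) * T1
                d_at = (h / 6.0) * (a1 + 2 * a2 + 2 * a3 + a4)
                d_a2m = (h / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
                at = max(at + d_at, 0.0)
                a2m = max(a2m + d_a2m, 0.0)
                tat -= d_at
                ta2m -= d_a2m
            else:
                # Simpson's rule on the flux (constant inhibitors)
                seg = (h / 6.0) * (T0 + 4.0 * Tm + T1)
                tat += k_at * at * seg
                ta2m += k_a2m * a2m * seg
            idx += 2
        AT[i], A2M[i], TAT[i], TA2M[i] = at, a2m, tat, ta2m
    return AT, A2M, TAT, TA2M


def summarize_td(
    conv: ConversionCurve, traj: InactivationTrajectory, tdc: float
) -> TDResult:
    """Scalar summary: PCtot (clipped area over the active support),
    PCmax (peak rate), final complex totals, and bookkeeping diagnostics."""
    if conv.time.size != traj.time.size or not np.allclose(conv.time, traj.time):
        raise ValueError("conversion curve and trajectory must share a grid")
    i_lo, i_hi = conv.provenance.get("support", (0, conv.time.size - 1))
    t_sub = conv.time[i_lo : i_hi + 1]
    r_sub = conv.rate[i_lo : i_hi + 1]
    clipped = np.clip(r_sub, 0.0, None)
    pc_tot = float(np.trapezoid(clipped, t_sub))
    pc_max = max(float(r_sub.max(initial=0.0)), 0.0)
    t_at = float(traj.t_at[-1])
    t_a2m = float(traj.t_a2m[-1])
    residual = float(traj.t_free[-1])
    neg_frac = float(conv.provenance.get("negative_mass_frac", 0.0))
    return TDResult(
        pc_tot=pc_tot,
        pc_max=pc_max,
        t_at=t_at,
        t_a2m=t_a2m,
        tdc=tdc,
        residual_free_nM=float(conv.provenance.get("residual_free_nM", residual)),
        tail_added_nM=float(conv.provenance.get("tail_added_nM", 0.0)),
        conservation_gap_nM=pc_tot - (t_at + t_a2m + residual),
        clipped_mass_frac=neg_frac,
        noisy_flag=bool(conv.provenance.get("noisy_flag", False)),
    )


def analyze_curve(
    curve: ThrombinCurve,
    factors: PlasmaFactors,
    model: RateModel,
    options: ExtractionOptions = ExtractionOptions(),
) -> TDResult:
    """Convenience: extraction + summary in one call."""
    conv, traj = extract_conversion(curve, factors, model, options)
    tdc = thrombin_decay_capacity(factors, model)
    return summarize_td(conv, traj, tdc)
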