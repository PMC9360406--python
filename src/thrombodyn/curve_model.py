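"""Thrombin-generation (TG) curves and their descriptive parameters.

A TG curve is the time course of free thrombin concentration (nM) in
clotting plasma, the primary output of fluorogenic thrombin-generation
assays.  This module holds the curve container, uniform resampling,
replicate averaging, and the classic descriptive parameters: lag time,
peak height, time-to-peak, endogenous thrombin potential (ETP, the area
under the curve) and velocity index.  It also provides the
reference-plasma normalization arithmetic and the ETP-inhibition measure
used to quantify the thrombomodulin response.

TG parameters here are purely descriptive of the recorded curve: the ETP
is the trapezoidal area over the record with no tail extrapolation (tail
handling belongs to the conversion analysis, which needs the kinetic
model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ThrombinCurve",
    "TGParameters",
    "LagRule",
    "resample_uniform",
    "average_replicates",
    "compute_tg_parameters",
    "normalize_result",
    "etp_inhibition",
]

REAGENTS = ("bleed", "thrombo", "drug")

#: Largest negative thrombin value (nM) tolerated as baseline noise.
DEFAULT_NOISE_FLOOR = 30.0


@dataclass
class ThrombinCurve:
    """A sampled free-thrombin concentration time series.

    Parameters
    ----------
    time : array of minutes, strictly increasing, first point >= 0.
    thrombin : array of nM, same length as ``time``.  Small negative
        excursions (baseline noise) down to ``-noise_floor`` are kept and
        flagged via :attr:`has_negative`; anything lower is rejected.
    sample_id, reagent, tm_present, replicate : assay metadata.
    truncated : set (or auto-detected) when the record ends at or before
        the thrombin peak, i.e. the decay phase was cut off.
    """

    time: np.ndarray
    thrombin: np.ndarray
    sample_id: str = ""
    reagent: str = "thrombo"
    tm_present: bool = False
    replicate: int = 1
    truncated: bool = False
    noise_floor: float = DEFAULT_NOISE_FLOOR
    has_negative: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.thrombin = np.asarray(self.thrombin, dtype=float)
        if self.time.ndim != 1 or self.thrombin.ndim != 1:
            raise ValueError("time and thrombin must be 1-D arrays")
        if self.time.size != self.thrombin.size:
            raise ValueError(
                f"time ({self.time.size}) and thrombin ({self.thrombin.size}) "
                "lengths differ"
            )
        if self.time.size < 8:
            raise ValueError(f"curve needs >= 8 samples, got {self.time.size}")
        diffs = np.diff(self.time)
        if np.any(diffs <= 0):
            idx = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"time must be strictly increasing; violation at index {idx + 1} "
                f"(t[{idx}]={self.time[idx]:g}, t[{idx + 1}]={self.time[idx + 1]:g})"
            )
        if self.time[0] < 0:
            raise ValueError(f"first time point must be >= 0, got {self.time[0]:g}")
        if not np.all(np.isfinite(self.thrombin)):
            raise ValueError("thrombin contains non-finite values")
        if self.reagent not in REAGENTS:
            raise ValueError(f"reagent must be one of {REAGENTS}, got {self.reagent!r}")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        lo = float(self.thrombin.min(initial=0.0))
        if lo < -self.noise_floor:
            raise ValueError(
                f"thrombin minimum {lo:.2f} nM below noise floor -{self.noise_floor:g} nM"
            )
        self.has_negative = lo < 0.0
        # peak sitting on the last sample means the decay was not recorded
        if self.thrombin.size and int(np.argmax(self.thrombin)) == self.thrombin.size - 1:
            if self.thrombin.max() > 0 and not self.truncated:
                self.truncated = True
                warnings.warn(
                    f"curve {self.sample_id!r}: peak at last sample, flagged truncated",
                    stacklevel=2,
                )

    # -- convenience -------------------------------------------------------
    @property
    def dt(self) -> float:
        """Median sampling interval in minutes."""
        return float(np.median(np.diff(self.time)))

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.time)
        return bool(np.allclose(d, d[0], rtol=1e-8, atol=1e-10))

    def clipped(self) -> np.ndarray:
        """Thrombin with baseline negatives set to zero (copy)."""
        return np.clip(self.thrombin, 0.0, None)

    def condition_key(self) -> tuple:
        return (self.sample_id, self.reagent, self.tm_present)


@dataclass(frozen=True)
class LagRule:
    """Lag-time rule: first time thrombin exceeds max(threshold_nM,
    peak_fraction * peak).  Instrument definitions are proprietary; these
    defaults mirror common CAT-style conventions and are configurable."""

    threshold_nM: float = 2.0
    peak_fraction: float = 0.05


@dataclass(frozen=True)
class TGParameters:
    """Descriptive TG parameters (Calibrated-Automated-Thrombinography style)."""

    lag_time: float  # min
    peak: float  # nM
    time_to_peak: float  # min
    etp: float  # nM*min
    velocity_index: float  # nM/min
    is_null: bool = False  # all-zero curve: lag/ttp undefined
    truncated: bool = False

    @classmethod
    def null(cls, truncated: bool = False) -> "TGParameters":
        nan = float("nan")
        return cls(nan, 0.0, nan, 0.0, nan, is_null=True, truncated=truncated)


def resample_uniform(curve: ThrombinCurve, dt: float) -> ThrombinCurve:
    """Resample a curve onto the uniform grid t0, t0+dt, ... by monotone
    piecewise-cubic (PCHIP) interpolation.

    ``dt`` must be positive and no larger than twice the median input
    spacing (finer output is interpolation; much coarser would alias).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    med = float(np.median(np.diff(curve.time)))
    if dt > 2.0 * med:
        raise ValueError(f"dt={dt:g} too coarse for median spacing {med:g}")
    t0, t1 = curve.time[0], curve.time[-1]
    n = int(math.floor((t1 - t0) / dt + 1e-9)) + 1
    grid = t0 + dt * np.arange(n)
    interp = PchipInterpolator(curve.time, curve.thrombin, extrapolate=False)
    values = interp(grid)
    return replace_curve(curve, grid, np.asarray(values))


def replace_curve(curve: ThrombinCurve, time: np.ndarray, thrombin: np.ndarray) -> ThrombinCurve:
    """New curve with the same metadata but different samples."""
    return ThrombinCurve(
        time=time,
        thrombin=thrombin,
        sample_id=curve.sample_id,
        reagent=curve.reagent,
        tm_present=curve.tm_present,
        replicate=curve.replicate,
        truncated=curve.truncated,
        noise_floor=curve.noise_floor,
    )


def average_replicates(curves: list[ThrombinCurve], dt: float | None = None) -> ThrombinCurve:
    """Point-wise mean of replicate curves after resampling to a common grid.

    Mirrors instrument practice where duplicate wells are averaged into a
    single result.  All curves must share (sample_id, reagent, tm).
    """
    if not curves:
        raise ValueError("no curves to average")
    if len({c.condition_key() for c in curves}) != 1:
        raise ValueError("replicates must share sample, reagent and TM condition")
    if len(curves) == 1:
        return curves[0]
    if dt is None:
        dt = min(c.dt for c in curves)
    t0 = max(c.time[0] for c in curves)
    t1 = min(c.time[-1] for c in curves)
    n = int(math.floor((t1 - t0) / dt + 1e-9)) + 1
    grid = t0 + dt * np.arange(n)
    stack = np.vstack(
        [PchipInterpolator(c.time, c.thrombin, extrapolate=False)(grid) for c in curves]
    )
    out = replace_curve(curves[0], grid, stack.mean(axis=0))
    return replace(out, replicate=1)


def compute_tg_parameters(
    curve: ThrombinCurve, lag_rule: LagRule = LagRule()
) -> TGParameters:
    """Compute lag time, peak, time-to-peak, ETP and velocity index.

    The curve should be on a uniform grid (resample first).  Baseline
    negatives are clipped to zero for the descriptive statistics only;
    the stored curve is never modified.  An all-zero curve yields flagged
    null parameters rather than an exception.
    """
    y = curve.clipped()
    t = curve.time
    peak = float(y.max())
    if peak <= 0.0:
        return TGParameters.null(truncated=curve.truncated)
    ipk = int(np.argmax(y))
    ttp = float(t[ipk])
    etp = float(np.trapezoid(y, t))
    thr = max(lag_rule.threshold_nM, lag_rule.peak_fraction * peak)
    lag = _first_crossing(t, y, thr)
    if lag is None:  # threshold above peak cannot happen (thr <= peak unless
        lag = ttp  # threshold_nM > peak); degrade gracefully
    vi = float("nan")
    if ttp - lag > 0:
        vi = peak / (ttp - lag)
    if curve.truncated:
        warnings.warn(
            f"curve {curve.sample_id!r} is truncated; TG parameters underestimate "
            "peak/ETP",
            stacklevel=2,
        )
    return TGParameters(
        lag_time=float(lag),
        peak=peak,
        time_to_peak=ttp,
        etp=etp,
        velocity_index=vi,
        truncated=curve.truncated,
    )


def _first_crossing(
    t: np.ndarray, y: np.ndarray, threshold: float, sustain: int = 5
) -> float | None:
    """Time of the first sustained upward crossing of ``threshold``,
    linearly interpolated between the bracketing samples.

    The crossing must hold for ``sustain`` consecutive samples (or to the
    record end) so isolated baseline-noise spikes do not trigger an
    artificially early lag time."""
    above = y >= threshold
    if not above.any():
        return None
    i = None
    for c in np.flatnonzero(above):
        j = min(c + sustain, y.size)
        if np.all(y[c:j] >= threshold):
            i = int(c)
            break
    if i is None:
        return None
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (threshold - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def normalize_result(sample_value: float, reference_value: float, assigned_activity: float) -> float:
    """Reference-plasma normalization: sample / reference x assigned activity.

    Automated TG analysers report each parameter relative to a reference
    plasma run in the same series, scaled by the activity assigned to that
    reference lot.
    """
    if reference_value <= 0:
        raise ValueError(
            f"reference plasma value must be > 0 (got {reference_value:g}); invalid reference run"
        )
    return sample_value / reference_value * assigned_activity


def etp_inhibition(etp_no_tm: float, etp_tm: float) -> float:
    """Percent reduction of ETP by thrombomodulin: (1 - ETP_TM/ETP) x 100.

    A negative value (thrombomodulin paradoxically raising the ETP) is
    returned but flagged with a warning.
    """
    if etp_no_tm <= 0:
        raise ValueError(f"ETP without TM must be > 0, got {etp_no_tm:g}")
    if etp_tm < 0:
        raise ValueError(f"ETP with TM must be >= 0, got {etp_tm:g}")
    pct = (1.0 - etp_tm / etp_no_tm) * 100.0
    if pct < 0:
        warnings.warn(f"negative ETP inhibition ({pct:.1f}%)", stacklevel=2)
    return pct
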