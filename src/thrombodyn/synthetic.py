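"""Synthetic healthy-donor cohorts with known ground truth.

Real thrombin-generation instruments output only the net thrombin curve;
the true prothrombin-conversion curve underneath is never observable.
This module therefore generates cohorts the other way round: it draws a
ground-truth conversion pulse and plasma factor levels per subject,
forward-simulates the thrombin curve through the inactivation model, and
adds measurement noise — so every stage of the analysis pipeline can be
validated against known truth.

The conversion pulse is a gamma-density shape::

    rate(t) = pc_tot * gamma_pdf(t - delay; shape, scale),   t >= delay

a two-parameter unimodal pulse whose area (PCtot) and peak (PCmax, at
the closed-form mode) span realistic combinations.  Three reagent
presets emulate low/mid/high tissue-factor triggers ("bleed", "thrombo",
"drug": stronger triggers give earlier, sharper pulses), and a
thrombomodulin condition scales the thrombo pulse down by a per-subject
fraction f — thrombomodulin suppresses conversion, here modelled as a
pure input effect.

Default factor distributions centre on healthy-plasma medians
(antithrombin 113%, α2-macroglobulin 2.6 μM, fibrinogen 2.9 g/L) with
spreads matching reported interquartile ranges; pulse presets are
calibrated so extracted cohort medians land near published healthy
reference medians.  Covariate effects (sex on α2M, oral-contraceptive
use on conversion and thrombomodulin response) are OFF by default to
keep the null cohort exchangeable; a "paper-like" profile enables them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

from .curve_model import ThrombinCurve
from .inactivation import (
    PlasmaFactors,
    RateModel,
    InactivationTrajectory,
    simulate_inactivation,
    thrombin_decay_capacity,
)

__all__ = [
    "ConversionShape",
    "CohortConfig",
    "ReagentPreset",
    "CohortData",
    "sample_factors",
    "forward_simulate_tg",
    "generate_cohort",
]


@dataclass(frozen=True)
class ConversionShape:
    """Gamma-density conversion pulse: area pc_tot (nM), onset ``delay``
    (min), dimensionless ``shape`` > 1 and time ``scale`` (min)."""

    pc_tot: float
    delay: float
    shape: float = 4.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.pc_tot < 0:
            raise ValueError("pc_tot must be >= 0")
        if self.shape <= 1 or self.scale <= 0:
            raise ValueError("need shape > 1 and scale > 0 for a finite-mode pulse")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    def rate(self, t: float | np.ndarray) -> float | np.ndarray:
        """-d(P)/dt at time t (nM/min)."""
        if np.isscalar(t):  # closed-form scalar path: called per ode stage
            x = (float(t) - self.delay) / self.scale
            if x <= 0:
                return 0.0
            a = self.shape
            logp = (a - 1.0) * math.log(x) - x - math.lgamma(a) - math.log(self.scale)
            return self.pc_tot * math.exp(logp)
        x = np.asarray(t, dtype=float) - self.delay
        return self.pc_tot * gamma_dist.pdf(x, self.shape, scale=self.scale)

    @property
    def mode_time(self) -> float:
        """Time of the pulse maximum."""
        return self.delay + (self.shape - 1.0) * self.scale

    @property
    def pc_max(self) -> float:
        """Closed-form pulse maximum (nM/min)."""
        return float(
            self.pc_tot * gamma_dist.pdf((self.shape - 1.0) * self.scale, self.shape, scale=self.scale)
        )


def _scale_for_pc_max(pc_tot: float, pc_max: float, shape: float) -> float:
    """Scale giving a gamma pulse of area pc_tot its target peak pc_max."""
    unit_peak = float(gamma_dist.pdf(shape - 1.0, shape))  # peak of pdf at scale 1
    return pc_tot * unit_peak / pc_max


@dataclass(frozen=True)
class Dist:
    """A truncated-normal sampler spec (loc, scale, lower truncation)."""

    loc: float
    scale: float
    low: float = 0.0
    high: float = math.inf

    def draw(self, rng: np.random.Generator) -> float:
        if self.scale == 0:
            return self.loc
        for _ in range(1000):
            v = rng.normal(self.loc, self.scale)
            if self.low < v < self.high:
                return float(v)
        raise RuntimeError(f"truncated sampling failed for {self}")


@dataclass(frozen=True)
class ReagentPreset:
    """Per-reagent conversion-pulse distribution (medians + jitter)."""

    pc_tot_median: float  # nM
    pc_max_median: float  # nM/min (sets the pulse scale via closed form)
    delay: Dist  # min
    shape: float = 4.0
    scale_cv: float = 0.06  # lognormal-ish jitter on the pulse scale

    def median_scale(self) -> float:
        return _scale_for_pc_max(self.pc_tot_median, self.pc_max_median, self.shape)


def _default_presets() -> dict[str, ReagentPreset]:
    # medians chosen so extracted cohort medians land near published
    # healthy reference medians for low/mid/high tissue-factor triggers
    return {
        "bleed": ReagentPreset(902.0, 172.0, Dist(1.9, 0.30, low=0.5)),
        "thrombo": ReagentPreset(933.0, 206.0, Dist(1.35, 0.25, low=0.4)),
        "drug": ReagentPreset(988.0, 508.0, Dist(1.0, 0.12, low=0.2)),
    }


@dataclass(frozen=True)
class CovariateEffects:
    """Multiplicative covariate effects; all neutral by default so the
    null cohort stays exchangeable."""

    oc_pc_tot_mult: float = 1.0  # oral contraceptives raise conversion
    oc_pc_max_extra: float = 1.0  # extra sharpening of the pulse (scale /= this)
    oc_tm_effect_mult: float = 1.0  # OC blunts the thrombomodulin response
    sex_a2m_shift_uM: float = 0.0  # women +shift, men -shift

    @classmethod
    def paper_like(cls) -> "CovariateEffects":
        return cls(
            oc_pc_tot_mult=1.21,
            oc_pc_max_extra=1.25,
            oc_tm_effect_mult=0.55,
            sex_a2m_shift_uM=0.15,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a cohort deterministically."""

    n_subjects: int = 112
    seed: int = 0
    at_pct: Dist = field(default_factory=lambda: Dist(113.0, 7.4, low=20.0, high=249.0))
    a2m_uM: Dist = field(default_factory=lambda: Dist(2.6, 0.67, low=0.3))
    fib_gL: Dist = field(default_factory=lambda: Dist(2.9, 0.44, low=0.8))
    presets: dict[str, ReagentPreset] = field(default_factory=_default_presets)
    # per-subject overall conversion strength (shared across reagents) and
    # TM response fraction f in (0, 1): pulse scaled by (1 - f) under TM
    subject_strength: Dist = field(default_factory=lambda: Dist(1.0, 0.17, low=0.3))
    tm_effect: Dist = field(default_factory=lambda: Dist(0.44, 0.12, low=0.05, high=0.90))
    covariates: CovariateEffects = field(default_factory=CovariateEffects)
    frac_male: float = 0.4
    frac_oc_in_women: float = 0.35
    noise_sd: float = 5.0  # nM, additive i.i.d. Gaussian
    dt: float = 0.05  # min
    duration: float = 40.0  # min
    rate_model: RateModel = field(default_factory=RateModel)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dt <= 0 or self.duration <= 5 * self.dt:
            raise ValueError("invalid grid: need dt > 0 and duration >> dt")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.frac_male <= 1 or not 0 <= self.frac_oc_in_women <= 1:
            raise ValueError("fractions must be in [0, 1]")
        missing = {"bleed", "thrombo", "drug"} - set(self.presets)
        if missing:
            raise ValueError(f"presets missing reagents: {sorted(missing)}")

    def grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return self.dt * np.arange(n)


def sample_factors(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[PlasmaFactors, dict]:
    """Draw one subject's plasma factors and covariates.

    Deterministic given the generator state; the cohort driver hands each
    subject an independent child stream so draws are reproducible per
    subject index.
    """
    male = bool(rng.random() < config.frac_male)
    oc = bool((not male) and rng.random() < config.frac_oc_in_women)
    shift = config.covariates.sex_a2m_shift_uM * (-1.0 if male else 1.0)
    a2m = replace(config.a2m_uM, loc=config.a2m_uM.loc + shift)
    factors = PlasmaFactors(
        at_pct=config.at_pct.draw(rng),
        a2m_uM=a2m.draw(rng),
        fib_gL=config.fib_gL.draw(rng),
    )
    return factors, {"sex": "M" if male else "F", "oc_use": oc}


def forward_simulate_tg(
    shape: ConversionShape,
    factors: PlasmaFactors,
    model: RateModel,
    grid: np.ndarray,
    meta: dict | None = None,
) -> tuple[ThrombinCurve, InactivationTrajectory]:
    """Forward model: thrombin curve implied by a known conversion pulse.

    Integrates dT/dt = rate(t) - inactivation flux on the grid and wraps
    the free-thrombin course as a ThrombinCurve; the trajectory carries
    the true complex totals for oracle use.  Flags truncation if the grid
    ends with residual thrombin above 1% of the peak.
    """
    traj = simulate_inactivation(factors, model, grid, bolus=0.0, source=shape.rate)
    meta = meta or {}
    peak = float(traj.t_free.max(initial=0.0))
    truncated = peak > 0 and traj.t_free[-1] > 0.01 * peak
    curve = ThrombinCurve(
        time=grid.copy(),
        thrombin=traj.t_free.copy(),
        sample_id=meta.get("sample_id", ""),
        reagent=meta.get("reagent", "thrombo"),
        tm_present=meta.get("tm_present", False),
        replicate=meta.get("replicate", 1),
        truncated=truncated,
    )
    return curve, traj


#: the four measured conditions: (label, preset reagent, TM present)
CONDITIONS = (
    ("bleed", "bleed", False),
    ("thrombo", "thrombo", False),
    ("thrombo_tm", "thrombo", True),
    ("drug", "drug", False),
)


@dataclass
class CohortData:
    """Generated cohort: noisy curves, the factor table, and the hidden
    ground-truth table used only by recovery tests."""

    curves: list[ThrombinCurve]
    factors: "object"  # pandas.DataFrame (subject_id indexed)
    truth: "object"  # pandas.DataFrame (subject_id, condition rows)
    config: CohortConfig


def generate_cohort(config: CohortConfig) -> CohortData:
    """Generate the full cohort: per subject, four conditions (three
    reagents, thrombo with and without thrombomodulin)."""
    import pandas as pd

    grid = config.grid()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_subjects)
    model = config.rate_model

    curves: list[ThrombinCurve] = []
    fact_rows = []
    truth_rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        subject = f"S{i + 1:03d}"
        factors, cov = sample_factors(config, rng)
        strength = config.subject_strength.draw(rng)
        f_tm = config.tm_effect.draw(rng)
        if cov["oc_use"]:
            f_tm = min(f_tm * config.covariates.oc_tm_effect_mult, 0.95)
        tdc = thrombin_decay_capacity(factors, model)
        fact_rows.append(
            {
                "sample_id": subject,
                "at_pct": factors.at_pct,
                "a2m_uM": factors.a2m_uM,
                "fib_gL": factors.fib_gL,
                "sex": cov["sex"],
                "oc_use": cov["oc_use"],
            }
        )
        shapes: dict[str, ConversionShape] = {}
        for reagent, preset in config.presets.items():
            pc_tot = preset.pc_tot_median * strength
            scale = preset.median_scale() * math.exp(
                rng.normal(0.0, preset.scale_cv)
            )
            delay = preset.delay.draw(rng)
            if cov["oc_use"]:
                pc_tot *= config.covariates.oc_pc_tot_mult
                scale /= config.covariates.oc_pc_max_extra
            shapes[reagent] = ConversionShape(
                pc_tot=pc_tot, delay=delay, shape=preset.shape, scale=scale
            )

        for label, reagent, tm in CONDITIONS:
            shape = shapes[reagent]
            if tm:
                shape = replace(shape, pc_tot=shape.pc_tot * (1.0 - f_tm))
            curve, traj = forward_simulate_tg(
                shape,
                factors,
                model,
                grid,
                meta={"sample_id": subject, "reagent": reagent, "tm_present": tm},
            )
            if config.noise_sd > 0:
                noisy = curve.thrombin + rng.normal(0.0, config.noise_sd, grid.size)
                curve = ThrombinCurve(
                    time=grid.copy(),
                    thrombin=noisy,
                    sample_id=subject,
                    reagent=reagent,
                    tm_present=tm,
                    replicate=1,
                    truncated=curve.truncated,
                    noise_floor=max(30.0, 8.0 * config.noise_sd),
                )
            curves.append(curve)
            truth_rows.append(
                {
                    "sample_id": subject,
                    "condition": label,
                    "reagent": reagent,
                    "tm_present": tm,
                    "pc_tot_true": shape.pc_tot,
                    "pc_max_true": shape.pc_max,
                    "delay_true": shape.delay,
                    "t_at_true": float(traj.t_at[-1]),
                    "t_a2m_true": float(traj.t_a2m[-1]),
                    "tdc_true": tdc,
                    "tm_fraction": f_tm if tm else 0.0,
                }
            )

    factors_df = pd.DataFrame(fact_rows).set_index("sample_id")
    truth_df = pd.DataFrame(truth_rows)
    return CohortData(curves=curves, factors=factors_df, truth=truth_df, config=config)
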