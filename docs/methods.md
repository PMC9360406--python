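# Methods

## The model

A thrombin-generation (TG) curve `T(t)` — free thrombin in nM sampled over
tens of minutes — is the net of two opposing fluxes: prothrombin conversion
(`-dP/dt`, the prothrombinase input) and thrombin inactivation. In plasma,
inactivation is dominated by two second-order reactions,

    d(T-AT)/dt  = k_AT  · [AT]_t  · [T]_t
    d(T-α2M)/dt = k_α2M · [α2M]_t · [T]_t
    -d(T)/dt    = (k_AT·[AT]_t + k_α2M·[α2M]_t) · [T]_t  −  (-dP/dt)

with antithrombin (AT) and α2-macroglobulin (α2M) consumed 1:1 as complexes
form (stoichiometric mode; an excess-inhibitor mode freezes them for
closed-form checks). Fibrin(ogen) binds thrombin and shields it from both
inhibitors, so the effective constants are `k_i(fib) = k_i_ref · g(fib)`
with `g` a non-increasing factor in (0, 1], `g(fib_ref) = 1`.

Because both inhibitors are in large molar excess over thrombin, a thrombin
bolus decays pseudo-first-order with rate

    TDC = k_AT(fib)·[AT]₀ + k_α2M(fib)·[α2M]₀     (min⁻¹),

the thrombin decay capacity — an inhibition-side summary independent of
conversion.

The inverse computation rearranges the balance: given the measured curve and
the per-sample factor levels,

    -dP/dt = dT/dt + k_AT·[AT]_t·[T]_t + k_α2M·[α2M]_t·[T]_t ,

where `[AT]_t`, `[α2M]_t` are obtained by marching the inhibitor odes along
the measured thrombin course. The conversion curve is summarized by PCtot
(area, nM), PCmax (peak rate, nM/min), and the end-point complex totals
T-AT and T-α2M (nM).

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `k_at_ref` | 3.5e-4 | nM⁻¹min⁻¹ | AT rate constant at reference fibrinogen |
| `k_a2m_ref` | 1.0e-5 | nM⁻¹min⁻¹ | α2M rate constant at reference fibrinogen |
| `fib_form` / `fib_beta` | saturating / 0.15 | — / (g/L)⁻¹ | `g = 1/(1+β(fib−fib_ref))`, clipped to (0,1] |
| `fib_ref_gL` | 2.9 | g/L | healthy-median fibrinogen |
| `at_nM_per_pct` | 24 | nM/% | AT activity→molar (normal plasma ≈ 2.4 μM) |
| lag rule | max(2 nM, 5% peak) | — | sustained (5-sample) threshold crossing |
| SG window | ≥ 0.5 min, adaptive | min | see "Numerical choices" |
| tail | 10 half-lives if residual > 1% peak | — | completes complex formation |

The true values of `k_AT`, `k_α2M`, the fibrinogen dependence, and the
activity→molar factor are an external calibration that is not published with
the assay descriptions this package works from. The defaults here are
**calibration placeholders**: chosen once so that, at healthy median factor
levels (AT 113%, α2M 2.6 μM, fibrinogen 2.9 g/L) and the default conversion
pulses, simulated curves land near healthy-cohort TG descriptives (peak
≈ 170 nM, ETP ≈ 1.1e3 nM·min, T-α2M/T-AT ≈ 0.03, TDC ≈ 0.95 min⁻¹). All of
them live in `RateModel` and serialized run configs, never in the
algorithms; users with an instrument-specific calibration should supply it.

## Numerical choices

**Integration.** Fixed-step classical RK4 on the curve grid, sub-stepping so
the fastest pseudo-first-order increment per sub-step stays below 0.05. The
system is non-stiff at physiological constants; the scheme is deterministic
and conserves mass identically (stage derivatives sum to the source term),
which the tests exploit. An excess-mode bolus reproduces `T₀e^(−TDC·t)` to
better than 1e-6 relative over a 40-min record.

**Differentiation and smoothing.** `dT/dt` comes from a Savitzky-Golay
degree-3 filter (exact for cubics, one-sided fits at the ends). The window
floor is 0.5 min; when the record is noisy — noise sd estimated robustly
from second differences — the window widens as `W ∝ (σ̂/3.5 nM·min⁻¹)^(2/3)`
(capped at 2.5 min) to hold the propagated derivative noise near 3.5 nM/min,
about 2% of a low-trigger conversion peak. Clean records are untouched by
this rule.

**Clipping and support.** Thrombin below zero (baseline noise) is clipped to
zero before extraction; on noisy records the curve driving the odes is the
SG-smoothed one. Negative conversion rates are kept in the returned curve
but clipped for PCtot/PCmax; the clipped area is integrated over the active
pulse support only (the contiguous region around the rate maximum above
max(0.5% of peak, 2× propagated noise), padded by 1–2 windows). Without the
support restriction, rectified noise over the ~30 min of zero-conversion
baseline biases PCtot by ~+20% at 5 nM noise; with it the median error is
<1%. The clipped-mass fraction is reported, and >5% negative mass within the
support flags the result as noisy/model-mismatched.

**Tail extension.** If the record ends with residual free thrombin above 1%
of the peak, the curve is extended by `T_end·e^(−k·t)` for 10 half-lives at
the decay rate implied by the *remaining* (depleted) inhibitor levels, and
complex accumulation continues over the tail. This recovers end-point
complex totals from records cut during the decay phase to <0.5% of PCtot.
It cannot recover conversion that had not yet happened at the cut — records
truncated mid-pulse stay biased and are flagged.

**Degenerate inputs.** All-zero curves yield flagged null TG parameters and
zero TD results, not exceptions; non-monotone time axes and inconsistent
grids are hard errors naming the offending index; a peak on the last sample
flags truncation.

**Statistics.** Reference intervals are the 2.5th/97.5th percentiles with
linear interpolation of order statistics at position `1+(n−1)p` (fixed for
reproducibility). Paired designs use Friedman + Dunn's z-tests on
within-block mean ranks; independent groups use Kruskal-Wallis + Dunn's
z-tests on pooled mean ranks with tie correction; both Dunn variants use
Bonferroni family adjustment over the tested pairs (the common "Dunn's
multiple comparison" behaviour; the adjustment is configurable by passing an
explicit pair list). Paired tests drop incomplete rows and report the count.

## The synthetic cohort

No donor-level dataset accompanies the method descriptions this package
implements, so validation uses a generator that works in the causal
direction: draw truth, simulate the measurement.

* **Conversion pulse**: a gamma-density `rate(t) = PCtot·γ(t−delay; k, θ)`
  with shape k = 4 — a two-parameter unimodal pulse whose area and
  closed-form peak span realistic PCtot/PCmax combinations.
* **Reagent presets** emulate low/mid/high tissue-factor triggers
  ("bleed"/"thrombo"/"drug"), with pulse medians solved in closed form so
  the implied true medians sit at PCtot 902/933/988 nM and PCmax
  172/206/508 nM/min, and delays 1.9/1.35/1.0 min; per-subject strength
  (cv 17%, shared across reagents) and per-reagent jitter reproduce
  healthy-cohort spreads.
* **Factors**: truncated normals centred on AT 113% (sd 7.4), α2M 2.6 μM
  (sd 0.67), fibrinogen 2.9 g/L (sd 0.44) — medians and IQR-derived spreads
  of a healthy adult cohort.
* **Thrombomodulin** is modelled as pure pulse scaling by `1−f`,
  `f ~ N(0.44, 0.12)` truncated to (0.05, 0.9): TM suppresses conversion.
* **Noise**: additive i.i.d. Gaussian on thrombin, default sd 5 nM.
* **Covariates** (oral-contraceptive multipliers on the pulse, sex shift on
  α2M) are OFF by default so the null cohort is exchangeable for
  type-I-error tests; `CovariateEffects.paper_like()` switches on a profile
  qualitatively matching reported sex/OC differences.

What the generator does **not** emulate: instrument fluorescence artifacts
(inner-filter effect, substrate depletion, α2M-complex amidolytic activity —
inputs here are finished thrombin curves), correlated or heteroscedastic
noise, multimodal or secondary conversion pulses, and TM kinetics beyond
amplitude scaling (in particular, real TM shortens and reshapes the pulse,
which is why measured PCmax falls less than PCtot under TM; under pure
scaling both fall equally). Passing recovery tests therefore demonstrates
correctness of the inverse computation under the stated model, not
robustness to every instrument artifact.

## Problem sizes

Cohort-level checks use 112 subjects × 4 conditions on a 40-min, 0.05-min
grid (801 samples/curve) — full decay for every preset, so end-point complex
totals are well defined. The statistics calibration uses 1000 simulated
Kruskal-Wallis runs at n = 20/group and 1e5 draws for the percentile check.

## Known limitations

* PCtot/PCmax/T-AT/T-α2M accuracy is bounded by the rate-model calibration;
  with a mismatched `RateModel` the split between conversion and
  inactivation shifts systematically (the per-curve diagnostics — negative
  mass, conservation gap — surface gross mismatch but not a calibrated
  bias).
* Minor thrombin inhibitors (heparin cofactor II, α1-antitrypsin) are not
  modelled; their contribution is implicitly folded into the AT term.
* Prothrombin level is not an input: conversion is reported in cumulative
  nM, never as a fraction of available prothrombin.
* Records truncated before the conversion pulse has finished cannot be
  fully recovered by the tail extension (decay-only model).
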