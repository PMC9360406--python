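"""Curve inversion: differentiation, extraction, tail handling, summaries."""

import numpy as np
import pytest

from thrombodyn import (
    ConversionCurve,
    ExtractionOptions,
    InactivationTrajectory,
    PlasmaFactors,
    RateModel,
    ThrombinCurve,
    analyze_curve,
    differentiate_curve,
    extract_conversion,
    extrapolate_tail,
    forward_simulate_tg,
    summarize_td,
    thrombin_decay_capacity,
)
from thrombodyn.synthetic import ConversionShape


def uniform_curve(y, dt=0.05):
    return ThrombinCurve(dt * np.arange(len(y)), np.asarray(y, dtype=float))


class TestDifferentiate:
    def test_linear_exact(self):
        t = 0.05 * np.arange(200)
        d = differentiate_curve(uniform_curve(10.0 * t))
        np.testing.assert_allclose(d, 10.0, atol=1e-9)

    def test_quadratic_exact(self):
        t = 0.05 * np.arange(201)
        d = differentiate_curve(uniform_curve(t**2))
        np.testing.assert_allclose(d, 2 * t, atol=1e-9)

    def test_beats_naive_finite_differences_on_noise(self):
        rng = np.random.default_rng(3)
        t = 0.05 * np.arange(600)
        clean = 100 * (1.1 + np.sin(t))
        noisy = clean + rng.normal(0, 2.0, t.size)
        truth = 100 * np.cos(t)
        sg = differentiate_curve(uniform_curve(noisy))
        naive = np.gradient(noisy, 0.05)
        rmse = lambda est: np.sqrt(np.mean((est - truth) ** 2))
        assert rmse(sg) < rmse(naive)

    def test_window_validation(self):
        c = uniform_curve(np.zeros(100))
        with pytest.raises(ValueError, match="odd"):
            differentiate_curve(c, window=10)
        with pytest.raises(ValueError, match="too large"):
            differentiate_curve(c, window=99)
        with pytest.raises(ValueError, match="uniform"):
            differentiate_curve(
                ThrombinCurve(np.cumsum(np.linspace(0.01, 0.2, 20)), np.zeros(20))
            )


class TestExtraction:
    def test_zero_curve_zero_everything(self, model, median_factors):
        curve = uniform_curve(np.zeros(400))
        conv, traj = extract_conversion(curve, median_factors, model)
        assert np.allclose(conv.rate, 0.0, atol=1e-12)
        assert traj.t_at[-1] == 0.0 and traj.t_a2m[-1] == 0.0
        td = summarize_td(conv, traj, thrombin_decay_capacity(median_factors, model))
        assert td.pc_tot == 0.0 and td.pc_max == 0.0

    def test_no_inactivation_limit_ramp(self, median_factors):
        # with k = 0 the conversion rate is just dT/dt
        null = RateModel(k_at_ref=0.0, k_a2m_ref=0.0, fib_form="constant")
        t = 0.05 * np.arange(301)
        y = np.clip(100.0 * t, 0, 300.0)  # ramp to 300 nM at 3 min, then flat
        conv, traj = extract_conversion(uniform_curve(y), median_factors, null)
        # interior of ramp: 100 nM/min; well after the kink: 0
        interior = (conv.time > 0.6) & (conv.time < 2.4)
        np.testing.assert_allclose(conv.rate[interior], 100.0, atol=1e-8)
        late = conv.time > 4.0
        np.testing.assert_allclose(conv.rate[late], 0.0, atol=1e-8)
        td = summarize_td(conv, traj, 0.0)
        assert td.pc_tot == pytest.approx(300.0, rel=5e-3)
        assert td.t_at == 0.0 and td.t_a2m == 0.0

    def test_round_trip_matches_forward_model(self, bleed_truth, model, median_factors):
        curve, traj_true, shape = bleed_truth
        conv, traj = extract_conversion(curve, median_factors, model)
        true_rate = shape.rate(conv.time)
        assert np.max(np.abs(conv.rate - true_rate)) < 0.01 * shape.pc_max
        td = summarize_td(conv, traj, thrombin_decay_capacity(median_factors, model))
        assert td.pc_tot == pytest.approx(shape.pc_tot, rel=0.01)
        assert td.pc_max == pytest.approx(shape.pc_max, rel=0.02)
        assert td.t_at == pytest.approx(traj_true.t_at[-1], rel=0.01)
        assert td.t_a2m == pytest.approx(traj_true.t_a2m[-1], rel=0.02)

    def test_complex_split_matches_forward(self, bleed_truth, model, median_factors):
        curve, traj_true, _ = bleed_truth
        _, traj = extract_conversion(curve, median_factors, model)
        ratio_true = traj_true.t_at[-1] / traj_true.t_a2m[-1]
        ratio_est = traj.t_at[-1] / traj.t_a2m[-1]
        assert ratio_est == pytest.approx(ratio_true, rel=0.02)

    def test_conservation_on_full_decay(self, bleed_truth, model, median_factors):
        curve, _, shape = bleed_truth
        td = analyze_curve(curve, median_factors, model)
        assert abs(td.pc_tot - (td.t_at + td.t_a2m)) < 0.005 * td.pc_tot

    def test_tm_scaling_is_linear_in_pulse(self, model, median_factors, grid40):
        # thrombomodulin modelled as pure pulse scaling: extracted PCtot
        # scales by the same factor
        shape = ConversionShape(pc_tot=933.0, delay=2.0, shape=4.0, scale=1.015)
        f = 0.44
        scaled = ConversionShape(pc_tot=933.0 * (1 - f), delay=2.0, shape=4.0, scale=1.015)
        c1, _ = forward_simulate_tg(shape, median_factors, model, grid40)
        c2, _ = forward_simulate_tg(scaled, median_factors, model, grid40)
        td1 = analyze_curve(c1, median_factors, model)
        td2 = analyze_curve(c2, median_factors, model)
        assert td2.pc_tot / td1.pc_tot == pytest.approx(1 - f, abs=0.01)

    def test_mismatched_grid_rejected(self, model, median_factors):
        c = ThrombinCurve(np.cumsum(np.linspace(0.02, 0.2, 50)), np.zeros(50))
        with pytest.raises(ValueError, match="uniform"):
            extract_conversion(c, median_factors, model)

    def test_noise_flag_on_garbage(self, model, median_factors):
        rng = np.random.default_rng(0)
        t = 0.05 * np.arange(400)
        pulse = 30 * np.exp(-((t - 8) ** 2))
        y = pulse + rng.normal(0, 15.0, t.size)  # noise comparable to signal
        c = ThrombinCurve(t, y, noise_floor=200.0)
        with pytest.warns(UserWarning, match="negative"):
            conv, _ = extract_conversion(
                c, median_factors, model,
                ExtractionOptions(adaptive_smoothing=False),
            )
        assert conv.provenance["noisy_flag"]


class TestTail:
    def test_no_residual_unchanged(self):
        t = 0.05 * np.arange(100)
        y = np.concatenate([np.linspace(0, 50, 50), np.linspace(50, 0, 50)])
        c = ThrombinCurve(t, y)
        assert extrapolate_tail(c, tdc=0.7) is c

    def test_exponential_tail_area(self):
        t = 0.05 * np.arange(100)
        y = np.full(100, 10.0)
        c = ThrombinCurve(t, y, truncated=True)
        ext = extrapolate_tail(c, tdc=0.7, horizon_halflives=10)
        tail_area = np.trapezoid(ext.thrombin[99:], ext.time[99:])
        assert tail_area == pytest.approx(10.0 / 0.7, rel=2e-3)

    def test_invalid_tdc_rejected(self):
        c = ThrombinCurve(0.05 * np.arange(100), np.full(100, 5.0), truncated=True)
        with pytest.raises(ValueError, match="tdc"):
            extrapolate_tail(c, tdc=0.0)

    def test_tail_recovers_truncated_complexes(self, model, median_factors):
        # cut the record in the decay phase (conversion essentially over,
        # ~2% of the peak still circulating); the extrapolated tail should
        # complete complex formation.  An earlier cut would also truncate
        # unobserved conversion, which no tail model can recover.
        shape = ConversionShape(pc_tot=902.0, delay=2.6, shape=4.0, scale=1.175)
        full_grid = 0.05 * np.arange(1201)  # 60 min, full decay
        curve_full, traj_full = forward_simulate_tg(shape, median_factors, model, full_grid)
        peak = curve_full.thrombin.max()
        i_cut = int(np.argmax((curve_full.thrombin < 0.02 * peak) & (full_grid > 5)))
        short = ThrombinCurve(
            full_grid[: i_cut + 1], curve_full.thrombin[: i_cut + 1], truncated=True
        )
        td = analyze_curve(short, median_factors, model)
        total_true = traj_full.t_at[-1] + traj_full.t_a2m[-1]
        assert abs((td.t_at + td.t_a2m) - total_true) < 0.005 * shape.pc_tot
        assert td.tail_added_nM > 0


class TestSummary:
    def test_rectangle_rate(self):
        t = 0.05 * np.arange(401)  # 20 min
        rate = np.where(t <= 9.0, 100.0, 0.0)
        conv = ConversionCurve(time=t, rate=rate)
        traj = InactivationTrajectory(
            time=t, t_free=np.zeros_like(t), t_at=np.zeros_like(t),
            t_a2m=np.zeros_like(t), at_remaining=np.zeros_like(t),
            a2m_remaining=np.zeros_like(t),
        )
        td = summarize_td(conv, traj, tdc=0.7)
        # trapezoid carries half a sample (2.5 nM) across the step edge
        assert td.pc_tot == pytest.approx(900.0, rel=5e-3)
        assert td.pc_max == pytest.approx(100.0)

    def test_grid_mismatch_rejected(self):
        t = 0.05 * np.arange(100)
        conv = ConversionCurve(time=t, rate=np.zeros(100))
        traj = InactivationTrajectory(
            time=t[:-1], t_free=np.zeros(99), t_at=np.zeros(99),
            t_a2m=np.zeros(99), at_remaining=np.zeros(99), a2m_remaining=np.zeros(99),
        )
        with pytest.raises(ValueError, match="grid"):
            summarize_td(conv, traj, 0.7)
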