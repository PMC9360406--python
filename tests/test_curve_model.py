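"""Curve container, resampling, and descriptive TG parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thrombodyn import (
    LagRule,
    ThrombinCurve,
    average_replicates,
    compute_tg_parameters,
    etp_inhibition,
    normalize_result,
    resample_uniform,
)


def triangle_curve(dt=0.5):
    """0 until t=2, linear to 300 nM at t=5, linear back to 0 at t=15."""
    t = np.arange(0, 15 + dt / 2, dt)
    y = np.where(t < 2, 0.0, np.where(t <= 5, 100.0 * (t - 2), 300.0 * (15 - t) / 10))
    return ThrombinCurve(t, y)


class TestThrombinCurve:
    def test_rejects_nonmonotone_time_with_index(self):
        t = np.array([0, 1, 2, 2, 3, 4, 5, 6], dtype=float)
        with pytest.raises(ValueError, match="index 3"):
            ThrombinCurve(t, np.ones(8))

    def test_rejects_short_and_mismatched(self):
        with pytest.raises(ValueError, match=">= 8"):
            ThrombinCurve(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError, match="lengths differ"):
            ThrombinCurve(np.arange(8.0), np.zeros(9))

    def test_negative_baseline_flagged_or_rejected(self):
        t = np.arange(8.0)
        c = ThrombinCurve(t, np.array([-2, 0, 5, 20, 10, 5, 2, 1.0]))
        assert c.has_negative
        with pytest.raises(ValueError, match="noise floor"):
            ThrombinCurve(t, np.array([-500, 0, 5, 20, 10, 5, 2, 1.0]))

    def test_peak_at_end_flags_truncation(self):
        t = np.arange(8.0)
        with pytest.warns(UserWarning, match="truncated"):
            c = ThrombinCurve(t, np.arange(8.0) * 10)
        assert c.truncated


class TestResample:
    def test_identity_on_existing_grid(self):
        c = triangle_curve(dt=0.5)
        r = resample_uniform(c, 0.5)
        np.testing.assert_allclose(r.time, c.time, atol=1e-12)
        np.testing.assert_allclose(r.thrombin, c.thrombin, atol=1e-12)
        assert r.sample_id == c.sample_id and r.reagent == c.reagent

    def test_linear_ramp_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.1, 0.4, 30))
        y = 7.5 * t + 3.0
        r = resample_uniform(ThrombinCurve(t, y), 0.1)
        np.testing.assert_allclose(r.thrombin, 7.5 * r.time + 3.0, atol=1e-9)

    def test_sine_interpolation_accuracy(self):
        # irregular sampling of a sine; monotone cubic should reproduce it
        # to well under 1e-3 of the amplitude
        rng = np.random.default_rng(1)
        t = np.concatenate([[0.0], np.cumsum(rng.uniform(0.05, 0.12, 120))])
        amp = 100.0
        y = amp * (1.1 + np.sin(t))
        r = resample_uniform(ThrombinCurve(t, y), 0.05)
        exact = amp * (1.1 + np.sin(r.time))
        assert np.max(np.abs(r.thrombin - exact)) < 1e-3 * amp

    def test_rejects_bad_dt(self):
        c = triangle_curve(dt=0.5)
        with pytest.raises(ValueError):
            resample_uniform(c, -0.1)
        with pytest.raises(ValueError, match="too coarse"):
            resample_uniform(c, 2.0)


class TestTGParameters:
    def test_triangle_geometry(self):
        tg = compute_tg_parameters(triangle_curve(), LagRule(threshold_nM=10.0, peak_fraction=0.0))
        assert tg.peak == pytest.approx(300.0)
        assert tg.time_to_peak == pytest.approx(5.0)
        assert tg.etp == pytest.approx(0.5 * 13 * 300)  # 1950 nM*min
        assert tg.lag_time == pytest.approx(2.1)  # 10 nM at 100 nM/min slope
        assert tg.velocity_index == pytest.approx(300 / (5 - 2.1))

    def test_all_zero_curve_returns_flagged_null(self):
        tg = compute_tg_parameters(ThrombinCurve(np.arange(10.0), np.zeros(10)))
        assert tg.is_null
        assert np.isnan(tg.lag_time) and np.isnan(tg.time_to_peak)
        assert tg.peak == 0.0 and tg.etp == 0.0

    def test_truncated_curve_warns_but_returns(self):
        t = np.arange(10.0)
        with pytest.warns(UserWarning):
            c = ThrombinCurve(t, 10.0 * t)
        with pytest.warns(UserWarning, match="truncated"):
            tg = compute_tg_parameters(c)
        assert tg.truncated and tg.peak == pytest.approx(90.0)

    def test_negatives_clipped_for_stats_only(self):
        t = np.arange(0, 8, 0.5)
        y = np.where((t > 2) & (t < 5), 100.0, -3.0)  # noisy baseline
        c = ThrombinCurve(t, y)
        tg = compute_tg_parameters(c)
        assert tg.etp >= 0
        assert c.thrombin.min() == -3.0  # stored curve untouched

    @settings(derandomize=True, max_examples=25)
    @given(c=st.floats(min_value=0.01, max_value=100.0))
    def test_scaling_invariance(self, c):
        # peak/ETP scale linearly; lag (pure peak-fraction rule) and ttp
        # are scale-invariant
        base = triangle_curve()
        rule = LagRule(threshold_nM=0.0, peak_fraction=0.05)
        tg0 = compute_tg_parameters(base, rule)
        scaled = ThrombinCurve(base.time, base.thrombin * c)
        tg1 = compute_tg_parameters(scaled, rule)
        assert tg1.peak == pytest.approx(c * tg0.peak, rel=1e-12)
        assert tg1.etp == pytest.approx(c * tg0.etp, rel=1e-12)
        assert tg1.lag_time == pytest.approx(tg0.lag_time, rel=1e-12)
        assert tg1.time_to_peak == tg0.time_to_peak

    def test_etp_additive_over_time_partition(self):
        c = triangle_curve(dt=0.25)
        t, y = c.time, c.thrombin
        full = np.trapezoid(y, t)
        split = 21  # arbitrary interior node
        assert np.trapezoid(y[: split + 1], t[: split + 1]) + np.trapezoid(
            y[split:], t[split:]
        ) == pytest.approx(full, rel=1e-12)


class TestReplicates:
    def test_average_of_two_offset_replicates(self):
        t = np.arange(0, 10, 0.5)
        y = np.interp(t, [0, 3, 10], [0, 200, 0])
        c1 = ThrombinCurve(t, y + 10, sample_id="s", replicate=1)
        c2 = ThrombinCurve(t, y - 10, sample_id="s", replicate=2)
        avg = average_replicates([c1, c2])
        np.testing.assert_allclose(avg.thrombin, np.interp(avg.time, [0, 3, 10], [0, 200, 0]), atol=1e-9)

    def test_mixed_conditions_rejected(self):
        t = np.arange(0, 10, 0.5)
        y = np.interp(t, [0, 3, 10], [0, 200, 0])
        c1 = ThrombinCurve(t, y, sample_id="a")
        c2 = ThrombinCurve(t, y, sample_id="b")
        with pytest.raises(ValueError, match="share"):
            average_replicates([c1, c2])


class TestNormalization:
    def test_reference_normalization(self):
        assert normalize_result(168, 150, 100) == pytest.approx(112.0)
        assert normalize_result(42.0, 42.0, 87.5) == pytest.approx(87.5)
        assert normalize_result(0.0, 150, 100) == 0.0

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_result(100, 0.0, 100)

    @settings(derandomize=True, max_examples=25)
    @given(
        a=st.floats(min_value=0.01, max_value=1e3),
        x=st.floats(min_value=0.01, max_value=1e3),
        r=st.floats(min_value=0.01, max_value=1e3),
    )
    def test_multiplicative_invariance(self, a, x, r):
        assert normalize_result(a * x, a * r, 100.0) == pytest.approx(
            normalize_result(x, r, 100.0), rel=1e-9
        )


class TestEtpInhibition:
    def test_values(self):
        assert etp_inhibition(1000, 530) == pytest.approx(47.0)
        assert etp_inhibition(1234.5, 1234.5) == 0.0
        assert etp_inhibition(1000, 0.0) == 100.0

    def test_negative_inhibition_flagged(self):
        with pytest.warns(UserWarning, match="negative"):
            assert etp_inhibition(1000, 1100) == pytest.approx(-10.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            etp_inhibition(0.0, 100)
        with pytest.raises(ValueError):
            etp_inhibition(1000, -5)
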