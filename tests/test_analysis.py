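"""Trace analysis: extent of inactivation, decay fits, I-V curves, leak."""

import numpy as np
import pytest

from cracdi import (
    CurrentTrace,
    IVCurve,
    extent_of_inactivation,
    fit_double_exponential,
    iv_from_ramp,
    leak_subtract,
    reversal_potential,
)
from cracdi.errors import (
    AmbiguousCrossingError,
    InvalidParameterError,
    WindowError,
)


def make_step_trace(i_fn, duration=0.300, fs=5000.0, v=-0.100):
    t = np.arange(0, duration, 1 / fs)
    return CurrentTrace(t=t, v=np.full_like(t, v), i=i_fn(t))


class TestCurrentTrace:
    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            CurrentTrace(t=[0, 1], v=[0], i=[0, 0])

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(InvalidParameterError):
            CurrentTrace(t=[0, 2, 1], v=[0, 0, 0], i=[0, 0, 0])


class TestExtent:
    def test_constant_current_has_zero_extent(self):
        trace = make_step_trace(lambda t: np.full_like(t, -30e-12))
        assert extent_of_inactivation(trace, (0.0, 0.300)).extent == 0.0

    def test_half_decay_gives_half(self):
        """A step decaying to exactly half its peak has extent 0.5."""
        trace = make_step_trace(
            lambda t: np.where(t < 0.150, -40e-12, -20e-12)
        )
        fit = extent_of_inactivation(trace, (0.0, 0.300))
        assert fit.extent == pytest.approx(0.5, abs=1e-6)

    def test_potentiating_current_reports_negative_extent(self):
        trace = make_step_trace(lambda t: -10e-12 * (1 + 2 * t))
        assert extent_of_inactivation(trace, (0.0, 0.300)).extent < 0

    def test_gain_invariance(self):
        decay = lambda t: -(20e-12 * np.exp(-t / 0.02) + 10e-12)
        trace = make_step_trace(decay)
        scaled = CurrentTrace(t=trace.t, v=trace.v, i=trace.i * 7.3)
        e1 = extent_of_inactivation(trace, (0.0, 0.300)).extent
        e2 = extent_of_inactivation(scaled, (0.0, 0.300)).extent
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_low_signal_flagged(self):
        trace = make_step_trace(lambda t: np.full_like(t, -1e-13))
        fit = extent_of_inactivation(trace, (0.0, 0.300), noise_floor=1e-12)
        assert fit.low_signal and np.isnan(fit.extent)

    def test_window_outside_trace_rejected(self):
        trace = make_step_trace(lambda t: np.full_like(t, -1e-12))
        with pytest.raises(WindowError):
            extent_of_inactivation(trace, (0.0, 1.0))


class TestDoubleExponentialFit:
    def test_noiseless_roundtrip_within_1pc(self):
        decay = lambda t: -(20e-12 * np.exp(-t / 0.010)
                            + 10e-12 * np.exp(-t / 0.100) + 5e-12)
        fit = fit_double_exponential(make_step_trace(decay), (0.0, 0.300))
        assert fit.fit_ok
        assert fit.tau_fast == pytest.approx(0.010, rel=0.01)
        assert fit.tau_slow == pytest.approx(0.100, rel=0.01)
        assert fit.tau_fast <= fit.tau_slow

    def test_deterministic_bit_identical(self):
        rng = np.random.default_rng(7)
        i = -(20e-12 * np.exp(-np.arange(1500) / 5000 / 0.015) + 5e-12)
        i = i + rng.normal(0, 1e-12, 1500)
        trace = make_step_trace(lambda t: i)
        f1 = fit_double_exponential(trace, (0.0, 0.300))
        f2 = fit_double_exponential(trace, (0.0, 0.300))
        assert (f1.tau_fast, f1.tau_slow, f1.a_fast, f1.a_slow, f1.offset) == (
            f2.tau_fast, f2.tau_slow, f2.a_fast, f2.a_slow, f2.offset
        )

    def test_single_exponential_collapses_gracefully(self):
        decay = lambda t: -(30e-12 * np.exp(-t / 0.030) + 5e-12)
        fit = fit_double_exponential(make_step_trace(decay), (0.0, 0.300))
        # nested-model behaviour: one amplitude vanishes or taus merge
        amp_collapsed = min(abs(fit.a_fast), abs(fit.a_slow)) < 0.05 * 30e-12
        taus_merged = fit.tau_slow / fit.tau_fast < 1.5
        assert amp_collapsed or taus_merged
        assert fit.residual_rms < 1e-15

    def test_noisy_tau_recovery_within_10pc_median(self):
        """Monte-Carlo recovery at 5%-of-peak noise across seeds."""
        t = np.arange(0, 0.300, 1 / 5000)
        clean = -(20e-12 * np.exp(-t / 0.010) + 10e-12 * np.exp(-t / 0.100)
                  + 5e-12)
        errs_fast, errs_slow = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 0.05 * np.abs(clean).max(), len(t))
            fit = fit_double_exponential(
                CurrentTrace(t=t, v=np.full_like(t, -0.1), i=noisy),
                (0.0, 0.300),
            )
            errs_fast.append(abs(fit.tau_fast - 0.010) / 0.010)
            errs_slow.append(abs(fit.tau_slow - 0.100) / 0.100)
        assert np.median(errs_fast) < 0.10
        assert np.median(errs_slow) < 0.10

    def test_too_few_samples_rejected(self):
        trace = make_step_trace(lambda t: -1e-12 * np.exp(-t / 0.01),
                                duration=0.005)
        with pytest.raises(WindowError):
            fit_double_exponential(trace, (0.0, 0.005))


class TestIVCurve:
    def _ramp_trace(self, g=1e-9, e_rev=0.0, noise=None):
        t = np.arange(0, 0.100, 1 / 5000)
        v = -0.100 + 2.0 * t  # -100 -> +100 mV over 100 ms
        i = g * (v - e_rev)
        if noise is not None:
            i = i + noise
        return CurrentTrace(t=t, v=v, i=i)

    def test_ohmic_line_through_origin(self):
        ivc = iv_from_ramp(self._ramp_trace(), (0.0, 0.100))
        assert ivc.e_rev == pytest.approx(0.0, abs=1e-9)
        slope = np.polyfit(ivc.v, ivc.i, 1)[0]
        assert slope == pytest.approx(1e-9, rel=1e-9)

    def test_reversed_ramp_sorts_identically(self):
        fwd = self._ramp_trace()
        rev = CurrentTrace(t=fwd.t, v=fwd.v[::-1], i=fwd.i[::-1])
        a = iv_from_ramp(fwd, (0.0, 0.100))
        b = iv_from_ramp(rev, (0.0, 0.100))
        assert np.allclose(a.v, b.v) and np.allclose(a.i, b.i)

    def test_non_monotone_window_rejected(self):
        t = np.arange(0, 0.1, 1 / 5000)
        v = 0.1 * np.sin(50 * t)
        trace = CurrentTrace(t=t, v=v, i=np.zeros_like(t))
        with pytest.raises(WindowError):
            iv_from_ramp(trace, (0.0, 0.1))

    def test_analytic_crossing_at_50mV(self):
        ivc = IVCurve(v=np.linspace(-0.1, 0.1, 201),
                      i=1e-9 * (np.linspace(-0.1, 0.1, 201) - 0.050))
        assert reversal_potential(ivc) == pytest.approx(0.050, abs=1e-12)

    def test_no_crossing_is_undefined(self):
        ivc = IVCurve(v=np.linspace(-0.1, 0.1, 50),
                      i=-1e-12 * np.ones(50))
        assert reversal_potential(ivc) is None

    def test_multiple_crossings_listed(self):
        v = np.linspace(-0.1, 0.1, 201)
        ivc = IVCurve(v=v, i=np.sin(v * 200) * 1e-12)
        with pytest.raises(AmbiguousCrossingError) as err:
            reversal_potential(ivc)
        assert len(err.value.candidates) > 1


class TestLeakSubtract:
    def _trace(self):
        t = np.arange(0, 0.1, 1 / 5000)
        v = np.full_like(t, -0.100)
        return CurrentTrace(t=t, v=v, i=-30e-12 * np.ones_like(t))

    def test_zero_leak_is_identity(self):
        trace = self._trace()
        out = leak_subtract(
            trace, CurrentTrace(t=trace.t, v=trace.v, i=np.zeros_like(trace.t))
        )
        assert np.array_equal(out.i, trace.i)
        assert out.meta["leak_subtracted"]

    def test_recovers_signal_exactly(self):
        trace = self._trace()
        g = 2e-9
        leak_i = g * trace.v
        contaminated = CurrentTrace(t=trace.t, v=trace.v, i=trace.i + leak_i)
        out = leak_subtract(
            contaminated, CurrentTrace(t=trace.t, v=trace.v, i=leak_i)
        )
        assert np.allclose(out.i, trace.i)

    def test_iv_fallback(self):
        trace = self._trace()
        leak = IVCurve(v=np.linspace(-0.12, 0.1, 23),
                       i=2e-9 * np.linspace(-0.12, 0.1, 23))
        out = leak_subtract(trace, leak)
        assert np.allclose(out.i, trace.i - 2e-9 * trace.v)

    def test_double_application_warns_and_refuses(self):
        trace = self._trace()
        leak = CurrentTrace(t=trace.t, v=trace.v, i=np.ones_like(trace.t))
        once = leak_subtract(trace, leak)
        with pytest.warns(UserWarning, match="already"):
            twice = leak_subtract(once, leak)
        assert np.array_equal(twice.i, once.i)

    def test_grid_mismatch_rejected(self):
        trace = self._trace()
        other = CurrentTrace(t=trace.t + 0.5, v=trace.v, i=trace.i)
        with pytest.raises(InvalidParameterError):
            leak_subtract(trace, other)

    def test_extent_invariant_under_leak_roundtrip(self):
        t = np.arange(0, 0.3, 1 / 5000)
        v = np.full_like(t, -0.100)
        signal = -(20e-12 * np.exp(-t / 0.02) + 10e-12)
        leak = CurrentTrace(t=t, v=v, i=1.5e-9 * v)
        raw = CurrentTrace(t=t, v=v, i=signal + 1.5e-9 * v)
        cleaned = leak_subtract(raw, leak)
        e_clean = extent_of_inactivation(cleaned, (0.0, 0.3)).extent
        e_true = extent_of_inactivation(
            CurrentTrace(t=t, v=v, i=signal), (0.0, 0.3)
        ).extent
        assert e_clean == pytest.approx(e_true, rel=1e-9)
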