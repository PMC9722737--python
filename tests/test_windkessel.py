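"""Windkessel update, parameter allocation, 0D model and compliance tuning."""

import numpy as np
import pytest

from csfsim.waveforms import InletSource
from csfsim.windkessel import (
    ComplianceFit,
    OutletAllocation,
    WindkesselOutlet,
    ZeroDModel,
    allocate_compliances,
    allocate_resistances,
    pulsation_amplitude,
    simulate_0d,
    total_resistance_from_physiology,
    tune_total_compliance,
    wk_update,
)

CASE_A_INFLOW = (
    InletSource("production", "node", mean_flow=6.67e-3),
    InletSource("arterial", "node", amplitude=5.16, frequency=1.0),
)


def discrete_gain(R, C, dt, omega):
    """Closed-form gain of the backward-difference windkessel filter."""
    return R / (1.0 + C * R * (1.0 - np.exp(-1j * omega * dt)) / dt)


def fourier_amplitude(trace, freq, window):
    """Amplitude of the component at ``freq`` over whole cycles.

    Exact for a uniformly sampled sinusoid, unlike the sampled extremes
    which can miss the true peaks by up to half a sample.
    """
    mask = (trace.time > window[0]) & (trace.time <= window[1])
    t, p = trace.time[mask], trace.pressure[mask]
    return 2.0 * np.abs(np.sum(p * np.exp(-2j * np.pi * freq * t))) / t.size


class TestWkUpdate:
    @pytest.mark.parametrize(
        "p_prev, q, r, c, dt, p_out, expected",
        [
            (123.0, 0.01, 1500.0, 0.0, 0.05, 0.0, 15.0),  # C=0: resistor law
            (0.0, 1.0, 1000.0, 0.1, 0.05, 0.0, 1000.0 / 2001.0),
            (0.0, 0.01, 1500.0, 0.0, 0.05, 2.0, 17.0),  # external pressure offset
        ],
    )
    def test_values(self, p_prev, q, r, c, dt, p_out, expected):
        assert wk_update(p_prev, q, r, c, dt, p_out) == pytest.approx(expected, rel=1e-14)

    def test_resistor_law_is_exact_for_zero_compliance(self):
        for p_prev in (-5.0, 0.0, 42.0):
            assert wk_update(p_prev, 0.2, 750.0, 0.0, 0.05) == 0.2 * 750.0

    def test_constant_inflow_fixed_point_is_qr(self):
        q, r, c = 0.00667, 1500.0, 0.51
        fixed = q * r  # 10.005 mmHg
        assert wk_update(fixed, q, r, c, 0.05) == pytest.approx(fixed, rel=1e-14)
        # approach from below is monotone
        p = 0.0
        for _ in range(1000):
            p_next = wk_update(p, q, r, c, 0.05)
            assert fixed >= p_next > p
            p = p_next

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            wk_update(0.0, 1.0, 0.0, 0.1, 0.05)
        with pytest.raises(ValueError):
            wk_update(0.0, 1.0, 1500.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            wk_update(0.0, 1.0, 1500.0, -0.1, 0.05)


class TestAllocation:
    def alloc(self, c_tot=0.51, c=None):
        return OutletAllocation(
            R_tot=1500.0,
            C_tot=c_tot,
            q={"int": 0.2, "sp": 0.2, "lym": 0.3, "av": 0.3},
            c=c or {"int": 0.33, "sp": 0.67, "lym": 0.0, "av": 0.0},
        )

    def test_resistances_follow_outflow_fractions(self):
        r = allocate_resistances(self.alloc())
        assert r["int"] == pytest.approx(7500.0)
        assert r["sp"] == pytest.approx(7500.0)
        # R_i = R_tot / q_i throughout
        assert r["lym"] == pytest.approx(5000.0)
        assert r["av"] == pytest.approx(5000.0)

    def test_single_outlet_gets_total_resistance(self):
        a = OutletAllocation(1500.0, 0.0, q={"sp": 1.0}, c={"sp": 1.0})
        assert allocate_resistances(a)["sp"] == 1500.0

    def test_parallel_recombination_returns_total(self):
        r = allocate_resistances(self.alloc())
        assert 1.0 / sum(1.0 / ri for ri in r.values()) == pytest.approx(
            1500.0, rel=1e-15
        )

    def test_zero_outflow_fraction_rejected(self):
        a = OutletAllocation(
            1500.0, 0.0,
            q={"int": 0.0, "sp": 1.0}, c={"sp": 1.0},
        )
        with pytest.raises(ValueError, match="int"):
            allocate_resistances(a)

    def test_compliances_are_fraction_times_total(self):
        c = allocate_compliances(self.alloc(c_tot=0.51))
        assert c["sp"] == pytest.approx(0.67 * 0.51)
        assert c["lym"] == 0.0
        case_c = self.alloc(c={"int": 0.11, "sp": 0.67, "lym": 0.11, "av": 0.11})
        assert sum(allocate_compliances(case_c).values()) == pytest.approx(0.51)

    def test_fraction_sums_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            OutletAllocation(1500.0, 0.5, q={"int": 0.5, "sp": 0.4}, c={"int": 1.0})
        with pytest.raises(ValueError, match="sum to 1"):
            OutletAllocation(1500.0, 0.5, q={"int": 1.0}, c={"int": 0.9})


@pytest.mark.parametrize(
    "icp, production, expected",
    [
        (10.0, 0.00667, 1499.2503748125936),
        (10.0, 0.01, 1000.0),
        (22.0, 0.00667, 3298.3508245877062),
    ],
)
def test_total_resistance_from_physiology(icp, production, expected):
    assert total_resistance_from_physiology(icp, production) == pytest.approx(expected)


def test_total_resistance_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        total_resistance_from_physiology(10.0, 0.0)
    with pytest.raises(ValueError):
        total_resistance_from_physiology(0.0, 0.00667)


class TestSimulate0d:
    def test_zero_inflow_stays_at_zero(self):
        m = ZeroDModel(1500.0, 0.17, (), P0=0.0)
        trace = simulate_0d(m, 5.0)
        assert trace.time.size == 101
        assert np.all(trace.pressure == 0.0)

    def test_trace_starts_at_initial_pressure(self):
        m = ZeroDModel(1500.0, 0.17, CASE_A_INFLOW, P0=3.0)
        assert simulate_0d(m, 1.0).pressure[0] == 3.0

    def test_constant_inflow_converges_to_production_times_resistance(self):
        source = (InletSource("production", "node", mean_flow=0.00667),)
        m = ZeroDModel(1500.0, 0.17, source, P0=0.0)
        trace = simulate_0d(m, 2000.0)
        assert trace.pressure[-1] == pytest.approx(0.00667 * 1500.0, abs=0.01)

    def test_mean_transient_bounded_by_exponential_decay(self):
        """|mean - Q R| decays like exp(-t / (R C)) regardless of P0."""
        source = (InletSource("production", "node", mean_flow=0.00667),)
        fixed = 0.00667 * 1500.0
        for p0 in (0.0, 25.0):
            m = ZeroDModel(1500.0, 0.17, source, P0=p0)
            trace = simulate_0d(m, 100.0)
            window = trace.time >= 99.0
            bound = abs(p0 - fixed) * np.exp(-99.0 / (1500.0 * 0.17)) * 1.001
            assert abs(trace.pressure[window].mean() - fixed) <= bound

    def test_matches_closed_form_discrete_gain(self):
        """Steady-cycle response equals the backward-difference filter gain.

        Starting on the particular solution removes the slow transient,
        so the simulated trace must follow a*Im(H e^{i w t}) pointwise.
        """
        a, freq, R, C, dt = 5.16, 1.0, 1500.0, 0.17, 0.05
        omega = 2 * np.pi * freq
        H = discrete_gain(R, C, dt, omega)
        source = (InletSource("arterial", "node", amplitude=a, frequency=freq),)
        m = ZeroDModel(R, C, source, dt=dt, P0=a * np.imag(H))
        trace = simulate_0d(m, 2.0)
        analytic = a * np.imag(H * np.exp(1j * omega * trace.time))
        np.testing.assert_allclose(trace.pressure, analytic, atol=1e-9)
        measured = fourier_amplitude(trace, freq, (1.0, 2.0))
        assert measured == pytest.approx(a * abs(H), rel=5e-3)

    def test_gain_converges_to_continuous_windkessel_as_dt_shrinks(self):
        a, R, C = 1.0, 1500.0, 0.17
        omega = 2 * np.pi
        continuous = R / np.sqrt(1.0 + (omega * R * C) ** 2)
        errors = []
        for dt in (0.05, 0.01, 0.002):
            H = discrete_gain(R, C, dt, omega)
            source = (InletSource("s", "node", amplitude=a, frequency=1.0),)
            m = ZeroDModel(R, C, source, dt=dt, P0=a * np.imag(H))
            trace = simulate_0d(m, 2.0)
            measured = fourier_amplitude(trace, 1.0, (1.0, 2.0))
            errors.append(abs(measured - a * continuous) / (a * continuous))
        assert errors[0] < 5e-3
        assert errors[2] < errors[1] < errors[0]


class TestPulsationAmplitude:
    def test_pure_sinusoid(self):
        t = np.arange(0, 5.0001, 1e-3)
        assert pulsation_amplitude(t, 2.5 * np.sin(2 * np.pi * t)) == pytest.approx(
            2.5, abs=1e-4
        )

    def test_constant_trace_is_zero(self):
        t = np.arange(0, 5.05, 0.05)
        assert pulsation_amplitude(t, np.full_like(t, 9.3)) == 0.0

    def test_two_tone_sum(self):
        # 1 Hz and 0.2 Hz sines reach +-1 together at t = 1.25 / 3.75 s,
        # both on the 0.05 s sampling grid
        t = np.arange(0, 5.05, 0.05)
        values = 1.61 * np.sin(2 * np.pi * t) + 1.58 * np.sin(0.4 * np.pi * t)
        assert pulsation_amplitude(t, values, (0.0, 5.0)) == pytest.approx(
            3.19, abs=1e-9
        )

    def test_empty_window_rejected(self):
        t = np.arange(0, 1.0, 0.05)
        with pytest.raises(ValueError):
            pulsation_amplitude(t, np.zeros_like(t), (2.0, 3.0))


class TestTuneTotalCompliance:
    def test_amplitude_strictly_decreasing_in_compliance(self):
        fit = tune_total_compliance(CASE_A_INFLOW, target_amplitude=5.0, n_grid=100)
        assert np.all(np.diff(fit.amplitudes) < 0.0)

    def test_target_on_grid_point_is_returned_exactly(self):
        coarse = tune_total_compliance(CASE_A_INFLOW, target_amplitude=5.0, n_grid=50)
        j = 20
        fit = tune_total_compliance(
            CASE_A_INFLOW, target_amplitude=float(coarse.amplitudes[j]), n_grid=50
        )
        assert fit.c_tot == pytest.approx(float(coarse.grid[j]), abs=1e-12)

    def test_linearity_in_source_amplitudes(self):
        """Halving every source halves the pressure everywhere (P0 = 0),
        so fitting half sources at half target gives the same compliance."""
        half = tuple(
            InletSource(s.name, s.node, s.mean_flow / 2, s.amplitude / 2, s.frequency)
            for s in CASE_A_INFLOW
        )
        full_fit = tune_total_compliance(CASE_A_INFLOW, target_amplitude=5.0, n_grid=200)
        half_fit = tune_total_compliance(half, target_amplitude=2.5, n_grid=200)
        assert half_fit.c_tot == pytest.approx(full_fit.c_tot, abs=1e-9)

    def test_unreachable_target_reports_achieved_range(self):
        with pytest.raises(ValueError, match="achieved range"):
            tune_total_compliance(CASE_A_INFLOW, target_amplitude=1e6, n_grid=50)

    def test_result_record(self):
        fit = tune_total_compliance(CASE_A_INFLOW, target_amplitude=5.0, n_grid=100)
        assert isinstance(fit, ComplianceFit)
        assert fit.grid.size == 100 and fit.grid[0] > 0.0
        assert fit.achieved_amplitude == pytest.approx(5.0)
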