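"""Single-unit dynamics: output nonlinearity, conductance kernel, synaptic
drive, Euler integration, probabilistic spiking, adaptation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olfnet.core import (
    KernelParams,
    PopulationSpec,
    PopulationState,
    adaptation_step,
    conductance_kernel,
    integrate_step,
    kernel_peak_time,
    output_activation,
    spike_draw,
    synaptic_drive,
)


def make_spec(**kw):
    base = dict(name="test", n=4, spiking=True, tau=5.0, beta=2.0,
                theta_min=0.0, theta_max=10.0)
    base.update(kw)
    return PopulationSpec(**base)


class TestOutputActivation:
    @pytest.mark.parametrize(
        "v, kw, expected",
        [
            (-1.0, dict(theta_min=0.0, theta_max=15.0), 0.0),   # below threshold
            (20.0, dict(theta_min=0.0, theta_max=15.0), 1.0),   # above saturation
            (5.0, dict(theta_min=0.0, theta_max=10.0, beta=2.0), 0.25),
            (0.0, dict(theta_min=-0.5, theta_max=15.0, beta=1.0), 0.5 / 15.5),
        ],
    )
    def test_values(self, v, kw, expected):
        assert output_activation(v, make_spec(**kw)) == pytest.approx(expected)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_monotone(self, v1, v2):
        """F(v) stays in [0,1] and is non-decreasing for every group row."""
        from olfnet.params import DEFAULT_POPULATIONS

        for name, row in DEFAULT_POPULATIONS.items():
            spec = PopulationSpec(name=name, n=1, **row)
            a1, a2 = output_activation(v1, spec), output_activation(v2, spec)
            assert 0.0 <= a1 <= 1.0
            if v1 <= v2:
                assert a1 <= a2 + 1e-12

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            make_spec(theta_min=5.0, theta_max=5.0)
        with pytest.raises(ValueError):
            make_spec(tau=0.0)
        with pytest.raises(ValueError):
            make_spec(beta=0.5)


class TestConductanceKernel:
    def test_zero_at_spike_time(self):
        k = KernelParams(g_max=3.0, tau_rise=1.0, tau_decay=2.0, E_N=70.0)
        assert conductance_kernel(0.0, k) == pytest.approx(0.0)

    def test_peak_time_and_value(self):
        """With rise 1 ms / decay 2 ms the kernel peaks at 2 ln 2 with value
        g_max/4."""
        k = KernelParams(g_max=1.0, tau_rise=1.0, tau_decay=2.0, E_N=70.0)
        t_peak = kernel_peak_time(k)
        assert t_peak == pytest.approx(2.0 * np.log(2.0))
        assert conductance_kernel(t_peak, k) == pytest.approx(0.25)
        # single interior maximum
        t = np.linspace(0, 20, 2001)
        g = conductance_kernel(t, k)
        assert np.argmax(g) == np.argmin(np.abs(t - t_peak))

    @given(
        st.floats(0.1, 10.0), st.floats(0.0, 100.0), st.floats(1.05, 10.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_nonnegative_and_vanishing(self, tau_rise, t, ratio):
        k = KernelParams(g_max=2.0, tau_rise=tau_rise,
                         tau_decay=tau_rise * ratio, E_N=0.0)
        assert conductance_kernel(t, k) >= 0.0
        assert conductance_kernel(100.0 * k.tau_decay, k) == pytest.approx(0.0, abs=1e-12)

    def test_negative_time_rejected(self):
        k = KernelParams(g_max=1.0, tau_rise=1.0, tau_decay=2.0, E_N=0.0)
        with pytest.raises(ValueError):
            conductance_kernel(-0.1, k)

    def test_rise_must_precede_decay(self):
        with pytest.raises(ValueError):
            KernelParams(g_max=1.0, tau_rise=2.0, tau_decay=1.0, E_N=0.0)


class TestSynapticDrive:
    def test_zero_driving_force(self):
        assert synaptic_drive(0.7, 1.2, E_N=-10.0, v_post=-10.0) == 0.0

    def test_excitatory_example(self):
        assert synaptic_drive(0.5, 0.2, E_N=70.0, v_post=0.0) == pytest.approx(7.0)

    def test_inhibitory_sign(self):
        assert synaptic_drive(0.3, 0.4, E_N=-10.0, v_post=0.0) < 0.0


class TestIntegrateStep:
    def test_fixed_point(self):
        spec = make_spec()
        state = PopulationState.zeros(4)
        state.v[:] = 3.0
        out = integrate_step(state, np.full(4, 3.0), dt=0.5, spec=spec)
        np.testing.assert_allclose(out.v, 3.0)

    def test_single_step(self):
        spec = make_spec(tau=5.0)
        state = PopulationState.zeros(4)
        out = integrate_step(state, np.full(4, 10.0), dt=0.5, spec=spec)
        np.testing.assert_allclose(out.v, 1.0)

    def test_geometric_decay_ten_steps(self):
        spec = make_spec(tau=5.0)
        state = PopulationState.zeros(4)
        state.v[:] = 1.0
        for _ in range(10):
            state = integrate_step(state, np.zeros(4), dt=0.5, spec=spec)
        np.testing.assert_allclose(state.v, 0.9**10)

    def test_refractory_holds_reset_potential(self):
        spec = make_spec(v_hyper=-10.0, t_refrac=2.0)
        state = PopulationState.zeros(4)
        state.refrac_remaining[:] = 2.0
        out = integrate_step(state, np.full(4, 50.0), dt=0.5, spec=spec)
        np.testing.assert_allclose(out.v, -10.0)
        # the clock advances in spike_draw, after the eligibility check
        out = spike_draw(np.ones(4), out, np.random.default_rng(0), spec, dt=0.5)
        assert out.fired.sum() == 0
        np.testing.assert_allclose(out.refrac_remaining, 1.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate_step(PopulationState.zeros(4), np.zeros(3), 0.5, make_spec())


class TestSpikeDraw:
    def test_zero_activation_never_fires(self):
        spec = make_spec()
        state = PopulationState.zeros(4)
        out = spike_draw(np.zeros(4), state, np.random.default_rng(0), spec)
        assert out.fired.sum() == 0

    def test_refractory_units_cannot_fire(self):
        spec = make_spec()
        state = PopulationState.zeros(4)
        state.refrac_remaining[:] = 1.0
        out = spike_draw(np.ones(4), state, np.random.default_rng(0), spec)
        assert out.fired.sum() == 0

    def test_firing_resets_and_starts_refractory_clock(self):
        spec = make_spec(v_hyper=-10.0, t_refrac=2.0)
        state = PopulationState.zeros(4)
        state.v[:] = 5.0
        out = spike_draw(np.ones(4), state, np.random.default_rng(0), spec)
        np.testing.assert_allclose(out.v, -10.0)
        np.testing.assert_allclose(out.refrac_remaining, 2.0)

    def test_graded_group_rejected(self):
        spec = make_spec(spiking=False)
        with pytest.raises(ValueError):
            spike_draw(np.zeros(4), PopulationState.zeros(4), np.random.default_rng(0), spec)

    def test_empirical_firing_fraction(self):
        """Held at activation 0.1 with no refractoriness, the firing fraction
        matches the Bernoulli rate within 3 binomial SDs."""
        n, steps, p = 100, 10_000, 0.1
        spec = make_spec(n=n, t_refrac=0.0)
        state = PopulationState.zeros(n)
        rng = np.random.default_rng(42)
        count = 0
        for _ in range(steps):
            state.refrac_remaining[:] = 0.0
            out = spike_draw(np.full(n, p), state, rng, spec)
            count += out.fired.sum()
        total = n * steps
        sd = np.sqrt(total * p * (1 - p))
        assert abs(count - total * p) < 3 * sd

    def test_renewal_rate_with_refractoriness(self):
        """At constant activation p the spike rate follows the renewal
        formula p / (dt + p * t_refrac)."""
        n, steps, p, dt = 200, 20_000, 0.3, 0.5
        spec = make_spec(n=n, t_refrac=2.0)
        state = PopulationState.zeros(n)
        rng = np.random.default_rng(7)
        count = 0
        for _ in range(steps):
            state = integrate_step(state, np.zeros(n), dt, spec)
            state = spike_draw(np.full(n, p), state, rng, spec)
            count += state.fired.sum()
        rate = count / (n * steps * dt)  # spikes per ms
        expected = p / (dt + p * spec.t_refrac)
        assert rate == pytest.approx(expected, rel=0.05)


class TestAdaptation:
    def test_silent_stays_zero(self):
        spec = make_spec(ahc_amplitude=10.0, ahc_tau=100.0)
        state = PopulationState.zeros(4)
        ahc, contrib = adaptation_step(state, 0.5, spec)
        np.testing.assert_allclose(ahc, 0.0)
        np.testing.assert_allclose(contrib, 0.0)

    def test_zero_amplitude_under_full_modulation(self):
        spec = make_spec(ahc_amplitude=10.0, ahc_tau=100.0)
        state = PopulationState.zeros(4)
        state.fired[:] = 1.0
        ahc, _ = adaptation_step(state, 0.5, spec, ahc_amplitude=0.0)
        np.testing.assert_allclose(ahc, 0.0)

    def test_single_euler_step_after_spike(self):
        """One spike step with amplitude 10 and tau 100 ms raises the
        adaptation variable by dt/tau * amplitude = 0.05."""
        spec = make_spec(ahc_amplitude=10.0, ahc_tau=100.0)
        state = PopulationState.zeros(4)
        state.fired[:] = 1.0
        ahc, _ = adaptation_step(state, 0.5, spec)
        np.testing.assert_allclose(ahc, 0.05)

    def test_contribution_is_hyperpolarising_at_rest(self):
        spec = make_spec(ahc_amplitude=10.0, ahc_tau=100.0, ahc_E=-15.0)
        state = PopulationState.zeros(4)
        state.fired[:] = 1.0
        state.v[:] = 0.0
        ahc, contrib = adaptation_step(state, 0.5, spec)
        assert np.all(contrib < 0.0)
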