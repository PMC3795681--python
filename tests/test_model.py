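"""Unit tests of the pure single-neuron/synapse update rules.

Closed-form examples are checked directly; where no closed form exists
the update is compared against a fine-step (1 µs) numerical oracle.
"""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nsburst import model
from nsburst.params import (AdaptationParams, NeuronParams, STPParams,
                            SynapseParams, ParameterError)

SYN = SynapseParams()
STP = STPParams()
AD = AdaptationParams()
NRN = NeuronParams()


class TestMgBlock:
    def test_value_at_zero(self):
        # 1/(1+0.28) at V=0
        assert model.mg_block(0.0, SYN) == pytest.approx(0.78125)

    def test_value_at_minus50(self):
        assert model.mg_block(-50.0, SYN) == pytest.approx(
            1.0 / (1.0 + 0.28 * math.exp(3.1)), rel=1e-12)

    def test_limits(self):
        assert model.mg_block(-1e4, SYN) < 1e-100
        assert model.mg_block(1e4, SYN) == pytest.approx(1.0)

    def test_monotone_increasing(self):
        v = np.linspace(-100, 50, 301)
        b = np.array([model.mg_block(x, SYN) for x in v])
        assert np.all(np.diff(b) > 0)
        assert np.all((b > 0) & (b < 1))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            model.mg_block(float("nan"), SYN)


class TestSynapticCurrent:
    def test_zero_driving_force(self):
        assert model.synaptic_current(0.0, 3.0, 5.0, SYN) == 0.0

    def test_zero_gating(self):
        assert model.synaptic_current(-55.0, 0.0, 0.0, SYN) == 0.0

    def test_negative_gating_rejected(self):
        with pytest.raises(ValueError):
            model.synaptic_current(-55.0, -1.0, 0.0, SYN)

    def test_inward_below_reversal(self):
        # below the excitatory reversal the current is negative (inward),
        # hence depolarizing under the subtract convention
        assert model.synaptic_current(-55.0, 1.0, 1.0, SYN) < 0

    def test_r_ratio_mixing(self):
        mixed = SynapseParams(r_ratio=0.9)
        assert mixed.g_ampa_eff == pytest.approx(10 * 0.1 * SYN.g_ampa)
        assert mixed.g_nmda_eff == pytest.approx(0.9 * SYN.g_nmda)
        unmixed = SynapseParams(r_ratio=None)
        assert unmixed.g_ampa_eff == SYN.g_ampa
        assert unmixed.g_nmda_eff == SYN.g_nmda


class TestGating:
    def test_ampa_exponential_decay(self):
        g = model.GatingState(s_ampa=1.0)
        out = model.gating_decay(g, dt=SYN.tau_ampa, params=SYN)
        assert out.s_ampa == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_zero_fixed_point(self):
        g = model.GatingState()
        out = model.gating_decay(g, dt=5.0, params=SYN)
        assert (out.s_ampa, out.x_aux, out.s_nmda) == (0.0, 0.0, 0.0)

    def test_presyn_spike_jump(self):
        g = model.gating_on_presyn_spike(model.GatingState())
        assert (g.s_ampa, g.x_aux, g.s_nmda) == (1.0, 1.0, 0.0)
        g2 = model.gating_on_presyn_spike(model.GatingState(), n_spikes=2)
        assert (g2.s_ampa, g2.x_aux) == (2.0, 2.0)

    def test_jump_then_decay_roundtrip(self):
        g = model.gating_on_presyn_spike(model.GatingState())
        out = model.gating_decay(g, dt=2.0, params=SYN)
        assert out.s_ampa == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_nmda_transient_peak_in_slow_decay_limit(self):
        # with tau_decay >> tau_rise the open fraction approaches
        # 1 - exp(-alpha*tau_rise) = 1 - 1/e before decaying
        params = SynapseParams(tau_nmda_decay=1e7)
        g = model.GatingState(x_aux=1.0)
        peak = 0.0
        dt = 1e-3  # 1 us
        for _ in range(40000):
            g = model.gating_decay(g, dt=dt, params=params)
            peak = max(peak, g.s_nmda)
        assert peak == pytest.approx(1.0 - math.exp(-1.0), rel=1e-3)

    def test_fine_step_oracle_agreement(self):
        # stepping the update at 1 us for 2 ms reproduces the closed-form
        # exponentials to within 0.1%
        g = model.GatingState(s_ampa=1.0, x_aux=1.0, s_nmda=0.2)
        dt = 1e-3
        for _ in range(2000):
            g = model.gating_decay(g, dt=dt, params=SYN)
        assert g.s_ampa == pytest.approx(math.exp(-1.0), rel=1e-3)
        assert g.x_aux == pytest.approx(math.exp(-1.0), rel=1e-3)

    @given(st.floats(0, 5), st.floats(0, 1), st.floats(0.01, 50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_nmda_stays_in_unit_interval(self, x_aux, s_nmda, dt):
        g = model.GatingState(x_aux=x_aux, s_nmda=s_nmda)
        for _ in range(5):
            g = model.gating_decay(g, dt=dt, params=SYN)
            assert 0.0 <= g.s_nmda <= 1.0


class TestSTP:
    def test_spike_update_convention(self):
        u, x = model.stp_on_spike(0.0, 1.0, STPParams(U=0.5))
        assert (u, x) == (0.5, 0.5)

    def test_depleted_pool_stays_depleted(self):
        for u0 in (0.0, 0.3, 1.0):
            _, x = model.stp_on_spike(u0, 0.0, STP)
            assert x == 0.0

    def test_update_order_switch(self):
        u1, x1 = model.stp_on_spike(0.2, 1.0, STPParams(update_order="u_first"))
        u2, x2 = model.stp_on_spike(0.2, 1.0, STPParams(update_order="x_first"))
        assert u1 == u2
        assert x1 == 1.0 - u1       # uses updated u
        assert x2 == 1.0 - 0.2      # uses pre-spike u

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            model.stp_on_spike(1.2, 0.5, STP)

    def test_relax_closed_forms(self):
        u, x = model.stp_relax(1.0, 0.0, dt=STP.tau_x, params=STP)
        assert x == pytest.approx(1.0 - math.exp(-1.0), rel=1e-12)
        u, x = model.stp_relax(1.0, 0.0, dt=1e6, params=STP)
        assert (u, x) == (pytest.approx(STP.U), pytest.approx(1.0))

    def test_periodic_spiking_steady_state(self):
        # brute-force iteration of spike+relax converges to the algebraic
        # fixed point of the map
        delta = 0.5  # s
        u, x = STP.U, 1.0
        for _ in range(500):
            u, x = model.stp_on_spike(u, x, STP)
            u, x = model.stp_relax(u, x, delta, STP)
        fu = math.exp(-delta / STP.tau_u)
        fx = math.exp(-delta / STP.tau_x)
        # fixed point: u* = U + (u* + U(1-u*) - U) f_u  -> solve directly
        u_star = (STP.U * (1 - fu) + STP.U * fu) / (1 - fu * (1 - STP.U))
        u_plus = u_star + STP.U * (1 - u_star)
        x_star = (1 - fx) / (1 - fx * (1 - u_plus))
        assert u == pytest.approx(u_star, rel=1e-9)
        assert x == pytest.approx(x_star, rel=1e-9)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounds_preserved(self, u, x):
        for _ in range(3):
            u, x = model.stp_on_spike(u, x, STP)
            assert 0.0 <= u <= 1.0 and 0.0 <= x <= 1.0
            u, x = model.stp_relax(u, x, 0.1, STP)
            assert 0.0 <= u <= 1.0 and 0.0 <= x <= 1.0

    def test_facilitation_window_iff_tau_u_exceeds_tau_x(self):
        # after a network spike (u elevated, x depleted) the net
        # modulation u(t)x(t) transiently exceeds the resting value U
        # exactly when facilitation outlives depression
        U = 0.5
        u0, x0 = 0.75, 0.3
        t = np.linspace(0, 10, 2000)

        def net(tau_u, tau_x):
            p = STPParams(U=U, tau_u=tau_u, tau_x=tau_x)
            traj = np.array([model.stp_relax(u0, x0, dt, p)[0]
                             * model.stp_relax(u0, x0, dt, p)[1] for dt in t])
            return traj.max()

        # resting-state modulation is U * 1
        assert net(1.6, 0.8) > U + 1e-3
        assert net(0.8, 1.6) <= U + 1e-9

    def test_tau_ordering_enforced_in_defaults(self):
        assert STP.tau_u > STP.tau_x


class TestAdaptation:
    def test_spike_increment_and_additivity(self):
        g = model.adaptation_on_spike(0.0, AD)
        assert g == AD.dg_a
        for _ in range(4):
            g = model.adaptation_on_spike(g, AD)
        assert g == pytest.approx(5 * AD.dg_a)

    def test_decay_closed_form(self):
        assert model.adaptation_decay(1.0, AD.tau_ca, AD) == pytest.approx(
            math.exp(-1.0), rel=1e-12)
        assert model.adaptation_decay(0.0, 3.0, AD) == 0.0
        assert model.adaptation_decay(0.7, 0.0, AD) == 0.7


class TestMembrane:
    def test_resting_fixed_point(self):
        nrn = NeuronParams(sigma=0.0)
        s = model.NeuronState(V=nrn.V_L)
        s2, spiked = model.membrane_step(s, 0.0, 0.0, dt=0.025, neuron=nrn,
                                         adaptation=AD)
        assert not spiked
        assert s2.V == pytest.approx(nrn.V_L)

    def test_leak_decay_matches_closed_form(self):
        # V0 = -60 mV decays to -70 + 10/e after one membrane time constant
        nrn = NeuronParams(sigma=0.0)
        s = model.NeuronState(V=-60.0)
        dt = 0.001
        for _ in range(int(nrn.tau_m / dt)):
            s, _ = model.membrane_step(s, 0.0, 0.0, dt, nrn, AD)
        assert s.V == pytest.approx(-70.0 + 10.0 * math.exp(-1.0), rel=1e-3)

    def test_threshold_reset_and_refractoriness(self):
        nrn = NeuronParams(sigma=0.0)
        s = model.NeuronState(V=nrn.V_thr - 0.001)
        # strong depolarizing current crosses threshold in one step
        s, spiked = model.membrane_step(s, -1e5, 0.0, 0.025, nrn, AD)
        assert spiked and s.V == nrn.V_reset
        assert s.refractory_remaining == nrn.tau_ref
        # clamped during refractoriness even under strong drive
        s, spiked = model.membrane_step(s, -1e5, 0.0, 0.5, nrn, AD)
        assert not spiked and s.V == nrn.V_reset

    def test_subthreshold_silent_without_noise(self):
        nrn = NeuronParams(sigma=0.0)
        s = model.NeuronState(V=-60.0)
        for _ in range(2000):
            s, spiked = model.membrane_step(s, 0.0, 0.0, 0.05, nrn, AD)
            assert not spiked

    def test_blowup_guard(self):
        nrn = NeuronParams(sigma=0.0)
        s = model.NeuronState(V=float("inf"))
        with pytest.raises(FloatingPointError):
            model.membrane_step(s, 0.0, 0.0, 0.025, nrn, AD)

    def test_noise_contract_stationary_sd(self):
        # leak only: empirical s.d. of V approaches sigma
        # threshold far out of reach so the trajectory never resets
        nrn = NeuronParams(sigma=5.0, V_thr=20.0, V_reset=-55.0)
        rng = np.random.default_rng(42)
        dt = 0.05
        n = 10 ** 6
        draws = rng.standard_normal(n)
        s = model.NeuronState(V=nrn.V_L)
        vs = np.empty(n)
        for i in range(n):
            s, _ = model.membrane_step(s, 0.0, draws[i], dt, nrn, AD)
            vs[i] = s.V
        sd = vs[n // 10:].std()
        assert sd == pytest.approx(5.0, rel=0.03)

    def test_ahp_current_form(self):
        assert model.ahp_current(-60.0, 2.0, AD) == pytest.approx(
            2.0 * (-60.0 + 80.0))


class TestParameterValidation:
    def test_reset_below_threshold_enforced(self):
        with pytest.raises(ParameterError):
            NeuronParams(V_reset=-40.0)

    def test_stp_range(self):
        with pytest.raises(ParameterError):
            STPParams(U=0.0)
        with pytest.raises(ParameterError):
            STPParams(tau_x=-1.0)

    def test_tau_m_derived(self):
        assert NRN.tau_m == pytest.approx(20.0)
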