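import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from levmodel.neural_mass import (ElectricalConstants, ElectricalParams,
                                  ElectricalState, extracellular_current,
                                  logistic_rate, nmm_derivatives,
                                  simulate_electrical, synaptic_currents)
from levmodel.stimulus import build_protocol_inputs


class TestLogistic:
    def test_midpoint(self):
        assert logistic_rate(0.6, 0.6, 4.0) == pytest.approx(0.5)

    def test_saturates_at_one(self):
        assert logistic_rate(1e4, 0.6, 4.0) == pytest.approx(1.0)

    @given(v=st.floats(-10, 10), dv=st.floats(1e-3, 1.0))
    def test_strictly_increasing(self, v, dv):
        assert logistic_rate(v + dv, 0.5, 3.0) > logistic_rate(v, 0.5, 3.0)

    def test_negative_growth_rate_rejected(self):
        with pytest.raises(ValueError):
            logistic_rate(0.0, 0.5, -1.0)


class TestSynapticCurrents:
    def test_zero_gaba_silences_inhibition(self, consts):
        state = ElectricalState(v_in_t=1.0, v_in_f=0.5)
        cur = synaptic_currents(state, ElectricalParams(gaba_factor=0.0),
                                consts)
        assert cur["pc_inhibitory"] == 0.0

    def test_inhibition_linear_in_gaba(self, consts):
        state = ElectricalState(v_in_t=2.0, v_in_f=1.0)
        c1 = synaptic_currents(state, ElectricalParams(gaba_factor=0.3),
                               consts)
        c2 = synaptic_currents(state, ElectricalParams(gaba_factor=0.6),
                               consts)
        assert c2["pc_inhibitory"] == pytest.approx(2 * c1["pc_inhibitory"])

    def test_rest_state_currents_vanish(self, consts):
        cur = synaptic_currents(ElectricalState(), ElectricalParams(), consts)
        assert cur["pc_inhibitory"] == pytest.approx(0.0, abs=1e-12)
        assert cur["fb_excitatory"] == pytest.approx(0.0, abs=1e-12)


class TestDerivatives:
    def test_rest_is_fixed_point(self, consts):
        d = nmm_derivatives(ElectricalState(), (0.0, 0.0, 0.0),
                            ElectricalParams(), consts)
        assert np.linalg.norm(d) < 1e-8

    def test_steady_state_of_driven_interneuron(self, consts):
        # decoupled transmission IN under constant current: V* = R * I
        current = 0.7
        v_star = consts.r_in * current
        d = nmm_derivatives(ElectricalState(v_in_t=v_star),
                            (current, 0.0, 0.0), ElectricalParams(), consts)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_exponential_decay_rate(self, consts):
        # transmission IN with no input decays at 1/tau_m
        v0 = 1.0
        d = nmm_derivatives(ElectricalState(v_in_t=v0), (0.0, 0.0, 0.0),
                            ElectricalParams(gaba_factor=0.0), consts)
        assert d[0] == pytest.approx(-v0 / consts.tau_m)

    def test_non_finite_state_rejected(self, consts):
        state = ElectricalState(v_in_t=np.nan)
        with pytest.raises(FloatingPointError):
            nmm_derivatives(state, (0.0, 0.0, 0.0), ElectricalParams(),
                            consts)


class TestExtracellularCurrent:
    def test_no_gradient_no_current(self, consts):
        state = ElectricalState(v_pc_soma=0.4, v_pc_apical=0.4)
        assert extracellular_current(state, consts) == 0.0

    def test_linearity_and_antisymmetry(self, consts):
        a = ElectricalState(v_pc_soma=0.1, v_pc_apical=0.5)
        b = ElectricalState(v_pc_soma=0.5, v_pc_apical=0.1)
        ja = extracellular_current(a, consts)
        assert extracellular_current(b, consts) == pytest.approx(-ja)
        doubled = ElectricalState(v_pc_soma=0.2, v_pc_apical=1.0)
        assert extracellular_current(doubled, consts) == pytest.approx(2 * ja)


@pytest.fixture(scope="module")
def block(truth, protocol, consts):
    p1, p2, p3 = build_protocol_inputs(10.0, truth.electrical, protocol, 1e-3)
    return simulate_electrical(p1, p2, p3, truth.electrical, consts, 1e-3)


class TestSimulation:

    def test_bounded_over_full_block(self, block):
        assert np.all(np.isfinite(block.states))
        assert np.abs(block.states).max() < 50.0  # mV scale stays sane

    def test_step_refinement_converges(self, truth, protocol, consts):
        # halving the step from 1 ms to 0.5 ms moves the EEG RMS by < 1%
        rms = {}
        for dt in (1e-3, 5e-4):
            p1, p2, p3 = build_protocol_inputs(10.0, truth.electrical,
                                               protocol, dt, duration=10.0)
            traj = simulate_electrical(p1, p2, p3, truth.electrical, consts,
                                       dt)
            rms[dt] = np.sqrt(np.mean(traj.extracellular_current**2))
        assert abs(rms[1e-3] - rms[5e-4]) / rms[5e-4] < 0.01

    @pytest.mark.parametrize("freq", [4.0, 10.0, 20.0])
    def test_eeg_phase_locks_to_stimulus(self, truth, protocol, consts, freq):
        p1, p2, p3 = build_protocol_inputs(freq, truth.electrical, protocol,
                                           1e-3)
        traj = simulate_electrical(p1, p2, p3, truth.electrical, consts, 1e-3)
        stim = traj.extracellular_current[:15000]
        spec = np.abs(np.fft.rfft(stim - stim.mean()))
        f_axis = np.fft.rfftfreq(stim.size, 1e-3)
        peak = f_axis[np.argmax(spec)]
        # dominant component at the reversal frequency or a harmonic
        ratio = peak / freq
        assert abs(ratio - round(ratio)) < 0.02 and round(ratio) >= 1

    def test_mismatched_input_grids_rejected(self, truth, consts):
        with pytest.raises(ValueError):
            simulate_electrical(np.zeros(10), np.zeros(11), np.zeros(10),
                                truth.electrical, consts, 1e-3)
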