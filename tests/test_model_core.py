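"""Unit tests of the conductance-based plant and its canonical decomposition."""

import numpy as np
import pytest

from caedbs import _kernels as K
from caedbs.model_core import (DelayLine, DivergenceError, PlantState,
                               firing_rate, ionic_currents, isi_stats,
                               membrane_derivative, neurotransmitter_release,
                               simulate, spike_times, step_plant,
                               synapse_kinetics, synaptic_currents,
                               true_dynamics_split)
from caedbs.params import PlantParams, gate_steady_state, initial_state

from conftest import random_plant_states


def uncoupled(preset="normal", i_ext=(0.0, 0.0, 0.0)):
    p = PlantParams.preset(preset)
    p.i_ext = i_ext
    for f in ("g_ampa_ct_tc", "g_gabaa_rt_tc", "g_gabab",
              "g_ampa_tc_ct", "g_gabaa_rt_rt", "g_ampa_tc_rt"):
        setattr(p.syn, f, 0.0)
    return p


class TestNeurotransmitterRelease:
    @pytest.mark.parametrize("v, expected, tol", [
        (2.0, 1.42, 1e-12),              # sigmoid midpoint
        (1e4, 2.84, 1e-9),               # saturation limit
        (-60.0, 2.84 / (1 + np.exp(12.4)), 1e-12),
    ])
    def test_values(self, v, expected, tol):
        assert neurotransmitter_release(v) == pytest.approx(expected, abs=tol)

    def test_monotone_and_bounded(self):
        vs = np.linspace(-120, 80, 400)
        ts = np.array([neurotransmitter_release(v) for v in vs])
        assert np.all(np.diff(ts) > 0)
        assert np.all((ts > 0) & (ts < 2.84))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            neurotransmitter_release(np.nan)


class TestSynapseKinetics:
    def test_pure_decay_at_zero_transmitter(self):
        assert synapse_kinetics(0.4, 0.0, 0.94, 0.18) == pytest.approx(-0.18 * 0.4)

    def test_first_order_fixed_point(self):
        # s* = alpha T / (alpha T + beta) for AMPA at saturating T
        a, b, t = 0.94, 0.18, 2.84
        s_star = a * t / (a * t + b)
        assert s_star == pytest.approx(0.9368, abs=5e-4)
        assert synapse_kinetics(s_star, t, a, b) == pytest.approx(0.0, abs=1e-14)

    def test_gabab_fixed_point_ratio(self):
        r = 0.3
        s_star = 0.18 / 0.034 * r
        ds, dr = synapse_kinetics(s_star, 0.0, None, None, r=r, kind="gabab")
        assert ds == pytest.approx(0.0, abs=1e-14)
        assert dr == pytest.approx(-0.0012 * r)

    def test_preserves_unit_interval(self):
        # ds/dt >= 0 at s = 0 and <= 0 at s = 1 for any T >= 0
        for t in (0.0, 0.5, 2.84):
            assert synapse_kinetics(0.0, t, 0.94, 0.18) >= 0
            assert synapse_kinetics(1.0, t, 0.94, 0.18) <= 0

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            synapse_kinetics(0.5, 1.0, -0.1, 0.18)


class TestIonicAndSynapticCurrents:
    def test_channel_current_zero_at_reversal(self, normal_params):
        y = initial_state(-65.0, normal_params)
        y[0] = normal_params.ionic["TC"]["Na"].e_rev
        cur = ionic_currents(PlantState(y=y), normal_params, "TC")
        assert cur["Na"] == 0.0

    def test_zero_conductances_zero_total(self, normal_params):
        p = PlantParams.preset("normal")
        for ch in p.ionic["RT"].values():
            ch.gbar = 0.0
        st = PlantState(y=initial_state(-55.0, p))
        assert ionic_currents(st, p, "RT")["total"] == 0.0

    def test_unknown_channel_rejected(self, normal_params):
        st = PlantState(y=initial_state(-65.0, normal_params))
        with pytest.raises(KeyError):
            ionic_currents(st, normal_params, "GC")

    def test_gating_steady_state_is_kinetic_fixed_point(self, normal_params):
        # at the voltage-dependent steady state, d(gating)/dt = 0
        y = initial_state(-63.0, normal_params)
        st = PlantState(y=y)
        dy = np.empty(K.S_LEN)
        K.plant_deriv(y, normal_params.pack(), 0.0, 0.0,
                      0, 0, 0, 0, 0, 0, dy)
        assert np.allclose(dy[3:19], 0.0, atol=1e-12)

    def test_all_gates_zero_means_no_synaptic_current(self, normal_params):
        y = initial_state(-65.0, normal_params)
        y[19:26] = 0.0
        assert np.allclose(synaptic_currents(PlantState(y=y), normal_params), 0.0)

    def test_gabab_half_activation(self, normal_params):
        # s^4 = Kd => conductance = gbar/2
        p = normal_params
        y = initial_state(-65.0, p)
        y[19:26] = 0.0
        y[K.S_GABAB] = p.syn.kd ** 0.25
        i_tc = synaptic_currents(PlantState(y=y), p)[0]
        expected = 0.5 * p.syn.g_gabab * (y[0] - p.syn.e_gabab)
        assert i_tc == pytest.approx(expected)

    def test_ampa_zero_at_reversal(self, normal_params):
        y = initial_state(-65.0, normal_params)
        y[0] = normal_params.syn.e_ampa
        y[20] = y[21] = y[22] = 0.0  # isolate the AMPA term
        assert synaptic_currents(PlantState(y=y), normal_params)[0] == 0.0


class TestMembraneDerivative:
    def test_pure_external_drive(self):
        # all conductances off, I_ext = (5,0,0), C = 1 => dV_TC/dt = 5
        p = uncoupled(i_ext=(5.0, 0.0, 0.0))
        for chans in p.ionic.values():
            for ch in chans.values():
                ch.gbar = 0.0
        st = PlantState(y=initial_state(-65.0, p))
        dv = membrane_derivative(st, p)
        assert dv == pytest.approx([5.0, 0.0, 0.0])

    def test_control_additivity(self, cae_params, rng):
        st = random_plant_states(cae_params, rng, 1)[0]
        base = membrane_derivative(st, cae_params)
        u = np.array([3.0, -2.0, 0.7])
        assert membrane_derivative(st, cae_params, u=u) == pytest.approx(base + u)

    def test_divergence_guard(self, cae_params):
        y = initial_state(-65.0, cae_params)
        y[0] = np.nan
        with pytest.raises(DivergenceError):
            membrane_derivative(PlantState(y=y), cae_params)


class TestTrueDynamicsSplit:
    def test_recombination_matches_derivative(self, cae_params, rng):
        # f + f_tau + G u + d == dV/dt to machine precision, 1000 random states
        u = rng.normal(size=3)
        d = rng.normal(size=3)
        for st in random_plant_states(cae_params, rng, 1000):
            f, f_tau, g = true_dynamics_split(st, cae_params)
            lhs = f + f_tau + g @ u + d
            rhs = membrane_derivative(st, cae_params, u=u, d=d)
            assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_gain_matrix_structure(self, cae_params):
        st = PlantState(y=initial_state(-65.0, cae_params))
        _, _, g = true_dynamics_split(st, cae_params)
        assert np.allclose(g, np.eye(3))  # C = (1,1,1)
        chi0 = 1.0 / max(cae_params.c_m)
        assert np.all(np.linalg.eigvalsh(g) >= chi0 - 1e-15)

    def test_kernel_derivative_consistency(self, cae_params, rng):
        # compiled plant_deriv voltage rows match the NumPy reference path
        p = cae_params.pack()
        for st in random_plant_states(cae_params, rng, 50):
            dy = np.empty(K.S_LEN)
            td1 = neurotransmitter_release(st.y[1])
            td2 = neurotransmitter_release(st.y[0])
            K.plant_deriv(st.y, p, td1, td2, 0, 0, 0, 0, 0, 0, dy)
            ref = membrane_derivative(st, cae_params)
            assert np.allclose(dy[:3], ref, rtol=1e-12, atol=1e-10)


class TestDelayLine:
    def test_prehistory_and_exact_lookup(self):
        dl = DelayLine(3, fill=-70.0)
        assert dl.delayed() == -70.0
        for v in (1.0, 2.0, 3.0, 4.0):
            dl.push(v)
        assert dl.delayed() == 2.0  # exactly 3 steps ago

    def test_zero_delay_has_no_history(self):
        dl = DelayLine(0, fill=-70.0)
        with pytest.raises(ValueError):
            dl.delayed()


class TestStepAndSimulate:
    def test_stationary_state_unchanged(self):
        # a true fixed point of the uncoupled plant stays put
        p = uncoupled()
        df = simulate(p, init=-70.0, duration=4000.0, dt=0.01)
        y_rest = df.attrs["final_state"].copy()
        st = PlantState(y=y_rest.copy())
        n1, n2 = p.delay_steps(0.01)
        vct = DelayLine(n1, y_rest[1])
        vtc = DelayLine(n2, y_rest[0])
        out = step_plant(st, p, 0.01, vct, vtc)
        assert np.allclose(out.y, y_rest, atol=1e-9)

    def test_step_determinism(self, cae_params):
        n1, n2 = cae_params.delay_steps(0.01)
        outs = []
        for _ in range(2):
            st = PlantState(y=initial_state(-55.0, cae_params))
            vct = DelayLine(n1, st.y[1])
            vtc = DelayLine(n2, st.y[0])
            outs.append(step_plant(st, cae_params, 0.01, vct, vtc).y)
        assert np.array_equal(outs[0], outs[1])

    def test_rk4_observed_order(self, cae_params):
        # halving dt shrinks the 10 ms trajectory error ~16x (order 4 +- 0.5)
        errs = []
        ref = simulate(cae_params, init=-60.0, duration=10.0, dt=0.0005)
        vref = ref["V_TC"].values[-1]
        for dt in (0.004, 0.002):
            df = simulate(cae_params, init=-60.0, duration=10.0, dt=dt)
            errs.append(abs(df["V_TC"].values[-1] - vref))
        order = np.log2(errs[0] / errs[1])
        assert 3.5 <= order <= 4.5

    def test_rest_with_zero_input(self):
        # no coupling, no external current: all voltages settle to rest
        p = uncoupled()
        df = simulate(p, init=-65.0, duration=6000.0, dt=0.01)
        st = PlantState(y=df.attrs["final_state"])
        dv = membrane_derivative(st, p)
        assert np.all(np.abs(dv) < 1e-6)

    def test_row_count_scales_with_duration(self, cae_params):
        d1 = simulate(cae_params, duration=100.0, dt=0.01, record_every=0.1)
        d2 = simulate(cae_params, duration=200.0, dt=0.01, record_every=0.1)
        assert len(d2) == 2 * len(d1)

    def test_gates_stay_in_unit_interval(self, cae_params):
        df = simulate(cae_params, init=-55.0, duration=500.0, dt=0.01)
        gating = df.iloc[:, 4:20].values          # gating variables
        first_order = df[["s_ampa_ct_tc", "s_gabaa_rt_tc", "r_gabab",
                          "s_ampa_tc_ct", "s_gabaa_rt_rt", "s_ampa_tc_rt"]].values
        assert gating.min() >= 0.0 and gating.max() <= 1.0
        assert first_order.min() >= 0.0 and first_order.max() <= 1.0
        # the slow GABA_B gate obeys its own kinetic bound 0.18/0.034
        assert df["s_gabab"].min() >= 0.0
        assert df["s_gabab"].max() <= 0.18 / 0.034

    def test_zero_delay_equals_instantaneous_drive(self):
        # tau1 = tau2 = 0: delayed transmitter == instantaneous transmitter
        p0 = PlantParams.preset("cae", tau1=0.0, tau2=0.0)
        df = simulate(p0, init=-60.0, duration=50.0, dt=0.01)
        # compare against a manual run where the delayed drive is forced to
        # the instantaneous presynaptic value at every step
        y = initial_state(-60.0, p0)
        scratch = [np.empty(K.S_LEN) for _ in range(5)]
        p = p0.pack()
        n = 5000
        for _ in range(n):
            td1 = float(K.t_conc(y[1]))
            td2 = float(K.t_conc(y[0]))
            K.rk4_step(y, p, td1, td2, 0, 0, 0, 0, 0, 0, 0.01, *scratch)
        assert df.attrs["final_state"] == pytest.approx(y, abs=1e-12)


class TestPresets:
    def test_presets_differ_only_in_two_values(self):
        a = PlantParams.preset("normal").pack()
        b = PlantParams.preset("cae").pack()
        diff = np.nonzero(a != b)[0]
        assert set(diff) == {K.P_G_GABAA_RT_TC, K.P_IEXT_TC}

    def test_cae_fires_faster_and_more_tonic(self):
        rates, cvs = {}, {}
        for name in ("normal", "cae"):
            df = simulate(PlantParams.preset(name), init=-65.0,
                          duration=2000.0, dt=0.01)
            t = df["t_ms"].values
            rates[name] = firing_rate(df["V_TC"].values, t)
            cvs[name] = isi_stats(df["V_TC"].values, t)["cv_isi"]
        assert rates["cae"] > rates["normal"]
        assert cvs["cae"] < cvs["normal"]  # tonic (regular) vs bursting

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            PlantParams.preset("seizure-free")
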