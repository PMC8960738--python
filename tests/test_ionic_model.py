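"""Membrane model unit and property tests: reversal potentials, gate
kinetics, current identities and single-cell dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from pigatria import (CellState, ModelParameters, compute_currents,
                      compute_fn_and_qca, gate_kinetics, nernst_potential,
                      simulate_cell, step_ca_subsystem, step_cell)
from pigatria.constants import FARADAY, R_GAS
from pigatria.ionic_model import CurrentSet, currents_from_states
from pigatria.protocols import extract_ap_features

ALL_GATES = ["m", "h", "j", "d", "f", "u_a", "u_if", "u_is", "x_r", "x_s", "w"]


# --------------------------------------------------------------------------
# Nernst potential
# --------------------------------------------------------------------------

class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst_potential(1, 5.4, 5.4) == 0.0

    def test_potassium_reversal_matches_direct_arithmetic(self):
        expected = R_GAS * 310.15 / FARADAY * math.log(5.4 / 139.0)
        got = nernst_potential(1, 139.0, 5.4, 310.15)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(-86.8, abs=0.05)

    @given(st.floats(0.01, 500), st.floats(0.01, 500),
           st.integers(-3, 3).filter(lambda z: z != 0))
    def test_valence_antisymmetry(self, ci, co, z):
        e1 = nernst_potential(z, ci, co)
        e2 = nernst_potential(-z, ci, co)
        assert e1 == pytest.approx(-e2, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("ci,co", [(0.0, 5.4), (-1.0, 5.4), (5.4, 0.0)])
    def test_nonpositive_concentration_rejected(self, ci, co):
        with pytest.raises(ValueError):
            nernst_potential(1, ci, co)

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            nernst_potential(0, 1.0, 1.0)


# --------------------------------------------------------------------------
# gate kinetics
# --------------------------------------------------------------------------

class TestGateKinetics:
    def test_xr_half_rise_point(self, params):
        inf, _ = gate_kinetics("x_r", 4.4451, params)
        assert inf == pytest.approx(0.5, abs=1e-12)

    def test_xs_at_p1_is_inverse_sqrt_two(self, params):
        inf, _ = gate_kinetics("x_s", params.p1, params)
        assert inf == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_fca_half_saturation(self, params):
        inf, tau = gate_kinetics("f_ca", 0.00035, params)
        assert inf == pytest.approx(0.5, abs=1e-12)
        assert tau == 2.0

    def test_unknown_gate_rejected(self):
        with pytest.raises(KeyError):
            gate_kinetics("zz", 0.0)

    @pytest.mark.parametrize("gate", ALL_GATES)
    def test_steady_state_bounded_and_tau_positive(self, gate, params):
        for v in np.linspace(-120.0, 100.0, 221):
            inf, tau = gate_kinetics(gate, float(v), params)
            assert 0.0 <= inf <= 1.0, f"{gate} inf at {v}"
            assert tau > 0.0, f"{gate} tau at {v}"

    @given(st.floats(-120.0, 100.0))
    @pytest.mark.parametrize("gate", ["m", "h", "j"])
    def test_sodium_gate_kinetics_continuous_targets(self, gate, v):
        inf, tau = gate_kinetics(gate, v)
        assert 0.0 <= inf <= 1.0 and 0.0 < tau < 1e4

    def test_porcine_tau_scalings_applied(self, params):
        base = params.replace(tau_m_scale=1.0, tau_h_scale=1.0,
                              tau_j_scale=1.0)
        for gate, scale in (("m", 1.7), ("h", 2.0), ("j", 2.0)):
            _, tau_pig = gate_kinetics(gate, -40.0, params)
            _, tau_src = gate_kinetics(gate, -40.0, base)
            assert tau_pig == pytest.approx(scale * tau_src, rel=1e-12)

    @pytest.mark.parametrize("gate,increasing", [
        ("m", True), ("d", True), ("u_a", True), ("x_r", True),
        ("x_s", True), ("h", False), ("j", False), ("f", False),
        ("u_if", False), ("w", False),
    ])
    def test_steady_state_monotone_in_voltage(self, gate, increasing, params):
        v = np.linspace(-100.0, 60.0, 161)
        inf = np.array([gate_kinetics(gate, float(x), params)[0] for x in v])
        d = np.diff(inf)
        assert np.all(d >= -1e-12) if increasing else np.all(d <= 1e-12)

    def test_slow_kur_inactivation_is_slower_by_fixed_factor(self, params):
        _, tf = gate_kinetics("u_if", -10.0, params)
        _, ts = gate_kinetics("u_is", -10.0, params)
        assert ts == pytest.approx(params.tau_uis_factor * tf, rel=1e-12)


# --------------------------------------------------------------------------
# currents
# --------------------------------------------------------------------------

class TestCurrents:
    def test_iion_is_sum_of_twelve_membrane_currents(self, rest, params):
        cur = compute_currents(rest, params)
        assert cur.I_ion == pytest.approx(cur.membrane_sum(), abs=1e-14)

    def test_ik1_vanishes_at_shifted_reversal(self, rest, params):
        e_k = nernst_potential(1, rest.K_i, params.K_o, params.T)
        st = CellState(**{**rest.to_dict(), "V": e_k + 5.0})
        assert compute_currents(st, params).I_K1 == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_ik1_zero_crossing_near_measured_reversal(self, params):
        """The inward rectifier reverses within 0.2 mV of -81.76 mV with
        [K]o = 5.4, [K]i = 139 mM at 310.15 K."""
        ref = CellState(K_i=139.0)

        def ik1(v):
            st = CellState(**{**ref.to_dict(), "V": v})
            return compute_currents(st, params).I_K1

        crossing = brentq(ik1, -95.0, -65.0, xtol=1e-10)
        assert abs(crossing - (-81.76)) < 0.2
        # sign change around the crossing
        assert ik1(crossing - 1.0) < 0 < ik1(crossing + 1.0)

    def test_ical_zero_at_65mV_regardless_of_gates(self, rest, params):
        st = CellState(**{**rest.to_dict(), "V": 65.0, "d": 1.0, "f": 1.0,
                          "f_ca": 1.0})
        assert compute_currents(st, params).I_CaL == 0.0

    def test_closed_gates_give_zero_current(self, rest, params):
        st = CellState(**{**rest.to_dict(), "m": 0.0, "q_ca": 0.0})
        cur = compute_currents(st, params)
        assert cur.I_Na == 0.0
        assert cur.I_ClCa == 0.0

    @pytest.mark.parametrize("v,expected_factor", [(-150.0, 0.005),
                                                   (150.0, 0.055)])
    def test_kur_conductance_sigmoid_limits(self, v, expected_factor,
                                            rest, params):
        st = CellState(**{**rest.to_dict(), "V": v, "u_a": 1.0, "u_if": 1.0,
                          "u_is": 1.0})
        cur = compute_currents(st, params)
        e_k = nernst_potential(1, st.K_i, params.K_o, params.T)
        g = cur.I_Kur / (v - e_k)
        assert g == pytest.approx(expected_factor * params.g_Kur_amp,
                                  rel=1e-3)

    def test_vectorised_currents_match_scalar_evaluation(self, paced_trace,
                                                         params):
        cur = paced_trace.currents()
        k = len(paced_trace.times) // 2
        single = compute_currents(CellState.from_array(paced_trace.states[k]),
                                  params)
        for name, arr in cur.items():
            assert arr[k] == pytest.approx(getattr(single, name),
                                           rel=1e-12, abs=1e-15)


class TestFnAndQca:
    def _currents_with_fn(self, fn_target, params):
        i_rel = fn_target / (1.0e-12 * params.V_rel)
        zeros = {f: 0.0 for f in CurrentSet.__dataclass_fields__}
        zeros.update(I_rel=i_rel)
        return CurrentSet(**zeros)

    @pytest.mark.parametrize("fn,expected", [
        (1.1e-10, 0.5),
        (0.0, 0.0),
        (1.1e-9, 1.0 - 1.0 / 1001.0),
    ])
    def test_qca_steady_state_hill_curve(self, fn, expected, rest, params):
        cur = self._currents_with_fn(fn, params)
        got_fn, qca_inf, tau = compute_fn_and_qca(rest, cur, params)
        assert got_fn == pytest.approx(fn, rel=1e-12)
        assert qca_inf == pytest.approx(expected, abs=1e-9)
        assert tau == 2.0

    def test_negative_flux_clipped_to_closed_gate(self, rest, params):
        cur = self._currents_with_fn(-5e-10, params)
        _, qca_inf, _ = compute_fn_and_qca(rest, cur, params)
        assert qca_inf == 0.0


# --------------------------------------------------------------------------
# Ca subsystem stepping
# --------------------------------------------------------------------------

class TestCaSubsystem:
    def test_total_calcium_conserved_without_transmembrane_flux(self, rest,
                                                                params):
        cur = compute_currents(rest, params)
        d = cur.to_dict()
        for name in ("I_CaL", "I_bCa", "I_pCa", "I_NaCa"):
            d[name] = 0.0
        new = step_ca_subsystem(rest, CurrentSet(**d), dt=0.02, params=params)
        before = rest.total_calcium(params)
        after = new.total_calcium(params)
        assert abs(after - before) / params.V_i < 1e-9  # mM equivalent

    def test_zero_sr_fluxes_leave_sr_unchanged(self, rest, params):
        zeros = {f: 0.0 for f in CurrentSet.__dataclass_fields__}
        new = step_ca_subsystem(rest, CurrentSet(**zeros), dt=0.02,
                                params=params)
        assert new.Ca_up == rest.Ca_up
        assert new.Ca_rel == rest.Ca_rel

    def test_draining_calcium_raises_instability_error(self, rest, params):
        zeros = {f: 0.0 for f in CurrentSet.__dataclass_fields__}
        zeros.update(I_pCa=1e6)  # absurd efflux
        with pytest.raises(FloatingPointError):
            step_ca_subsystem(rest, CurrentSet(**zeros), dt=0.05,
                              params=params)

    def test_nonpositive_dt_rejected(self, rest, params):
        cur = compute_currents(rest, params)
        with pytest.raises(ValueError):
            step_ca_subsystem(rest, cur, dt=0.0, params=params)

    def test_quiescent_cell_calcium_drifts_below_one_percent(self, params):
        """Without stimulation the model settles: from the equilibrated
        quiescent state (slow Na+ relaxation included), all Ca2+ state
        variables move by less than 1% over a further 10 s."""
        from pigatria import resting_state
        settled = resting_state(params, duration_ms=200_000.0)
        tr = simulate_cell(params, settled, duration=10_000.0,
                           record_every=50.0)
        final = tr.final_state()
        for name in ("Ca_i", "Ca_up", "Ca_rel"):
            rel = abs(getattr(final, name) - getattr(settled, name)) \
                / getattr(settled, name)
            assert rel < 0.01, name


# --------------------------------------------------------------------------
# cell stepping
# --------------------------------------------------------------------------

class TestStepCell:
    def test_resting_state_is_an_equilibrium(self, rest, params):
        new = step_cell(rest, params, I_stim=0.0, dt=0.02)
        assert abs(new.V - rest.V) < 1e-6

    def test_dt_bounds_enforced(self, rest, params):
        for dt in (0.0, -0.01, 0.06):
            with pytest.raises(ValueError):
                step_cell(rest, params, dt=dt)

    def test_unknown_scheme_rejected(self, rest, params):
        with pytest.raises(ValueError):
            step_cell(rest, params, scheme="implicit")

    def test_nonfinite_state_raises_named_instability(self, rest, params):
        bad = CellState(**{**rest.to_dict(), "V": float("nan")})
        with pytest.raises(FloatingPointError, match="V"):
            for _ in range(3):
                bad = step_cell(bad, params)

    def test_gates_stay_in_bounds_over_voltage_sweep(self, rest, params):
        """Euler gate updates stay in [0,1] over the voltage range the model
        visits (below about -84 mV the m-gate time constant drops under
        dt/2, so strongly hyperpolarised states need the exponential
        scheme, which is bounded for any voltage)."""
        gate_names = ["m", "h", "j", "d", "f", "f_ca", "u_a", "u_if",
                      "u_is", "x_r", "x_s", "q_ca", "u", "v", "w"]
        sweep = {"euler": np.linspace(-80.0, 80.0, 33),
                 "rush-larsen": np.linspace(-120.0, 100.0, 45)}
        for scheme, voltages in sweep.items():
            for v in voltages:
                st = CellState(**{**rest.to_dict(), "V": float(v)})
                out = st
                for _ in range(5):
                    out = step_cell(out, params, dt=0.02, scheme=scheme)
                for g in gate_names:
                    assert 0.0 <= getattr(out, g) <= 1.0, (v, scheme, g)

    def test_rush_larsen_tracks_euler_over_one_beat(self, rest, params):
        kw = dict(duration=400.0, stim_times=[1.0], stim_amplitude=70.0,
                  stim_duration=1.0, record_every=1.0)
        a = simulate_cell(params, rest, scheme="euler", **kw)
        b = simulate_cell(params, rest, scheme="rush-larsen", **kw)
        assert np.max(np.abs(a.V - b.V)) < 5.0  # mV, same AP morphology


class TestActionPotential:
    def test_paced_beat_is_physiological(self, paced_trace):
        feats = extract_ap_features(paced_trace.times, paced_trace.V,
                                    paced_trace.stim_times)
        last = feats[-1]
        assert last.captured
        assert -85.0 < last.RMP < -70.0
        assert 90.0 < last.APA < 160.0
        assert 80.0 < last.dVdt_max < 400.0
        assert 120.0 < last.apd[90] < 260.0
        assert np.all(paced_trace.V >= -150.0)
        assert np.all(paced_trace.V <= 100.0)

    def test_apd90_converges_under_dt_refinement(self, rest, params):
        """Halving dt from 0.02 to 0.01 ms moves APD90 by less than 1 ms."""
        apd = {}
        for dt in (0.02, 0.01):
            tr = simulate_cell(params, rest, duration=900.0, dt=dt,
                               stim_times=[1.0], stim_amplitude=70.0,
                               stim_duration=1.0, record_every=0.2)
            f = extract_ap_features(tr.times, tr.V, [1.0])[0]
            apd[dt] = f.apd[90]
        assert abs(apd[0.02] - apd[0.01]) < 1.0

    def test_simulation_is_bitwise_deterministic(self, rest, params):
        kw = dict(duration=300.0, stim_times=[1.0], stim_amplitude=70.0,
                  stim_duration=1.0, record_every=0.5)
        a = simulate_cell(params, rest, **kw)
        b = simulate_cell(params, rest, **kw)
        assert np.array_equal(a.states, b.states)


class TestParameters:
    def test_table_defaults(self, params):
        assert params.g_K1 == 0.08218
        assert params.g_Na == 13.99
        assert params.g_Kur_amp == 0.45539
        assert params.g_ClCa == 0.15731
        assert params.g_Kr == 0.0173
        assert params.g_Ks == 0.0594
        assert params.g_CaL == 0.06574
        assert params.I_NaK_max == 0.94935
        assert params.I_NaCa_max == 2304.0
        assert params.a_Kur + params.b_Kur == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(g_Na=-1.0)
        with pytest.raises(ValueError):
            ModelParameters(a_Kur=0.3, b_Kur=0.75)
        with pytest.raises(KeyError):
            ModelParameters().replace(g_nonexistent=1.0)

    def test_stimulus_conversion_through_capacitance(self, params):
        assert params.stimulus_per_pF(7.0) == pytest.approx(70.0)
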