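"""Simulator contracts: closed-form oracles and convergence invariants."""

import math

import numpy as np
import pytest

from neurofit.biophys_sim import (CaDynamicsParams, PassiveParameters,
                                  SolverOptions, build_model, nernst,
                                  simulate, update_calcium, voltage_clamp)
from neurofit.channels import q10_factor
from neurofit.ephys_features import detect_spikes
from neurofit.morphology import (KINDS, CompartmentalMorphology, discretize,
                                 soma_to_cylinder)
from neurofit.protocols import StimulusProtocol


class TestNernst:
    def test_zero_at_equal_concentrations(self):
        for z in (1, 2, -1):
            assert nernst(1.0, 1.0, z, 34.0) == 0.0

    def test_calcium_reversal_at_rest(self):
        # 100 nM internal vs 2 mM external, divalent, 34 C
        assert nernst(100e-9, 2e-3, 2, 34.0) == pytest.approx(131.0, abs=0.1)

    def test_log_law_doubling(self):
        base = nernst(1.0, 2.0, 1, 34.0)
        assert nernst(1.0, 4.0, 1, 34.0) - base == pytest.approx(
            1000 * 8.314462 * 307.15 / 96485.332 * math.log(2), rel=1e-9)

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            nernst(1.0, 2.0, 0, 34.0)


class TestQ10:
    def test_unity_at_reference(self):
        assert q10_factor(21.0, 21.0, 2.3) == 1.0

    def test_experimental_temperature_factor(self):
        assert q10_factor(34.0, 21.0, 2.3) == pytest.approx(2.954, abs=0.01)

    def test_monotone_in_temperature(self):
        f = [q10_factor(t, 21.0, 2.3) for t in (25, 30, 35, 40)]
        assert all(a < b for a, b in zip(f, f[1:]))


def _single_compartment(cm=1.0, rm=20000.0, e=-70.0):
    m = CompartmentalMorphology([soma_to_cylinder(8.0)])
    pas = PassiveParameters(cm_by_kind={k: cm for k in KINDS}, ri=100.0,
                            g_leak_by_kind={k: 1 / rm for k in KINDS}, e_leak=e)
    return build_model(m, pas, "A", {})


class TestPassiveOracles:
    def test_rc_charging_curve(self):
        """Single passive compartment vs the analytic exponential."""
        model = _single_compartment()
        area = model.area_cm2[0]
        proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                                 amplitude=-20.0, total_duration=1.3)
        sw = simulate(model, proto)
        r_m = 20000.0 / area * 1e-6        # MOhm
        tau = 20000.0 * 1.0 * 1e-3         # ms (Rm Cm)
        dv = -20e-3 * r_m                  # mV deflection
        sel = (sw.t >= 0.1) & (sw.t <= 1.1)
        tt = (sw.t[sel] - 0.1) * 1000.0
        analytic = -70.0 + dv * (1 - np.exp(-tt / tau))
        rms = np.sqrt(np.mean((sw.v[sel] - analytic) ** 2))
        assert rms / abs(dv) < 0.005

    def test_input_resistance_matches_analytic(self):
        model = _single_compartment()
        proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                                 amplitude=-20.0, total_duration=1.35)
        sw = simulate(model, proto)
        base = sw.v[(sw.t > 0.05) & (sw.t < 0.1)].mean()
        plat = sw.v[(sw.t > 1.0) & (sw.t < 1.1)].mean()
        rin = (base - plat) / 20.0 * 1000.0   # MOhm
        expected = 20000.0 / model.area_cm2[0] * 1e-6
        assert rin == pytest.approx(expected, rel=0.01)

    def test_zero_stimulus_stays_at_rest(self, rs_model):
        proto = StimulusProtocol("long_step", onset=0.1, duration=2.0,
                                 amplitude=0.0, total_duration=2.2)
        sw = simulate(model=rs_model, protocol=proto)
        assert np.max(np.abs(sw.v - sw.v[0])) < 0.1


class TestActiveSimulation:
    def test_gating_variables_bounded(self, rs_model):
        proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                                 amplitude=120.0, total_duration=1.35)
        rs_model.gate_lo[:] = 1.0
        rs_model.gate_hi[:] = 0.0
        simulate(rs_model, proto)
        assert np.all(rs_model.gate_lo >= 0.0)
        assert np.all(rs_model.gate_hi <= 1.0)

    def test_spike_times_stable_under_dt_refinement(self, rs_model):
        proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                                 amplitude=100.0, total_duration=1.35)
        times = {}
        for dt in (0.025, 0.0125):
            so = SolverOptions(dt_ms=dt, rec_dt_ms=0.05)
            sw = simulate(rs_model, proto, so)
            times[dt] = detect_spikes(sw, stim_end=proto.end).spike_times
        assert times[0.025].size == times[0.0125].size
        assert np.max(np.abs(times[0.025] - times[0.0125])) < 0.2e-3

    def test_discretization_convergence_on_step_response(self, uniform_passive):
        """Refining nseg changes the somatic step response by < 1% RMS."""
        from neurofit.morphology import make_ball_and_stick
        proto = StimulusProtocol("long_step", onset=0.05, duration=1.0,
                                 amplitude=-50.0, total_duration=1.1)
        vs = {}
        for rule in (20.0, 20.0 / 3):
            m = discretize(make_ball_and_stick(6.0, 500.0, 2.0), rule)
            model = build_model(m, uniform_passive, "A", {})
            vs[rule] = simulate(model, proto).v
        diff = vs[20.0] - vs[20.0 / 3]
        swing = vs[20.0].max() - vs[20.0].min()
        assert np.sqrt(np.mean(diff ** 2)) / swing < 0.01


class TestCalcium:
    params = CaDynamicsParams(tau_removal_ms=80.0, binding_ratio=20.0)
    area = 4.5e-6  # cm^2

    def test_rest_is_fixed_point(self):
        ca0 = self.params.ca_rest_nM * 1e-6
        assert update_calcium(ca0, 0.0, 1.0, self.params, self.area) == \
            pytest.approx(ca0, rel=1e-12)

    def test_exponential_decay_to_rest(self):
        ca0 = 2 * self.params.ca_rest_nM * 1e-6
        rest = self.params.ca_rest_nM * 1e-6
        ca = ca0
        for _ in range(80):
            ca = update_calcium(ca, 0.0, 1.0, self.params, self.area)
        expected = rest + (ca0 - rest) * math.exp(-80.0 / 80.0)
        assert ca == pytest.approx(expected, rel=1e-9)

    def test_constant_current_steady_state(self):
        """Closed-form fixed point: rest + |I| tau / (2 F vol (1+kappa))."""
        i_ca = -0.05  # nA inward
        ca = self.params.ca_rest_nM * 1e-6
        for _ in range(4000):
            ca = update_calcium(ca, i_ca, 1.0, self.params, self.area)
        vol_l = self.area * self.params.shell_depth_nm * 1e-7 * 1e-3
        expected = self.params.ca_rest_nM * 1e-6 + \
            0.05e-9 * 80.0 / (2 * 96485.332 * vol_l * 21.0)
        assert ca == pytest.approx(expected, rel=1e-6)


class TestVoltageClamp:
    def test_no_k_current_at_ek(self, ball_and_stick, uniform_passive):
        model = build_model(ball_and_stick, uniform_passive, "A",
                            {"Kv3_1": 0.5})
        out = voltage_clamp(model, holding_mV=-90.0, test_levels_mV=[-107.0],
                            duration_ms=50.0, pre_ms=20.0)
        t = out[-107.0]["t_ms"]
        i_k = out[-107.0]["i_chan"]["Kv3_1"][t >= 21.0]
        assert np.max(np.abs(i_k)) < 1e-6

    def test_passive_model_zero_current_at_rest(self, ball_and_stick,
                                                uniform_passive):
        model = build_model(ball_and_stick, uniform_passive, "A", {})
        out = voltage_clamp(model, holding_mV=-77.0, test_levels_mV=[-77.0])
        tail = out[-77.0]["i_total_nA"][-100:]
        assert np.max(np.abs(tail)) < 1e-3

    def test_transient_na_peak_nonmonotone_in_level(self, ball_and_stick,
                                                    uniform_passive):
        """Peak inward Na current rises then falls toward E_Na (I-V shape)."""
        model = build_model(ball_and_stick, uniform_passive, "A",
                            {"NaTs": 0.5})
        levels = [-40.0, -20.0, 0.0, 20.0, 40.0]
        out = voltage_clamp(model, holding_mV=-90.0, test_levels_mV=levels,
                            duration_ms=10.0)
        peaks = [-(out[lv]["i_chan"]["NaTs"].min()) for lv in levels]
        imax = int(np.argmax(peaks))
        assert 0 < imax < len(levels) - 1
        assert peaks[-1] < peaks[imax]


class TestConductanceSets:
    def test_set_b_reaches_narrower_spikes_than_set_a(self, ball_and_stick,
                                                      uniform_passive):
        """Minimum attainable width over a small density grid: B < A."""
        from neurofit.ephys_features import sweep_features

        def min_width(set_name, na_name, k_name):
            widths = []
            for gna in (0.5, 1.5):
                for gk in (0.5, 1.5):
                    model = build_model(ball_and_stick, uniform_passive,
                                        set_name, {na_name: gna, k_name: gk})
                    proto = StimulusProtocol("long_step", onset=0.1,
                                             duration=1.0, amplitude=300.0,
                                             total_duration=1.35)
                    f = sweep_features(simulate(model, proto))
                    if f["ap_width"] is not None and f["avg_rate"] >= 5:
                        widths.append(f["ap_width"])
            return min(widths) if widths else None

        wa = min_width("A", "NaTs", "Kv3_1")
        wb = min_width("B", "NaV", "Kv3_1")
        assert wa is not None and wb is not None
        assert wb < wa

    def test_purely_passive_when_densities_zero(self, ball_and_stick,
                                                uniform_passive):
        model = build_model(ball_and_stick, uniform_passive, "B", {})
        assert np.all(model.chan_g == 0.0)

    def test_apical_controls_free_parameter_count(self, uniform_passive):
        from neurofit.morphology import Section
        m = CompartmentalMorphology([
            soma_to_cylinder(6.0),
            Section("basal", [0, 100.0], [2, 2], parent=0),
            Section("apical", [0, 200.0], [2, 2], parent=0)])
        from neurofit.morphology import replace_axon
        m = discretize(replace_axon(m))
        model = build_model(m, uniform_passive, "A", {})
        assert len(model.free_parameter_names()) == 16

    def test_unknown_channel_rejected(self, ball_and_stick, uniform_passive):
        with pytest.raises(ValueError, match="unknown"):
            build_model(ball_and_stick, uniform_passive, "A", {"NaV": 1.0})
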