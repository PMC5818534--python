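"""Passive-parameter recovery and the spiny Cm redistribution."""

import numpy as np
import pytest

from neurofit.biophys_sim import (PassiveParameters, SolverOptions,
                                  build_model, simulate)
from neurofit.io_formats import SweepSet
from neurofit.morphology import KINDS, discretize, make_ball_and_stick
from neurofit.passive_fit import (DEFAULT_X0, PassiveFitError,
                                  PassiveFitResult, default_passive,
                                  fit_passive, passive_parameters_from_fit,
                                  spiny_cm_adjust)
from neurofit.protocols import StimulusProtocol

TRUTH = dict(cm=1.5, rm=12000.0, ri=120.0)


def _pulse_sweeps(morph, noise_sd=0.0, seed=0):
    pas = PassiveParameters(cm_by_kind={k: TRUTH["cm"] for k in KINDS},
                            ri=TRUTH["ri"],
                            g_leak_by_kind={k: 1 / TRUTH["rm"] for k in KINDS},
                            e_leak=-75.0)
    model = build_model(morph, pas, "A", {})
    so = SolverOptions(dt_ms=0.02, rec_dt_ms=0.04, settle_ms=20.0)
    rng = np.random.default_rng(seed)
    ss = SweepSet()
    for amp, rep in [(200.0, 0), (200.0, 1), (-200.0, 0), (-200.0, 1)]:
        proto = StimulusProtocol("brief_step", onset=0.02, duration=5e-4,
                                 amplitude=amp, total_duration=0.2)
        sw = simulate(model, proto, so)
        if noise_sd > 0:
            sw.v = sw.v + rng.normal(0.0, noise_sd, sw.v.size)
        sw.repeat_index = rep
        ss.add(sw)
    return ss


@pytest.fixture(scope="module")
def bs_morph():
    return discretize(make_ball_and_stick(6.0, 300.0, 2.0))


class TestRecovery:
    def test_noise_free_recovery_within_2_percent(self, bs_morph):
        fit = fit_passive(_pulse_sweeps(bs_morph), bs_morph)
        assert fit.cm_fit == pytest.approx(TRUTH["cm"], rel=0.02)
        assert fit.rm_fit == pytest.approx(TRUTH["rm"], rel=0.02)
        assert fit.ri_fit == pytest.approx(TRUTH["ri"], rel=0.02)

    def test_noisy_recovery_within_10_percent(self, bs_morph):
        fit = fit_passive(_pulse_sweeps(bs_morph, noise_sd=0.1, seed=1),
                          bs_morph)
        assert fit.cm_fit == pytest.approx(TRUTH["cm"], rel=0.10)
        assert fit.rm_fit == pytest.approx(TRUTH["rm"], rel=0.10)
        assert fit.ri_fit == pytest.approx(TRUTH["ri"], rel=0.10)

    def test_initializing_at_truth_returns_truth(self, bs_morph):
        fit = fit_passive(_pulse_sweeps(bs_morph), bs_morph,
                          x0=(TRUTH["cm"], TRUTH["rm"], TRUTH["ri"]))
        assert fit.cm_fit == pytest.approx(TRUTH["cm"], rel=1e-3)
        assert fit.rm_fit == pytest.approx(TRUTH["rm"], rel=1e-3)
        assert fit.ri_fit == pytest.approx(TRUTH["ri"], rel=1e-3)
        assert fit.rms_error < 1e-6

    def test_objective_not_worse_than_initial_guess(self, bs_morph):
        """The optimizer may never return something worse than its start."""
        sweeps = _pulse_sweeps(bs_morph)
        fit = fit_passive(sweeps, bs_morph)
        start = fit_passive(sweeps, bs_morph, x0=DEFAULT_X0, bounds=(
            (DEFAULT_X0[0], DEFAULT_X0[0] + 1e-9),
            (DEFAULT_X0[1], DEFAULT_X0[1] + 1e-9),
            (DEFAULT_X0[2], DEFAULT_X0[2] + 1e-9)))
        assert fit.rms_error <= start.rms_error

    def test_missing_pulse_polarity_rejected(self, bs_morph):
        ss = _pulse_sweeps(bs_morph)
        ups = SweepSet([s for s in ss.all_sweeps() if s.stimulus.amplitude > 0])
        with pytest.raises(PassiveFitError):
            fit_passive(ups, bs_morph)


class TestSpinyCmAdjust:
    def test_capacitance_conservation_example(self):
        areas = {"soma": 800.0, "axon": 200.0, "basal": 3000.0, "apical": 0.0}
        cm = spiny_cm_adjust(1.75, areas)
        assert cm["soma"] == 1.0 and cm["axon"] == 1.0
        assert cm["basal"] == pytest.approx(2.0)

    def test_degenerate_unity_fit(self):
        areas = {"soma": 500.0, "axon": 500.0, "basal": 2000.0, "apical": 0.0}
        cm = spiny_cm_adjust(1.0, areas)
        assert cm["basal"] == pytest.approx(1.0)

    def test_total_capacitance_conserved(self):
        areas = {"soma": 700.0, "axon": 300.0, "basal": 2500.0, "apical": 1500.0}
        cm_fit = 1.6
        cm = spiny_cm_adjust(cm_fit, areas)
        total_before = cm_fit * sum(areas.values())
        total_after = sum(cm[k] * areas[k] for k in areas)
        assert total_after == pytest.approx(total_before, rel=1e-12)

    def test_infeasible_fit_falls_back_with_warning(self):
        areas = {"soma": 3000.0, "axon": 1000.0, "basal": 100.0, "apical": 0.0}
        with pytest.warns(UserWarning):
            cm = spiny_cm_adjust(0.5, areas)
        assert cm == {"soma": 1.0, "axon": 1.0, "basal": 2.0, "apical": 2.0}


class TestDefaults:
    def test_spiny_standard_values(self):
        p = default_passive("spiny")
        assert p.ri == 100.0
        assert p.cm_by_kind["soma"] == 1.0 and p.cm_by_kind["axon"] == 1.0
        assert p.cm_by_kind["basal"] == 2.0 and p.cm_by_kind["apical"] == 2.0

    def test_aspiny_uniform(self):
        p = default_passive("aspiny")
        assert set(p.cm_by_kind.values()) == {1.0}

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            default_passive("hairy")

    def test_fit_to_parameters_spiny_redistribution(self, bs_morph):
        fit = PassiveFitResult(cm_fit=1.75, rm_fit=12000.0, ri_fit=120.0,
                               rms_error=0.01, fit_window=(0.02, 0.17),
                               dendrite_type="spiny")
        pas = passive_parameters_from_fit(fit, bs_morph, e_leak=-75.0)
        assert pas.cm_by_kind["soma"] == 1.0
        assert pas.cm_by_kind["basal"] > 1.75
        assert pas.ri == 120.0
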