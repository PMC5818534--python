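"""Stage-0 passive fitting from brief-pulse responses.

The return to baseline after 0.5 ms, +/-200 pA current pulses is fit
directly with an all-passive model of the cell's morphology by varying
uniform specific membrane capacitance Cm, membrane resistance Rm and axial
resistivity Ri (derivative-free local search).  Fitting the post-pulse decay
rather than the pulse itself keeps pipette artifacts out of the objective.

For spiny cells the fitted Cm is then redistributed: soma and axon are
pinned at 1 uF/cm^2 and the dendritic Cm is raised so total capacitance is
conserved, standing in for unreconstructed spine membrane.  Ri (and Cm) stay
frozen during the later conductance optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .biophys_sim import (NeuronModel, PassiveParameters, SolverOptions,
                          build_model, simulate)
from .ephys_features import detect_spikes
from .io_formats import SweepSet
from .morphology import KINDS, CompartmentalMorphology

DEFAULT_BOUNDS = ((0.3, 4.0), (1e3, 1e5), (30.0, 300.0))   # Cm, Rm, Ri
DEFAULT_X0 = (1.0, 1e4, 100.0)
FIT_WINDOW_S = 0.150


class PassiveFitError(RuntimeError):
    pass


@dataclass
class PassiveFitResult:
    """Fitted uniform passive parameters and fit quality."""

    cm_fit: float          # uF/cm^2
    rm_fit: float          # Ohm cm^2
    ri_fit: float          # Ohm cm
    rms_error: float       # mV over the fit window
    fit_window: tuple      # (start, end) seconds relative to sweep start
    dendrite_type: str     # "spiny" | "aspiny"

    def __post_init__(self):
        if min(self.cm_fit, self.rm_fit, self.ri_fit) <= 0:
            raise ValueError("passive parameters must be positive")
        if self.rms_error < 0:
            raise ValueError("rms_error must be non-negative")


def default_passive(dendrite_type: str, e_leak: float = -75.0,
                    rm: float = 2e4) -> PassiveParameters:
    """Standard passive values used when no pulse data are available:
    Ri = 100 Ohm cm; Cm = 1 uF/cm^2 everywhere, except 2 uF/cm^2 in the
    dendrites of spiny cells."""
    if dendrite_type not in ("spiny", "aspiny"):
        raise ValueError("dendrite_type must be 'spiny' or 'aspiny'")
    cm = {k: 1.0 for k in KINDS}
    if dendrite_type == "spiny":
        cm["basal"] = cm["apical"] = 2.0
    return PassiveParameters(cm_by_kind=cm, ri=100.0,
                             g_leak_by_kind={k: 1.0 / rm for k in KINDS},
                             e_leak=e_leak)


def spiny_cm_adjust(cm_fit: float, areas_by_kind: dict) -> dict:
    """Redistribute a uniform fitted Cm for a spiny cell.

    Soma and axon get 1 uF/cm^2; the dendritic Cm absorbs the remainder so
    that total capacitance ``cm_fit * A_total`` is conserved.  Falls back to
    the standard values (with a warning) if the fitted capacitance cannot
    cover the somatic/axonal share.
    """
    a_sa = areas_by_kind.get("soma", 0.0) + areas_by_kind.get("axon", 0.0)
    a_dend = areas_by_kind.get("basal", 0.0) + areas_by_kind.get("apical", 0.0)
    a_total = a_sa + a_dend
    if a_dend <= 0:
        return {k: cm_fit for k in KINDS}
    cm_dend = (cm_fit * a_total - a_sa) / a_dend
    if cm_dend <= 0:
        warnings.warn("fitted Cm too small to pin soma/axon at 1 uF/cm^2; "
                      "using standard spiny values")
        return {"soma": 1.0, "axon": 1.0, "basal": 2.0, "apical": 2.0}
    return {"soma": 1.0, "axon": 1.0, "basal": cm_dend, "apical": cm_dend}


def passive_parameters_from_fit(fit: PassiveFitResult,
                                morph: CompartmentalMorphology,
                                e_leak: float) -> PassiveParameters:
    """Turn a fit into per-kind parameters (spiny Cm redistribution applied)."""
    if fit.dendrite_type == "spiny":
        cm = spiny_cm_adjust(fit.cm_fit, morph.areas_by_kind)
    else:
        cm = {k: fit.cm_fit for k in KINDS}
    return PassiveParameters(cm_by_kind=cm, ri=fit.ri_fit,
                             g_leak_by_kind={k: 1.0 / fit.rm_fit for k in KINDS},
                             e_leak=e_leak)


def _decay_data(sweeps, window_s: float):
    """Average baseline-subtracted post-pulse decay across pulse sweeps,
    sign-flipping hyperpolarizing responses.  Returns (t_rel, y, pulse_proto)."""
    ups = [s for s in sweeps if s.stimulus.amplitude > 0]
    downs = [s for s in sweeps if s.stimulus.amplitude < 0]
    if not ups or not downs:
        raise PassiveFitError("need at least one depolarizing and one "
                              "hyperpolarizing pulse response")
    proto = ups[0].stimulus
    curves = []
    t_rel = None
    for s in ups + downs:
        st = s.stimulus
        base = s.v[(s.t >= st.onset - 0.02) & (s.t < st.onset)].mean()
        sel = (s.t >= st.end) & (s.t <= st.end + window_s)
        spk = detect_spikes(s)
        if len(spk):
            raise PassiveFitError("spike detected in a passive pulse response")
        y = (s.v[sel] - base) * np.sign(st.amplitude)
        tr = s.t[sel] - st.end
        if t_rel is None:
            t_rel = tr
            curves.append(y)
        else:
            curves.append(np.interp(t_rel, tr, y))
    return t_rel, np.mean(curves, axis=0), proto


def fit_passive(sweeps: SweepSet, morph: CompartmentalMorphology,
                dendrite_type: str = "spiny",
                window_s: float = FIT_WINDOW_S,
                bounds=DEFAULT_BOUNDS, x0=DEFAULT_X0,
                solver: SolverOptions | None = None) -> PassiveFitResult:
    """Fit (Cm, Rm, Ri) to the post-pulse decay of +/-200 pA brief pulses.

    The objective is the RMS difference (mV) between the averaged
    experimental decay and the simulated decay of an all-passive model over
    ``window_s`` after pulse end, minimized by bounded Powell search.
    """
    pulse_sweeps = sweeps.by_kind("brief_step") if isinstance(sweeps, SweepSet) \
        else list(sweeps)
    if not pulse_sweeps:
        raise PassiveFitError("no brief_step sweeps in store")
    t_rel, y_data, proto = _decay_data(pulse_sweeps, window_s)
    solver = solver or SolverOptions(dt_ms=0.02, rec_dt_ms=0.04, settle_ms=20.0)

    def model_decay(cm, rm, ri):
        pas = PassiveParameters(cm_by_kind={k: cm for k in KINDS}, ri=ri,
                                g_leak_by_kind={k: 1.0 / rm for k in KINDS},
                                e_leak=-75.0)
        model = build_model(morph, pas, "A", {})
        sim = simulate(model, proto, solver)
        base = sim.v[(sim.t >= proto.onset - 0.02) & (sim.t < proto.onset)].mean()
        sel = (sim.t >= proto.end) & (sim.t <= proto.end + window_s)
        return np.interp(t_rel, sim.t[sel] - proto.end, sim.v[sel] - base)

    def objective(x):
        resid = model_decay(*x) - y_data
        return float(np.sqrt(np.mean(resid ** 2)))

    res = minimize(objective, x0=np.asarray(x0, dtype=float), method="Powell",
                   bounds=bounds, options={"xtol": 1e-4, "ftol": 1e-8,
                                           "maxiter": 20})
    if not res.success and res.fun > objective(np.asarray(x0, dtype=float)):
        raise PassiveFitError(f"passive fit failed to converge: {res.message}")
    cm, rm, ri = res.x
    return PassiveFitResult(cm_fit=float(cm), rm_fit=float(rm), ri_fit=float(ri),
                            rms_error=float(res.fun),
                            fit_window=(proto.end, proto.end + window_s),
                            dendrite_type=dendrite_type)
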