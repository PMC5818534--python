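"""Conductance-based simulation of compartmental neuron models.

A :class:`NeuronModel` couples a discretized morphology with uniform-per-kind
passive properties, the ten somatic active conductances of set A or B, and a
first-order submembrane Ca2+ shell.  Dendrites and axon carry only leak and
capacitance.  Fixed reversal potentials follow the experimental solutions
(E_Na = +53 mV, E_K = -107 mV, E_h = -45 mV); the Ca2+ reversal is recomputed
from the shell concentration through the Nernst equation at every time step.
Simulations run at 34 C with gate kinetics Q10-scaled from their reference
temperature.

Voltage integrates by a damped Crank-Nicolson (theta) scheme on the
Hines-ordered compartment tree with a fixed step (default 0.025 ms; narrow-
spiking cells use 0.01 ms); gates use exact exponential updates staggered at
half steps.  Convergence is checked by step-size refinement in the test
suite rather than against any external simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import protocols as _protocols
from ._engine import run_kernel
from .channels import CONDUCTANCE_SETS, load_set, q10_factor
from .io_formats import Sweep
from .morphology import CompartmentalMorphology
from .protocols import StimulusProtocol

FARADAY = 96485.332  # C/mol
GAS_R = 8.314462     # J/(mol K)

E_NA = 53.0
E_K = -107.0
TEMPERATURE_C = 34.0


class SimulationError(RuntimeError):
    pass


def nernst(ci: float, co: float, z: int, temperature_c: float) -> float:
    """Nernst reversal potential in mV for concentrations in identical units."""
    if ci <= 0 or co <= 0:
        raise ValueError("concentrations must be positive")
    if z == 0:
        raise ValueError("valence must be nonzero")
    t_k = temperature_c + 273.15
    return 1000.0 * GAS_R * t_k / (z * FARADAY) * math.log(co / ci)


@dataclass
class PassiveParameters:
    """Uniform-per-kind passive membrane properties.

    cm_by_kind : uF/cm^2 per section kind
    ri : axial resistivity, Ohm cm (uniform across the cell)
    g_leak_by_kind : S/cm^2 per section kind
    e_leak : leak reversal, mV (fixed to the measured resting potential)
    """

    cm_by_kind: dict
    ri: float
    g_leak_by_kind: dict
    e_leak: float

    def __post_init__(self):
        if self.ri <= 0:
            raise ValueError("Ri must be positive")
        if any(v <= 0 for v in self.cm_by_kind.values()):
            raise ValueError("Cm must be positive")
        if any(v <= 0 for v in self.g_leak_by_kind.values()):
            raise ValueError("leak conductances must be positive")


@dataclass
class CaDynamicsParams:
    """Submembrane Ca2+ shell: d[Ca]/dt = -I_Ca/(2 F d (1+kappa)) - ([Ca]-rest)/tau."""

    shell_depth_nm: float = 100.0
    tau_removal_ms: float = 80.0
    binding_ratio: float = 20.0
    ca_rest_nM: float = 100.0
    ca_out_mM: float = 2.0

    def __post_init__(self):
        for f in ("shell_depth_nm", "tau_removal_ms", "binding_ratio",
                  "ca_rest_nM", "ca_out_mM"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class SolverOptions:
    dt_ms: float = 0.025
    rec_dt_ms: float = 0.05
    settle_ms: float = 500.0
    settle_dt_ms: float = 0.1
    init_dvdt_tol: float = 1e-3  # mV/ms steady-state criterion
    theta: float = 0.55          # damped Crank-Nicolson; 1.0 = backward Euler


_VGRID = np.arange(-150.0, 100.0 + 1e-9, 0.05)
_EMPTY = np.zeros(1)


def update_calcium(ca_mM: float, i_ca_nA: float, dt_ms: float,
                   params: CaDynamicsParams, soma_area_cm2: float) -> float:
    """Advance the shell Ca2+ concentration one step (closed-form update).

    Inward Ca2+ current (negative by the outward-positive convention) raises
    the concentration; removal relaxes it back to rest with ``tau_removal``.
    The result is floored at 1 nM to protect the Nernst logarithm.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    depth_cm = params.shell_depth_nm * 1e-7
    vol_l = soma_area_cm2 * depth_cm * 1e-3
    cafac = 1e-9 / (2.0 * FARADAY * vol_l * (1.0 + params.binding_ratio))
    carest = params.ca_rest_nM * 1e-6
    ca_inf = carest - i_ca_nA * cafac * params.tau_removal_ms
    ca = ca_inf + (ca_mM - ca_inf) * math.exp(-dt_ms / params.tau_removal_ms)
    return max(ca, 1e-6)


class NeuronModel:
    """Compiled, simulation-ready model; parameters can be swapped in place.

    Built by :func:`build_model`.  ``set_params`` updates the free parameters
    (conductance densities, Ca2+ dynamics, leak densities) without recompiling
    geometry, which is what the optimizer loop relies on.
    """

    def __init__(self, morph: CompartmentalMorphology, passive: PassiveParameters,
                 channel_set: str, densities: dict, ca_params: CaDynamicsParams,
                 temperature_c: float = TEMPERATURE_C):
        if channel_set not in CONDUCTANCE_SETS:
            raise ValueError(f"unknown conductance set {channel_set!r}")
        self.morph = morph
        self.passive = passive
        self.channel_set = channel_set
        self.channels = load_set(channel_set)
        self.ca_params = replace(ca_params)
        self.temperature_c = temperature_c
        self._compile_geometry()
        self._compile_channels()
        self._settled = None
        self.set_params({f"gbar_{c.name}": densities.get(c.name, 0.0)
                         for c in self.channels})

    # ---- geometry ----
    def _compile_geometry(self):
        morph = self.morph
        sections = morph.sections
        if sections[0].nseg != 1:
            sections[0].nseg = 1  # soma is a single iso-potential compartment
        ncomp = sum(s.nseg for s in sections)
        parent = np.full(ncomp, -1, dtype=np.int32)
        area_cm2 = np.zeros(ncomp)
        ga = np.zeros(ncomp)          # uS to parent
        kind_of_comp = []
        first = []
        ri = self.passive.ri          # Ohm cm
        idx = 0
        last_comp_of_sec = []
        for si, sec in enumerate(sections):
            areas, half_rfac = sec.segment_geometry()
            first.append(idx)
            for j in range(sec.nseg):
                area_cm2[idx] = areas[j] * 1e-8
                kind_of_comp.append(sec.kind)
                if j == 0:
                    if si == 0:
                        parent[idx] = -1
                    else:
                        psec = sec.parent
                        if psec == 0:
                            pcomp = first[0]        # attach at soma midpoint
                            rfac = half_rfac[0]
                        else:
                            pcomp = last_comp_of_sec[psec]
                            p_half = _section_halves[psec][-1]
                            rfac = half_rfac[0] + p_half
                        parent[idx] = pcomp
                        ga[idx] = 1.0 / (ri * rfac * 1e-2)  # MOhm -> uS
                else:
                    parent[idx] = idx - 1
                    rfac = half_rfac[2 * j - 1] + half_rfac[2 * j]
                    ga[idx] = 1.0 / (ri * rfac * 1e-2)
                idx += 1
            last_comp_of_sec.append(idx - 1)
            if si == 0:
                _section_halves = [half_rfac]
            else:
                _section_halves.append(half_rfac)
        self.ncomp = ncomp
        self.parent = parent
        self.area_cm2 = area_cm2
        self.ga = ga
        self.kind_of_comp = np.array(kind_of_comp)
        self.first_comp_of_sec = first
        self.last_comp_of_sec = last_comp_of_sec
        cm = np.array([self.passive.cm_by_kind[k] for k in kind_of_comp])
        self.c_nF = cm * area_cm2 * 1e3
        self.gpas = np.array([self.passive.g_leak_by_kind[k] for k in kind_of_comp]) \
            * area_cm2 * 1e6
        self.epas = np.full(ncomp, self.passive.e_leak)
        self.soma_area_cm2 = float(area_cm2[0])

    # ---- channels ----
    def _compile_channels(self):
        chans = self.channels
        nchan = len(chans)
        vg_state, vg_chan, vg_power = [], [], []
        infs, taus = [], []
        chan_e = np.zeros(nchan)
        chan_carev = np.zeros(nchan, dtype=np.int8)
        chan_cacur = np.zeros(nchan, dtype=np.int8)
        chan_sk = np.zeros(nchan, dtype=np.int8)
        sk_state = np.zeros(nchan, dtype=np.int32)
        sk_cahalf = np.ones(nchan)
        sk_hill = np.ones(nchan)
        sk_tau = np.ones(nchan)
        state = 0
        for ci, ch in enumerate(chans):
            if ch.ion == "ca":
                chan_carev[ci] = 1
                chan_cacur[ci] = 1
            else:
                chan_e[ci] = ch.erev
            gate_infs, gate_taus = ch.tables(_VGRID, self.temperature_c)
            for g, gi, gt in zip(ch.gates, gate_infs, gate_taus):
                vg_state.append(state)
                vg_chan.append(ci)
                vg_power.append(int(g["power"]))
                infs.append(gi)
                taus.append(gt)
                state += 1
            if ch.ca_gate is not None:
                chan_sk[ci] = 1
                sk_state[ci] = state
                sk_cahalf[ci] = ch.ca_gate["ca_half"]
                sk_hill[ci] = ch.ca_gate["hill"]
                qt = q10_factor(self.temperature_c, ch.t_ref, ch.q10)
                sk_tau[ci] = max(ch.ca_gate.get("tau", 1.0) / qt, 1e-3)
                state += 1
        self.nstate = state
        self.vg_state = np.array(vg_state, dtype=np.int32)
        self.vg_chan = np.array(vg_chan, dtype=np.int32)
        self.vg_power = np.array(vg_power, dtype=np.int32)
        self.vg_inf = np.array(infs) if infs else np.zeros((0, _VGRID.size))
        self.vg_tau = np.array(taus) if taus else np.zeros((0, _VGRID.size))
        self.chan_e = chan_e
        self.chan_carev = chan_carev
        self.chan_cacur = chan_cacur
        self.chan_sk = chan_sk
        self.sk_state = sk_state
        self.sk_cahalf = sk_cahalf
        self.sk_hill = sk_hill
        self.sk_tau = sk_tau
        self.chan_g = np.zeros(nchan)
        self.eca_fac = 1000.0 * GAS_R * (self.temperature_c + 273.15) / (2 * FARADAY)
        self._update_ca_factors()
        self.gate_lo = np.ones(max(state, 1))
        self.gate_hi = np.zeros(max(state, 1))

    def _update_ca_factors(self):
        p = self.ca_params
        depth_cm = p.shell_depth_nm * 1e-7
        vol_l = self.soma_area_cm2 * depth_cm * 1e-3
        self.cafac = 1e-9 / (2.0 * FARADAY * vol_l * (1.0 + p.binding_ratio))
        self.catau = p.tau_removal_ms
        self.carest = p.ca_rest_nM * 1e-6
        self.ca_ext = p.ca_out_mM

    # ---- parameters ----
    def free_parameter_names(self) -> list:
        names = [f"gbar_{c.name}" for c in self.channels]
        names += ["tau_removal", "binding_ratio"]
        names += [f"g_pas_{k}" for k in self.morph.leak_kinds()]
        return names

    def set_params(self, params: dict) -> None:
        """Update free parameters in place (densities in S/cm^2, tau in ms)."""
        chan_index = {c.name: i for i, c in enumerate(self.channels)}
        for name, value in params.items():
            if name.startswith("gbar_"):
                cname = name[5:]
                if cname not in chan_index:
                    raise KeyError(f"unknown conductance {name!r} for set {self.channel_set}")
                if value < 0:
                    raise ValueError(f"{name} must be non-negative")
                self.chan_g[chan_index[cname]] = value * self.soma_area_cm2 * 1e6
            elif name == "tau_removal":
                self.ca_params.tau_removal_ms = float(value)
                self._update_ca_factors()
            elif name == "binding_ratio":
                self.ca_params.binding_ratio = float(value)
                self._update_ca_factors()
            elif name.startswith("g_pas_"):
                kind = name[6:]
                mask = self.kind_of_comp == kind
                if not mask.any():
                    raise KeyError(f"no {kind} compartments for {name!r}")
                self.gpas[mask] = value * self.area_cm2[mask] * 1e6
            else:
                raise KeyError(f"unknown parameter {name!r}")
        self._settled = None

    def get_params(self) -> dict:
        out = {}
        for i, c in enumerate(self.channels):
            out[f"gbar_{c.name}"] = self.chan_g[i] / (self.soma_area_cm2 * 1e6)
        out["tau_removal"] = self.ca_params.tau_removal_ms
        out["binding_ratio"] = self.ca_params.binding_ratio
        for k in self.morph.leak_kinds():
            i = int(np.argmax(self.kind_of_comp == k))
            out[f"g_pas_{k}"] = self.gpas[i] / (self.area_cm2[i] * 1e6)
        return out

    # ---- state ----
    def init_state(self, v0: float | None = None):
        v = np.full(self.ncomp, self.passive.e_leak if v0 is None else v0)
        gates = np.zeros(self.nstate)
        if self.nstate:
            pos = (v[0] - _VGRID[0]) / 0.05
            j = int(np.clip(pos, 0, _VGRID.size - 2))
            w = pos - j
            for g in range(self.vg_state.size):
                gates[self.vg_state[g]] = (self.vg_inf[g, j] * (1 - w)
                                           + self.vg_inf[g, j + 1] * w)
            ca = self.carest
            for k in range(len(self.channels)):
                if self.chan_sk[k]:
                    gates[self.sk_state[k]] = 1.0 / (1.0 + (self.sk_cahalf[k] / ca)
                                                     ** self.sk_hill[k])
        return v, gates, self.carest

    def _run(self, v, gates, ca, istim_nA, dt_ms, rec_every,
             clamp=False, vcmd=None, per_chan=False, theta=0.5):
        nstep = istim_nA.size
        nrec = (nstep + rec_every - 1) // rec_every
        vout = np.empty(nrec)
        iclamp = np.empty(nrec if clamp else 1)
        ichan = np.empty((len(self.channels), nrec) if per_chan else (1, 1))
        dv_last = np.zeros(1)
        ca = run_kernel(v, gates, ca, nstep, dt_ms,
                        self.parent, self.c_nF, self.gpas, self.epas, self.ga,
                        istim_nA, 0,
                        self.vg_state, self.vg_chan, self.vg_power,
                        self.vg_inf, self.vg_tau, _VGRID[0], 1.0 / 0.05,
                        self.chan_g, self.chan_e, self.chan_carev, self.chan_cacur,
                        self.chan_sk, self.sk_state, self.sk_cahalf, self.sk_hill,
                        self.sk_tau,
                        self.cafac, self.catau, self.carest, self.eca_fac,
                        self.ca_ext, 1e-6,
                        1 if clamp else 0, vcmd if clamp else _EMPTY,
                        1e5,
                        rec_every, vout, iclamp,
                        1 if per_chan else 0, ichan,
                        self.gate_lo, self.gate_hi, dv_last, theta)
        return vout, iclamp, ichan, ca, dv_last[0]

    def settled_state(self, solver: SolverOptions):
        """Steady state at zero injected current (cached until params change)."""
        key = (solver.settle_ms, solver.settle_dt_ms)
        if self._settled is not None and self._settled[0] == key:
            _, v, g, ca = self._settled
            return v.copy(), g.copy(), ca
        v, gates, ca = self.init_state()
        dt = solver.settle_dt_ms
        for attempt in range(2):
            ms = solver.settle_ms * (1 if attempt == 0 else 4)
            nstep = int(round(ms / dt))
            _, _, _, ca, dvdt = self._run(v, gates, ca, np.zeros(nstep), dt,
                                          rec_every=nstep, theta=1.0)
            if dvdt < solver.init_dvdt_tol:
                break
        else:
            raise SimulationError("model failed to reach steady state at rest")
        self._settled = (key, v.copy(), gates.copy(), ca)
        return v.copy(), gates.copy(), ca

    @property
    def resting_potential(self) -> float:
        v, _, _ = self.settled_state(SolverOptions())
        return float(v[0])


def build_model(morph: CompartmentalMorphology, passive: PassiveParameters,
                channel_set: str = "A", densities: dict | None = None,
                ca_params: CaDynamicsParams | None = None,
                temperature_c: float = TEMPERATURE_C) -> NeuronModel:
    """Assemble a simulation-ready model.

    ``densities`` maps channel names (e.g. ``"NaTs"``) to maximal conductance
    densities in S/cm^2; channels absent from the map get zero density, so an
    empty map yields a purely passive model.
    """
    densities = dict(densities or {})
    known = set(CONDUCTANCE_SETS[channel_set]) if channel_set in CONDUCTANCE_SETS else set()
    unknown = set(densities) - known
    if unknown:
        raise ValueError(f"unknown channels for set {channel_set}: {sorted(unknown)}")
    if any(v < 0 for v in densities.values()):
        raise ValueError("densities must be non-negative")
    return NeuronModel(morph, passive, channel_set, densities,
                       ca_params or CaDynamicsParams(), temperature_c)


def simulate(model: NeuronModel, protocol: StimulusProtocol,
             solver: SolverOptions | None = None) -> Sweep:
    """Run a current-clamp protocol from rest and return the somatic sweep.

    The model is first settled to steady state at zero current (the cached
    settled state is reused across protocols until parameters change); the
    output voltage is recorded on a uniform grid of ``rec_dt_ms``.
    """
    solver = solver or SolverOptions()
    v, gates, ca = model.settled_state(solver)
    dt = solver.dt_ms
    i_pA = _protocols.waveform(protocol, dt * 1e-3)
    rec_every = max(1, int(round(solver.rec_dt_ms / dt)))
    vout, _, _, _, _ = model._run(v, gates, ca, i_pA * 1e-3, dt, rec_every,
                                  theta=solver.theta)
    nrec = vout.size
    t = np.arange(nrec) * (dt * rec_every) * 1e-3
    return Sweep(t=t, i_inj=i_pA[::rec_every][:nrec], v=vout,
                 sampling_rate=1.0 / (dt * rec_every * 1e-3), stimulus=protocol)


def voltage_clamp(model: NeuronModel, holding_mV: float, test_levels_mV,
                  duration_ms: float = 50.0, pre_ms: float = 20.0,
                  solver: SolverOptions | None = None) -> dict:
    """Ideal somatic voltage clamp: total and per-channel currents per level.

    Returns ``{level: {"t_ms", "i_total_nA", "i_chan": {name: trace}}}``.
    """
    solver = solver or SolverOptions()
    out = {}
    dt = solver.dt_ms
    rec_every = max(1, int(round(solver.rec_dt_ms / dt)))
    n_pre = int(round(pre_ms / dt))
    n_test = int(round(duration_ms / dt))
    for level in test_levels_mV:
        v, gates, ca = model.init_state(holding_mV)
        # equilibrate at the holding potential under clamp
        nh = int(round(200.0 / dt))
        vcmd = np.full(nh, holding_mV)
        self_v = v
        _, _, _, ca, _ = model._run(self_v, gates, ca, np.zeros(nh), dt,
                                    rec_every=nh, clamp=True, vcmd=vcmd,
                                    theta=1.0)
        vcmd = np.concatenate([np.full(n_pre, holding_mV), np.full(n_test, level)])
        _, iclamp, ichan, _, _ = model._run(self_v, gates, ca,
                                            np.zeros(vcmd.size), dt,
                                            rec_every, clamp=True, vcmd=vcmd,
                                            per_chan=True, theta=solver.theta)
        nrec = iclamp.size
        t = np.arange(nrec) * dt * rec_every
        out[level] = {
            "t_ms": t,
            "i_total_nA": iclamp,
            "i_chan": {c.name: ichan[i].copy() for i, c in enumerate(model.channels)},
        }
    return out
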