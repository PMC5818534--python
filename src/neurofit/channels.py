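"""Somatic ion-channel kinetics.

Channels follow the generic Hodgkin-Huxley form ``g = gbar * m^p * h^q``
with voltage-dependent steady states and time constants.  The kinetic
parameters live in JSON data files under ``channel_data/`` rather than in
code: two conductance repertoires are shipped, set A (the Hay et al. 2011
family used for wide-spiking cells: transient and persistent Na, slow and
transient K, Kv3.1, M-type K, SK, high- and low-voltage-activated Ca, and
h-current) and set B, in which the Na and slow-K components are replaced by
a faster-inactivating Na and two delayed-rectifier/D-type K conductances to
support sub-half-millisecond action potentials.

Rate laws are expressed through a small set of parametric forms (sigmoids,
exponential-linear "trap" rates, Gaussian bumps...).  At model-build time
each gate's steady state and time constant are tabulated on a fine voltage
grid (with the Q10 temperature factor folded into the time constants), so
the simulation kernel only interpolates tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

# canonical conductance repertoires; order defines genome layout
SET_A = ("NaTs", "Nap", "K_P", "K_T", "Kv3_1", "Im", "SK",
         "Ca_HVA", "Ca_LVA", "Ih")
SET_B = ("NaV", "Nap", "Kv2", "Kd", "Kv3_1", "Im", "SK",
         "Ca_HVA", "Ca_LVA", "Ih")
CONDUCTANCE_SETS = {"A": SET_A, "B": SET_B}

TAU_FLOOR = 1e-3  # ms; numerical floor, far below any physiological tau


class ChannelConfigError(ValueError):
    pass


def q10_factor(t_sim: float, t_ref: float, q10: float) -> float:
    """Temperature scaling factor ``q10 ** ((t_sim - t_ref) / 10)``.

    All gate time constants are divided by this factor, i.e. kinetics speed
    up with temperature.
    """
    if q10 <= 0:
        raise ChannelConfigError("q10 must be positive")
    return q10 ** ((t_sim - t_ref) / 10.0)


def _rate(term: dict, v: np.ndarray) -> np.ndarray:
    """Evaluate a parametric rate term (1/ms) on a voltage array."""
    form = term["form"]
    if form == "explinear":
        # a * (v - vh) / (1 - exp(-(v - vh)/k)); limit a*k at v == vh
        a, vh, k = term["a"], term["vh"], term["k"]
        u = v - vh
        with np.errstate(over="ignore"):
            denom = 1.0 - np.exp(-u / k)
        out = np.where(np.abs(u) < 1e-7, a * k, a * u / np.where(denom == 0, 1.0, denom))
        return out
    if form == "exp":
        a, vh, k = term["a"], term["vh"], term["k"]
        return a * np.exp((v - vh) / k)
    if form == "sigmoid":
        a, vh, k = term["a"], term["vh"], term["k"]
        return a / (1.0 + np.exp(-(v - vh) / k))
    raise ChannelConfigError(f"unknown rate form {form!r}")


def _inf_curve(spec: dict, v: np.ndarray) -> np.ndarray:
    form = spec["form"]
    if form == "sigmoid":
        return 1.0 / (1.0 + np.exp(-(v - spec["vhalf"]) / spec["k"]))
    if form == "rates":
        a = _rate(spec["alpha"], v)
        b = _rate(spec["beta"], v)
        return a / (a + b)
    raise ChannelConfigError(f"unknown inf form {form!r}")


def _tau_curve(spec: dict, v: np.ndarray) -> np.ndarray:
    form = spec["form"]
    if form == "constant":
        tau = np.full_like(v, float(spec["value"]))
    elif form == "rates":
        a = _rate(spec["alpha"], v)
        b = _rate(spec["beta"], v)
        tau = spec.get("scale", 1.0) / (a + b)
    elif form == "gauss":
        tau = spec["base"] + spec["amp"] * np.exp(-(((v - spec["vh"]) / spec["k"]) ** 2))
    elif form == "sigmoid":
        tau = spec["base"] + spec["amp"] / (1.0 + np.exp(-(v - spec["vh"]) / spec["k"]))
    elif form == "two_exp":
        lo = spec["base"] + spec["amp_lo"] * np.exp(spec["b_lo"] * v)
        hi = spec["base"] + spec["amp_hi"] * np.exp(spec["b_hi"] * v)
        tau = np.where(v < spec["vsplit"], lo, hi)
    else:
        raise ChannelConfigError(f"unknown tau form {form!r}")
    return np.maximum(tau, TAU_FLOOR)


@dataclass
class ChannelSpec:
    """One somatic conductance: gates, reversal, temperature scaling."""

    name: str
    ion: str                      # "na", "k", "ca", "nonspecific"
    erev: float | None            # mV; None for the Ca ion (dynamic Nernst)
    gates: list = field(default_factory=list)
    ca_gate: dict | None = None   # {"power", "ca_half" (mM), "hill", "tau" (ms)}
    q10: float = 2.3
    t_ref: float = 21.0

    @staticmethod
    def from_dict(d: dict) -> "ChannelSpec":
        erev = d.get("erev")
        spec = ChannelSpec(name=d["name"], ion=d["ion"], erev=erev,
                           gates=d.get("gates", []), ca_gate=d.get("ca_gate"),
                           q10=d.get("q10", 2.3), t_ref=d.get("t_ref", 21.0))
        if spec.ion == "ca" and erev is not None:
            raise ChannelConfigError("Ca channels use the dynamic Nernst reversal")
        if spec.ion != "ca" and erev is None:
            raise ChannelConfigError(f"channel {spec.name} needs a reversal potential")
        return spec

    def tables(self, v_grid: np.ndarray, t_sim: float):
        """(inf, tau) tables per voltage gate, Q10 folded into tau."""
        qt = q10_factor(t_sim, self.t_ref, self.q10)
        infs, taus = [], []
        for g in self.gates:
            inf = _inf_curve(g["inf"], v_grid)
            tau = _tau_curve(g["tau"], v_grid) / qt
            if np.any(inf < -1e-9) or np.any(inf > 1 + 1e-9):
                raise ChannelConfigError(f"gate steady state outside [0,1] in {self.name}")
            infs.append(np.clip(inf, 0.0, 1.0))
            taus.append(np.maximum(tau, TAU_FLOOR))
        return infs, taus


_REGISTRY_CACHE: dict = {}


def load_channel(name: str) -> ChannelSpec:
    """Load a channel description from the packaged data files."""
    if name not in _REGISTRY_CACHE:
        try:
            text = (resources.files("neurofit") / "channel_data" / f"{name}.json").read_text()
        except FileNotFoundError:
            raise ChannelConfigError(f"unknown channel name {name!r}") from None
        _REGISTRY_CACHE[name] = ChannelSpec.from_dict(json.loads(text))
    return _REGISTRY_CACHE[name]


def load_set(set_name: str) -> list:
    """Load the ordered channel list of conductance set "A" or "B"."""
    if set_name not in CONDUCTANCE_SETS:
        raise ChannelConfigError(f"unknown conductance set {set_name!r}")
    return [load_channel(n) for n in CONDUCTANCE_SETS[set_name]]
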