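"""Held-out evaluation: PSTH explained variance, f-I curve, ramp metrics.

Spike-timing reliability on repeated noise is quantified by the explained
variance between Gaussian-smoothed PSTHs,

    EV(P1, P2) = [var(P1) + var(P2) - var(P1 - P2)] / [var(P1) + var(P2)]
               = 2 cov(P1, P2) / [var(P1) + var(P2)],

computed across kernel widths from 0.5 to 20 ms and summarized at 10 ms.
The model's EV against each experimental trial is normalized by the mean
pairwise trial-to-trial EV ("EV ratio").  The f-I curve is sampled at 20 pA
increments of 1 s steps; the slope is a least-squares fit over the
suprathreshold (non-zero rate) portion and the rheobase is the smallest
amplitude with a non-zero rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .biophys_sim import SolverOptions, simulate
from .ephys_features import detect_spikes
from .protocols import StimulusProtocol

EV_DELTA_T_GRID_MS = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
EV_REPORT_DELTA_T_MS = 10.0
PSTH_GRID_DT_MS = 1.0
PSTH_TRUNCATE_SD = 4.0


@dataclass
class PSTH:
    """Gaussian-smoothed spike rate (spikes/s) on a uniform grid."""

    values: np.ndarray
    grid: np.ndarray      # seconds
    delta_t_ms: float

    @property
    def grid_dt(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else 0.0


@dataclass
class FICurve:
    amplitudes: np.ndarray   # pA
    rates: np.ndarray        # Hz
    rheobase: float | None   # pA
    slope: float | None      # Hz/pA


def make_psth(spike_times, delta_t_ms: float, grid: np.ndarray) -> PSTH:
    """Sum of unit-mass Gaussian kernels (SD = delta_t) at the spike times.

    Kernels are truncated at +/-4 SD and renormalized on the grid so every
    spike contributes unit mass regardless of boundary clipping.
    """
    if delta_t_ms <= 0:
        raise ValueError("delta_t must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    values = np.zeros(grid.size)
    if spike_times.size == 0:
        return PSTH(values, grid, delta_t_ms)
    sd = delta_t_ms * 1e-3
    dt = grid[1] - grid[0]
    half = int(np.ceil(PSTH_TRUNCATE_SD * sd / dt))
    for ts in spike_times:
        c = int(round((ts - grid[0]) / dt))
        lo, hi = max(0, c - half), min(grid.size, c + half + 1)
        if lo >= hi:
            continue
        k = np.exp(-0.5 * ((grid[lo:hi] - ts) / sd) ** 2)
        mass = k.sum() * dt
        if mass > 0:
            values[lo:hi] += k / mass
    return PSTH(values, grid, delta_t_ms)


def explained_variance(psth1: PSTH, psth2: PSTH) -> float:
    """Variance-decomposition agreement between two PSTHs; 1 means identical
    up to a constant offset, ~0 means unrelated.  Undefined (ValueError)
    when both PSTHs are constant."""
    if psth1.values.shape != psth2.values.shape or \
            psth1.delta_t_ms != psth2.delta_t_ms:
        raise ValueError("PSTHs must share grid and delta_t")
    v1 = float(np.var(psth1.values))
    v2 = float(np.var(psth2.values))
    if v1 + v2 == 0:
        raise ValueError("explained variance undefined for two constant PSTHs")
    vd = float(np.var(psth1.values - psth2.values))
    return (v1 + v2 - vd) / (v1 + v2)


def ev_ratio(model_spikes, trial_spikes, delta_t_ms: float = EV_REPORT_DELTA_T_MS,
             t_max: float | None = None) -> float:
    """Model-to-data EV normalized by trial-to-trial EV.

    ``trial_spikes`` is a list of >= 2 experimental spike-time arrays; the
    numerator averages EV(model, trial_i) over trials and the denominator
    averages EV(trial_i, trial_j) over all unordered pairs.
    """
    if len(trial_spikes) < 2:
        raise ValueError("need at least 2 experimental repeats")
    if t_max is None:
        cand = [np.max(ts) for ts in list(trial_spikes) + [np.asarray(model_spikes)]
                if np.size(ts)]
        t_max = max(cand) + 0.05 if cand else 1.0
    grid = np.arange(0.0, t_max, PSTH_GRID_DT_MS * 1e-3)
    pm = make_psth(model_spikes, delta_t_ms, grid)
    pts = [make_psth(ts, delta_t_ms, grid) for ts in trial_spikes]
    num = np.mean([explained_variance(pm, p) for p in pts])
    den = np.mean([explained_variance(a, b) for a, b in combinations(pts, 2)])
    if den <= 0:
        raise ValueError("trial-to-trial EV non-positive; ratio undefined")
    return float(num / den)


def ev_curve(model_spikes, trial_spikes, delta_ts=EV_DELTA_T_GRID_MS) -> dict:
    """EV ratio across kernel-width resolutions (0.5-20 ms)."""
    return {dt: ev_ratio(model_spikes, trial_spikes, dt) for dt in delta_ts}


def fi_curve(model, amplitudes_pA, duration: float = 1.0,
             solver: SolverOptions | None = None) -> FICurve:
    """Firing rate vs step amplitude on the 20 pA grid.

    Rheobase is the smallest amplitude with rate > 0; the slope is the
    least-squares slope over the non-zero portion (None if fewer than two
    suprathreshold points).
    """
    solver = solver or SolverOptions()
    amplitudes = np.asarray(sorted(amplitudes_pA), dtype=float)
    rates = np.empty(amplitudes.size)
    for i, amp in enumerate(amplitudes):
        p = StimulusProtocol("long_step", onset=0.1, duration=duration,
                             amplitude=float(amp),
                             total_duration=duration + 0.25)
        sw = simulate(model, p, solver)
        rates[i] = len(detect_spikes(sw, stim_end=p.end)) / duration
    return fi_curve_from_rates(amplitudes, rates)


def fi_curve_from_rates(amplitudes, rates) -> FICurve:
    """Assemble a FICurve (rheobase + suprathreshold least-squares slope)."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    rates = np.asarray(rates, dtype=float)
    nz = rates > 0
    rheo = float(amplitudes[nz][0]) if nz.any() else None
    slope = None
    if nz.sum() >= 2:
        slope = float(np.polyfit(amplitudes[nz], rates[nz], 1)[0])
    return FICurve(amplitudes=amplitudes, rates=rates, rheobase=rheo, slope=slope)


@dataclass
class RampMetrics:
    latency_s: float | None       # from ramp onset to first spike
    first_ap_height_mV: float | None


def ramp_metrics(model, ramp_rate: float = 25.0, max_duration: float = 16.0,
                 post_spike_s: float = 0.25,
                 solver: SolverOptions | None = None) -> RampMetrics:
    """First-spike latency and height on a slow current ramp.

    The ramp grows until a spike occurs (simulation proceeds in 2 s chunks
    and stops ``post_spike_s`` after the first spike, mirroring experiments
    that terminate the ramp after a few action potentials); a model that
    never spikes within ``max_duration`` is flagged with None fields.
    """
    solver = solver or SolverOptions()
    onset = 0.1
    dur = 2.0
    while dur <= max_duration:
        p = StimulusProtocol("ramp", onset=onset, duration=dur,
                             ramp_rate=ramp_rate, total_duration=onset + dur + 0.05)
        sw = simulate(model, p, solver)
        spikes = detect_spikes(sw, stim_end=p.end)
        if len(spikes):
            first = spikes.spike_times[0]
            if first + post_spike_s < onset + dur or dur >= max_duration:
                peak = float(sw.v[spikes.peak_idx[0]])
                return RampMetrics(latency_s=float(first - onset),
                                   first_ap_height_mV=peak)
        dur += 2.0
    return RampMetrics(latency_s=None, first_ap_height_mV=None)
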