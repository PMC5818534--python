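"""Action-potential detection and the 12 training features.

Spikes are detected by a dV/dt threshold crossing (default 20 V/s) confirmed
by a subsequent peak of at least -30 mV.  Per spike, four landmarks are
located: threshold, peak, fast trough (minimum within 5 ms after the peak)
and slow trough (minimum between the fast trough and the next spike, or the
stimulus end for the last spike).

The 12-feature vector used as the optimization target:

==================  =====  ==================================================
avg_rate            Hz     spike count / stimulus duration
ap_peak             mV     peak voltage, averaged over spikes
fast_trough         mV     fast-trough voltage
slow_trough         mV     slow-trough voltage
slow_trough_t_frac  --     slow-trough time as fraction of the ISI
ap_width            ms     width at half-height between fast trough and peak
latency             s      first spike time minus stimulus onset
first_isi           s      first interspike interval
isi_cv              --     SD(ISI)/mean(ISI) (sample SD)
mean_isi            s      mean interspike interval
adaptation_index    --     mean of (ISI[i+1]-ISI[i])/(ISI[i+1]+ISI[i])
baseline_v          mV     mean voltage over the 100 ms before onset
==================  =====  ==================================================

Per-spike quantities are averaged over all spikes in a sweep, then feature
vectors are averaged over repeats; trial-to-trial standard deviations come
from the repeat structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Sweep

FEATURE_NAMES = (
    "avg_rate", "ap_peak", "fast_trough", "slow_trough", "slow_trough_t_frac",
    "ap_width", "latency", "first_isi", "isi_cv", "mean_isi",
    "adaptation_index", "baseline_v",
)

DEFAULT_DVDT_THRESHOLD = 20.0   # V/s
PEAK_CONFIRM_MV = -30.0
FAST_TROUGH_WINDOW_MS = 5.0


@dataclass
class SpikeTrain:
    """Spike times (s) plus per-spike landmark sample indices."""

    spike_times: np.ndarray       # threshold-crossing times, s
    threshold_idx: np.ndarray
    peak_idx: np.ndarray
    fast_trough_idx: np.ndarray
    slow_trough_idx: np.ndarray

    def __len__(self):
        return self.spike_times.size


def detect_spikes(sweep: Sweep, dvdt_threshold: float = DEFAULT_DVDT_THRESHOLD,
                  stim_end: float | None = None) -> SpikeTrain:
    """Detect action potentials on a uniformly sampled somatic trace.

    A spike starts where dV/dt rises through ``dvdt_threshold`` (V/s) and the
    voltage subsequently reaches at least -30 mV before dV/dt turns negative
    for good.  Zero spikes is a valid result.
    """
    v, t = sweep.v, sweep.t
    fs = sweep.sampling_rate
    if fs < 5000:
        raise ValueError("spike detection requires >= 5 kHz sampling")
    dvdt = np.gradient(v) * fs / 1000.0  # mV/s -> V/s
    above = dvdt >= dvdt_threshold
    onsets = np.where(above[1:] & ~above[:-1])[0] + 1
    if stim_end is None and sweep.stimulus is not None:
        stim_end = sweep.stimulus.end
    end_idx = v.size if stim_end is None else min(v.size, int(stim_end * fs) + 1)

    thr_idx, pk_idx = [], []
    last_peak = -1
    for i0 in onsets:
        if i0 <= last_peak:
            continue  # still inside the previous spike
        # candidate peak: maximum before dV/dt returns below 0 persistently
        j = i0
        while j + 1 < v.size and not (dvdt[j] < 0 and v[j] < PEAK_CONFIRM_MV):
            if j - i0 > int(0.02 * fs):   # 20 ms without resolution: give up
                break
            if dvdt[j] < 0 and v[j] > PEAK_CONFIRM_MV:
                break
            j += 1
        seg = v[i0:j + 1]
        if seg.size == 0 or seg.max() < PEAK_CONFIRM_MV:
            continue
        p = i0 + int(np.argmax(seg))
        thr_idx.append(i0)
        pk_idx.append(p)
        last_peak = p
    thr_idx = np.asarray(thr_idx, dtype=int)
    pk_idx = np.asarray(pk_idx, dtype=int)

    ft_idx, st_idx = [], []
    win = int(FAST_TROUGH_WINDOW_MS / 1000.0 * fs)
    for k, p in enumerate(pk_idx):
        hi = min(p + win, v.size - 1)
        ft = p + int(np.argmin(v[p:hi + 1])) if hi > p else p
        nxt = thr_idx[k + 1] if k + 1 < len(thr_idx) else end_idx - 1
        nxt = max(nxt, ft + 1)
        st = ft + int(np.argmin(v[ft:nxt])) if nxt > ft else ft
        ft_idx.append(ft)
        st_idx.append(st)
    return SpikeTrain(spike_times=t[thr_idx] if len(thr_idx) else np.empty(0),
                      threshold_idx=thr_idx, peak_idx=pk_idx,
                      fast_trough_idx=np.asarray(ft_idx, dtype=int),
                      slow_trough_idx=np.asarray(st_idx, dtype=int))


def _interp_crossing(t, v, i, level, rising):
    """Linear-interpolated time where v crosses level between i and i+1."""
    v0, v1 = v[i], v[i + 1]
    if v1 == v0:
        return t[i]
    frac = (level - v0) / (v1 - v0)
    return t[i] + frac * (t[i + 1] - t[i])


def ap_width(sweep: Sweep, peak_i: int, fast_trough_i: int) -> float | None:
    """Spike width (ms) at half height between fast trough and peak.

    Returns None when the trace never recrosses the half-height level before
    the fast trough (feature undefined; excluded from averages).
    """
    v, t = sweep.v, sweep.t
    half = 0.5 * (v[peak_i] + v[fast_trough_i])
    # up-crossing: walk back from the peak
    i = peak_i
    while i > 0 and v[i - 1] >= half:
        i -= 1
    if i == 0:
        return None
    t_up = _interp_crossing(t, v, i - 1, half, rising=True)
    # down-crossing: walk forward from the peak
    j = peak_i
    while j < fast_trough_i and v[j + 1] > half:
        j += 1
    if j >= fast_trough_i:
        return None
    t_dn = _interp_crossing(t, v, j, half, rising=False)
    return (t_dn - t_up) * 1000.0


def adaptation_index(isis) -> float:
    """Mean of (ISI[i+1] - ISI[i]) / (ISI[i+1] + ISI[i]); needs >= 2 ISIs."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        raise ValueError("adaptation index needs at least 2 ISIs")
    a, b = isis[:-1], isis[1:]
    return float(np.mean((b - a) / (b + a)))


def train_features(spikes: SpikeTrain, sweep: Sweep, stimulus=None) -> dict:
    """Compute the 12-feature vector for one sweep.

    Features undefined for the sweep (no spikes, or too few ISIs) are set to
    ``None``; ``avg_rate`` is 0 for a silent sweep and ``baseline_v`` is
    always defined.
    """
    stim = stimulus or sweep.stimulus
    if stim is None:
        raise ValueError("stimulus window required for training features")
    v, t = sweep.v, sweep.t
    fs = sweep.sampling_rate
    out = dict.fromkeys(FEATURE_NAMES)

    pre = (t >= stim.onset - 0.1) & (t < stim.onset)
    out["baseline_v"] = float(v[pre].mean()) if pre.any() else float(v[0])
    n = len(spikes)
    out["avg_rate"] = n / stim.duration
    if n == 0:
        return out

    out["ap_peak"] = float(v[spikes.peak_idx].mean())
    out["fast_trough"] = float(v[spikes.fast_trough_idx].mean())
    out["slow_trough"] = float(v[spikes.slow_trough_idx].mean())
    widths = [w for k in range(n)
              if (w := ap_width(sweep, spikes.peak_idx[k],
                                spikes.fast_trough_idx[k])) is not None]
    out["ap_width"] = float(np.mean(widths)) if widths else None
    out["latency"] = float(spikes.spike_times[0] - stim.onset)

    if n >= 2:
        isis = np.diff(spikes.spike_times)
        out["first_isi"] = float(isis[0])
        out["mean_isi"] = float(isis.mean())
        out["isi_cv"] = float(isis.std(ddof=1) / isis.mean()) if n >= 3 else None
        if n >= 3:
            out["adaptation_index"] = adaptation_index(isis)
        # slow-trough time as a fraction of the ISI, non-final spikes
        fracs = []
        for k in range(n - 1):
            st_t = t[spikes.slow_trough_idx[k]]
            fracs.append((st_t - spikes.spike_times[k]) / isis[k])
        out["slow_trough_t_frac"] = float(np.mean(fracs))
    return out


@dataclass
class FeatureTargets:
    """Per-feature mean, trial-to-trial SD (may be absent), tolerance floor."""

    mean: dict
    sd: dict
    tolerance: dict

    def __post_init__(self):
        for name, tol in self.tolerance.items():
            if tol <= 0:
                raise ValueError(f"tolerance for {name} must be positive")

    def sigma(self, name: str) -> float:
        """Effective SD: max(trial SD, tolerance floor); tolerance alone when
        no repeat SD is available."""
        tol = self.tolerance[name]
        sd = self.sd.get(name)
        return tol if sd is None else max(sd, tol)


def aggregate_targets(feature_vectors, tolerances: dict) -> FeatureTargets:
    """Mean and sample SD per feature across repeats.

    With a single repeat the SD is absent and the tolerance floor alone
    scales the errors.  Features undefined in some repeats are averaged over
    the repeats where they are defined; features undefined everywhere get a
    None mean (and will draw the undefined-feature penalty during fitting).
    """
    if not feature_vectors:
        raise ValueError("need at least one repeat")
    mean, sd = {}, {}
    for name in FEATURE_NAMES:
        vals = [fv[name] for fv in feature_vectors if fv.get(name) is not None]
        if not vals:
            mean[name] = None
            continue
        mean[name] = float(np.mean(vals))
        if len(feature_vectors) > 1 and len(vals) > 1:
            sd[name] = float(np.std(vals, ddof=1))
    return FeatureTargets(mean=mean, sd=sd, tolerance=dict(tolerances))


def sweep_features(sweep: Sweep, dvdt_threshold: float = DEFAULT_DVDT_THRESHOLD) -> dict:
    """Convenience: detect spikes then compute the 12 features."""
    spikes = detect_spikes(sweep, dvdt_threshold)
    return train_features(spikes, sweep)
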