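"""The scalar training error: tolerance-floored absolute z-scores.

Each feature's error is ``|model - experimental mean| / max(SD, tolerance)``
where the SD comes from trial-to-trial variability (when repeats exist) and
the tolerance is a per-feature floor that stops low-variance features from
dominating.  The average of the absolute z-scores over the active stage's
features is the single objective the genetic algorithm minimizes.

Stage 1 targets seven basic features (rate, spike shape, baseline); stage 2
adds the five timing/adaptation features.  During stage 2 each candidate is
additionally simulated at a higher-amplitude step and checked for
depolarization block (failure to repolarize during or after the step); a
blocked candidate draws a large fixed penalty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .ephys_features import (FEATURE_NAMES, FeatureTargets, detect_spikes,
                             train_features)
from .io_formats import Sweep

STAGE1_FEATURES = ("avg_rate", "ap_peak", "fast_trough", "slow_trough",
                   "ap_width", "mean_isi", "baseline_v")
STAGE2_FEATURES = FEATURE_NAMES  # all 12

UNDEFINED_FEATURE_ERROR = 250.0
DEPOL_BLOCK_PENALTY = 250.0

# depolarization-block criterion (configurable)
BLOCK_LEVEL_MV = -30.0
BLOCK_WINDOW_MS = 50.0
BLOCK_RECOVERY_MS = 100.0
BLOCK_RECOVERY_MARGIN_MV = 10.0


def default_tolerances() -> dict:
    """Repository-default tolerance floors per feature."""
    text = (resources.files("neurofit") / "config_data" /
            "feature_tolerances.json").read_text()
    return json.loads(text)


def stage_features(stage: int):
    """Feature names entering the error at the given stage (1 -> 7, 2 -> 12)."""
    if stage == 1:
        return STAGE1_FEATURES
    if stage == 2:
        return STAGE2_FEATURES
    raise ValueError("stage must be 1 or 2")


def feature_error(model_value, mean, sd, tolerance,
                  cap: float = UNDEFINED_FEATURE_ERROR) -> float:
    """Absolute z-score with tolerance floor.

    An undefined model value (None; e.g. no spikes fired) or an undefined
    target draws the fixed cap error.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if model_value is None or mean is None:
        return cap
    sigma = tolerance if sd is None else max(sd, tolerance)
    return abs(model_value - mean) / sigma


@dataclass
class ErrorReport:
    """Per-feature absolute z-scores plus the averaged training error."""

    per_feature_abs_z: dict
    average_error: float
    depol_block: bool = False
    penalty_applied: float = 0.0

    def __post_init__(self):
        feats = list(self.per_feature_abs_z.values())
        expect = float(np.mean(feats)) + self.penalty_applied
        if abs(expect - self.average_error) > 1e-9 * max(1.0, abs(expect)):
            raise ValueError("average_error inconsistent with per-feature errors")


def detect_depol_block(sweep: Sweep, stimulus=None) -> bool:
    """Failure to repolarize during or after a current step.

    True if, inside the stimulus window, the voltage stays above -30 mV for
    a continuous stretch longer than 50 ms without any spike-threshold
    crossing, or if the voltage has not returned to within 10 mV of baseline
    within 100 ms after stimulus end.
    """
    stim = stimulus or sweep.stimulus
    if stim is None:
        raise ValueError("stimulus window required")
    v, t = sweep.v, sweep.t
    fs = sweep.sampling_rate
    spikes = detect_spikes(sweep, stim_end=stim.end)
    in_stim = (t >= stim.onset) & (t <= stim.end)
    # longest run above the level uninterrupted by a spike threshold crossing
    window = int(BLOCK_WINDOW_MS / 1000.0 * fs)
    ok = (v > BLOCK_LEVEL_MV) & in_stim
    ok[spikes.threshold_idx] = False
    if ok.any() and window > 0:
        breaks = np.where(~ok)[0]
        edges = np.concatenate(([-1], breaks, [ok.size]))
        if int(np.max(np.diff(edges))) - 1 > window:
            return True
    base = v[(t >= stim.onset - 0.1) & (t < stim.onset)]
    baseline = float(base.mean()) if base.size else float(v[0])
    after = (t >= stim.end + BLOCK_RECOVERY_MS / 1000.0)
    if after.any():
        i_rec = int(np.argmax(after))
        if v[i_rec] > baseline + BLOCK_RECOVERY_MARGIN_MV:
            return True
    return False


def error_report(model_features: dict, targets: FeatureTargets, stage: int,
                 depol_block: bool = False,
                 cap: float = UNDEFINED_FEATURE_ERROR,
                 penalty: float = DEPOL_BLOCK_PENALTY) -> ErrorReport:
    """Assemble per-feature absolute z-scores into the scalar training error."""
    feats = stage_features(stage)
    z = {}
    for name in feats:
        z[name] = feature_error(model_features.get(name), targets.mean.get(name),
                                targets.sd.get(name), targets.tolerance[name],
                                cap=cap)
    applied = penalty if (depol_block and stage == 2) else 0.0
    avg = float(np.mean(list(z.values()))) + applied
    return ErrorReport(per_feature_abs_z=z, average_error=avg,
                       depol_block=bool(depol_block and stage == 2),
                       penalty_applied=applied)


def training_error(simulate_fn, training_protocol, block_protocol,
                   stage: int, targets: FeatureTargets,
                   cap: float = UNDEFINED_FEATURE_ERROR,
                   penalty: float = DEPOL_BLOCK_PENALTY) -> ErrorReport:
    """Evaluate one candidate model.

    ``simulate_fn(protocol) -> Sweep`` runs the candidate.  The training
    step is always simulated and scored; the depolarization-block check step
    is simulated only in stage 2 (where the penalty applies).  A simulation
    failure yields the maximal error so the optimizer bookkeeping survives.
    """
    try:
        sweep = simulate_fn(training_protocol)
        spikes = detect_spikes(sweep, stim_end=training_protocol.end)
        feats = train_features(spikes, sweep, training_protocol)
    except Exception:
        z = {name: cap for name in stage_features(stage)}
        return ErrorReport(per_feature_abs_z=z, average_error=cap)
    block = False
    if stage == 2 and block_protocol is not None:
        try:
            bsweep = simulate_fn(block_protocol)
            block = detect_depol_block(bsweep, block_protocol)
        except Exception:
            block = True
    return error_report(feats, targets, stage, depol_block=block,
                        cap=cap, penalty=penalty)
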