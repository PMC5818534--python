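"""Miniature staged fit: recover conductance densities from features.

Runs the full two-stage genetic algorithm at toy scale (population 16,
8+8 generations, one seed) against targets measured from a synthetic
regular-spiking cell.  At production scale (population 64+, 50+50
generations, several seeds) the same call recovers the cell's features to
within fractions of a standard deviation; this demo just shows the moving
parts in under two minutes.
"""

from neurofit import (CellData, FitConfig, GASettings, StimulusProtocol,
                      aggregate_targets, staged_fit, sweep_features)
from neurofit.objective import default_tolerances
from neurofit.synthetic_data import generate_protocol, make_cell, training_sweeps

cell = make_cell("regular_spiking", seed=1)
sweeps = generate_protocol(cell)
reps = training_sweeps(sweeps)
targets = aggregate_targets([sweep_features(s) for s in reps],
                            default_tolerances())
proto = reps[0].stimulus
print(f"training step: {proto.amplitude:.0f} pA x {proto.duration:.1f} s, "
      f"{len(reps)} repeats; target rate {targets.mean['avg_rate']:.1f} Hz")

cd = CellData(morph=cell.morphology, passive=cell.passive, targets=targets,
              training_protocol=proto,
              block_protocol=StimulusProtocol(
                  "long_step", onset=proto.onset, duration=proto.duration,
                  amplitude=round(proto.amplitude * 1.2),
                  total_duration=proto.total_duration),
              ca_params=cell.ca_params)
cfg = FitConfig(conductance_set="A",
                ga=GASettings(population_size=16, generations=8, seeds=(1,)))
outcome = staged_fit(cd, cfg, polish_maxfev=60)
print(f"\naverage training error (mean |z| over 12 features): "
      f"{outcome.average_training_error:.2f}  ({outcome.accepted})")
worst = max(outcome.per_feature_errors, key=outcome.per_feature_errors.get)
print(f"worst feature: {worst} "
      f"(|z| = {outcome.per_feature_errors[worst]:.2f})")
print("\nAn error below 1 means the model matches the cell to within one "
      "trial-to-trial standard deviation on a typical feature.")
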