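"""Simulate a ground-truth cell and extract its training features.

Builds the regular-spiking synthetic cell (ten somatic conductances on a
ball-and-stick morphology), injects a 1 s current step, and prints the
twelve electrophysiological features that the optimizer would train on.
"""

from neurofit import StimulusProtocol, simulate, sweep_features
from neurofit.synthetic_data import make_cell

cell = make_cell("regular_spiking", seed=1)
model = cell.build()
print(f"cell: {cell.name} (conductance set {cell.conductance_set}, "
      f"{model.ncomp} compartments, rest {model.resting_potential:.1f} mV)")

proto = StimulusProtocol("long_step", onset=0.1, duration=1.0, amplitude=100.0,
                         total_duration=1.35)
sweep = simulate(model, proto)
features = sweep_features(sweep)
print(f"\n100 pA step, 1 s:")
for name, value in features.items():
    print(f"  {name:>20s}: {value:.4g}" if value is not None
          else f"  {name:>20s}: undefined")
print("\nRates are Hz, voltages mV, widths ms, times s; these twelve numbers "
      "are what the genetic algorithm matches against experimental targets.")
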