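"""Held-out evaluation of a model: f-I curve, ramp response, spike timing.

Uses the fast-spiking ground-truth cell as the "model" and its own noisy
pink-noise repeats as the "experiment", so the explained-variance ratio
shows what a perfect fit looks like.
"""

import numpy as np

from neurofit import detect_spikes, ev_ratio, fi_curve, ramp_metrics, simulate
from neurofit.synthetic_data import (find_rheobase, generate_protocol,
                                     make_cell)

cell = make_cell("regular_spiking", seed=1)
model = cell.build()

rheo = find_rheobase(model)
fi = fi_curve(model, np.arange(rheo - 40, rheo + 101, 20.0))
print(f"f-I curve: rheobase {fi.rheobase:.0f} pA, "
      f"slope {fi.slope:.3f} Hz/pA over the suprathreshold points")

ramp = ramp_metrics(model, ramp_rate=25.0)
print(f"25 pA/s ramp: first spike after {ramp.latency_s:.2f} s "
      f"(i.e. at {25 * ramp.latency_s:.0f} pA), height {ramp.first_ap_height_mV:.1f} mV")

sweeps = generate_protocol(cell)
noise_sweeps = sweeps.by_kind("pink_noise")
trials = [detect_spikes(s, stim_end=s.stimulus.end).spike_times
          for s in noise_sweeps]
model_spikes = detect_spikes(simulate(model, noise_sweeps[0].stimulus),
                             stim_end=noise_sweeps[0].stimulus.end).spike_times
r = ev_ratio(model_spikes, trials, delta_t_ms=10.0)
print(f"explained-variance ratio (10 ms window): {r:.3f}")
print("\nA ratio near 1 means the model predicts single-trial spike timing "
      "as well as one experimental repeat predicts another.")
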