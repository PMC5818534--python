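# neurofit

Automated generation of biophysically detailed single-neuron models from
patch-clamp recordings.

Building a conductance-based model of one recorded neuron by hand takes
weeks of expert tuning; building hundreds, as systematic cell-type surveys
require, demands an automated pipeline.  `neurofit` implements such a
pipeline end to end for somatic whole-cell data: it reads an SWC dendritic
morphology and a battery of current-clamp sweeps, fits the passive cable
properties, optimizes the densities of ten somatic voltage- and
calcium-gated conductances with a staged genetic algorithm, guards the
result against depolarization block, and evaluates how the optimized model
generalizes to stimuli it was never trained on.  A synthetic-data module
generates ground-truth cells and noisy "recordings" of them, so the whole
workflow is testable without access to any experimental database.

It is aimed at computational neuroscientists who want per-cell models (for
example, to populate network simulations with measured cell-type
diversity) and at methodologists studying feature-based model optimization
itself.

## The method in brief

**Model.**  A compartmental cable model with the soma converted to an
equal-area cylinder (L = D), reconstructed axons replaced by a 60 × 1 um
initial segment, and passive dendrites.  Ten active conductances sit at
the soma — Na (transient + persistent), four K currents, Ca-activated K,
high- and low-threshold Ca, and I_h — in two alternative kinetic
repertoires: set A for wide spikes, set B (faster Na inactivation, two
replacement K currents) for the sub-0.5 ms spikes of fast-spiking
interneurons.  Intracellular Ca²⁺ follows a 100 nm submembrane shell,
d[Ca]/dt = −I_Ca/(2·F·d·(1+κ)) − ([Ca]−[Ca]₀)/τ, with E_Ca from the Nernst
equation at every step.  E_Na = +53 mV, E_K = −107 mV, T = 34 °C, kinetics
Q10-scaled (2.3).

**Stage 0 — passive fit.**  Uniform (C_m, R_m, R_i) are fit by bounded
derivative-free search to the voltage decay after 0.5 ms ±200 pA pulses;
for spiny cells the fitted C_m is redistributed so soma/axon sit at
1 uF/cm² and dendrites absorb the spine membrane, conserving total
capacitance.  R_i and C_m are then frozen.

**Stages 1–2 — evolutionary fit.**  The genome is 15–16 parameters (10
conductance densities, 2 Ca parameters, 3–4 leak densities).  A candidate
is scored by the mean absolute z-score of 12 spike-train features (rate,
AP peak, troughs, width, latency, ISI statistics, adaptation, baseline)
against the experimental mean, with per-feature tolerance floors
σ_eff = max(SD, tolerance).  Stage 1 fits 7 basic features from several
seeded random populations; stage 2 continues from the best stage-1
population on all 12 features, adding a heavy penalty for candidates that
fail to repolarize on a higher-amplitude check step.  Survivors are
screened for block on the pink-noise stimulus, and the winner gets a short
bounded local refinement.  Cells are routed to set A or B (or both) by
their measured spike width; fits with average error ≤ 2 are accepted,
2–3 flagged for review, > 3 rejected.

**Evaluation.**  f–I curves on a 20 pA grid (rheobase, suprathreshold
slope), slow ramp responses (25 pA/s), spike-timing reliability on
repeated pink noise via the explained variance between Gaussian-smoothed
PSTHs, EV = 2·cov/(var₁+var₂), normalized by the trial-to-trial EV; and a
cell-class audit that asks a linear SVM (with recursive feature
elimination and 5-fold cross-validation) to predict class labels from
features or from the fitted parameters.

See `docs/methods.md` for assumptions, numerical choices, and limitations.

## Worked example

```bash
python examples/simulate_cell.py
```

```
cell: regular_spiking (conductance set A, 19 compartments, rest -77.0 mV)

100 pA step, 1 s:
              avg_rate: 35
               ap_peak: 37.42
           fast_trough: -77.44
           slow_trough: -79.39
    slow_trough_t_frac: 0.2494
              ap_width: 1.142
               latency: 0.00925
             first_isi: 0.0263
                isi_cv: 0.02135
              mean_isi: 0.02881
      adaptation_index: 0.001323
            baseline_v: -77.03
```

The cell fires 35 spikes in the 1 s step (35 Hz), peaks at +37 mV,
repolarizes to a −77 mV fast trough, and has a 1.14 ms-wide action
potential — a typical wide-spiking, weakly adapting regular-spiking
profile.  These twelve numbers are exactly what the optimizer matches: a
fitted model is "good" when each lands within about one trial-to-trial
standard deviation of the recorded cell's values.

Other examples: `passive_fit_demo.py` (recovers C_m, R_m, R_i from pulse
decays to machine precision), `optimize_demo.py` (a toy-scale staged GA
fit), `evaluate_generalization.py` (f–I, ramp, and spike-timing EV), and
`classify_cells.py` (class prediction from features of a synthetic cell
bank).  The `neurofit` command-line tool wraps the same library calls
(`neurofit synth`, `fit-passive`, `optimize`, `features`, `morph-summary`,
`validate`).

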