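# Methods

`neurofit` generates biophysically detailed single-neuron models from
current-clamp data: it fits passive cable properties directly from brief
pulse responses, then optimizes somatic conductance densities with a staged
genetic algorithm against feature-based targets, guards against
depolarization block, and evaluates the result on held-out stimuli.  This
note records the model, the numerical choices, and the reasoning behind the
design decisions that were genuinely open.

## The biophysical model

Each cell is a compartmental cable model built from an SWC reconstruction
(or a parametric ball-and-stick).  The spherical soma is converted to a
cylinder with L = D = 2r, which preserves membrane area exactly
(pi·D·L = 4·pi·r²).  Reconstructed axons are discarded and replaced by a
synthetic initial segment (60 um long, 1 um diameter) attached to the soma,
because reconstruction completeness varies too much for the axon to carry
meaningful information.  Dendrites are represented as chains of frusta so
tapering neurites keep their reconstructed membrane area; sections are
discretized into an odd number of segments no longer than 20 um by default
(the refinement contract below justifies the rule).

Active conductances live only at the soma; dendrites and the axon stub are
passive.  Two somatic repertoires are shipped, each with ten conductances:

* **Set A** (wide-spiking cells): transient and persistent Na (NaTs, Nap),
  slow and transient K (K_P, K_T), Kv3.1, M-type K (Im), Ca-activated K
  (SK), high- and low-voltage-activated Ca (Ca_HVA, Ca_LVA), and the
  h-current (Ih).  Kinetics follow the Hay et al. (2011) channel family.
* **Set B** (narrow-spiking cells): the Na and the slow-K components are
  replaced — a faster-inactivating Na (NaV) and two delayed-rectifier /
  D-type K conductances (Kv2, Kd) — so that sub-0.5 ms action potentials
  are attainable.  Replacing rather than adding channels keeps the genome
  at ten conductance densities for both sets.

All gate kinetics are data, not code: each channel is a JSON file under
`neurofit/channel_data/` describing m^p·h^q gates through a small algebra
of parametric forms (sigmoids, exponential-linear "trap" rates, Gaussian
and sigmoidal time-constant profiles).  The shipped parameters are
literature-style defaults, tuned only for qualitative plausibility (set B
reaches narrower minimum spike widths than set A, a property asserted in
the tests); they are not fits to any particular published channel.

Fixed reversal potentials follow the experimental solutions:
E_Na = +53 mV, E_K = −107 mV, E_h = −45 mV.  The leak reversal is pinned to
the measured resting potential.  Simulations run at 34 °C; every gate time
constant is divided by q10^((34 − T_ref)/10) with Q10 = 2.3 and a
per-channel reference temperature (21 °C by default).

Intracellular Ca²⁺ follows a first-order submembrane-shell ODE
(depth 100 nm):

    d[Ca]/dt = −I_Ca / (2·F·d·(1 + kappa)) − ([Ca] − [Ca]_rest) / tau

with resting [Ca] = 100 nM, external Ca 2 mM, buffering ratio kappa and
removal time constant tau as free parameters.  The Ca reversal is
recomputed each step from the Nernst equation; [Ca] is floored at 1 nM
purely to protect the logarithm (negligible against the 100 nM rest).
A single removal term absorbs any separate pump contribution — the two are
not separately identifiable from somatic recordings.

## Numerics

The cable equation is integrated by the method of lines on the
Hines-ordered compartment tree with a fixed step (numba-compiled kernel).
Voltage advances by a theta-method solve (theta = 0.55: Crank–Nicolson
with mild damping); gates advance by exact exponential relaxation toward
their voltage-frozen steady states, staggered at half steps, with steady
states and time constants interpolated from tables on a 0.05 mV grid.  The
Ca ODE uses its closed-form per-step solution with the Ca current evaluated
at the midpoint voltage.  Rationale for theta = 0.55: plain Crank–Nicolson
rings on the sub-millisecond Na transient of fast-spiking cells at the
default step, while backward Euler's first-order phase error accumulates to
visible spike-time drift over one-second trains; the slightly damped scheme
removes the ringing at a negligible accuracy cost.

Default steps: dt = 0.025 ms with 20 kHz output for wide-spiking cells,
dt = 0.01 ms for narrow-spiking cells (chosen where spike width changes by
well under the 0.1 ms feature tolerance upon further refinement).  Because
this engine is its own implementation rather than a wrapper around an
established simulator, correctness is defined by convergence contracts
rather than bit-compatibility with any external code: halving dt changes no
spike count and shifts spike times by < 0.2 ms; tripling the spatial
subdivision changes a somatic step response by < 1 % RMS.  Both contracts
are asserted in the test suite.

Before every protocol the model is settled at zero current (implicit
Euler, coarse step) until |dV/dt| < 10⁻³ mV/ms everywhere; the settled
state is cached until parameters change.  Voltage clamp is ideal (series
conductance 10⁵ uS), appropriate because clamp is used here to
characterize model currents, not to reproduce recording artifacts.

## Passive fitting

Uniform Cm, Rm, Ri are fit by bounded Powell search (initial guess 1
uF/cm², 10 kOhm·cm², 100 Ohm·cm; bounds 0.3–4, 1k–100k, 30–300) minimizing
the RMS mismatch of the voltage decay for 150 ms after 0.5 ms ±200 pA
pulses; depolarizing and sign-flipped hyperpolarizing responses are
averaged.  Fitting only the post-pulse decay keeps pipette artifacts out of
the objective; the 150 ms window covers several membrane time constants
while staying inside the sweep.  For spiny cells the fitted Cm is
redistributed — soma and axon pinned at 1 uF/cm², dendritic Cm raised to
conserve total capacitance — standing in for unreconstructed spine
membrane.  When no pulse data exist the standard values are used (Ri 100
Ohm·cm; Cm 1 uF/cm² everywhere, 2 uF/cm² in spiny dendrites).  Ri and Cm
are frozen during conductance optimization; the leak densities remain free.

## Features and the objective

Twelve features summarize a training sweep: average rate, AP peak, fast and
slow trough depths, slow-trough time (as ISI fraction), width at
half-height (trough-to-peak), latency, first ISI, ISI coefficient of
variation, mean ISI, adaptation index, and baseline voltage.  Spikes are
detected at a 20 V/s dV/dt crossing confirmed by a −30 mV peak (the
convention is configurable; the detection criterion is not part of any
published specification of the workflow this package implements).  The
fast trough is the minimum within 5 ms of the peak; the slow trough is
bounded by the next spike or the stimulus end.  Per-spike features are
averaged over all spikes, then over repeats, with sample (n−1) standard
deviations measuring trial-to-trial variability.

The error of a candidate model on a feature is the absolute z-score
|model − mean| / max(SD, tolerance); the tolerance floor (a per-feature
config table, e.g. 2 mV for AP peak, 0.1 ms for width, 1 Hz for rate)
prevents features with freakishly low measured variance from dominating,
and substitutes for the SD when only one trial exists.  The single
training objective is the mean absolute z-score over the active feature
set.  Features the model leaves undefined (e.g. no spikes) draw a fixed
error of 250 — large enough to dominate any realistic error (accepted
models average below 3) without numerical overflow.

## Staged optimization

The genome holds 15 or 16 free parameters: ten conductance densities, the
two Ca parameters, and one leak density per section kind (3, or 4 when
apical dendrites exist).  Stage 1 fits seven basic features (rate, spike
shape, baseline); stage 2 fits all twelve.  Each stage runs once per seed;
the final population containing the best stage-1 organism becomes the
starting population of every stage-2 run, and the best stage-2 organism
overall wins.

GA operators (all config fields): log-uniform initialization within
bounds; tournament selection of size 2; blend (BLX-0.5) crossover in log
space with probability 0.5; per-parameter Gaussian mutation in log space
with probability 0.15; clipping to bounds; single-organism elitism (the
best error per generation is therefore non-increasing, which the tests
assert).  The default mutation scale is 0.3 decades: at desk-scale
populations the stage-1 survivors are nearly homogeneous, and smaller
mutations could not re-diversify the population enough for stage 2 to fix
the timing features it newly introduces (latency, first ISI); large log-
space jumps let stage 2 relocate between basins.  Default bounds per
parameter span two to four decades around physiological values
(`config_data/parameter_bounds.json`).

The winning genome receives a short bounded Nelder–Mead refinement in log
space (200 evaluations).  The evolutionary search is good at locating
basins and poor at settling their last fraction of a z-score; the local
step is deterministic and respects the same objective, bounds, and
depolarization-block screens.

**Depolarization block.**  During stage 2 every candidate with a training
error below 10 is additionally simulated at a higher-amplitude step
(1.2x the training amplitude by default, matching the largest stimulus the
cell itself received) and checked for failure to repolarize: voltage above
−30 mV for a continuous spike-free 50 ms during the stimulus, or voltage
still more than 10 mV above baseline 100 ms after stimulus end (all three
numbers configurable; the criterion is qualitative in origin).  Blocked
candidates draw a fixed 250 penalty.  The error-below-10 gate only skips
candidates the penalty could never re-rank, saving roughly a third of the
stage-2 simulation time.  After optimization the surviving candidates are
screened once more on the pink-noise stimulus, worst-first discarding any
that block there.

**Conductance-set routing.**  Cells with measured spike width < 0.5 ms are
fit with set B only, > 1 ms with set A only, and intermediate cells with
both (the lower-error fit is kept).  A fitted cell is accepted when its
average training error is at most 2, flagged for review between 2 and 3,
and rejected above 3.

## Synthetic ground truth

The synthetic-data module makes the whole pipeline testable without any
external recordings.  A `SyntheticCell` couples a known genome with a
ball-and-stick morphology (soma r = 6 um; basal dendrite 300 x 2 um;
synthetic axon) and a recording-noise model.  `generate_protocol` simulates
the full experimental battery: 0.5 ms ±200 pA pulses (2 repeats per sign),
1 s steps at 20 pA increments spanning rheobase ±100 pA, the training
step (the lowest step evoking ≥ 5 spikes) three further times, a
block-check step at 1.2x the training amplitude, a 25 pA/s ramp, and four
repeats of a frozen pink-noise injection (1/f power between 1 and 100 Hz,
mean 0.9x the training amplitude, CV 0.35 — the stimulus statistics are a
repository choice).  Additive Gaussian recording noise (SD 0.2 mV,
low-passed at 10 kHz) makes repeats differ, so feature targets carry
realistic trial-to-trial SDs.  Ground-truth cells that themselves block
anywhere on the battery are rejected as invalid fixtures.

Three archetypes are shipped: a wide-spiking regular-spiking cell (set A;
width ≈ 1.1 ms, rheobase ≈ 50 pA), a narrow-spiking fast-spiking cell
(set B; width ≈ 0.25 ms, rheobase ≈ 220 pA, steep f–I), and a weak-slow-K
"block-prone" variant whose targets attract depolarization-block-prone
fits — the fixture for exercising the stage-2 penalty.  Cell banks sample
genomes log-normally around an archetype (SD 0.08 decades, clipped to the
optimizer bounds) to create labelled classes with internal variability.

What the generator does **not** emulate: electrode/series-resistance
artifacts, liquid-junction offsets, slow drift, channel noise, dendritic
active conductances, and real morphological diversity.  Passing tests
therefore demonstrate that the pipeline recovers models under its own
biophysical assumptions, not that those assumptions capture any particular
real neuron.

## Generalization metrics

Spike-timing reliability on repeated noise uses the explained variance
between Gaussian-smoothed PSTHs,

    EV(P1, P2) = [var(P1) + var(P2) − var(P1 − P2)] / [var(P1) + var(P2)],

i.e. 2·cov/(var+var).  PSTHs live on a 1 ms grid with kernels truncated at
±4 SD and renormalized to unit mass per spike.  The model-vs-trial EV
(averaged over trials) is divided by the mean pairwise trial-to-trial EV
over all unordered pairs; the ratio is computed for kernel widths 0.5–20 ms
and reported at 10 ms.  The f–I curve uses 1 s steps at 20 pA increments;
rheobase is the smallest amplitude with a non-zero rate and the slope is a
least-squares fit over the non-zero portion.  Ramp responses (25 pA/s) are
simulated in chunks and stopped shortly after the first spike, mirroring
experiments that terminate ramps early; latency is measured from ramp
onset (absolute, not threshold-relative — a documented choice).

## Classification audit

Class labels are predicted from one of four predictor sources
(experimental features, model features, model parameters, model parameters
plus morphology) with a linear-kernel maximum-margin classifier, class
weights inverse to class frequency, recursive feature elimination with
cross-validated selection (step 1), and stratified five-fold evaluation;
the confusion matrix is row-normalized.  Predictors are standardized
first — margin methods are not scale-invariant and the predictors mix
units.  The three morphology predictors are total capacitance (sum of
area x Cm), the soma-to-dendrite capacitance ratio, and the mean
steady-state attenuation at dendritic tips with the soma clamped 10 mV
above rest (computed by a direct linear solve of the passive system; on a
finite cable this reproduces the cosh-based analytic solution, which the
tests assert to 2 %).

## Scales used in the automated checks

Production use of pipelines like this one runs on cluster scale — on the
order of 1200 organisms for 500 generations per stage with five seeds per
cell; population-scale statements (error statistics over hundreds of
cells, classification accuracies on real transgenic classes) require that
scale plus real recordings and are not targeted here.  The automated
checks instead verify
property-level behaviour at desk scale, as their own experiment design:
end-to-end parameter recovery uses population 64, 50 + 50 generations and
two seeds (about twelve minutes on one core); the block-penalty experiment
uses population 32, 20 + 20 generations, one seed, restricted
K-conductance bounds (so that feature-matching genomes sit near the block
boundary) and the pink-noise screen disabled, isolating the step-penalty
mechanism; full-scale settings
remain one config field away.  Determinism of the staged fit under a fixed
seed list is asserted at reduced scale (population 8), where it is the same
code path; repeating the twelve-minute run verbatim would double the suite
time for no additional coverage.

## Known limitations

* Somatic-only active conductances: spike initiation lacks the axonal
  "kink", and dendritic integration is linear by construction.
* Fixed-step integration: no event detection; accuracy is by refinement
  contract, not adaptive error control.
* The channel kinetics are representative defaults, not cell-type fits;
  only qualitative claims (e.g. set B reaches narrower spikes) should be
  read into them.
* Latency near rheobase is intrinsically ill-conditioned (the membrane
  crawls across threshold), which is the hard case for desk-scale recovery;
  the large-mutation default and the local polish exist mostly for it.
* The classifier audit on synthetic banks bounds what classification can
  show: synthetic classes are cleanly separable by construction.
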