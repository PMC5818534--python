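"""Ground-truth cells and synthetic "experimental" recordings.

Every pipeline stage is testable without any external data: a
:class:`SyntheticCell` couples a known conductance genome with a morphology
and a recording-noise model, and :func:`generate_protocol` simulates the
full experimental battery from it -- brief +/-200 pA passive pulses, 1 s
current steps on a 20 pA grid spanning rheobase, a repeated training-
amplitude step, a higher-amplitude depolarization-block check step, a
25 pA/s ramp, and repeated pink-noise injections -- with additive filtered
Gaussian recording noise providing trial-to-trial feature variability.

Three archetypes are shipped: a wide-spiking "regular-spiking" cell built
on conductance set A, a narrow-spiking "fast-spiking" cell built on set B,
and a weak-slow-K "block_prone" variant used by the depolarization-block-
penalty experiment.  Cell banks sample genomes log-normally around the
archetype means, which gives class structure for the classification audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .biophys_sim import (CaDynamicsParams, PassiveParameters, SolverOptions,
                          build_model, simulate)
from .ephys_features import detect_spikes
from .ga_optimize import CellData, Genome, default_parameter_bounds
from .io_formats import Sweep, SweepSet
from .morphology import CompartmentalMorphology, discretize, make_ball_and_stick
from .objective import detect_depol_block
from .protocols import StimulusProtocol, pink_noise_wave

RECORDING_NOISE_SD_MV = 0.2
NOISE_LOWPASS_HZ = 10000.0

# ground-truth archetype densities (S/cm^2) and Ca parameters; chosen to
# give a wide-spiking (~1.1 ms) adapting cell and a narrow-spiking
# (~0.2 ms) high-rheobase cell, both inside the optimizer's default bounds
ARCHETYPES = {
    "regular_spiking": {
        "conductance_set": "A",
        "densities": {"NaTs": 0.8, "Nap": 5e-5, "K_P": 0.08, "K_T": 0.002,
                      "Kv3_1": 0.005, "Im": 1.5e-4, "SK": 4e-4,
                      "Ca_HVA": 1.5e-5, "Ca_LVA": 1e-4, "Ih": 3e-5},
        "tau_removal": 80.0, "binding_ratio": 20.0,
        "g_pas": 1.0 / 12000.0, "e_leak": -77.0, "solver_dt_ms": 0.025,
    },
    "fast_spiking": {
        "conductance_set": "B",
        "densities": {"NaV": 1.8, "Nap": 1e-5, "Kv2": 0.1, "Kd": 2e-4,
                      "Kv3_1": 0.6, "Im": 5e-5, "SK": 1e-4,
                      "Ca_HVA": 1e-5, "Ca_LVA": 5e-5, "Ih": 1e-5},
        "tau_removal": 50.0, "binding_ratio": 20.0,
        "g_pas": 1.0 / 10000.0, "e_leak": -77.0, "solver_dt_ms": 0.01,
    },
    # weak slow-K variant that fires normally on its own battery but whose
    # feature targets attract depolarization-block-prone fits; the fixture
    # for exercising the stage-2 block penalty
    "block_prone": {
        "conductance_set": "A",
        "densities": {"NaTs": 0.6, "Nap": 5e-5, "K_P": 0.05, "K_T": 0.02,
                      "Kv3_1": 0.1, "Im": 2e-4, "SK": 3e-4,
                      "Ca_HVA": 1e-5, "Ca_LVA": 1e-4, "Ih": 2e-5},
        "tau_removal": 80.0, "binding_ratio": 20.0,
        "g_pas": 1.0 / 12000.0, "e_leak": -77.0, "solver_dt_ms": 0.025,
    },
}


@dataclass
class SyntheticCell:
    """A ground-truth model cell plus its recording-noise settings."""

    name: str
    class_label: str
    conductance_set: str
    genome: Genome
    passive: PassiveParameters
    morphology: CompartmentalMorphology
    ca_params: CaDynamicsParams
    noise_sd_mv: float = RECORDING_NOISE_SD_MV
    rng_seed: int = 0
    # narrow-spiking cells need a finer step to resolve their spike shape
    solver: SolverOptions = field(default_factory=SolverOptions)

    def build(self, densities_override: dict | None = None):
        params = self.genome.as_dict()
        dens = {n[5:]: v for n, v in params.items() if n.startswith("gbar_")}
        model = build_model(self.morphology, self.passive, self.conductance_set,
                            dens, replace(self.ca_params))
        extra = {k: v for k, v in params.items() if not k.startswith("gbar_")}
        model.set_params(extra)
        if densities_override:
            model.set_params(densities_override)
        return model


def _default_morphology() -> CompartmentalMorphology:
    m = make_ball_and_stick(soma_radius=6.0, dend_length=300.0, dend_diam=2.0)
    return discretize(m)


def make_cell(archetype: str = "regular_spiking", name: str | None = None,
              seed: int = 0, noise_sd_mv: float = RECORDING_NOISE_SD_MV,
              density_scale: dict | None = None) -> SyntheticCell:
    """Construct a ground-truth cell from a named archetype.

    ``density_scale`` multiplies individual archetype densities (used by
    :func:`make_cell_bank` to create within-class variability); results are
    clipped to the optimizer bounds so the genome stays recoverable.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    spec = ARCHETYPES[archetype]
    morph = _default_morphology()
    pas = PassiveParameters(
        cm_by_kind={k: 1.0 for k in ("soma", "axon", "basal", "apical")},
        ri=120.0,
        g_leak_by_kind={k: spec["g_pas"] for k in ("soma", "axon", "basal", "apical")},
        e_leak=spec["e_leak"])
    bounds_map = default_parameter_bounds(spec["conductance_set"],
                                          morph.leak_kinds())
    names = tuple(bounds_map.keys())
    bounds = np.array([bounds_map[n] for n in names])
    vals = []
    for n in names:
        if n.startswith("gbar_"):
            v = spec["densities"][n[5:]]
            if density_scale and n[5:] in density_scale:
                v *= density_scale[n[5:]]
        elif n == "tau_removal":
            v = spec["tau_removal"]
        elif n == "binding_ratio":
            v = spec["binding_ratio"]
        else:
            v = spec["g_pas"]
        vals.append(v)
    vals = np.clip(np.array(vals), bounds[:, 0], bounds[:, 1])
    genome = Genome(names, vals, bounds)
    return SyntheticCell(name=name or archetype, class_label=archetype,
                         conductance_set=spec["conductance_set"], genome=genome,
                         passive=pas, morphology=morph,
                         ca_params=CaDynamicsParams(
                             tau_removal_ms=spec["tau_removal"],
                             binding_ratio=spec["binding_ratio"]),
                         noise_sd_mv=noise_sd_mv, rng_seed=seed,
                         solver=SolverOptions(dt_ms=spec["solver_dt_ms"]))


def pink_noise_stimulus(duration: float, mean_amp: float, cv: float,
                        seed: int, dt: float = 5e-5) -> np.ndarray:
    """Band-limited 1/f current noise (pA); see :func:`protocols.pink_noise_wave`."""
    return pink_noise_wave(duration, mean_amp, cv, seed, dt)


def _add_noise(sweep: Sweep, sd_mv: float, rng: np.random.Generator) -> Sweep:
    """Additive Gaussian recording noise, low-passed at 10 kHz."""
    if sd_mv <= 0:
        return sweep
    noise = rng.normal(0.0, sd_mv, size=sweep.v.size)
    nyq = sweep.sampling_rate / 2.0
    if NOISE_LOWPASS_HZ < nyq:
        sos = butter(4, NOISE_LOWPASS_HZ / nyq, output="sos")
        noise = sosfiltfilt(sos, noise)
        noise *= sd_mv / max(noise.std(), 1e-12)
    return Sweep(sweep.t, sweep.i_inj, sweep.v + noise,
                 sampling_rate=sweep.sampling_rate, stimulus=sweep.stimulus,
                 repeat_index=sweep.repeat_index)


def find_rheobase(model, lo_pA: float = 0.0, hi_pA: float = 600.0,
                  step_pA: float = 20.0, duration: float = 1.0,
                  solver: SolverOptions | None = None) -> float | None:
    """Smallest step amplitude on the 20 pA grid that evokes >= 1 spike."""
    solver = solver or SolverOptions()
    for amp in np.arange(lo_pA + step_pA, hi_pA + step_pA / 2, step_pA):
        p = StimulusProtocol("long_step", onset=0.1, duration=duration,
                             amplitude=float(amp), total_duration=duration + 0.25)
        sw = simulate(model, p, solver)
        if len(detect_spikes(sw, stim_end=p.end)):
            return float(amp)
    return None


class ProtocolGenerationError(RuntimeError):
    pass


def generate_protocol(cell: SyntheticCell, n_training_repeats: int = 3,
                      n_noise_repeats: int = 4,
                      min_training_spikes: int = 5,
                      block_amp_factor: float = 1.2,
                      solver: SolverOptions | None = None) -> SweepSet:
    """Simulate the full experimental battery for a ground-truth cell.

    The training amplitude is the lowest 20 pA step evoking at least
    ``min_training_spikes`` spikes; the block-check step is 1.2x that.  The
    ground-truth model must not itself show depolarization block anywhere in
    the battery, otherwise the fixture is invalid and generation fails.
    """
    solver = solver or cell.solver
    model = cell.build()
    rng = np.random.default_rng(cell.rng_seed)
    out = SweepSet()

    def emit(proto, repeat=0):
        sw = simulate(model, proto, solver)
        sw.repeat_index = repeat
        return _add_noise(sw, cell.noise_sd_mv, rng)

    # passive pulses (2 repeats each sign)
    for amp in (200.0, -200.0):
        for rep in range(2):
            out.add(emit(StimulusProtocol("brief_step", onset=0.02,
                                          duration=5e-4, amplitude=amp,
                                          total_duration=0.2), rep))

    rheo = find_rheobase(model, solver=solver)
    if rheo is None:
        raise ProtocolGenerationError("ground-truth cell never spikes on the grid")

    # f-I steps: rheobase -100 .. +100 pA at 20 pA increments
    training_amp = None
    for amp in np.arange(max(20.0, rheo - 100.0), rheo + 100.0 + 1.0, 20.0):
        p = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                             amplitude=float(amp), total_duration=1.35)
        sw = emit(p)
        out.add(sw)
        n = len(detect_spikes(sw, stim_end=p.end))
        if detect_depol_block(sw, p):
            raise ProtocolGenerationError(
                f"ground-truth cell blocks at {amp} pA: invalid fixture")
        if training_amp is None and n >= min_training_spikes:
            training_amp = float(amp)
    if training_amp is None:
        raise ProtocolGenerationError("no step evoked enough training spikes")

    # training repeats
    train_proto = StimulusProtocol("long_step", onset=0.1, duration=1.0,
                                   amplitude=training_amp, total_duration=1.35)
    for rep in range(n_training_repeats):
        out.add(emit(train_proto, rep))

    # block-check step
    block_proto = StimulusProtocol(
        "long_step", onset=0.1, duration=1.0,
        amplitude=round(training_amp * block_amp_factor), total_duration=1.35)
    bsweep = emit(block_proto)
    if detect_depol_block(bsweep, block_proto):
        raise ProtocolGenerationError("ground-truth cell blocks on the check step")
    out.add(bsweep)

    # slow ramp, terminated shortly after the first spikes
    ramp_dur = min(max(rheo / 25.0 * 1.5, 2.0), 16.0)
    out.add(emit(StimulusProtocol("ramp", onset=0.1, duration=ramp_dur,
                                  ramp_rate=25.0,
                                  total_duration=ramp_dur + 0.35)))

    # pink noise repeats (frozen noise: same seed across repeats)
    for rep in range(n_noise_repeats):
        noise_proto = StimulusProtocol(
            "pink_noise", onset=0.1, duration=2.0, amplitude=training_amp * 0.9,
            noise_cv=0.35, noise_seed=1000 + cell.rng_seed,
            total_duration=2.35)
        sw = emit(noise_proto, rep)
        if detect_depol_block(sw, noise_proto):
            raise ProtocolGenerationError("ground-truth cell blocks on noise")
        out.add(sw)
    return out


def training_sweeps(sweeps: SweepSet) -> list:
    """The repeated training-amplitude step sweeps (>= 2 repeats)."""
    groups = [g for g in sweeps.groups.values()
              if len(g) >= 2 and g[0].stimulus is not None
              and g[0].stimulus.kind == "long_step"]
    if not groups:
        raise ValueError("no repeated training step in store")
    return max(groups, key=len)


def make_cell_bank(n_per_class: int, class_archetypes=("regular_spiking",
                                                       "fast_spiking"),
                   seed: int = 0, dispersion_decades: float = 0.08) -> list:
    """Sample a labelled bank of ground-truth cells around the archetypes.

    Genomes vary log-normally (SD ``dispersion_decades`` decades) around the
    archetype densities, clipped to the optimizer bounds, so classes are
    distinct but internally variable.
    """
    rng = np.random.default_rng(seed)
    bank = []
    for arch in class_archetypes:
        dens_names = list(ARCHETYPES[arch]["densities"].keys())
        for i in range(n_per_class):
            scale = {n: 10 ** rng.normal(0.0, dispersion_decades)
                     for n in dens_names}
            cell = make_cell(arch, name=f"{arch}_{i:02d}",
                             seed=int(rng.integers(0, 2**31 - 1)),
                             density_scale=scale)
            bank.append(cell)
    return bank


def make_block_penalty_fixture(seed: int = 3):
    """The engineered depolarization-block-penalty experiment.

    Returns ``(cell, cell_data, fit_config)``: a block-prone ground-truth
    cell (validated non-blocking on its own battery), its feature targets,
    and a fit configuration whose restricted K-conductance bounds and fixed
    GA seed make the best *unpenalized* stage-2 candidate fail to
    repolarize at 1.2x the training amplitude.  Fitting the same fixture
    with the stage-2 penalty enabled selects a non-blocking model at a
    comparable training error, which is the property the experiment
    demonstrates.  The pink-noise screen is left out so the step-penalty
    mechanism is isolated.
    """
    from .ephys_features import aggregate_targets, sweep_features
    from .io_formats import FitConfig, GASettings
    from .objective import default_tolerances

    cell = make_cell("block_prone", seed=seed)
    sweeps = generate_protocol(cell)
    reps = training_sweeps(sweeps)
    targets = aggregate_targets([sweep_features(s) for s in reps],
                                default_tolerances())
    proto = reps[0].stimulus
    block_proto = StimulusProtocol(
        "long_step", onset=proto.onset, duration=proto.duration,
        amplitude=round(proto.amplitude * 1.2),
        total_duration=proto.total_duration)
    cd = CellData(morph=cell.morphology, passive=cell.passive, targets=targets,
                  training_protocol=proto, block_protocol=block_proto,
                  noise_protocol=None, ca_params=cell.ca_params)
    bounds = default_parameter_bounds("A", cell.morphology.leak_kinds())
    bounds.update({
        "gbar_K_P": (5e-3, 0.08),
        "gbar_Kv3_1": (1e-4, 0.15),
        "gbar_SK": (1e-5, 5e-4),
        "gbar_Im": (1e-6, 5e-4),
        "gbar_K_T": (1e-4, 0.05),
    })
    cfg = FitConfig(conductance_set="A", parameter_bounds=bounds,
                    ga=GASettings(population_size=32, generations=20,
                                  seeds=(1236,)))
    return cell, cd, cfg
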