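"""Staged evolutionary optimization of somatic conductance densities.

The genome is the vector of 15 or 16 free parameters (10 maximal
conductance densities, the two Ca2+-shell parameters, and 3-4 per-kind leak
densities).  Populations are initialized log-uniformly within bounds and
evolve by tournament selection (size 2), blend crossover in log space,
per-parameter Gaussian mutation in log space (sigma 0.1 decade), clipping
to bounds, and single-organism elitism, so the best error per generation is
non-increasing and a fixed seed reproduces a run exactly.

Fitting runs in two stages: stage 1 matches the seven basic features over
several independently seeded runs; the final population containing the
best stage-1 organism seeds every stage-2 run, which matches all 12
features and applies the depolarization-block penalty on a high-amplitude
check step.  After stage 2, candidates are screened for block on the pink
noise stimulus (best non-blocking candidate wins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .biophys_sim import (CaDynamicsParams, NeuronModel, PassiveParameters,
                          SolverOptions, build_model, simulate)
from .channels import CONDUCTANCE_SETS
from .ephys_features import FeatureTargets, detect_spikes, sweep_features
from .io_formats import FitConfig, GASettings
from .morphology import CompartmentalMorphology
from .objective import DEPOL_BLOCK_PENALTY, detect_depol_block, training_error
from .protocols import StimulusProtocol

# block check is skipped for candidates whose training error already exceeds
# this (the penalty only has to re-rank low-error candidates); config field
BLOCK_CHECK_MAX_ERROR = 10.0


class GAConfigError(ValueError):
    pass


@dataclass
class Genome:
    """Named, bounded parameter vector."""

    names: tuple
    values: np.ndarray
    bounds: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.values.shape != (len(self.names),):
            raise GAConfigError("genome length mismatch")
        if np.any(self.values < self.bounds[:, 0] - 1e-12) or \
           np.any(self.values > self.bounds[:, 1] + 1e-12):
            raise GAConfigError("genome outside bounds")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def default_parameter_bounds(channel_set: str, leak_kinds) -> dict:
    """Shipped per-parameter (lo, hi) bounds in S/cm^2 / ms / dimensionless."""
    text = (resources.files("neurofit") / "config_data" /
            "parameter_bounds.json").read_text()
    table = json.loads(text)
    names = [f"gbar_{c}" for c in CONDUCTANCE_SETS[channel_set]]
    names += ["tau_removal", "binding_ratio"]
    names += [f"g_pas_{k}" for k in leak_kinds]
    out = {}
    for n in names:
        key = n if n in table else ("g_pas" if n.startswith("g_pas_") else None)
        if key is None or key not in table:
            raise GAConfigError(f"no default bounds for parameter {n!r}")
        out[n] = tuple(table[key])
    return out


def init_population(bounds: np.ndarray, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Log-uniform sample within bounds; shape (size, nparam)."""
    if size < 2:
        raise GAConfigError("population size must be >= 2")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(lo <= 0):
        raise GAConfigError("log-uniform sampling needs positive lower bounds")
    u = rng.random((size, lo.size))
    return 10 ** (np.log10(lo) + u * (np.log10(hi) - np.log10(lo)))


def evolve(population: np.ndarray, errors: np.ndarray, bounds: np.ndarray,
           settings: GASettings, rng: np.random.Generator) -> np.ndarray:
    """One generation: tournament-2 selection, log-space blend crossover and
    Gaussian mutation, bound clipping, single-elite preservation."""
    n, npar = population.shape
    log_lo, log_hi = np.log10(bounds[:, 0]), np.log10(bounds[:, 1])
    # selection
    picks = rng.integers(0, n, size=(n, settings.tournament_size))
    winners = picks[np.arange(n), np.argmin(errors[picks], axis=1)]
    parents = population[winners]
    children = np.log10(parents)
    # blend crossover (BLX-0.5 in log space) on consecutive pairs
    for i in range(0, n - 1, 2):
        if rng.random() < settings.crossover_prob:
            a, b = children[i].copy(), children[i + 1].copy()
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            span = hi - lo
            u = rng.random(npar)
            children[i] = lo - 0.5 * span + u * 2.0 * span
            u = rng.random(npar)
            children[i + 1] = lo - 0.5 * span + u * 2.0 * span
    # mutation
    mask = rng.random((n, npar)) < settings.mutation_prob
    children = children + mask * rng.normal(0.0, settings.mutation_sigma_decades,
                                            size=(n, npar))
    children = np.clip(children, log_lo, log_hi)
    out = 10 ** children
    # elitism: best organism survives unchanged
    out[0] = population[int(np.argmin(errors))]
    return out


@dataclass
class GARun:
    """State of one seeded run at one stage."""

    population: np.ndarray
    errors: np.ndarray
    generation: int
    best_error_trajectory: list
    rng_seed: int
    stage: int

    @property
    def best_genome_values(self) -> np.ndarray:
        return self.population[int(np.argmin(self.errors))]

    @property
    def best_error(self) -> float:
        return float(np.min(self.errors))


def run_ga(eval_fn, bounds: np.ndarray, settings: GASettings, seed: int,
           stage: int, start_population: np.ndarray | None = None,
           generations: int | None = None, log_fn=None) -> GARun:
    """Run one seeded GA stage to completion.

    ``eval_fn(values) -> float`` scores a parameter vector (lower is
    better); evaluations are memoized by genome bytes.  The trajectory of
    the best error is non-increasing by elitism.
    """
    rng = np.random.default_rng(seed)
    gens = settings.generations if generations is None else generations
    pop = (init_population(bounds, settings.population_size, rng)
           if start_population is None else start_population.copy())
    cache: dict[bytes, float] = {}

    def score(p):
        out = np.empty(p.shape[0])
        for i, row in enumerate(p):
            key = row.tobytes()
            if key not in cache:
                cache[key] = float(eval_fn(row))
            out[i] = cache[key]
        return out

    errors = score(pop)
    traj = [float(np.min(errors))]
    for gen in range(gens):
        pop = evolve(pop, errors, bounds, settings, rng)
        errors = score(pop)
        traj.append(float(np.min(errors)))
        if log_fn is not None:
            log_fn({"stage": stage, "seed": seed, "generation": gen + 1,
                    "best": traj[-1], "median": float(np.median(errors))})
    return GARun(population=pop, errors=errors, generation=gens,
                 best_error_trajectory=traj, rng_seed=seed, stage=stage)


def select_conductance_set(ap_width_ms: float) -> list:
    """Route by experimental spike width: narrow -> B, wide -> A, both between."""
    if ap_width_ms < 0.5:
        return ["B"]
    if ap_width_ms > 1.0:
        return ["A"]
    return ["A", "B"]


def accept_model(error: float) -> str:
    """Acceptance status from the average training error."""
    if error < 0:
        raise ValueError("error must be non-negative")
    if error > 3.0:
        return "rejected"
    if error > 2.0:
        return "flagged_for_review"
    return "accepted"


@dataclass
class CellData:
    """Everything staged fitting needs about one cell."""

    morph: CompartmentalMorphology
    passive: PassiveParameters
    targets: FeatureTargets
    training_protocol: StimulusProtocol
    block_protocol: StimulusProtocol | None = None
    noise_protocol: StimulusProtocol | None = None
    ca_params: CaDynamicsParams = field(default_factory=CaDynamicsParams)


@dataclass
class FitOutcome:
    """Result of a staged fit for one cell and one conductance set."""

    best_genome: Genome
    average_training_error: float
    per_feature_errors: dict
    conductance_set: str
    accepted: str
    stage_runs: list = field(default_factory=list)
    noise_block_discards: int = 0


class _Evaluator:
    """Genome -> training error, reusing one compiled model."""

    def __init__(self, cell: CellData, conductance_set: str, names,
                 solver: SolverOptions):
        self.cell = cell
        self.names = names
        self.solver = solver
        self.model = build_model(cell.morph, cell.passive, conductance_set,
                                 {}, replace(cell.ca_params))
        self.block_checks = 0

    def simulate_fn(self, protocol):
        return simulate(self.model, protocol, self.solver)

    def set_values(self, values):
        self.model.set_params(dict(zip(self.names, values)))

    def __call__(self, values, stage, apply_block=True):
        self.set_values(values)
        block_proto = (self.cell.block_protocol
                       if stage == 2 and apply_block else None)
        return training_error(self.simulate_fn, self.cell.training_protocol,
                              block_proto, stage, self.cell.targets)

    def error_fn(self, stage, apply_block=True):
        def fn(values):
            self.set_values(values)
            # score the training step first; only low-error candidates get
            # the (costly) block-check simulation
            report = training_error(self.simulate_fn,
                                    self.cell.training_protocol, None,
                                    1 if stage == 1 else 2, self.cell.targets)
            err = report.average_error
            if (stage == 2 and apply_block and self.cell.block_protocol is not None
                    and err < BLOCK_CHECK_MAX_ERROR):
                self.block_checks += 1
                try:
                    bsweep = self.simulate_fn(self.cell.block_protocol)
                    if detect_depol_block(bsweep, self.cell.block_protocol):
                        err += DEPOL_BLOCK_PENALTY
                except Exception:
                    err += DEPOL_BLOCK_PENALTY
            return err
        return fn


def _polish(error_fn, values, bounds, maxfev: int = 200) -> np.ndarray:
    """Bounded Nelder-Mead refinement of a genome in log space.

    The evolutionary search locates the basin; this deterministic local
    step settles the last fraction of a z-score that the population-level
    operators resolve slowly once the population has converged.
    """
    from scipy.optimize import minimize

    log_lo, log_hi = np.log10(bounds[:, 0]), np.log10(bounds[:, 1])

    def f(logv):
        vals = 10 ** np.clip(logv, log_lo, log_hi)
        return error_fn(vals)

    res = minimize(f, np.log10(values), method="Nelder-Mead",
                   options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-4})
    out = 10 ** np.clip(res.x, log_lo, log_hi)
    return out if error_fn(out) <= error_fn(values) else values


def staged_fit(cell: CellData, config: FitConfig,
               solver: SolverOptions | None = None,
               block_penalty_enabled: bool = True,
               polish_maxfev: int = 200,
               log_fn=None) -> FitOutcome:
    """Two-stage, multi-seed fit of one cell with one conductance set.

    Stage 1 (7 features) runs once per seed from independent log-uniform
    populations; the final population holding the lowest-error organism
    seeds each stage-2 run (12 features + block penalty).  The best stage-2
    organism wins, subject to the post-hoc pink-noise block screen, which
    discards blocking candidates in error order; the winner then receives a
    short bounded local refinement (set ``polish_maxfev=0`` to disable).
    """
    solver = solver or SolverOptions()
    bounds_map = dict(config.parameter_bounds) or default_parameter_bounds(
        config.conductance_set, cell.morph.leak_kinds())
    names = tuple(bounds_map.keys())
    bounds = np.array([bounds_map[n] for n in names], dtype=float)
    ev = _Evaluator(cell, config.conductance_set, names, solver)

    stage1_runs = [run_ga(ev.error_fn(1), bounds, config.ga, seed, stage=1,
                          log_fn=log_fn)
                   for seed in config.ga.seeds]
    best1 = min(stage1_runs, key=lambda r: r.best_error)

    stage2_runs = [run_ga(ev.error_fn(2, apply_block=block_penalty_enabled),
                          bounds, config.ga, seed, stage=2,
                          start_population=best1.population, log_fn=log_fn)
                   for seed in config.ga.seeds]

    # pool stage-2 candidates, best first, deduplicated
    pool = []
    seen = set()
    for r in stage2_runs:
        for vals, err in zip(r.population, r.errors):
            key = vals.tobytes()
            if key not in seen:
                seen.add(key)
                pool.append((err, vals))
    pool.sort(key=lambda p: p[0])

    discards = 0
    chosen = None
    for err, vals in pool:
        if cell.noise_protocol is not None:
            ev.set_values(vals)
            sweep = ev.simulate_fn(cell.noise_protocol)
            if detect_depol_block(sweep, cell.noise_protocol):
                discards += 1
                continue
        chosen = (err, vals)
        break

    if chosen is None:
        # every candidate blocks on the noise stimulus
        err, vals = pool[0]
        genome = Genome(names, vals, bounds)
        return FitOutcome(best_genome=genome, average_training_error=float(err),
                          per_feature_errors={}, conductance_set=config.conductance_set,
                          accepted="rejected", stage_runs=stage1_runs + stage2_runs,
                          noise_block_discards=discards)

    err, vals = chosen
    if polish_maxfev > 0:
        refined = _polish(ev.error_fn(2, apply_block=block_penalty_enabled),
                          vals, bounds, maxfev=polish_maxfev)
        # the refined genome must still pass the noise screen
        if cell.noise_protocol is not None and not np.array_equal(refined, vals):
            ev.set_values(refined)
            if not detect_depol_block(ev.simulate_fn(cell.noise_protocol),
                                      cell.noise_protocol):
                vals = refined
        else:
            vals = refined
    genome = Genome(names, vals, bounds)
    report = ev(vals, stage=2, apply_block=block_penalty_enabled)
    return FitOutcome(best_genome=genome,
                      average_training_error=report.average_error,
                      per_feature_errors=report.per_feature_abs_z,
                      conductance_set=config.conductance_set,
                      accepted=accept_model(report.average_error),
                      stage_runs=stage1_runs + stage2_runs,
                      noise_block_discards=discards)


def fit_cell(cell: CellData, config: FitConfig, ap_width_ms: float,
             solver: SolverOptions | None = None, log_fn=None) -> FitOutcome:
    """Full routing: choose conductance set(s) by spike width, fit each,
    keep the lower-training-error outcome.

    Narrow-spiking cells get a finer default time step so that their spike
    shape features are resolved."""
    if solver is None:
        solver = SolverOptions(dt_ms=0.01) if ap_width_ms < 0.5 else SolverOptions()
    outcomes = []
    for set_name in select_conductance_set(ap_width_ms):
        cfg = replace(config, conductance_set=set_name,
                      parameter_bounds=config.parameter_bounds if
                      config.conductance_set == set_name else {})
        outcomes.append(staged_fit(cell, cfg, solver, log_fn=log_fn))
    return min(outcomes, key=lambda o: o.average_training_error)
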