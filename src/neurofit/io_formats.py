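"""On-disk formats: SWC morphologies, sweep stores, fit configs, model files.

The native sweep dialect is a small documented HDF5 schema (one group per
sweep with ``t``/``i``/``v`` datasets and protocol attributes); a CSV
directory with a JSON manifest is supported for hand-made fixtures.  All
readers validate and reject structural violations rather than repairing
them, and every format round-trips bit-exactly.

HDF5 sweep schema::

    /sweep_NNN
        t   float64 (s)     i  float64 (pA)     v  float64 (mV)
        attrs: protocol (JSON string), repeat_index (int),
               sampling_rate (Hz)
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .protocols import StimulusProtocol


class SwcError(ValueError):
    pass


class SweepFormatError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SwcNode:
    """One SWC sample point (id, type, position um, radius um, parent id)."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


def read_swc(path) -> list:
    """Parse a whitespace-delimited 7-column SWC file.

    Enforces: unique ids, radius > 0, parent declared earlier (or -1).
    Raises :class:`SwcError` naming the offending line.
    """
    nodes = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                tc = int(parts[1])
                x, y, z, r = (float(p) for p in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SwcError(f"line {lineno}: {exc}") from None
            if nid in seen:
                raise SwcError(f"line {lineno}: duplicate node id {nid}")
            if r <= 0:
                raise SwcError(f"line {lineno}: non-positive radius")
            if pid != -1 and pid not in seen:
                raise SwcError(f"line {lineno}: parent {pid} not declared before node {nid}")
            seen.add(nid)
            nodes.append(SwcNode(nid, tc, x, y, z, r, pid))
    return nodes


def write_swc(path, nodes) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in nodes:
            fh.write(f"{n.id} {n.type_code} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                     f"{n.radius:.6g} {n.parent_id}\n")


@dataclass
class Sweep:
    """One recorded or simulated trace: time (s), current (pA), voltage (mV)."""

    t: np.ndarray
    i_inj: np.ndarray
    v: np.ndarray
    sampling_rate: float
    stimulus: StimulusProtocol | None = None
    repeat_index: int = 0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.i_inj = np.asarray(self.i_inj, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (self.t.shape == self.i_inj.shape == self.v.shape):
            raise SweepFormatError("t, i_inj, v must have equal length")
        if self.sampling_rate <= 0:
            raise SweepFormatError("sampling_rate must be positive")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise SweepFormatError("t must be strictly increasing")


class SweepSet:
    """Sweeps grouped by stimulus protocol, repeats ordered by repeat index."""

    def __init__(self, sweeps=()):
        self.groups: dict[str, list] = {}
        for s in sweeps:
            self.add(s)

    def add(self, sweep: Sweep) -> None:
        key = sweep.stimulus.key() if sweep.stimulus is not None else "unlabeled"
        group = self.groups.setdefault(key, [])
        group.append(sweep)
        group.sort(key=lambda s: s.repeat_index)

    def all_sweeps(self) -> list:
        return [s for g in self.groups.values() for s in g]

    def __len__(self) -> int:
        return sum(len(g) for g in self.groups.values())

    def by_kind(self, kind: str) -> list:
        """All sweeps whose stimulus kind matches, e.g. ``"long_step"``."""
        return [s for s in self.all_sweeps()
                if s.stimulus is not None and s.stimulus.kind == kind]


def write_sweeps(path, sweeps: SweepSet) -> None:
    with h5py.File(path, "w") as f:
        for idx, s in enumerate(sweeps.all_sweeps()):
            g = f.create_group(f"sweep_{idx:03d}")
            g.create_dataset("t", data=s.t)
            g.create_dataset("i", data=s.i_inj)
            g.create_dataset("v", data=s.v)
            g.attrs["sampling_rate"] = s.sampling_rate
            g.attrs["repeat_index"] = s.repeat_index
            if s.stimulus is not None:
                g.attrs["protocol"] = json.dumps(s.stimulus.to_dict())


def read_sweeps(path) -> SweepSet:
    """Load a sweep store (HDF5 native dialect, or a CSV fixture directory)."""
    p = Path(path)
    if p.is_dir():
        return _read_sweeps_csv(p)
    out = SweepSet()
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            for ds in ("t", "i", "v"):
                if ds not in g:
                    raise SweepFormatError(f"{name}: missing dataset {ds!r}")
            t, i, v = g["t"][()], g["i"][()], g["v"][()]
            if not (t.shape == i.shape == v.shape):
                raise SweepFormatError(f"{name}: mismatched dataset lengths")
            proto = None
            if "protocol" in g.attrs:
                proto = StimulusProtocol.from_dict(json.loads(g.attrs["protocol"]))
            out.add(Sweep(t, i, v, sampling_rate=float(g.attrs["sampling_rate"]),
                          stimulus=proto, repeat_index=int(g.attrs.get("repeat_index", 0))))
    return out


def _read_sweeps_csv(directory: Path) -> SweepSet:
    manifest = directory / "manifest.json"
    if not manifest.exists():
        raise SweepFormatError("CSV sweep directory needs a manifest.json")
    meta = json.loads(manifest.read_text())
    out = SweepSet()
    for entry in meta["sweeps"]:
        rows = list(csv.reader((directory / entry["file"]).open()))
        header, data = rows[0], rows[1:]
        if header[:3] != ["t", "i", "v"]:
            raise SweepFormatError(f"{entry['file']}: columns must be t,i,v")
        arr = np.array(data, dtype=float)
        proto = StimulusProtocol.from_dict(entry["protocol"]) if "protocol" in entry else None
        out.add(Sweep(arr[:, 0], arr[:, 1], arr[:, 2],
                      sampling_rate=float(entry["sampling_rate"]),
                      stimulus=proto, repeat_index=int(entry.get("repeat_index", 0))))
    return out


@dataclass
class GASettings:
    """Evolutionary-search settings (defaults are the desk-scale profile)."""

    population_size: int = 64
    generations: int = 50
    seeds: tuple = (1234, 1235)
    crossover_prob: float = 0.5
    mutation_prob: float = 0.15
    mutation_sigma_decades: float = 0.30
    tournament_size: int = 2


@dataclass
class FitConfig:
    """Declarative fit style: conductance set, tolerances, GA settings, bounds."""

    conductance_set: str = "A"
    feature_tolerances: dict = field(default_factory=dict)
    ga: GASettings = field(default_factory=GASettings)
    parameter_bounds: dict = field(default_factory=dict)
    stage1_features: tuple = ()
    stage2_features: tuple = ()

    def __post_init__(self):
        if self.conductance_set not in ("A", "B"):
            raise ConfigError("conductance_set must be 'A' or 'B'")
        for name, (lo, hi) in self.parameter_bounds.items():
            if not lo < hi:
                raise ConfigError(f"bounds for {name}: need lo < hi")
        if self.stage1_features and self.stage2_features:
            if not set(self.stage1_features) <= set(self.stage2_features):
                raise ConfigError("stage1_features must be a subset of stage2_features")

    def to_json(self, path) -> None:
        d = {
            "conductance_set": self.conductance_set,
            "feature_tolerances": self.feature_tolerances,
            "ga": self.ga.__dict__ | {"seeds": list(self.ga.seeds)},
            "parameter_bounds": {k: list(v) for k, v in self.parameter_bounds.items()},
            "stage1_features": list(self.stage1_features),
            "stage2_features": list(self.stage2_features),
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @staticmethod
    def from_json(path) -> "FitConfig":
        d = json.loads(Path(path).read_text())
        ga = d.get("ga", {})
        ga["seeds"] = tuple(ga.get("seeds", (1234, 1235)))
        return FitConfig(
            conductance_set=d.get("conductance_set", "A"),
            feature_tolerances=d.get("feature_tolerances", {}),
            ga=GASettings(**ga),
            parameter_bounds={k: tuple(v) for k, v in d.get("parameter_bounds", {}).items()},
            stage1_features=tuple(d.get("stage1_features", ())),
            stage2_features=tuple(d.get("stage2_features", ())),
        )


def write_model_json(path, parameters: dict, conductance_set: str,
                     passive: dict, metadata: dict | None = None) -> None:
    """Serialize an optimized model: named parameters in SI-consistent units
    (densities S/cm^2, Cm uF/cm^2, Ri Ohm cm) plus provenance metadata."""
    doc = {
        "schema": "neurofit-model-1",
        "conductance_set": conductance_set,
        "parameters": dict(parameters),
        "passive": dict(passive),
        "metadata": dict(metadata or {}),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model_json(path, known_parameters=None) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "neurofit-model-1":
        raise ConfigError("not a neurofit model file")
    if known_parameters is not None:
        unknown = set(doc["parameters"]) - set(known_parameters)
        if unknown:
            raise ConfigError(f"unknown parameters in model file: {sorted(unknown)}")
    return doc
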