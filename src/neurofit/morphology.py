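"""SWC-derived compartmental morphologies.

Converts an SWC point tree into a tree of :class:`Section` objects ready for
cable simulation, applying the standard substitutions used for somatic-only
active models: the spherical soma becomes a cylinder of equal membrane area
(L = D convention), and any reconstructed axon is replaced by a synthetic
60 um x 1 um initial segment attached to the soma.

Each section carries a piecewise-linear diameter profile; lateral areas and
axial resistances are computed per frustum so that tapering dendrites keep
their reconstructed membrane area (which drives the capacitance bookkeeping
downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

KIND_NAMES = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
KINDS = ("soma", "axon", "basal", "apical")


class MorphologyError(ValueError):
    pass


@dataclass
class Section:
    """An unbranched neurite stretch with a piecewise-linear diameter profile.

    ``x`` holds arc-length positions (um, increasing, starting at 0) and
    ``diam`` the diameters (um) at those positions.  ``parent`` is the index
    of the parent section (-1 for the root soma); children always attach at
    the parent's distal end except for soma children, which attach at the
    soma midpoint.
    """

    kind: str
    x: np.ndarray
    diam: np.ndarray
    parent: int = -1
    nseg: int = 1

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.diam = np.asarray(self.diam, dtype=float)
        if self.kind not in KINDS:
            raise MorphologyError(f"unknown section kind {self.kind!r}")
        if self.x.size < 2 or self.length <= 0:
            raise MorphologyError("section needs positive length")
        if np.any(np.diff(self.x) < 0):
            raise MorphologyError("arc-length positions must be non-decreasing")
        if np.any(self.diam <= 0):
            raise MorphologyError("diameters must be positive")

    @property
    def length(self) -> float:
        return float(self.x[-1] - self.x[0])

    def lateral_area(self) -> float:
        """Total lateral (frustum) area in um^2."""
        r = self.diam / 2.0
        dx = np.diff(self.x)
        dr = np.diff(r)
        slant = np.sqrt(dx * dx + dr * dr)
        return float(np.sum(math.pi * (r[:-1] + r[1:]) * slant))

    def segment_geometry(self, nseg: int | None = None):
        """Per-segment (area um^2, left/right axial half-resistance factors).

        The axial factor is ``integral dx / (pi r(x)^2)`` in um^-1; multiply by
        axial resistivity (converted to Ohm um) to obtain resistance.
        Returned arrays have length nseg (areas) and nseg (half-resistance of
        each half-segment, left and right).
        """
        n = int(nseg or self.nseg)
        edges = np.linspace(self.x[0], self.x[-1], 2 * n + 1)
        # fine sampling of the diameter profile between consecutive edges
        areas = np.zeros(n)
        half_rfac = np.zeros(2 * n)
        for j in range(2 * n):
            a, b = edges[j], edges[j + 1]
            xs = np.linspace(a, b, 9)
            ds = np.interp(xs, self.x, self.diam)
            r = ds / 2.0
            dx = np.diff(xs)
            dr = np.diff(r)
            slant = np.sqrt(dx * dx + dr * dr)
            areas[j // 2] += np.sum(math.pi * (r[:-1] + r[1:]) * slant)
            # trapezoidal integral of 1/(pi r^2)
            f = 1.0 / (math.pi * r * r)
            half_rfac[j] = float(np.sum(0.5 * (f[:-1] + f[1:]) * dx))
        return areas, half_rfac


@dataclass
class CompartmentalMorphology:
    """Tree of sections; section 0 is always the soma."""

    sections: list

    def __post_init__(self):
        if not self.sections or self.sections[0].kind != "soma":
            raise MorphologyError("section 0 must be the soma")
        for i, s in enumerate(self.sections):
            if i == 0:
                if s.parent != -1:
                    raise MorphologyError("soma must be the root")
            elif not (0 <= s.parent < i):
                raise MorphologyError("parent must precede child (acyclic tree)")

    @property
    def has_apical(self) -> bool:
        return any(s.kind == "apical" for s in self.sections)

    @property
    def areas_by_kind(self) -> dict:
        out = {k: 0.0 for k in KINDS}
        for s in self.sections:
            out[s.kind] += s.lateral_area()
        return out

    def total_area(self) -> float:
        return sum(self.areas_by_kind.values())

    def n_compartments(self) -> int:
        return sum(s.nseg for s in self.sections)

    def leak_kinds(self):
        """Section kinds carrying an independent leak density (3 or 4)."""
        kinds = ["soma", "axon", "basal"]
        if self.has_apical:
            kinds.append("apical")
        return kinds


def soma_to_cylinder(radius: float) -> Section:
    """Equivalent-area soma cylinder with L = D = 2 r.

    A sphere of radius r has area 4 pi r^2; a cylinder with length equal to
    its diameter 2r has lateral area pi D L = 4 pi r^2, so membrane area is
    preserved exactly.
    """
    if radius <= 0:
        raise MorphologyError("soma radius must be positive")
    d = 2.0 * radius
    return Section("soma", x=[0.0, d], diam=[d, d], parent=-1)


def replace_axon(morph: CompartmentalMorphology,
                 length: float = 60.0, diam: float = 1.0) -> CompartmentalMorphology:
    """Drop reconstructed axon sections and attach a synthetic initial segment.

    The substitution is unconditional (applied whether or not an axon was
    reconstructed) and idempotent: the output always carries exactly one
    axon section of the given dimensions, attached to the soma.
    """
    kept = [s for s in morph.sections if s.kind != "axon"]
    # reindex parents after removal
    old_index = {id(s): i for i, s in enumerate(morph.sections)}
    new_index = {id(s): i for i, s in enumerate(kept)}
    out = []
    for s in kept:
        if s.parent == -1:
            p = -1
        else:
            parent_sec = morph.sections[s.parent]
            if parent_sec.kind == "axon":
                raise MorphologyError("dendrite attached to axon is unsupported")
            p = new_index[id(parent_sec)]
        out.append(Section(s.kind, s.x.copy(), s.diam.copy(), parent=p, nseg=s.nseg))
    out.append(Section("axon", x=[0.0, length], diam=[diam, diam], parent=0))
    return CompartmentalMorphology(out)


def discretize(morph: CompartmentalMorphology,
               max_seg_length: float = 20.0) -> CompartmentalMorphology:
    """Assign nseg per section: smallest odd integer with segments <= rule."""
    if max_seg_length <= 0:
        raise MorphologyError("max segment length must be positive")
    for s in morph.sections:
        n = max(1, math.ceil(s.length / max_seg_length))
        if n % 2 == 0:
            n += 1
        s.nseg = n
    return morph


def make_ball_and_stick(soma_radius: float, dend_length: float,
                        dend_diam: float) -> CompartmentalMorphology:
    """Soma cylinder plus a single uniform basal dendrite (no apical)."""
    if dend_length <= 0 or dend_diam <= 0:
        raise MorphologyError("dendrite dimensions must be positive")
    soma = soma_to_cylinder(soma_radius)
    dend = Section("basal", x=[0.0, dend_length], diam=[dend_diam, dend_diam], parent=0)
    m = CompartmentalMorphology([soma, dend])
    return replace_axon(m)


def from_swc_nodes(nodes) -> CompartmentalMorphology:
    """Build a section tree from parsed SWC nodes.

    Multi-node soma contours are collapsed to an equivalent-area sphere and
    then converted to the L = D cylinder; neurite sections are split at
    branch points and at type changes.  The reconstructed axon (if any) is
    *not* yet replaced; callers normally follow with :func:`replace_axon`.
    """
    by_id = {n.id: n for n in nodes}
    soma_nodes = [n for n in nodes if n.type_code == 1]
    if not soma_nodes:
        raise MorphologyError("no soma node in SWC file")
    # equivalent-area sphere radius for multi-node somas
    if len(soma_nodes) == 1:
        r_eq = soma_nodes[0].radius
    else:
        area = 0.0
        for a, b in zip(soma_nodes[:-1], soma_nodes[1:]):
            dist = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            slant = math.sqrt(dist * dist + (a.radius - b.radius) ** 2)
            area += math.pi * (a.radius + b.radius) * slant
        if area <= 0:
            area = 4 * math.pi * soma_nodes[0].radius ** 2
        r_eq = math.sqrt(area / (4 * math.pi))
    soma = soma_to_cylinder(r_eq)
    sections = [soma]

    soma_ids = {n.id for n in soma_nodes}
    children = {}
    for n in nodes:
        if n.parent_id != -1 and n.id not in soma_ids:
            children.setdefault(n.parent_id, []).append(n.id)

    # walk unbranched chains from each neurite root
    sec_of_tip = {}  # last swc id of a section -> section index

    def chain_from(start_id, parent_sec):
        node = by_id[start_id]
        pts = []
        pnode = by_id.get(node.parent_id)
        if pnode is not None and pnode.id not in soma_ids:
            pts.append(pnode)
        pts.append(node)
        while True:
            kids = children.get(pts[-1].id, [])
            same = [k for k in kids if by_id[k].type_code == pts[-1].type_code]
            if len(kids) == 1 and len(same) == 1:
                pts.append(by_id[kids[0]])
            else:
                break
        xs = [0.0]
        for a, b in zip(pts[:-1], pts[1:]):
            xs.append(xs[-1] + math.dist((a.x, a.y, a.z), (b.x, b.y, b.z)))
        diams = [2 * p.radius for p in pts]
        if len(pts) == 1:
            # lone sample (e.g. an axon stub): span from the soma surface
            ref = soma_nodes[0]
            length = max(math.dist((ref.x, ref.y, ref.z),
                                   (node.x, node.y, node.z)), 2 * node.radius)
            xs = [0.0, length]
            diams = [diams[0], diams[0]]
        elif xs[-1] <= 0:
            xs[-1] = max(2 * pts[-1].radius, 1e-3)
        kind = KIND_NAMES.get(pts[-1].type_code)
        if kind is None:
            raise MorphologyError(f"unsupported SWC type code {pts[-1].type_code}")
        sec = Section(kind, xs, diams, parent=parent_sec)
        sections.append(sec)
        idx = len(sections) - 1
        sec_of_tip[pts[-1].id] = idx
        for k in children.get(pts[-1].id, []):
            chain_from(k, idx)

    roots = [n for n in nodes if n.id not in soma_ids
             and (n.parent_id == -1 or n.parent_id in soma_ids)]
    for r in roots:
        chain_from(r.id, 0)
    return CompartmentalMorphology(sections)
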