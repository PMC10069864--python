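"""Neuron morphologies as trees of cylindrical sections.

A morphology is a tree of *sections*: short cylindrical cables described by a
3D polyline, a mean diameter and a region label.  This mirrors how
reconstruction pipelines export electron-microscopy skeletons: SWC nodes are
grouped into unbranched runs between branch points, and each run becomes one
section.  The mushroom body output neuron modelled here consists of a large
dendritic tree (thousands of ~1 μm sections), a proximal neurite, five axon /
terminal sections and a soma.

Synapse tables map presynaptic Kenyon cell (KC) identifiers to locations on
the dendrite, either as raw 3D coordinates (mapped to the nearest section) or
directly as ``(section_id, position)`` pairs.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "Section",
    "Morphology",
    "GeometryStats",
    "SynapseSite",
    "ConnectivityTable",
    "MorphologyError",
    "parse_swc",
    "read_swc",
    "write_swc",
    "augment_axon_soma",
    "geometry_summary",
    "map_synapses",
    "path_distance",
    "path_distances_from",
    "load_synapse_json",
    "dump_synapse_json",
    "DEFAULT_AXON_SPEC",
    "DEFAULT_SOMA_DIAMETER",
]

#: Region labels a section may carry.
REGIONS = (
    "dendrite",
    "proximal_neurite",
    "axon1",
    "axon2",
    "axon3",
    "axon4",
    "axon5",
    "soma",
)

#: Placeholder axon/terminal geometry, (length μm, diameter μm) per section.
#: The five sections stand for the axonal arbor between the proximal neurite
#: and the synaptic terminal; the true dimensions come from a reconstruction
#: supplement and are configurable wherever this default is accepted.
DEFAULT_AXON_SPEC = (
    (40.0, 0.80),
    (30.0, 0.60),
    (25.0, 0.50),
    (20.0, 0.50),
    (15.0, 0.60),
)

#: Soma diameter in μm (confocal measurement of the MBON-α3 cell body).
DEFAULT_SOMA_DIAMETER = 6.45


class MorphologyError(ValueError):
    """Structural or validation failure in a morphology or synapse table."""


@dataclass
class Section:
    """One unbranched cylindrical cable.

    Parameters
    ----------
    id : int
        Unique section index.
    parent_id : int or None
        Index of the parent section, ``None`` for the root.
    points : (n, 3) array
        Polyline in μm.  The first point coincides with the attachment point
        on the parent.
    diameter : float
        Mean diameter over the section, μm.
    region : str
        One of :data:`REGIONS`.
    parent_attach : float
        Where on the parent this section attaches: ``1.0`` distal end
        (default), ``0.0`` proximal end (used for appended axon/soma).
    """

    id: int
    parent_id: int | None
    points: np.ndarray
    diameter: float
    region: str = "dendrite"
    parent_attach: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.shape[0] < 2:
            raise MorphologyError(f"section {self.id}: needs >= 2 points")
        if not self.diameter > 0:
            raise MorphologyError(f"section {self.id}: diameter must be > 0")
        if self.region not in REGIONS:
            raise MorphologyError(f"section {self.id}: unknown region {self.region!r}")
        if not self.length > 0:
            raise MorphologyError(f"section {self.id}: zero length")

    @property
    def length(self) -> float:
        """Arc length of the polyline, μm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def lateral_area(self) -> float:
        """Cylinder lateral surface π·d·L, μm²."""
        return math.pi * self.diameter * self.length

    @property
    def volume(self) -> float:
        """Cylinder volume π·d²/4·L, μm³."""
        return math.pi * self.diameter**2 / 4.0 * self.length

    def point_at(self, frac: float) -> np.ndarray:
        """3D point at fractional arc length ``frac`` in [0, 1]."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = frac * cum[-1]
        i = int(np.clip(np.searchsorted(cum, s) - 1, 0, len(seg) - 1))
        t = 0.0 if seg[i] == 0 else (s - cum[i]) / seg[i]
        return self.points[i] + t * (self.points[i + 1] - self.points[i])


class Morphology:
    """A connected tree of :class:`Section` objects."""

    def __init__(self, sections: Iterable[Section], provenance: str = ""):
        self.sections: dict[int, Section] = {}
        for s in sections:
            if s.id in self.sections:
                raise MorphologyError(f"duplicate section id {s.id}")
            self.sections[s.id] = s
        self.provenance = provenance
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        roots = [s for s in self.sections.values() if s.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        for s in self.sections.values():
            if s.parent_id is not None and s.parent_id not in self.sections:
                raise MorphologyError(
                    f"section {s.id} references missing parent {s.parent_id}"
                )
        # connectivity: every section must reach the root
        if len(self.traversal_order()) != len(self.sections):
            raise MorphologyError("sections do not form a single connected tree")

    @property
    def root(self) -> Section:
        return next(s for s in self.sections.values() if s.parent_id is None)

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {i: [] for i in self.sections}
        for s in self.sections.values():
            if s.parent_id is not None:
                ch[s.parent_id].append(s.id)
        return ch

    def traversal_order(self) -> list[int]:
        """Depth-first order from the root; parents precede children."""
        ch = self.children()
        order, stack = [], [self.root.id]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(ch[i]))
        return order

    def section_ids(self, regions: Sequence[str] | None = None) -> list[int]:
        if regions is None:
            return sorted(self.sections)
        rset = set(regions)
        return sorted(i for i, s in self.sections.items() if s.region in rset)

    @property
    def is_augmented(self) -> bool:
        return any(s.region == "soma" for s in self.sections.values())

    def find_region(self, region: str) -> int:
        """Id of the unique section with the given region label."""
        ids = [i for i, s in self.sections.items() if s.region == region]
        if len(ids) != 1:
            raise MorphologyError(f"expected one {region!r} section, found {len(ids)}")
        return ids[0]

    # -- geometry ----------------------------------------------------------
    def _endpoint_graph(self):
        """Undirected weighted graph on section endpoints for path metrics.

        Nodes are ``(section_id, 'start'|'end')``; each section contributes an
        edge of weight ``length`` plus a zero-weight edge tying its start to
        the parent attachment point.
        """
        import networkx as nx

        g = nx.Graph()
        for s in self.sections.values():
            g.add_edge((s.id, "start"), (s.id, "end"), weight=s.length)
            if s.parent_id is not None:
                anchor = "end" if s.parent_attach >= 0.5 else "start"
                g.add_edge((s.parent_id, anchor), (s.id, "start"), weight=0.0)
        return g


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

_SWC_TYPE_TO_REGION = {1: "soma", 2: "axon1", 3: "dendrite", 4: "dendrite"}
_REGION_TO_SWC_TYPE = {
    "soma": 1,
    "dendrite": 3,
    "proximal_neurite": 3,
    "axon1": 2,
    "axon2": 2,
    "axon3": 2,
    "axon4": 2,
    "axon5": 2,
}


def parse_swc(stream, unit_scale: float = 1.0, per_node: bool = False) -> Morphology:
    """Read an SWC morphology into a :class:`Morphology`.

    Parameters
    ----------
    stream : str or file-like
        SWC text (7 whitespace-separated columns: id, type, x, y, z, radius,
        parent; ``#`` comments allowed).
    unit_scale : float
        Factor applied to coordinates and radii, e.g. ``0.008`` to convert an
        8 nm-pixel export into μm.
    per_node : bool
        If ``True``, every SWC node becomes its own section.  By default
        unbranched runs of nodes are merged into single sections, which is the
        sectionization the archived reconstruction uses.

    Notes
    -----
    Section diameters are the mean node diameter over the section's own nodes
    (the shared anchor node at a branch point belongs to the parent run).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise MorphologyError(f"SWC line has {len(cols)} columns, expected 7")
        nid, ntype = int(cols[0]), int(cols[1])
        xyz = np.array([float(c) for c in cols[2:5]]) * unit_scale
        radius = float(cols[5]) * unit_scale
        parent = int(cols[6])
        if radius <= 0:
            raise MorphologyError(f"SWC node {nid}: non-positive radius")
        if nid in nodes:
            raise MorphologyError(f"SWC node {nid}: duplicate id")
        nodes[nid] = (ntype, xyz, radius, parent)

    roots = [i for i, (_, _, _, p) in nodes.items() if p == -1]
    if len(roots) != 1:
        raise MorphologyError(f"SWC must have exactly one root, found {len(roots)}")
    for i, (_, _, _, p) in nodes.items():
        if p != -1 and p not in nodes:
            raise MorphologyError(f"SWC node {i}: orphan parent reference {p}")

    nchild: dict[int, int] = {i: 0 for i in nodes}
    for i, (_, _, _, p) in nodes.items():
        if p != -1:
            nchild[p] += 1
    children: dict[int, list[int]] = {i: [] for i in nodes}
    for i in sorted(nodes):
        p = nodes[i][3]
        if p != -1:
            children[p].append(i)

    root = roots[0]
    sections: list[Section] = []
    next_id = 0

    def region_of(node_ids: list[int]) -> str:
        return _SWC_TYPE_TO_REGION.get(nodes[node_ids[0]][0], "dendrite")

    # The root *node* carries no section of its own: the first run (or node)
    # anchored at it becomes the root section; any further root-anchored runs
    # attach to that section's proximal end.
    root_sec: int | None = None
    if per_node:
        sec_of_node: dict[int, int] = {}
        for i in sorted(nodes):
            ntype, xyz, radius, p = nodes[i]
            if p == -1:
                continue
            pts = np.vstack([nodes[p][1], xyz])
            if p == root:
                parent_sec = root_sec
                attach = 0.0 if root_sec is not None else 1.0
            else:
                parent_sec, attach = sec_of_node[p], 1.0
            sections.append(
                Section(next_id, parent_sec, pts, 2 * radius,
                        region=_SWC_TYPE_TO_REGION.get(ntype, "dendrite"),
                        parent_attach=attach)
            )
            if p == root and root_sec is None:
                root_sec = next_id
            sec_of_node[i] = next_id
            next_id += 1
        if not sections:
            raise MorphologyError("SWC has no segments")
    else:
        # runs of nodes between branch points
        sec_of_tail: dict[int, int] = {}  # last node of a run -> section id
        stack = [(c, root) for c in reversed(children[root])]
        while stack:
            start, anchor = stack.pop()
            run = [start]
            while nchild[run[-1]] == 1:
                run.append(children[run[-1]][0])
            pts = np.vstack([nodes[anchor][1]] + [nodes[i][1] for i in run])
            diam = 2.0 * float(np.mean([nodes[i][2] for i in run]))
            if anchor == root:
                parent_sec = root_sec
                attach = 0.0 if root_sec is not None else 1.0
            else:
                parent_sec, attach = sec_of_tail[anchor], 1.0
            sections.append(
                Section(next_id, parent_sec, pts, diam, region=region_of(run),
                        parent_attach=attach)
            )
            if anchor == root and root_sec is None:
                root_sec = next_id
            sec_of_tail[run[-1]] = next_id
            next_id += 1
            for c in reversed(children[run[-1]]):
                stack.append((c, run[-1]))
        if not sections:
            raise MorphologyError("SWC has no segments")

    return Morphology(sections, provenance="swc")


def read_swc(path, unit_scale: float = 1.0, per_node: bool = False) -> Morphology:
    with open(path) as fh:
        m = parse_swc(fh, unit_scale=unit_scale, per_node=per_node)
    m.provenance = str(path)
    return m


def write_swc(m: Morphology, stream=None) -> str | None:
    """Serialize a morphology to SWC text.

    Every polyline point becomes one node with radius ``diameter/2``; the
    shared anchor point of a child section is not re-emitted.  Re-parsing the
    output reproduces the section graph and geometry exactly.
    """
    lines = ["# exported by mbonsim"]
    next_node = 1
    tail_node: dict[int, int] = {}
    head_node: dict[int, int] = {}
    for sid in m.traversal_order():
        s = m.sections[sid]
        swc_type = _REGION_TO_SWC_TYPE[s.region]
        r = s.diameter / 2.0
        if s.parent_id is None:
            pts = s.points
            parent = -1
        else:
            pts = s.points[1:]
            anchor = "end" if s.parent_attach >= 0.5 else "start"
            parent = (tail_node if anchor == "end" else head_node)[s.parent_id]
        first = True
        for p in pts:
            lines.append(
                f"{next_node} {swc_type} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {r:.6f} {parent}"
            )
            if first and s.parent_id is None:
                head_node[sid] = next_node
            elif first:
                head_node[sid] = parent  # anchor node on the parent
            parent = next_node
            next_node += 1
            first = False
        tail_node[sid] = next_node - 1
    text = "\n".join(lines) + "\n"
    if stream is None:
        return text
    stream.write(text)
    return None


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_axon_soma(
    m: Morphology,
    axon_spec: Sequence[tuple[float, float]] = DEFAULT_AXON_SPEC,
    soma_diameter: float = DEFAULT_SOMA_DIAMETER,
    neurite_link_length: float = 0.0,
) -> Morphology:
    """Append five axon/terminal sections and a soma to a dendrite-only tree.

    The root section of the dendritic tree is relabelled ``proximal_neurite``;
    the axon chain and the soma attach at its proximal end, so the soma is a
    leaf.  The soma is modelled as a cylinder with length equal to its
    diameter (lateral surface ≈ π·d²).  ``neurite_link_length`` offsets the
    soma geometrically (the thin soma-to-neurite link is not given its own
    section).

    Raises
    ------
    MorphologyError
        If the morphology already contains a soma, or spec values are not
        positive.
    """
    if m.is_augmented:
        raise MorphologyError("morphology already has soma/axon sections")
    if len(axon_spec) != 5:
        raise MorphologyError("axon_spec must give exactly 5 (length, diameter) pairs")
    for L, d in axon_spec:
        if L <= 0 or d <= 0:
            raise MorphologyError("axon_spec entries must be positive")
    if soma_diameter <= 0:
        raise MorphologyError("soma_diameter must be positive")
    if neurite_link_length < 0:
        raise MorphologyError("neurite_link_length must be >= 0")

    sections = [
        Section(s.id, s.parent_id, s.points.copy(), s.diameter,
                region=s.region, parent_attach=s.parent_attach)
        for s in m.sections.values()
    ]
    root = m.root
    for s in sections:
        if s.id == root.id:
            s.region = "proximal_neurite"

    base = max(m.sections) + 1
    origin = root.points[0]
    direction = root.points[0] - root.points[-1]
    n = np.linalg.norm(direction)
    direction = direction / n if n > 0 else np.array([1.0, 0.0, 0.0])

    parent, attach, tip = root.id, 0.0, origin
    for k, (L, d) in enumerate(axon_spec):
        pts = np.vstack([tip, tip + direction * L])
        sections.append(Section(base + k, parent, pts, d,
                                region=f"axon{k + 1}", parent_attach=attach))
        parent, attach, tip = base + k, 1.0, pts[-1]

    side = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(side, direction)) > 0.9:
        side = np.array([0.0, 0.0, 1.0])
    soma_start = origin + side * neurite_link_length
    soma_pts = np.vstack([soma_start, soma_start + side * soma_diameter])
    sections.append(Section(base + 5, root.id, soma_pts, soma_diameter,
                            region="soma", parent_attach=0.0))
    out = Morphology(sections, provenance=m.provenance + "+axon/soma")
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class GeometryStats:
    """Whole-morphology geometry summary (units: μm, μm²)."""

    n_sections: int
    total_length: float
    mean_section_length: float
    mean_diameter: float
    total_surface_area: float
    soma_diameter: float

    def to_dict(self) -> dict:
        return {
            "n_sections": self.n_sections,
            "total_length_um": self.total_length,
            "mean_section_length_um": self.mean_section_length,
            "mean_diameter_um": self.mean_diameter,
            "total_surface_area_um2": self.total_surface_area,
            "soma_diameter_um": self.soma_diameter,
        }


def geometry_summary(m: Morphology) -> GeometryStats:
    """Compute section-count, length, diameter and surface statistics."""
    lengths = np.array([s.length for s in m.sections.values()])
    diams = np.array([s.diameter for s in m.sections.values()])
    areas = np.array([s.lateral_area for s in m.sections.values()])
    soma_d = math.nan
    if m.is_augmented:
        soma_d = m.sections[m.find_region("soma")].diameter
    return GeometryStats(
        n_sections=m.n_sections,
        total_length=float(lengths.sum()),
        mean_section_length=float(lengths.mean()),
        mean_diameter=float(diams.mean()),
        total_surface_area=float(areas.sum()),
        soma_diameter=soma_d,
    )


# ---------------------------------------------------------------------------
# Synapse tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseSite:
    """One synaptic contact from a KC onto the morphology.

    ``position`` is the fractional arc length along the section in [0, 1].
    """

    kc_id: str
    section_id: int
    position: float
    coords: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not (0.0 <= self.position <= 1.0):
            raise MorphologyError(f"synapse position {self.position} outside [0, 1]")


@dataclass
class ConnectivityTable:
    """All synaptic contacts from the KC population onto one morphology."""

    sites: list[SynapseSite] = field(default_factory=list)

    @property
    def n_synapses(self) -> int:
        return len(self.sites)

    @property
    def n_kcs(self) -> int:
        return len({s.kc_id for s in self.sites})

    @property
    def mean_synapses_per_kc(self) -> float:
        return self.n_synapses / self.n_kcs

    def kc_ids(self) -> list[str]:
        return sorted({s.kc_id for s in self.sites})

    def sites_of(self, kc_id: str) -> list[SynapseSite]:
        return [s for s in self.sites if s.kc_id == kc_id]

    def counts_per_kc(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.sites:
            out[s.kc_id] = out.get(s.kc_id, 0) + 1
        return out

    def synapse_bearing_sections(self) -> list[int]:
        return sorted({s.section_id for s in self.sites})

    def validate_against(self, m: Morphology) -> None:
        for s in self.sites:
            if s.section_id not in m.sections:
                raise MorphologyError(
                    f"synapse references missing section {s.section_id}"
                )


def map_synapses(m: Morphology, coords: Sequence[tuple]) -> ConnectivityTable:
    """Assign each (kc_id, x, y, z) coordinate to its nearest section.

    Candidate sections are the dendritic tree (regions ``dendrite`` and
    ``proximal_neurite``); the synapse position is the fractional arc length
    of the nearest point on the section polyline.  Exact distance ties are
    broken toward the lowest section id.
    """
    if len(coords) == 0:
        return ConnectivityTable([])
    cand = m.section_ids(["dendrite", "proximal_neurite"]) or m.section_ids()

    seg_a, seg_b, seg_sec, seg_cum, sec_len = [], [], [], [], {}
    for sid in cand:  # sorted -> argmin tie-break picks lowest id
        s = m.sections[sid]
        pts = s.points
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(d)])
        sec_len[sid] = cum[-1]
        for k in range(len(pts) - 1):
            seg_a.append(pts[k])
            seg_b.append(pts[k + 1])
            seg_sec.append(sid)
            seg_cum.append(cum[k])
    A = np.asarray(seg_a)
    B = np.asarray(seg_b)
    AB = B - A
    ab2 = np.einsum("ij,ij->i", AB, AB)
    ab2[ab2 == 0] = 1.0
    seg_sec = np.asarray(seg_sec)
    seg_cum = np.asarray(seg_cum)

    sites: list[SynapseSite] = []
    kc_ids = [str(c[0]) for c in coords]
    P = np.asarray([[c[1], c[2], c[3]] for c in coords], dtype=float)
    chunk = max(1, int(2e7 // max(len(A), 1)))
    for lo in range(0, len(P), chunk):
        p = P[lo:lo + chunk]
        t = np.einsum("nik,ik->ni", p[:, None, :] - A[None], AB) / ab2
        t = np.clip(t, 0.0, 1.0)
        close = A[None] + t[..., None] * AB[None]
        d2 = np.einsum("nik,nik->ni", p[:, None, :] - close, p[:, None, :] - close)
        best = np.argmin(d2, axis=1)
        for row, j in enumerate(best):
            sid = int(seg_sec[j])
            seg_len = math.sqrt(ab2[j])
            arc = seg_cum[j] + t[row, j] * seg_len
            L = sec_len[sid]
            pos = float(np.clip(arc / L, 0.0, 1.0)) if L > 0 else 0.5
            c = P[lo + row]
            sites.append(SynapseSite(kc_ids[lo + row], sid, pos,
                                     coords=(c[0], c[1], c[2])))
    return ConnectivityTable(sites)


def load_synapse_json(source) -> list[tuple] | ConnectivityTable:
    """Read a synapse table in either accepted JSON dialect.

    Coordinate dialect ``[{"kc":…, "x":…, "y":…, "z":…}]`` returns a list of
    ``(kc, x, y, z)`` tuples to pass to :func:`map_synapses`.  Section dialect
    ``[{"kc":…, "section_id":…, "position":…}]`` returns a
    :class:`ConnectivityTable` directly.
    """
    if hasattr(source, "read"):
        data = json.load(source)
    elif isinstance(source, (list, tuple)):
        data = source
    else:
        with open(source) as fh:
            data = json.load(fh)
    if not data:
        return ConnectivityTable([])
    first = data[0]
    if "section_id" in first:
        return ConnectivityTable([
            SynapseSite(str(e["kc"]), int(e["section_id"]),
                        float(e.get("position", 0.5)))
            for e in data
        ])
    return [(str(e["kc"]), float(e["x"]), float(e["y"]), float(e["z"]))
            for e in data]


def dump_synapse_json(table: ConnectivityTable, stream=None) -> str | None:
    data = [
        {"kc": s.kc_id, "section_id": s.section_id, "position": s.position}
        for s in table.sites
    ]
    text = json.dumps(data, indent=1)
    if stream is None:
        return text
    stream.write(text)
    return None


# ---------------------------------------------------------------------------
# Path metrics
# ---------------------------------------------------------------------------

def _midpoint_node(m: Morphology, g, sid: int):
    """Insert a node for the midpoint of a section into graph ``g``."""
    s = m.sections[sid]
    node = (sid, "mid")
    if node not in g:
        g.add_edge((sid, "start"), node, weight=s.length / 2.0)
        g.add_edge(node, (sid, "end"), weight=s.length / 2.0)
        g.remove_edge((sid, "start"), (sid, "end"))
    return node


def path_distance(m: Morphology, a: int, b: int) -> float:
    """Arc length of the tree path between the midpoints of sections a and b."""
    import networkx as nx

    if a not in m.sections or b not in m.sections:
        raise KeyError(f"unknown section id {a if a not in m.sections else b}")
    if a == b:
        return 0.0
    g = m._endpoint_graph()
    na = _midpoint_node(m, g, a)
    nb = _midpoint_node(m, g, b)
    return float(nx.shortest_path_length(g, na, nb, weight="weight"))


def path_distances_from(m: Morphology, src: int) -> dict[int, float]:
    """Midpoint-to-midpoint distances from ``src`` to every section."""
    import networkx as nx

    if src not in m.sections:
        raise KeyError(f"unknown section id {src}")
    g = m._endpoint_graph()
    ns = _midpoint_node(m, g, src)
    dist_end = nx.single_source_dijkstra_path_length(g, ns, weight="weight")
    out = {}
    for sid, s in m.sections.items():
        if sid == src:
            out[sid] = 0.0
            continue
        out[sid] = min(dist_end[(sid, "start")], dist_end[(sid, "end")]) + s.length / 2.0
    return out
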