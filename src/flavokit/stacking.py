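"""Geometric pi-stacking detection and assembly-graph topology.

Aromatic-ring stacking contacts are detected from three geometric gates:
ring-centroid distance, interplanar angle (between unit normals, folded to
[0, 90] degrees), and lateral offset (the in-plane slip of one centroid
relative to the other ring).  Molecule-level contacts build an undirected
assembly graph whose connected components are classified by topology:

* SINGLETON — an unassembled molecule;
* PRIMARY   — a simple linear stack (path: all degrees <= 2, acyclic),
              the primary fiber structure;
* SECONDARY — a branched assembly (some molecule stacks with >= 3 partners),
              the secondary fiber structure grown off a primary stack;
* CYCLIC    — a closed loop without branching.

Parallel (face-to-face) stacking is the default; an optional T-shaped mode
admits near-perpendicular (edge-to-face) contacts through a high-angle
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SpecValidationError

SINGLETON = "SINGLETON"
PRIMARY = "PRIMARY"
SECONDARY = "SECONDARY"
CYCLIC = "CYCLIC"


@dataclass
class RingSpec:
    """An aromatic ring: a molecule id plus >= 5 ordered atom indices."""

    molecule_id: str
    atom_indices: tuple

    def __post_init__(self) -> None:
        self.atom_indices = tuple(int(i) for i in self.atom_indices)
        if len(self.atom_indices) < 5:
            raise SpecValidationError(
                "atom_indices", f"ring needs >=5 atoms, got {len(self.atom_indices)}"
            )

    def centroid(self, coords: np.ndarray) -> np.ndarray:
        return coords[list(self.atom_indices)].mean(axis=0)

    def normal(self, coords: np.ndarray) -> np.ndarray:
        """Unit normal of the best-fit plane (smallest singular vector)."""
        pts = coords[list(self.atom_indices)]
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        n = vt[-1]
        return n / np.linalg.norm(n)

    def planarity(self, coords: np.ndarray) -> float:
        """Max out-of-plane distance (same units as coords)."""
        pts = coords[list(self.atom_indices)]
        centered = pts - pts.mean(axis=0)
        return float(np.abs(centered @ self.normal(coords)).max())


@dataclass
class StackingThresholds:
    """Geometric gates, Angstrom / degrees.  Defaults are standard
    parallel pi-stacking geometry; all three are tunable."""

    max_centroid_dist: float = 4.5
    max_angle: float = 30.0
    max_offset: float = 2.0
    include_t_shaped: bool = False
    t_angle_min: float = 60.0


@dataclass
class StackingContact:
    ring_i: int
    ring_j: int
    molecule_i: str
    molecule_j: str
    centroid_distance: float
    interplanar_angle: float
    lateral_offset: float


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring planes in degrees, folded into [0, 90]."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def lateral_offset(c1: np.ndarray, c2: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> float:
    # in-plane slip of the centroid displacement, measured in each ring's
    # plane; the min over the two rings makes the gate symmetric and lets
    # ideal edge-on (T-shaped) contacts pass with offset 0
    d = c2 - c1
    off1 = np.linalg.norm(d - np.dot(d, n1) * n1)
    off2 = np.linalg.norm(d - np.dot(d, n2) * n2)
    return float(min(off1, off2))


def detect_stacking_contacts(
    coords: np.ndarray,
    rings: Sequence[RingSpec],
    thresholds: StackingThresholds | None = None,
) -> list[StackingContact]:
    """All ring pairs passing the distance, angle and offset gates.

    ``coords`` is an (n_atoms, 3) array in Angstrom for a single frame.
    Rings on the same molecule are never reported as contacts.
    """
    thr = thresholds or StackingThresholds()
    coords = np.asarray(coords, dtype=float)
    cents = np.array([r.centroid(coords) for r in rings])
    norms = np.array([r.normal(coords) for r in rings])
    contacts: list[StackingContact] = []
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if rings[i].molecule_id == rings[j].molecule_id:
                continue
            dist = float(np.linalg.norm(cents[j] - cents[i]))
            if dist > thr.max_centroid_dist:
                continue
            ang = interplanar_angle(norms[i], norms[j])
            parallel_ok = ang <= thr.max_angle
            t_ok = thr.include_t_shaped and ang >= thr.t_angle_min
            if not (parallel_ok or t_ok):
                continue
            off = lateral_offset(cents[i], cents[j], norms[i], norms[j])
            if off > thr.max_offset:
                continue
            contacts.append(
                StackingContact(
                    ring_i=i,
                    ring_j=j,
                    molecule_i=rings[i].molecule_id,
                    molecule_j=rings[j].molecule_id,
                    centroid_distance=dist,
                    interplanar_angle=ang,
                    lateral_offset=off,
                )
            )
    return contacts


def build_assembly_graph(
    contacts: Iterable[StackingContact], molecules: Iterable[str]
) -> nx.Graph:
    """Molecule-level undirected graph; ring-level contacts collapse to one
    edge per molecule pair.  Isolated molecules stay as singleton nodes."""
    g = nx.Graph()
    g.add_nodes_from(molecules)
    for c in contacts:
        if not g.has_node(c.molecule_i) or not g.has_node(c.molecule_j):
            raise SpecValidationError(
                "contacts", f"contact references unknown molecule {c.molecule_i}/{c.molecule_j}"
            )
        if g.has_edge(c.molecule_i, c.molecule_j):
            g[c.molecule_i][c.molecule_j]["n_ring_contacts"] += 1
        else:
            g.add_edge(c.molecule_i, c.molecule_j, n_ring_contacts=1)
    return g


def classify_assembly(component: nx.Graph) -> str:
    """Topology class of one connected component (see module docstring)."""
    n = component.number_of_nodes()
    if n == 1:
        return SINGLETON
    if any(d >= 3 for _, d in component.degree()):
        return SECONDARY
    if component.number_of_edges() >= n:  # connected + E >= V implies a cycle
        return CYCLIC
    return PRIMARY


def assembly_components(graph: nx.Graph) -> pd.DataFrame:
    """One row per connected component: members, size and topology class."""
    rows = []
    for cid, nodes in enumerate(sorted(nx.connected_components(graph), key=sorted)):
        sub = graph.subgraph(nodes)
        rows.append(
            {
                "component_id": cid,
                "size": len(nodes),
                "topology": classify_assembly(sub),
                "members": ";".join(str(n) for n in sorted(nodes)),
            }
        )
    return pd.DataFrame(rows, columns=["component_id", "size", "topology", "members"])
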