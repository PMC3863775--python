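"""Non-covalent chainmail: closed ring curves and Gauss linking numbers.

In an HK97-like capsid, the P-domains and E-loops of major-capsid-protein
subunits from neighbouring capsomers join head to tail into closed rings;
rings around adjacent capsomers thread through one another, and the shell
as a whole becomes a topologically interlocked chainmail. Catenation of
two disjoint closed curves is quantified by the Gauss linking number

    Lk(A, B) = (1 / 4 pi) oint_A oint_B (r1 - r2) . (dr1 x dr2) / |r1 - r2|^3,

an integer invariant. For polygonal curves the double integral has an
exact closed form as a sum of signed solid angles over segment pairs
(Klenin & Langowski style), which is what ``linking_number`` evaluates -
no quadrature error, so the sum rounds cleanly to an integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import GeometryError, ValidationError
from .structures import Structure, select

__all__ = [
    "RingCurve",
    "CatenationGraph",
    "build_ring",
    "linking_number",
    "catenation_graph",
    "MIN_RING_SEPARATION",
]

#: Minimum inter-ring distance below which linking is refused (A).
MIN_RING_SEPARATION = 0.5


@dataclass
class RingCurve:
    """Oriented closed polygonal curve (implicit edge last -> first)."""

    vertices: np.ndarray  # (n, 3)
    label: str = "ring"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError(f"ring {self.label}: vertices must be (n, 3)")
        if len(self.vertices) < 3:
            raise ValidationError(f"ring {self.label}: need >= 3 vertices")
        closed_edges = np.diff(
            np.vstack([self.vertices, self.vertices[:1]]), axis=0
        )
        if np.any(np.linalg.norm(closed_edges, axis=1) < 1e-9):
            raise ValidationError(f"ring {self.label}: zero-length edge")

    def __len__(self) -> int:
        return len(self.vertices)

    def reversed(self) -> "RingCurve":
        return RingCurve(self.vertices[::-1].copy(), label=self.label)

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Start and end points of every edge, including the closing one."""
        starts = self.vertices
        ends = np.roll(self.vertices, -1, axis=0)
        return starts, ends


@dataclass
class CatenationGraph:
    """Rings as nodes, nonzero pairwise linking numbers as edges."""

    graph: nx.Graph

    @property
    def n_rings(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def is_single_component(self) -> bool:
        """True when every ring belongs to one interlocked network."""
        return self.n_rings > 0 and nx.number_connected_components(self.graph) == 1

    def linking(self, a: str, b: str) -> int:
        if self.graph.has_edge(a, b):
            return self.graph.edges[a, b]["linking_number"]
        return 0


def build_ring(
    capsid: Structure,
    members: Sequence[tuple[str, tuple[int, int]]],
    label: str = "ring",
) -> RingCurve:
    """Closed Calpha trace through ordered member selections.

    Each member is (chain_id, inclusive residue range); traces are
    concatenated in member order and the curve closes back to the first
    vertex, so gaps between members become straight bridging edges.
    """
    if not members:
        raise ValidationError("ring needs at least one member selection")
    vertices = []
    for chain_id, seq_range in members:
        sel = select(capsid, chain_id, seq_range, atom_names=("CA",))
        vertices.append(sel.positions)
    return RingCurve(np.vstack(vertices), label=label)


def _min_separation(ring_a: RingCurve, ring_b: RingCurve) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(ring_b.vertices)
    d, _ = tree.query(ring_a.vertices)
    return float(np.min(d))


def _solid_angle_contributions(
    a0: np.ndarray, a1: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> float:
    """Gauss contribution of one edge of A against every edge of B.

    Exact polygonal formula: for segments (a0 -> a1) and (b0 -> b1), the
    signed solid angle of the quadrilateral they span, via four spherical
    arcsin terms (exact for straight segments).
    """
    # corner vectors, broadcast over B's edges
    r = np.stack(
        [
            starts - a0,
            ends - a0,
            ends - a1,
            starts - a1,
        ],
        axis=1,
    )  # (m, 4, 3)
    # face normals of the spherical quadrilateral
    cross = np.cross(r, np.roll(r, -1, axis=1))  # n_k = r_k x r_{k+1}
    norms = np.linalg.norm(cross, axis=2, keepdims=True)
    # degenerate faces (collinear corners) contribute zero angle
    safe = np.where(norms > 1e-12, norms, 1.0)
    n = cross / safe
    dots = np.clip(np.einsum("mkj,mkj->mk", n, np.roll(n, -1, axis=1)), -1.0, 1.0)
    omega_star = np.arcsin(dots).sum(axis=1)
    seg_b = ends - starts
    seg_a = a1 - a0
    sign = np.sign(np.einsum("mj,mj->m", np.cross(seg_b, seg_a), starts - a0))
    return float(np.sum(omega_star * sign))


def linking_number(ring_a: RingCurve, ring_b: RingCurve) -> int:
    """Exact Gauss linking number of two disjoint closed polygonal curves.

    Raises when the curves approach within ``MIN_RING_SEPARATION`` (the
    solid-angle sum is then numerically meaningless) or when the summed
    value fails to round to an integer within 1e-6.
    """
    sep = _min_separation(ring_a, ring_b)
    if sep < MIN_RING_SEPARATION:
        raise GeometryError(
            f"rings {ring_a.label!r} and {ring_b.label!r} approach to {sep:.3f} A "
            f"(< {MIN_RING_SEPARATION} A); clean up vertices before linking"
        )
    b_starts, b_ends = ring_b.edges()
    a_starts, a_ends = ring_a.edges()
    total = 0.0
    for a0, a1 in zip(a_starts, a_ends):
        total += _solid_angle_contributions(a0, a1, b_starts, b_ends)
    lk = total / (4.0 * np.pi)
    nearest = round(lk)
    if abs(lk - nearest) > 1e-6:
        raise GeometryError(
            f"Gauss sum {lk:.8f} for {ring_a.label!r}/{ring_b.label!r} is not "
            "within 1e-6 of an integer; curves may be nearly touching"
        )
    return int(nearest)


def catenation_graph(rings: Sequence[RingCurve]) -> CatenationGraph:
    """Pairwise linking across a ring set, as a graph.

    Nodes are ring labels; an edge carries each nonzero linking number.
    ``is_single_component`` answers whether the set forms one interlocked
    chainmail network.
    """
    if len(rings) < 2:
        raise ValidationError("need at least 2 rings for a catenation graph")
    labels = [r.label for r in rings]
    if len(set(labels)) != len(labels):
        raise ValidationError("ring labels must be unique")
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            lk = linking_number(rings[i], rings[j])
            if lk != 0:
                g.add_edge(labels[i], labels[j], linking_number=lk)
    return CatenationGraph(graph=g)
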