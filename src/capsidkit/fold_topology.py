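"""Johnson-fold element topology: enumeration, feasibility and permutant design.

The Johnson (HK97) fold of a major capsid protein can be decomposed into
three sequence-contiguous structural elements (conventionally N-, beta- and
alpha-elements). A *topology* is the N-to-C order in which those elements
appear in the chain; permuting k elements while preserving each element's
own polarity yields k! candidate topologies. Geometry prunes them: a
candidate junction between element Ei and Ej is only buildable if the
C-terminal anchor of Ei lies close enough to the N-terminal anchor of Ej in
the folded structure to be spanned by a short linker. With the N-element's
N-terminus buried ~42 A from every other element's C-terminus, only the two
topologies that start with the N-element survive - the geometric form of
the published two-topology rule.

Permutant design (the PM1/PM2-style constructs) is pure sequence surgery:
cut the element subsequences and concatenate them in the new order,
tracking per-position provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np

from .errors import GeometryError, SelectionError, ValidationError
from .structures import Structure

__all__ = [
    "ElementPartition",
    "TopologyOrder",
    "Junction",
    "JunctionTable",
    "PermutantDesign",
    "make_partition",
    "enumerate_orders",
    "classify_relation",
    "junction_distances",
    "feasible_orders",
    "design_permutant",
    "DEFAULT_D_MAX",
]

#: Default junction feasibility cutoff (A): bridgeable by a <=6-residue
#: extended linker at ~3.5 A/residue.
DEFAULT_D_MAX = 20.0

_MIN_ELEMENT_LEN = 3


@dataclass(frozen=True)
class ElementPartition:
    """Ordered, contiguous, non-overlapping labeled residue ranges on one chain."""

    chain_id: str
    elements: tuple[tuple[str, tuple[int, int]], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.elements)

    def range_of(self, label: str) -> tuple[int, int]:
        for lab, rng in self.elements:
            if lab == label:
                return rng
        raise KeyError(label)

    def length_of(self, label: str) -> int:
        lo, hi = self.range_of(label)
        return hi - lo + 1

    @property
    def native_order(self) -> "TopologyOrder":
        return TopologyOrder(self.labels)


@dataclass(frozen=True)
class TopologyOrder:
    """N-to-C order of element labels; each element keeps its own polarity."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"duplicate labels in order {self.labels}")

    def __str__(self) -> str:
        return "-".join(self.labels)


@dataclass(frozen=True)
class Junction:
    preceding: str
    following: str
    distance: float  # A, between Calpha anchors in the native structure
    feasible: bool


@dataclass
class JunctionTable:
    """The k-1 junctions a candidate topology requires, with native-frame distances."""

    order: TopologyOrder
    junctions: list[Junction] = field(default_factory=list)

    @property
    def all_feasible(self) -> bool:
        return all(j.feasible for j in self.junctions)


@dataclass
class PermutantDesign:
    """A permuted sequence with per-position provenance."""

    order: TopologyOrder
    sequence: str
    segment_map: list[tuple[str, int]]  # per output position: (source label, source seq_id)


def make_partition(
    chain_length: int,
    boundaries: Sequence[tuple[str, tuple[int, int]]],
    chain_id: str = "A",
) -> ElementPartition:
    """Validate labeled element ranges over a chain of the given length.

    Ranges must be within [1, chain_length], sorted, non-overlapping, and
    contiguous between internal elements (uncovered residues are allowed
    only at the chain termini). Elements shorter than 3 residues are
    rejected - their junction anchors would be degenerate.
    """
    if chain_length < 1:
        raise ValidationError(f"chain_length must be positive, got {chain_length}")
    if not boundaries:
        raise ValidationError("no elements given")
    labels = [label for label, _ in boundaries]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"element labels not unique: {labels}")
    for label, (lo, hi) in boundaries:
        if lo > hi:
            raise ValidationError(f"element {label}: empty range {lo}-{hi}")
        if lo < 1 or hi > chain_length:
            raise ValidationError(
                f"element {label}: range {lo}-{hi} outside chain 1-{chain_length}"
            )
        if hi - lo + 1 < _MIN_ELEMENT_LEN:
            raise ValidationError(
                f"element {label}: length {hi - lo + 1} < {_MIN_ELEMENT_LEN}"
            )
    ordered = sorted(boundaries, key=lambda b: b[1][0])
    if [b[0] for b in ordered] != labels:
        raise ValidationError("element ranges must be given sorted ascending")
    for (la, (_, hi_a)), (lb, (lo_b, _)) in zip(ordered, ordered[1:]):
        if lo_b <= hi_a:
            raise ValidationError(
                f"elements {la} and {lb} overlap ({hi_a} >= {lo_b})"
            )
        if lo_b != hi_a + 1:
            raise ValidationError(
                f"gap between internal elements {la} ({hi_a}) and {lb} ({lo_b})"
            )
    return ElementPartition(chain_id, tuple((l, (lo, hi)) for l, (lo, hi) in ordered))


def enumerate_orders(partition: ElementPartition) -> list[TopologyOrder]:
    """All k! polarity-preserving element orders, lexicographic by label sequence."""
    labels = partition.labels
    if len(labels) < 2:
        raise ValidationError("need at least 2 elements to permute")
    return [TopologyOrder(p) for p in sorted(permutations(labels))]


def classify_relation(order_a: TopologyOrder, order_b: TopologyOrder) -> str:
    """Classify two topologies: identical, circular, or non_circular.

    Circular means one order is a nontrivial cyclic rotation of the other -
    the distinction that separates ordinary circular permutants from the
    genuinely reordered (non-circular) case.
    """
    if set(order_a.labels) != set(order_b.labels):
        raise ValidationError(
            f"label sets differ: {sorted(order_a.labels)} vs {sorted(order_b.labels)}"
        )
    a, b = order_a.labels, order_b.labels
    if a == b:
        return "identical"
    k = len(a)
    for shift in range(1, k):
        if a[shift:] + a[:shift] == b:
            return "circular"
    return "non_circular"


def _anchor_ca(
    structure: Structure,
    chain_id: str,
    seq_range: tuple[int, int],
    end: str,
) -> np.ndarray:
    """Calpha of the first ('n') or last ('c') resolved residue of a range."""
    chain = structure.chain(chain_id)
    if chain is None:
        raise SelectionError(f"chain {chain_id!r} not in structure")
    lo, hi = seq_range
    resolved = [r for r in chain.residues if lo <= r.seq_id <= hi]
    if not resolved:
        raise SelectionError(f"no resolved residues in {chain_id}:{lo}-{hi}")
    res = resolved[0] if end == "n" else resolved[-1]
    ca = res.atom("CA")
    if ca is None:
        raise GeometryError(
            f"anchor residue {res.name}{res.seq_id} of {chain_id}:{lo}-{hi} has no CA atom"
        )
    return ca.position


def junction_distances(
    structure: Structure,
    partition: ElementPartition,
    order: TopologyOrder,
    d_max: float = DEFAULT_D_MAX,
) -> JunctionTable:
    """Anchor distances for each junction a candidate order requires.

    For the junction Ei -> Ej, the distance is between the Calpha of Ei's
    last resolved residue and the Calpha of Ej's first resolved residue,
    measured in the *native* structure: that is the gap a linker would have
    to span if the elements were rewired without refolding.
    """
    if set(order.labels) != set(partition.labels):
        raise ValidationError(
            f"order labels {order.labels} do not match partition {partition.labels}"
        )
    junctions = []
    for prev, nxt in zip(order.labels, order.labels[1:]):
        c_anchor = _anchor_ca(structure, partition.chain_id, partition.range_of(prev), "c")
        n_anchor = _anchor_ca(structure, partition.chain_id, partition.range_of(nxt), "n")
        dist = float(np.linalg.norm(c_anchor - n_anchor))
        junctions.append(Junction(prev, nxt, dist, dist <= d_max))
    return JunctionTable(order=order, junctions=junctions)


def feasible_orders(
    structure: Structure,
    partition: ElementPartition,
    d_max: float = DEFAULT_D_MAX,
) -> list[TopologyOrder]:
    """Topologies whose every junction is bridgeable within d_max.

    Chain-terminal ends of the hypothetical permutant are unconstrained;
    only inter-element junctions are tested. The native order is always in
    the result (its junctions are covalent in the native chain).
    """
    out = []
    for order in enumerate_orders(partition):
        table = junction_distances(structure, partition, order, d_max)
        if table.all_feasible:
            out.append(order)
    native = partition.native_order
    if native not in out:
        # native junctions are real covalent connections; always feasible
        out.append(native)
        out.sort(key=lambda o: o.labels)
    return out


def design_permutant(
    sequence: str,
    partition: ElementPartition,
    order: TopologyOrder,
) -> PermutantDesign:
    """Concatenate element subsequences in a new order (PM-construct design).

    The output covers exactly the partition's residues: its length is the
    sum of element lengths and the residue multiset is preserved. The
    segment map records, for every output position, which element and
    source residue it came from.
    """
    if set(order.labels) != set(partition.labels):
        raise ValidationError(
            f"order labels {order.labels} do not match partition {partition.labels}"
        )
    last_res = max(hi for _, (_, hi) in partition.elements)
    if len(sequence) < last_res:
        raise ValidationError(
            f"sequence length {len(sequence)} shorter than partition end {last_res}"
        )
    parts: list[str] = []
    segmap: list[tuple[str, int]] = []
    for label in order.labels:
        lo, hi = partition.range_of(label)
        parts.append(sequence[lo - 1 : hi])
        segmap.extend((label, seq_id) for seq_id in range(lo, hi + 1))
    return PermutantDesign(order=order, sequence="".join(parts), segment_map=segmap)
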