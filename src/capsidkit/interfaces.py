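"""Subunit-subunit interface characterisation.

Three complementary views of how capsid chains touch:

* atomic contacts - all inter-chain heavy-atom pairs within a distance
  cutoff, found with a k-d tree;
* salt bridges - charged side-chain nitrogen (Arg/Lys/His) against
  carboxylate oxygen (Asp/Glu) across chains, deduplicated per residue
  pair;
* beta-sheet augmentation - ladders of inter-chain backbone N...O hydrogen
  bonds, the mechanism by which a strand donated from a neighbouring chain
  extends a sheet (e.g. the F-strand pairing that cements cement-protein
  dimers into an augmented 8-stranded sheet).

The model is map-derived and has no hydrogens, so the hydrogen-bond
criterion is a donor-acceptor heavy-atom distance with no angle term.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structures import Structure

__all__ = [
    "ContactRecord",
    "SaltBridge",
    "SheetLadder",
    "find_contacts",
    "find_salt_bridges",
    "detect_sheet_augmentation",
    "HBOND_CUTOFF",
    "SALT_BRIDGE_CUTOFF",
    "MIN_LADDER",
]

#: Backbone N...O distance treated as a hydrogen bond (no angle term).
HBOND_CUTOFF = 3.5
#: Charged-group heavy-atom distance treated as a salt bridge.
SALT_BRIDGE_CUTOFF = 4.0
#: Minimum hydrogen bonds for a reportable sheet ladder.
MIN_LADDER = 3

_BASIC_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
_ACIDIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class ContactRecord:
    chain_a: str
    seq_id_a: int
    atom_a: str
    chain_b: str
    seq_id_b: int
    atom_b: str
    distance: float


@dataclass(frozen=True)
class SaltBridge:
    basic_chain: str
    basic_seq_id: int
    basic_res: str
    basic_atom: str
    acidic_chain: str
    acidic_seq_id: int
    acidic_res: str
    acidic_atom: str
    distance: float


@dataclass(frozen=True)
class SheetLadder:
    chain_a: str
    run_a: tuple[int, int]  # inclusive residue range on chain_a
    chain_b: str
    run_b: tuple[int, int]
    orientation: str  # 'parallel' | 'antiparallel'
    h_bond_count: int


def _flat_atoms(structure: Structure, chain_ids, heavy_only: bool = True):
    """(chain, seq_id, atom_name, position) tuples for the given chains."""
    out = []
    for cid in chain_ids:
        chain = structure.chain(cid)
        if chain is None:
            raise ValidationError(f"chain {cid!r} not in structure")
        for res in chain.residues:
            for atom in res.atoms:
                if heavy_only and atom.element.upper() == "H":
                    continue
                out.append((cid, res.seq_id, atom.name, atom.position))
    return out


def find_contacts(
    structure: Structure,
    chains_a: set[str] | list[str],
    chains_b: set[str] | list[str],
    cutoff: float,
) -> list[ContactRecord]:
    """All inter-set heavy-atom pairs within ``cutoff`` Angstrom.

    Spatial indexing via a k-d tree; the result is independent of which
    set is called A and which B (records are emitted A-side first).
    """
    set_a, set_b = set(chains_a), set(chains_b)
    if set_a & set_b:
        raise ValidationError(f"chain sets overlap: {sorted(set_a & set_b)}")
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    atoms_a = _flat_atoms(structure, sorted(set_a))
    atoms_b = _flat_atoms(structure, sorted(set_b))
    if not atoms_a or not atoms_b:
        return []
    pos_a = np.array([a[3] for a in atoms_a])
    pos_b = np.array([b[3] for b in atoms_b])
    tree_b = cKDTree(pos_b)
    contacts = []
    for i, neighbours in enumerate(cKDTree(pos_a).query_ball_tree(tree_b, cutoff)):
        for j in neighbours:
            d = float(np.linalg.norm(pos_a[i] - pos_b[j]))
            ca, ra, na, _ = atoms_a[i]
            cb, rb, nb, _ = atoms_b[j]
            contacts.append(ContactRecord(ca, ra, na, cb, rb, nb, d))
    contacts.sort(key=lambda c: (c.chain_a, c.seq_id_a, c.atom_a, c.chain_b, c.seq_id_b, c.atom_b))
    return contacts


def find_salt_bridges(
    structure: Structure,
    cutoff: float = SALT_BRIDGE_CUTOFF,
) -> list[SaltBridge]:
    """Inter-chain Arg/Lys/His(N) - Asp/Glu(O) pairs within ``cutoff``.

    One bridge per residue pair: the minimum-distance atom pair is kept.
    Residues with unmodelled side chains simply contribute no candidate
    atoms (reported implicitly, never fatal).
    """
    basic, acidic = [], []
    for chain in structure.chains:
        for res in chain.residues:
            rname = res.name.upper()
            if rname in _BASIC_ATOMS:
                for aname in _BASIC_ATOMS[rname]:
                    atom = res.atom(aname)
                    if atom is not None:
                        basic.append((chain.chain_id, res.seq_id, rname, aname, atom.position))
            if rname in _ACIDIC_ATOMS:
                for aname in _ACIDIC_ATOMS[rname]:
                    atom = res.atom(aname)
                    if atom is not None:
                        acidic.append((chain.chain_id, res.seq_id, rname, aname, atom.position))
    if not basic or not acidic:
        return []
    pos_b = np.array([b[4] for b in basic])
    pos_a = np.array([a[4] for a in acidic])
    best: dict[tuple, SaltBridge] = {}
    tree_a = cKDTree(pos_a)
    for i, neighbours in enumerate(cKDTree(pos_b).query_ball_tree(tree_a, cutoff)):
        for j in neighbours:
            cb, rb, nb, ab, _ = basic[i]
            ca, ra, na, aa, _ = acidic[j]
            if cb == ca:
                continue
            d = float(np.linalg.norm(pos_b[i] - pos_a[j]))
            key = (cb, rb, ca, ra)
            if key not in best or d < best[key].distance:
                best[key] = SaltBridge(cb, rb, nb, ab, ca, ra, na, aa, d)
    bridges = sorted(
        best.values(),
        key=lambda s: (s.basic_chain, s.basic_seq_id, s.acidic_chain, s.acidic_seq_id),
    )
    return bridges


def detect_sheet_augmentation(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    hbond_cutoff: float = HBOND_CUTOFF,
    min_ladder: int = MIN_LADDER,
) -> list[SheetLadder]:
    """Inter-chain backbone hydrogen-bond ladders between two chains.

    Backbone N...O pairs within ``hbond_cutoff`` are collected as residue
    pairings (i on chain_a, j on chain_b) and grouped into ladders: runs
    where consecutive pairings step by at most 2 in |i| and |j|. Ladder
    orientation comes from the direction j moves as i increases
    (antiparallel sheets pair ascending i with descending j). Only ladders
    with at least ``min_ladder`` hydrogen bonds are reported.
    """
    ca = structure.chain(chain_a)
    cb = structure.chain(chain_b)
    if ca is None or cb is None:
        raise ValidationError(f"chains {chain_a!r}/{chain_b!r} not both in structure")

    def backbone(chain, name):
        out = []
        for res in chain.residues:
            atom = res.atom(name)
            if atom is not None:
                out.append((res.seq_id, atom.position))
        return out

    n_a, o_a = backbone(ca, "N"), backbone(ca, "O")
    n_b, o_b = backbone(cb, "N"), backbone(cb, "O")

    # hydrogen bonds as residue pairs (i, j) with bond multiplicity
    bonds: dict[tuple[int, int], int] = defaultdict(int)
    for donors, acceptors in ((n_a, o_b), (o_a, n_b)):
        if not donors or not acceptors:
            continue
        pos_d = np.array([p for _, p in donors])
        pos_acc = np.array([p for _, p in acceptors])
        tree = cKDTree(pos_acc)
        for i, neighbours in enumerate(cKDTree(pos_d).query_ball_tree(tree, hbond_cutoff)):
            for j in neighbours:
                bonds[(donors[i][0], acceptors[j][0])] += 1
    if not bonds:
        return []

    # group residue pairings into ladders by proximity in (i, j) index space
    pairs = sorted(bonds)
    ladders: list[list[tuple[int, int]]] = []
    for pair in pairs:
        placed = False
        for ladder in ladders:
            if any(abs(pair[0] - p[0]) <= 2 and abs(pair[1] - p[1]) <= 2 for p in ladder):
                ladder.append(pair)
                placed = True
                break
        if not placed:
            ladders.append([pair])

    out = []
    for ladder in ladders:
        count = sum(bonds[p] for p in ladder)
        if count < min_ladder:
            continue
        i_vals = [p[0] for p in ladder]
        j_vals = [p[1] for p in ladder]
        distinct = sorted(set(zip(i_vals, j_vals)))
        if len(distinct) >= 2:
            slope = np.polyfit([p[0] for p in distinct], [p[1] for p in distinct], 1)[0]
            orientation = "parallel" if slope >= 0 else "antiparallel"
        else:
            orientation = "parallel"
        out.append(
            SheetLadder(
                chain_a=chain_a,
                run_a=(min(i_vals), max(i_vals)),
                chain_b=chain_b,
                run_b=(min(j_vals), max(j_vals)),
                orientation=orientation,
                h_bond_count=count,
            )
        )
    out.sort(key=lambda l: l.run_a)
    return out
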