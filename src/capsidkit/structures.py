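"""Macromolecular structure I/O, selection and superposition.

The in-memory model is a light hierarchy (Structure -> Chain -> Residue ->
AtomRecord) holding author residue numbering, which is what every selection
in this toolkit uses: ranges such as 5-331 are inclusive, 1-based, authored
numbers. Parsing and serialisation of PDB/mmCIF delegate to gemmi; FASTA to
Biopython.

Superposition is closed-form least squares over proper rotations (SVD with
determinant correction), the standard Kabsch procedure. RMSD ensembles over
quasi-equivalent conformers (the seven cement-protein or major-capsid-protein
copies of an icosahedral asymmetric unit) are built on top of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptySelectionError,
    FormatError,
    GeometryError,
    ParseError,
    SelectionError,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
TRACE_ATOMS = ("CA",)

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "Structure",
    "RigidTransform",
    "Selection",
    "read_structure",
    "write_structure",
    "read_fasta",
    "write_fasta",
    "select",
    "superpose",
    "pairwise_rmsd",
    "BACKBONE_ATOMS",
    "TRACE_ATOMS",
]


@dataclass
class AtomRecord:
    """One atom: label, element, position (Angstrom), occupancy, B (Angstrom^2)."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} not in [0,1]")


@dataclass
class Residue:
    """Residue with authored (1-based) number and uniquely named atoms."""

    seq_id: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seq_id < 1:
            raise ValueError(f"residue {self.name}: seq_id must be >= 1, got {self.seq_id}")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"residue {self.name}{self.seq_id}: duplicate atom names")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    """Chain of residues ordered by strictly increasing seq_id."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError(f"chain {self.chain_id}: seq_ids not strictly increasing")

    def residue(self, seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """A set of uniquely identified chains plus free-form metadata."""

    chains: list[Chain] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain_ids in structure")

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def all_positions(self) -> np.ndarray:
        pos = [a.position for c in self.chains for r in c.residues for a in r.atoms]
        if not pos:
            return np.empty((0, 3))
        return np.array(pos)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal within 1e-8")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


# ---------------------------------------------------------------------------
# I/O


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in ("pdb", "mmcif"):
            raise FormatError(f"unknown structure format {fmt!r} (expected pdb/mmcif/auto)")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise FormatError(f"cannot infer format from suffix {suffix!r} of {path}")


def _dedupe_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, tie broken by altloc label."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        elif (atom.occ, -ord(atom.altloc or "z")) > (prev.occ, -ord(prev.altloc or "z")):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the toolkit's hierarchy.

    All ATOM/HETATM records are kept; author residue numbering is preserved.
    Alternate locations are collapsed to the highest-occupancy conformer
    (deterministic label-order tie-break).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            gst = gemmi.read_pdb(str(path))
        else:
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if len(gst) == 0:
        raise ParseError(f"{path}: no models found")
    model = gst[0]
    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    b_iso=a.b_iso,
                )
                for a in _dedupe_altlocs(gres)
            ]
            residues.append(Residue(seq_id=gres.seqid.num, name=gres.name, atoms=atoms))
        chains.append(Chain(chain_id=gchain.name, residues=residues))
    return Structure(chains=chains, metadata={"source": str(path), "format": fmt})


def _to_gemmi(structure: Structure, name: str = "capsidkit") -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = name
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    gst.add_model(model)
    gst.setup_entities()
    return gst


#: PDB fixed-column format cannot address more than this many chains/atoms.
_PDB_MAX_CHAINS = 62
_PDB_MAX_ATOMS = 99999


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write PDB or mmCIF. PDB is refused beyond its fixed-column capacity."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        if len(structure.chains) > _PDB_MAX_CHAINS or structure.n_atoms() > _PDB_MAX_ATOMS:
            raise FormatError(
                f"PDB format cannot hold {len(structure.chains)} chains / "
                f"{structure.n_atoms()} atoms (limits: {_PDB_MAX_CHAINS} chains, "
                f"{_PDB_MAX_ATOMS} atoms); write mmCIF instead"
            )
        _to_gemmi(structure).write_pdb(str(path))
    else:
        _to_gemmi(structure).make_mmcif_document().write_file(str(path))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Selection


@dataclass
class Selection:
    """Resolved coordinate selection with a report of skipped residues."""

    positions: np.ndarray  # (N, 3)
    residue_ids: list[int]  # seq_id per position (repeated across atoms)
    atom_names: list[str]
    gaps: list[int]  # requested seq_ids with no resolved residue/atom

    def __len__(self) -> int:
        return len(self.positions)


def select(
    structure: Structure,
    chain_id: str,
    seq_range: tuple[int, int],
    atom_names: Iterable[str] | None = TRACE_ATOMS,
) -> Selection:
    """Select atom positions from an inclusive authored residue range.

    Missing residues (unresolved in the model) are skipped and reported in
    ``Selection.gaps``; an entirely empty result is an explicit error.
    With ``atom_names=None`` every atom of each residue is taken.
    """
    chain = structure.chain(chain_id)
    if chain is None:
        raise SelectionError(
            f"chain {chain_id!r} not in structure (have {structure.chain_ids})"
        )
    lo, hi = seq_range
    if lo > hi or lo < 1:
        raise SelectionError(f"invalid residue range {lo}-{hi}")
    wanted = set(atom_names) if atom_names is not None else None
    positions: list[np.ndarray] = []
    res_ids: list[int] = []
    names: list[str] = []
    present = {r.seq_id: r for r in chain.residues}
    gaps: list[int] = []
    for seq_id in range(lo, hi + 1):
        res = present.get(seq_id)
        if res is None:
            gaps.append(seq_id)
            continue
        got_any = False
        for atom in res.atoms:
            if wanted is None or atom.name in wanted:
                positions.append(atom.position)
                res_ids.append(seq_id)
                names.append(atom.name)
                got_any = True
        if not got_any:
            gaps.append(seq_id)
    if not positions:
        raise EmptySelectionError(
            f"selection {chain_id}:{lo}-{hi} (atoms {sorted(wanted) if wanted else 'all'}) "
            "resolved to zero atoms"
        )
    return Selection(np.array(positions), res_ids, names, gaps)


# ---------------------------------------------------------------------------
# Superposition


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation superposition of paired point sets.

    Returns the transform T minimising RMSD = sqrt(mean ||T(m_i) - t_i||^2)
    over rotations with det = +1 (Kabsch; reflections are disallowed via the
    SVD determinant correction).
    """
    m = np.asarray(mobile, dtype=float)
    t = np.asarray(target, dtype=float)
    if m.shape != t.shape or m.ndim != 2 or m.shape[1] != 3:
        raise GeometryError(f"point sets must both be Nx3, got {m.shape} vs {t.shape}")
    n = m.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")
    mc = m.mean(axis=0)
    tc = t.mean(axis=0)
    m0 = m - mc
    t0 = t - tc
    if np.linalg.matrix_rank(m0, tol=1e-9) < 2 or np.linalg.matrix_rank(t0, tol=1e-9) < 2:
        raise GeometryError("degenerate (collinear or coincident) point set")
    h = m0.T @ t0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    transform = RigidTransform(rot, trans)
    diff = transform.apply(m) - t
    rmsd = math.sqrt(float(np.mean(np.sum(diff * diff, axis=1))))
    return transform, rmsd


def pairwise_rmsd(
    conformers: Sequence[tuple[str, np.ndarray]],
) -> tuple[np.ndarray, list[str]]:
    """Symmetric matrix of superposition RMSDs between labeled position sets.

    Every conformer must present the same number of positions (a shared
    selection resolved in each); mismatches are reported by label.
    """
    if len(conformers) < 2:
        raise GeometryError("need at least 2 conformers")
    labels = [label for label, _ in conformers]
    sizes = {label: np.asarray(pos).shape for label, pos in conformers}
    shapes = set(sizes.values())
    if len(shapes) > 1:
        bad = ", ".join(f"{k}:{v[0]}" for k, v in sizes.items())
        raise SelectionError(f"conformers expose unequal selections ({bad})")
    k = len(conformers)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _, rmsd = superpose(conformers[i][1], conformers[j][1])
            mat[i, j] = mat[j, i] = rmsd
    return mat, labels


def conformer_rmsd_matrix(
    structure: Structure,
    chain_ids: Sequence[str],
    seq_range: tuple[int, int],
    atom_names: Iterable[str] = BACKBONE_ATOMS,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise backbone RMSDs among quasi-equivalent chains.

    The selection is restricted to residues resolved (with all requested
    atoms) in *every* chain, as is standard when comparing partially
    disordered conformers.
    """
    wanted = tuple(atom_names)
    per_chain: dict[str, dict[int, np.ndarray]] = {}
    for cid in chain_ids:
        sel = select(structure, cid, seq_range, wanted)
        by_res: dict[int, list[np.ndarray]] = {}
        for pos, rid in zip(sel.positions, sel.residue_ids):
            by_res.setdefault(rid, []).append(pos)
        per_chain[cid] = {
            rid: np.array(p) for rid, p in by_res.items() if len(p) == len(wanted)
        }
    shared = sorted(set.intersection(*(set(d) for d in per_chain.values())))
    if not shared:
        raise SelectionError(
            f"no residues of {seq_range} resolve with atoms {wanted} in all chains"
        )
    conformers = [
        (cid, np.concatenate([per_chain[cid][rid] for rid in shared]))
        for cid in chain_ids
    ]
    return pairwise_rmsd(conformers)
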