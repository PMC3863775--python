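"""Icosahedral capsid lattices: T-number arithmetic and symmetry expansion.

A Caspar-Klug lattice is indexed by non-negative integers (h, k); its
triangulation number T = h^2 + hk + k^2 counts both the quasi-equivalent
subunit conformers per icosahedral asymmetric unit and, via 60T, the
subunits of the full shell (12 pentons + 10(T-1) hexons). When h != k and
both are nonzero the lattice is chiral: laevo vs dextro. A T = 7 shell
(h,k) = (1,2) or (2,1) is the classic case.

The 60 proper rotations of the icosahedral group I are generated here by
closure from a 5-fold and a 2-fold generator, in either of two documented
axis conventions, and are used to expand one asymmetric unit into a full
capsid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .structures import Chain, RigidTransform, Structure

__all__ = [
    "CapsidLattice",
    "SymmetryOperatorSet",
    "t_number",
    "capsid_census",
    "icosahedral_operators",
    "expand_asymmetric_unit",
    "max_diameter",
]

_PHI = (1.0 + math.sqrt(5.0)) / 2.0


def t_number(h: int, k: int) -> int:
    """Triangulation number T = h^2 + hk + k^2 for lattice indices (h, k)."""
    if h < 0 or k < 0:
        raise ValidationError(f"lattice indices must be non-negative, got ({h}, {k})")
    if h == 0 and k == 0:
        raise ValidationError("lattice indices (0, 0) are not a capsid lattice")
    return h * h + h * k + k * k


@dataclass(frozen=True)
class CapsidLattice:
    """(h, k) lattice with its T number and, when chiral, handedness."""

    h: int
    k: int
    handedness: str | None = None  # 'laevo' | 'dextro' | None (achiral)

    def __post_init__(self) -> None:
        t_number(self.h, self.k)  # validates indices
        chiral = self.h != self.k and self.h != 0 and self.k != 0
        if chiral and self.handedness not in ("laevo", "dextro"):
            raise ValidationError(
                f"(h,k)=({self.h},{self.k}) is chiral; handedness must be laevo or dextro"
            )
        if not chiral and self.handedness is not None:
            raise ValidationError(
                f"(h,k)=({self.h},{self.k}) is achiral; handedness must be None"
            )

    @property
    def t_number(self) -> int:
        return t_number(self.h, self.k)


def _valid_t_numbers(up_to: int) -> set[int]:
    out = set()
    m = int(math.isqrt(up_to)) + 1
    for h in range(m + 1):
        for k in range(m + 1):
            if (h, k) != (0, 0) and h * h + h * k + k * k <= up_to:
                out.add(h * h + h * k + k * k)
    return out


def capsid_census(t: int) -> dict[str, int]:
    """Subunit bookkeeping of a T-lattice shell.

    60T subunits arrange as 12 pentons and 10(T-1) hexons; one icosahedral
    asymmetric unit holds T quasi-equivalent subunits.
    """
    if t < 1 or t not in _valid_t_numbers(t):
        raise ValidationError(f"{t} is not a triangulation number (h^2+hk+k^2)")
    return {
        "subunits": 60 * t,
        "pentons": 12,
        "hexons": 10 * (t - 1),
        "subunits_per_asym_unit": t,
    }


@dataclass
class SymmetryOperatorSet:
    """The 60 proper rotations of the icosahedral group about the origin."""

    operators: list[RigidTransform]
    convention: str = "I222"

    def __len__(self) -> int:
        return len(self.operators)

    def __iter__(self):
        return iter(self.operators)

    def rotation_order_census(self) -> dict[int, int]:
        """Count operators by rotational order (1, 2, 3 or 5).

        For a proper rotation by angle theta, trace = 1 + 2 cos(theta);
        in the icosahedral group the orders are 1 (identity), 2, 3 and 5.
        """
        census: dict[int, int] = {}
        for op in self.operators:
            cos_t = (float(np.trace(op.rotation)) - 1.0) / 2.0
            theta = math.acos(min(1.0, max(-1.0, cos_t)))
            if theta < 1e-6:
                order = 1
            elif abs(theta - math.pi) < 1e-6:
                order = 2
            elif abs(theta - 2 * math.pi / 3) < 1e-6:
                order = 3
            elif min(abs(theta - 2 * math.pi / 5), abs(theta - 4 * math.pi / 5)) < 1e-6:
                # elements rotated by 72 or 144 degrees both have order 5
                order = 5
            else:
                raise ValidationError(
                    f"rotation angle {math.degrees(theta):.3f} deg not icosahedral"
                )
            census[order] = census.get(order, 0) + 1
        return census


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


def _close_group(generators: list[np.ndarray], expected: int = 60) -> list[np.ndarray]:
    """Close a set of rotations under composition (breadth-first, deduplicated)."""
    ops: list[np.ndarray] = [np.eye(3)]

    def known(r: np.ndarray) -> bool:
        return any(np.allclose(r, o, atol=1e-9) for o in ops)

    frontier = [g for g in generators if not known(g)]
    ops.extend(frontier)
    while frontier:
        new = []
        for f in frontier:
            for g in generators:
                prod = f @ g
                if not any(np.allclose(prod, o, atol=1e-9) for o in ops + new):
                    new.append(prod)
        ops.extend(new)
        frontier = new
        if len(ops) > expected:
            raise ValidationError("generator closure exceeded expected group order")
    return ops


def icosahedral_operators(convention: str = "I222") -> SymmetryOperatorSet:
    """The 60 rotations of I in a documented axis convention.

    I222: two-fold axes along x, y and z (icosahedron vertices at cyclic
    permutations of (0, +-1, +-phi)). In25: the I222 frame rotated so one
    five-fold axis lies along z.
    """
    v5 = np.array([0.0, 1.0, _PHI])  # a vertex = 5-fold axis in the I222 frame
    g5 = _axis_rotation(v5, 2.0 * math.pi / 5.0)
    g2 = _axis_rotation(np.array([0.0, 0.0, 1.0]), math.pi)
    rotations = _close_group([g5, g2])
    if len(rotations) != 60:
        raise ValidationError(f"icosahedral closure produced {len(rotations)} != 60 ops")
    if convention == "I222":
        frame = np.eye(3)
    elif convention == "In25":
        # conjugate so the chosen 5-fold axis maps onto z
        axis = v5 / np.linalg.norm(v5)
        z = np.array([0.0, 0.0, 1.0])
        rot_axis = np.cross(axis, z)
        angle = math.acos(float(np.clip(axis @ z, -1.0, 1.0)))
        frame = _axis_rotation(rot_axis, angle)
    else:
        raise ValidationError(f"unknown convention {convention!r} (I222 or In25)")
    ops = [
        RigidTransform(frame @ r @ frame.T, np.zeros(3)) for r in rotations
    ]
    # deterministic ordering: identity first, then lexicographic by matrix
    ops.sort(key=lambda op: (-np.trace(op.rotation), tuple(np.round(op.rotation.ravel(), 9))))
    return SymmetryOperatorSet(operators=ops, convention=convention)


def expand_asymmetric_unit(
    asym: Structure,
    ops: SymmetryOperatorSet,
    warn_threshold_atoms: int = 2_000_000,
) -> Structure:
    """Replicate one asymmetric unit under all 60 rotations.

    Chains are renamed ``<orig>_<op index 00..59>``; copy 00 (identity
    operator) is bit-identical to the input. The icosahedral centre is
    assumed at the origin; a structure that already looks expanded (very
    many chains) triggers a warning flag in the output metadata rather
    than an error.
    """
    already_expanded = len(asym.chains) >= 60
    chains: list[Chain] = []
    for idx, op in enumerate(ops.operators):
        for chain in asym.chains:
            new_residues = []
            for res in chain.residues:
                new_atoms = [
                    type(a)(
                        name=a.name,
                        element=a.element,
                        position=op.apply(a.position),
                        occupancy=a.occupancy,
                        b_iso=a.b_iso,
                    )
                    for a in res.atoms
                ]
                new_residues.append(type(res)(seq_id=res.seq_id, name=res.name, atoms=new_atoms))
            chains.append(Chain(chain_id=f"{chain.chain_id}_{idx:02d}", residues=new_residues))
    meta = dict(asym.metadata)
    meta["expanded_from_chains"] = len(asym.chains)
    meta["symmetry_convention"] = ops.convention
    if already_expanded:
        meta["warning"] = (
            f"input had {len(asym.chains)} chains; it may already be an expanded capsid"
        )
    return Structure(chains=chains, metadata=meta)


def max_diameter(structure: Structure) -> float:
    """2 x the largest atomic radius from the icosahedral centre (origin).

    Defined over atom centres, not a density envelope, so it slightly
    underestimates map-level figures.
    """
    pos = structure.all_positions()
    if pos.shape[0] < 2:
        raise ValidationError("need at least 2 atoms for a diameter")
    return 2.0 * float(np.max(np.linalg.norm(pos, axis=1)))
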