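"""Synthetic fixtures with known ground truth for every analysis module.

Each generator emulates one geometric situation the analyses are built
for, at the scale the real system exhibits it:

* a three-element fold whose junction anchors sit at requested distances
  (cross-junctions ~5 A bridgeable, the N-element's N-terminus ~42 A
  remote - the configuration that prunes 3! = 6 topologies to 2);
* a toy icosahedral asymmetric unit with T quasi-equivalent placeholder
  subunits, expandable to the 60T-subunit shell;
* closed ring sets with designed pairwise linking numbers, up to a
  12-ring icosahedral chainmail interlocked at the 3-fold contacts;
* band-limited noisy map pairs whose true resolution is known;
* ideal two-strand beta-sheet pairings for hydrogen-bond ladder
  detection.

All draws go through one seeded generator, so a fixture is byte-identical
for the same spec + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .capsid_lattice import icosahedral_operators
from .chainmail import RingCurve
from .density_metrics import DensityMap
from .errors import GeometryError, ValidationError
from .fold_topology import ElementPartition, make_partition
from .structures import AtomRecord, Chain, Residue, Structure

__all__ = [
    "FixtureSpec",
    "make_three_element_fold",
    "make_toy_capsid",
    "make_ring_set",
    "make_map_pair",
    "make_sheet_pair",
    "make_sequence",
]

_PHI = (1.0 + math.sqrt(5.0)) / 2.0

#: The element lengths of the reference three-element fold (a 331-residue
#: chain split 1-168 / 169-241 / 242-331).
DEFAULT_ELEMENT_LENGTHS = (168, 73, 90)
#: Bridgeable inter-element anchor distance (A).
DEFAULT_CROSS_JUNCTION = 5.0
#: Buried-N-terminus distance to the other elements' C-termini (A).
DEFAULT_REMOTE_N = 42.0

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind + parameters + seed."""

    kind: str  # three_element_fold | toy_capsid | ring_set | map_pair | sheet_pair | sequence
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    _KINDS = (
        "three_element_fold",
        "toy_capsid",
        "ring_set",
        "map_pair",
        "sheet_pair",
        "sequence",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown fixture kind {self.kind!r}")

    def generate(self):
        fn = {
            "three_element_fold": make_three_element_fold,
            "toy_capsid": make_toy_capsid,
            "ring_set": make_ring_set,
            "map_pair": make_map_pair,
            "sheet_pair": make_sheet_pair,
            "sequence": make_sequence,
        }[self.kind]
        return fn(seed=self.seed, **self.parameters)


def _ca_residue(seq_id: int, position: np.ndarray) -> Residue:
    return Residue(
        seq_id=seq_id,
        name="GLY",
        atoms=[AtomRecord(name="CA", element="C", position=position)],
    )


def _wiggly_path(start: np.ndarray, end: np.ndarray, n: int, rng) -> np.ndarray:
    """n points from start to end (endpoints exact) with a non-degenerate
    sinusoidal detour so consecutive points never coincide."""
    t = np.linspace(0.0, 1.0, n)
    base = np.outer(1 - t, start) + np.outer(t, end)
    direction = end - start
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        direction = np.array([1.0, 0.0, 0.0])
        norm = 1.0
    direction = direction / norm
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    perp2 = np.cross(direction, perp)
    envelope = np.sin(np.pi * t)  # zero at both anchors
    waves = math.ceil(n / 4)
    detour = (
        np.outer(envelope * np.sin(waves * 2 * np.pi * t), perp)
        + np.outer(envelope * np.cos(waves * 2 * np.pi * t), perp2)
    ) * 2.0
    jitter = rng.normal(scale=0.05, size=(n, 3)) * envelope[:, None]
    return base + detour + jitter


def make_three_element_fold(
    lengths: tuple[int, int, int] = DEFAULT_ELEMENT_LENGTHS,
    cross_junction: float = DEFAULT_CROSS_JUNCTION,
    remote_n_terminus: float = DEFAULT_REMOTE_N,
    seed: int = 0,
) -> tuple[Structure, ElementPartition]:
    """Calpha-only model of a three-element fold with controlled junctions.

    Every element's C-terminal anchor sits exactly ``cross_junction`` A
    from every other element's N-terminal anchor, except the first
    element's N-terminus, which is placed ``remote_n_terminus`` A from
    both other C-termini - the buried-terminus geometry that forbids any
    topology placing another element before the first one.
    """
    if any(n < 3 for n in lengths):
        raise ValidationError(f"element lengths must be >= 3, got {lengths}")
    if len(lengths) != 3:
        raise ValidationError("exactly three elements expected")
    c = float(cross_junction)
    r = float(remote_n_terminus)
    if c <= 0:
        raise GeometryError("cross_junction must be positive")
    rho, delta = 0.8 * c, 0.6 * c  # rho^2 + delta^2 = c^2
    if r < rho:
        raise GeometryError(
            f"remote_n_terminus {r} A unsatisfiable: must exceed {rho:.2f} A"
        )
    # C-terminal anchors of the three elements on a circle of radius rho (z=0)
    angles = np.deg2rad([90.0, 210.0, 330.0])
    lasts = [np.array([rho * math.cos(a), rho * math.sin(a), 0.0]) for a in angles]
    # N-terminal anchors of elements 2 and 3 on the z-axis at +-delta
    firsts = {
        1: np.array([0.0, 0.0, delta]),
        2: np.array([0.0, 0.0, -delta]),
    }
    # remote N-terminus of element 1, equidistant (r) from every C-anchor
    z0 = math.sqrt(r * r - rho * rho)
    firsts[0] = np.array([0.0, 0.0, z0])

    rng = np.random.default_rng(seed)
    residues = []
    seq_id = 1
    boundaries = []
    labels = ("N", "beta", "alpha")
    for e, (label, n_res) in enumerate(zip(labels, lengths)):
        path = _wiggly_path(firsts[e], lasts[e], n_res, rng)
        start = seq_id
        for pos in path:
            residues.append(_ca_residue(seq_id, pos))
            seq_id += 1
        boundaries.append((label, (start, seq_id - 1)))
    structure = Structure(
        chains=[Chain(chain_id="A", residues=residues)],
        metadata={"fixture": "three_element_fold", "seed": seed},
    )
    partition = make_partition(sum(lengths), boundaries, chain_id="A")
    return structure, partition


# ---------------------------------------------------------------------------
# Toy capsid

# icosahedron vertex (5-fold), adjacent face centre (3-fold) and edge
# midpoint (2-fold) spanning one asymmetric unit, in the I222 frame
_V5 = np.array([0.0, 1.0, _PHI])
_V5B = np.array([0.0, -1.0, _PHI])
_V5C = np.array([_PHI, 0.0, 1.0])


def _asym_unit_triangle() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u1 = _V5 / np.linalg.norm(_V5)
    f3 = (_V5 + _V5B + _V5C) / 3.0
    u2 = f3 / np.linalg.norm(f3)
    e2 = (_V5 + _V5B) / 2.0
    u3 = e2 / np.linalg.norm(e2)
    return u1, u2, u3


# barycentric placements (5-fold, 3-fold, 2-fold weights) for up to 7
# quasi-equivalent subunits strictly inside one asymmetric unit
_QUASI_WEIGHTS = {
    1: [(0.4, 0.3, 0.3)],
    3: [(0.6, 0.2, 0.2), (0.2, 0.6, 0.2), (0.2, 0.2, 0.6)],
    7: [
        (0.70, 0.15, 0.15),
        (0.50, 0.35, 0.15),
        (0.50, 0.15, 0.35),
        (0.30, 0.50, 0.20),
        (0.30, 0.20, 0.50),
        (0.15, 0.45, 0.40),
        (0.40, 0.30, 0.30),
    ],
}


def make_toy_capsid(
    t: int = 7,
    subunit_atoms: int = 5,
    radius: float = 100.0,
    seed: int = 0,
) -> Structure:
    """Asymmetric unit with ``t`` placeholder subunits on a sphere.

    Subunit centres sit at distinct quasi-equivalent positions strictly
    inside one icosahedral asymmetric unit (so expansion under the 60
    rotations yields 60 t distinct subunits); each subunit is a compact
    blob of ``subunit_atoms`` pseudo-Calpha atoms with seeded jitter.
    The census (chains, atoms) is seed-independent.
    """
    if t not in _QUASI_WEIGHTS:
        raise ValidationError(f"unsupported T number {t} (supported: 1, 3, 7)")
    if subunit_atoms < 1:
        raise ValidationError("subunit_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    u1, u2, u3 = _asym_unit_triangle()
    chains = []
    for s_idx, (w1, w2, w3) in enumerate(_QUASI_WEIGHTS[t]):
        centre_dir = w1 * u1 + w2 * u2 + w3 * u3
        centre = radius * centre_dir / np.linalg.norm(centre_dir)
        residues = []
        for a_idx in range(subunit_atoms):
            angle = 2.0 * math.pi * a_idx / max(subunit_atoms, 2)
            local = 2.0 * np.array(
                [math.cos(angle), math.sin(angle), 0.25 * a_idx]
            )
            local = local + rng.normal(scale=0.2, size=3)
            residues.append(_ca_residue(a_idx + 1, centre + local))
        chains.append(Chain(chain_id=f"S{s_idx + 1}", residues=residues))
    return Structure(
        chains=chains,
        metadata={"fixture": "toy_capsid", "t": t, "seed": seed, "radius": radius},
    )


# ---------------------------------------------------------------------------
# Ring sets


def _circle(
    centre: np.ndarray, radius: float, normal: np.ndarray, n: int, label: str
) -> RingCurve:
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    pts = centre + radius * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
    return RingCurve(pts, label=label)


def _icosahedron_vertices() -> np.ndarray:
    verts = []
    for a, b in ((1.0, _PHI), (-1.0, _PHI), (1.0, -_PHI), (-1.0, -_PHI)):
        verts.append([0.0, a, b])
        verts.append([a, b, 0.0])
        verts.append([b, 0.0, a])
    v = np.array(verts)
    return v / np.linalg.norm(v[0])


def _capsid_chainmail_rings(
    n_vertices_per_ring: int = 240,
    sphere_radius: float = 50.0,
    ring_half_angle_deg: float = 33.0,
    weave_amplitude: float = 4.0,
    bump_sigma_deg: float = 6.0,
) -> list[RingCurve]:
    """12 rings around icosahedral 5-fold axes, interlocked at their crossings.

    Adjacent-vertex rings (axis separation ~63.4 deg) with angular radius
    37 deg intersect on the sphere at two points; at each crossing one
    ring is pushed radially outward and the other inward, with the
    over/under choice taken from the sign of the crossing point against
    v_i x v_j - a rule that is automatically antisymmetric between the
    two rings and opposite at the two crossings, producing |Lk| = 1 for
    every adjacent pair.
    """
    verts = _icosahedron_vertices()
    alpha = math.radians(ring_half_angle_deg)
    sigma = math.radians(bump_sigma_deg)
    rings = []
    for i, v in enumerate(verts):
        ref = np.array([1.0, 0.0, 0.0])
        if abs(v @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(v, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v, e1)
        # crossing azimuths and over/under signs against each adjacent ring
        crossings = []
        for j, w in enumerate(verts):
            if j == i:
                continue
            cos_g = float(np.clip(v @ w, -1.0, 1.0))
            gamma = math.acos(cos_g)
            if gamma >= 2.0 * alpha:  # non-adjacent: circles do not intersect
                continue
            p = math.cos(alpha) / (1.0 + cos_g)
            q_sq = 1.0 - 2.0 * p * p * (1.0 + cos_g)
            if q_sq <= 0:
                continue
            q = math.sqrt(q_sq)
            n_hat = np.cross(v, w)
            n_hat /= np.linalg.norm(n_hat)
            for sign_q in (+1.0, -1.0):
                u = p * (v + w) + sign_q * q * n_hat
                tang = u - math.cos(alpha) * v
                theta = math.atan2(float(tang @ e2), float(tang @ e1))
                # ring i goes over where the crossing lies on the +(v x w) side
                crossings.append((theta, weave_amplitude * sign_q))
        theta_grid = np.linspace(0.0, 2.0 * math.pi, n_vertices_per_ring, endpoint=False)
        r_theta = np.full_like(theta_grid, sphere_radius)
        for theta_c, amp in crossings:
            d = np.angle(np.exp(1j * (theta_grid - theta_c)))  # wrapped difference
            r_theta += amp * np.exp(-0.5 * (d / sigma) ** 2)
        dirs = (
            math.cos(alpha) * v[None, :]
            + math.sin(alpha)
            * (np.outer(np.cos(theta_grid), e1) + np.outer(np.sin(theta_grid), e2))
        )
        rings.append(RingCurve(r_theta[:, None] * dirs, label=f"R{i + 1:02d}"))
    return rings


def make_ring_set(
    pattern: str = "hopf",
    k: int = 3,
    radius: float = 10.0,
    n_vertices: int = 72,
    seed: int = 0,
) -> list[RingCurve]:
    """Closed polygonal ring sets with designed linking ground truth.

    Patterns: ``hopf`` (two rings, |Lk| = 1), ``unlinked_k`` (k distant
    coplanar rings, all pairs 0), ``chain_k`` (k rings Hopf-chained in a
    row: consecutive pairs |Lk| = 1, others 0), ``capsid_lattice``
    (12 rings interlocked like the capsomer rings of an icosahedral
    chainmail; connected catenation graph over all 12).
    """
    rng = np.random.default_rng(seed)
    jitter = rng.normal(scale=1e-3, size=3)  # breaks exact coincidences, keeps truth
    if pattern == "hopf":
        a = _circle(np.zeros(3), radius, [0, 0, 1], n_vertices, "A")
        b = _circle(
            np.array([radius, 0.0, 0.0]) + jitter, radius, [0, 1, 0], n_vertices, "B"
        )
        return [a, b]
    if pattern == "unlinked_k":
        return [
            _circle(
                np.array([3.0 * radius * i, 0.0, 0.0]), radius, [0, 0, 1],
                n_vertices, f"U{i + 1}",
            )
            for i in range(k)
        ]
    if pattern == "chain_k":
        rings = []
        for i in range(k):
            normal = [0, 0, 1] if i % 2 == 0 else [0, 1, 0]
            centre = np.array([1.3 * radius * i, 0.0, 0.0]) + (jitter if i % 2 else 0.0)
            rings.append(_circle(centre, radius, normal, n_vertices, f"C{i + 1}"))
        return rings
    if pattern == "capsid_lattice":
        return _capsid_chainmail_rings()
    raise ValidationError(f"unknown ring pattern {pattern!r}")


# ---------------------------------------------------------------------------
# Map pairs


def make_map_pair(
    box: int = 64,
    voxel_size: float = 1.5,
    band_limit: float = 6.0,
    snr: float = 4.0,
    seed: int = 0,
) -> tuple[DensityMap, DensityMap, float]:
    """Two noisy realizations of one band-limited random volume.

    The common signal is white noise low-passed at 1/band_limit, so its
    spectrum is flat in the pass band and (up to the cosine edge) zero
    beyond; each output adds independent white noise scaled to the
    requested real-space signal-to-noise variance ratio. The FSC of the
    pair therefore crosses 0.143 at the band limit, which is returned as
    the ground truth.
    """
    if band_limit < 2.0 * voxel_size:
        raise ValidationError(
            f"band limit {band_limit} A beyond Nyquist ({2 * voxel_size} A)"
        )
    if snr < 0:
        raise ValidationError("snr must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((box, box, box))
    # strict band limit: the boundary sphere itself carries no signal, so
    # the FSC drop sits exactly at 1/band_limit
    freqs = np.fft.fftfreq(box, d=voxel_size)
    s = np.sqrt(
        freqs[:, None, None] ** 2 + freqs[None, :, None] ** 2 + freqs[None, None, :] ** 2
    )
    f = np.fft.fftn(raw)
    f[s >= 1.0 / band_limit] = 0.0
    sig = np.fft.ifftn(f).real
    sig_std = float(sig.std())
    noise_std = sig_std / math.sqrt(snr) if snr > 0 else (sig_std if sig_std > 0 else 1.0)
    if snr == 0:
        sig = np.zeros_like(sig)
    maps = []
    for _ in range(2):
        noise = rng.standard_normal((box, box, box)) * noise_std
        maps.append(DensityMap(grid=sig + noise, voxel_size=voxel_size))
    return maps[0], maps[1], band_limit


# ---------------------------------------------------------------------------
# Sheet pairs


def make_sheet_pair(
    n_pairs: int = 2,
    parallel: bool = False,
    strand_separation: float = 4.9,
    chain_b_offset: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Two beta-strands on different chains at ideal pairing geometry.

    Each strand carries ``n_pairs`` residues and each paired residue
    contributes two backbone hydrogen bonds (N_a...O_b and O_a...N_b at
    2.2 A), giving 2 n_pairs hydrogen bonds in one ladder. ``parallel``
    switches the pairing progression; ``chain_b_offset`` translates
    strand B away (in +y) to destroy the ladder.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    del seed  # geometry is deterministic; signature kept uniform
    n = n_pairs + 2  # one flanking residue each side
    spacing = 3.4

    def strand_a_res(i: int) -> Residue:
        x = spacing * i
        return Residue(
            seq_id=i + 1,
            name="ALA",
            atoms=[
                AtomRecord("N", "N", np.array([x - 1.0, 0.8, 0.0])),
                AtomRecord("CA", "C", np.array([x, 0.0, 0.0])),
                AtomRecord("C", "C", np.array([x + 1.0, 0.8, 0.0])),
                AtomRecord("O", "O", np.array([x + 1.0, 1.9, 0.0])),
            ],
        )

    y0 = strand_separation + chain_b_offset

    def strand_b_res(j: int) -> Residue:
        # antiparallel: B runs in -x so residue j pairs with A residue n-1-j
        x = spacing * j if parallel else spacing * (n - 1 - j)
        return Residue(
            seq_id=j + 1,
            name="VAL",
            atoms=[
                AtomRecord("N", "N", np.array([x + 1.0, y0 - 0.8, 0.0])),
                AtomRecord("CA", "C", np.array([x, y0, 0.0])),
                AtomRecord("C", "C", np.array([x - 1.0, y0 - 0.8, 0.0])),
                AtomRecord("O", "O", np.array([x - 1.0, y0 - 1.9, 0.0])),
            ],
        )

    # only the inner n_pairs residues of B get pairing partners: trim the
    # flanks by keeping all residues but relying on distance for bonding
    chain_a = Chain("A", [strand_a_res(i) for i in range(1, n - 1)])
    chain_b = Chain("B", [strand_b_res(j) for j in range(1, n - 1)])
    return Structure(
        chains=[chain_a, chain_b],
        metadata={"fixture": "sheet_pair", "parallel": parallel},
    )


def make_sequence(length: int = 331, seed: int = 0) -> str:
    """Deterministic pseudo-random amino-acid sequence."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))
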