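"""Structure I/O, selection and superposition."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from capsidkit.errors import (
    EmptySelectionError,
    FormatError,
    GeometryError,
    SelectionError,
)
from capsidkit.structures import (
    AtomRecord,
    Chain,
    Residue,
    RigidTransform,
    Structure,
    pairwise_rmsd,
    read_structure,
    select,
    superpose,
    write_structure,
)
from conftest import make_ca_chain


def full_chain(n: int, rng) -> Chain:
    return make_ca_chain("A", rng.uniform(0, 50, size=(n, 3)))


class TestIO:
    def test_two_atom_pdb_roundtrip(self, two_atom_structure, tmp_path):
        path = tmp_path / "mini.pdb"
        write_structure(two_atom_structure, path)
        back = read_structure(path)
        assert len(back.chains) == 1
        assert len(back.chains[0]) == 1
        assert back.n_atoms() == 2
        # PDB stores coordinates at 1e-3 A precision
        np.testing.assert_allclose(
            back.all_positions(), two_atom_structure.all_positions(), atol=1e-3
        )

    @pytest.mark.parametrize("suffix", ["pdb", "cif"])
    def test_roundtrip_preserves_numbering(self, suffix, tmp_path):
        rng = np.random.default_rng(0)
        chain = make_ca_chain("B", rng.uniform(0, 30, size=(12, 3)), start=5)
        st = Structure([chain])
        path = tmp_path / f"x.{suffix}"
        write_structure(st, path)
        back = read_structure(path)
        assert [r.seq_id for r in back.chains[0].residues] == list(range(5, 17))
        np.testing.assert_allclose(back.all_positions(), st.all_positions(), atol=1e-3)

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(Exception):
            read_structure(bad)

    def test_unknown_format(self, tmp_path):
        f = tmp_path / "x.xyz"
        f.write_text("")
        with pytest.raises(FormatError):
            read_structure(f)

    def test_pdb_refused_beyond_capacity(self, tmp_path):
        rng = np.random.default_rng(1)
        chains = [
            make_ca_chain(f"C{i}", rng.uniform(0, 9, size=(1, 3))) for i in range(70)
        ]
        st = Structure(chains)
        with pytest.raises(FormatError, match="chains"):
            write_structure(st, tmp_path / "big.pdb")


class TestSelect:
    def test_published_residue_counts(self):
        """A 331-residue chain trimmed to 5-331 gives 327 traced positions;
        1-139 on a 140-residue chain gives 139."""
        rng = np.random.default_rng(2)
        mcp = Structure([full_chain(331, rng)])
        sel = select(mcp, "A", (5, 331))
        assert len(sel) == 327
        cp = Structure([full_chain(140, rng)])
        assert len(select(cp, "A", (1, 139))) == 139

    def test_single_residue_range(self):
        rng = np.random.default_rng(3)
        st = Structure([full_chain(20, rng)])
        assert len(select(st, "A", (10, 10))) == 1

    def test_gap_report(self):
        rng = np.random.default_rng(4)
        chain = full_chain(10, rng)
        chain.residues = [r for r in chain.residues if r.seq_id != 5]
        st = Structure([Chain("A", chain.residues)])
        sel = select(st, "A", (1, 10))
        assert len(sel) == 9
        assert sel.gaps == [5]

    def test_empty_selection_is_explicit(self):
        rng = np.random.default_rng(5)
        st = Structure([full_chain(10, rng)])
        with pytest.raises(EmptySelectionError):
            select(st, "A", (1, 10), atom_names=("CB",))

    def test_missing_chain(self):
        st = Structure([make_ca_chain("A", [[0, 0, 0], [1, 0, 0]])])
        with pytest.raises(SelectionError):
            select(st, "Z", (1, 2))


def brute_force_best_rmsd(mobile, target, seed=0, n_starts=64):
    """Rotation-search oracle: random quaternion starts + simplex refinement,
    independent of the closed-form solution."""
    m0 = mobile - mobile.mean(axis=0)
    t0 = target - target.mean(axis=0)

    def cost(q):
        rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        return np.sqrt(np.mean(np.sum((m0 @ rot.T - t0) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 3))
        tr, rmsd = superpose(pts, pts)
        assert rmsd < 1e-12
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_random_rigid_motion(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(20, 3))
        rot = Rotation.random(random_state=8).as_matrix()
        t = rng.normal(size=3)
        tr, rmsd = superpose(pts, pts @ rot.T + t)
        assert rmsd < 1e-8
        np.testing.assert_allclose(tr.rotation, rot, atol=1e-6)

    def test_reflected_set_vs_brute_force_oracle(self):
        """A reflected point set cannot be superposed exactly with a proper
        rotation; the constrained optimum must match a brute-force
        quaternion search."""
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(4, 3))
        reflected = pts * np.array([-1.0, 1.0, 1.0])
        tr, rmsd = superpose(pts, reflected)
        assert rmsd > 0
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
        oracle = brute_force_best_rmsd(pts, reflected)
        assert rmsd == pytest.approx(oracle, abs=1e-4)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, r_ab = superpose(a, b)
        _, r_ba = superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-8)

    def test_rigid_motion_gives_zero_rmsd(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(15, 3))
        t = RigidTransform(Rotation.random(random_state=12).as_matrix(), np.array([3.0, -1.0, 2.0]))
        _, rmsd = superpose(pts, t.apply(pts))
        assert rmsd < 1e-8

    def test_degenerate_inputs(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            superpose(line, line + 1.0)
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(GeometryError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestPairwiseRmsd:
    def test_identical_conformers(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 3))
        mat, labels = pairwise_rmsd([("a", pts), ("b", pts.copy())])
        np.testing.assert_allclose(mat, 0.0, atol=1e-10)
        assert labels == ["a", "b"]

    def test_matches_direct_formula(self):
        """Entries recomputed from the RMSD definition after optimal
        superposition of perturbed conformers."""
        rng = np.random.default_rng(14)
        base = rng.normal(size=(30, 3)) * 5
        conformers = []
        for i in range(3):
            rot = Rotation.random(random_state=20 + i).as_matrix()
            pert = base + rng.normal(scale=0.5, size=base.shape)
            conformers.append((f"c{i}", pert @ rot.T + rng.normal(size=3)))
        mat, _ = pairwise_rmsd(conformers)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        for i in range(3):
            for j in range(i + 1, 3):
                tr, _ = superpose(conformers[i][1], conformers[j][1])
                moved = tr.apply(conformers[i][1])
                direct = np.sqrt(np.mean(np.sum((moved - conformers[j][1]) ** 2, axis=1)))
                assert mat[i, j] == pytest.approx(direct, abs=1e-10)

    def test_unequal_selection_reported(self):
        rng = np.random.default_rng(15)
        with pytest.raises(SelectionError, match="a:"):
            pairwise_rmsd([("a", rng.normal(size=(5, 3))), ("b", rng.normal(size=(6, 3)))])


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        reflect = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            RigidTransform(reflect, np.zeros(3))

    def test_compose_inverse(self):
        rot = Rotation.random(random_state=30).as_matrix()
        t = RigidTransform(rot, np.array([1.0, 2.0, 3.0]))
        ident = t.compose(t.inverse())
        np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(ident.translation, 0.0, atol=1e-12)
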