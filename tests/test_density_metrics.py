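"""Map I/O, FSC / R-factor shells, resolution, filters and subunit averaging."""

import numpy as np
import pytest

from capsidkit import density_metrics as dm
from capsidkit import synthetic
from capsidkit.errors import GeometryError, ValidationError
from capsidkit.structures import AtomRecord, Chain, Residue, RigidTransform, Structure


def noise_map(seed, box=32, voxel=2.0):
    rng = np.random.default_rng(seed)
    return dm.DensityMap(rng.standard_normal((box, box, box)), voxel_size=voxel)


class TestMrcIO:
    def test_float32_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = rng.standard_normal((32, 32, 32)).astype(np.float32)
        m = dm.DensityMap(grid, voxel_size=1.32, origin=np.array([1.5, -2.0, 3.25]))
        path = tmp_path / "m.mrc"
        dm.write_mrc(m, path)
        back = dm.read_mrc(path)
        assert np.array_equal(back.grid.astype(np.float32), grid)
        assert back.voxel_size == pytest.approx(1.32, abs=1e-4)
        np.testing.assert_allclose(back.origin, m.origin, atol=1e-5)

    def test_cross_writer_fixture(self, tmp_path):
        """A mode-2 map written by gemmi's own high-level API (not our
        writer) reads back with the declared geometry and values."""
        import gemmi

        arr = np.arange(4 * 4 * 4, dtype=np.float32).reshape(4, 4, 4)
        g = gemmi.Ccp4Map()
        g.grid = gemmi.FloatGrid(arr)
        g.grid.unit_cell = gemmi.UnitCell(8, 8, 8, 90, 90, 90)
        g.grid.spacegroup = gemmi.SpaceGroup("P1")
        g.update_ccp4_header()
        path = tmp_path / "ext.mrc"
        g.write_ccp4_map(str(path))
        back = dm.read_mrc(path)
        assert back.voxel_size == pytest.approx(2.0, abs=1e-4)
        assert np.array_equal(back.grid.astype(np.float32), arr)


class TestSimulateMap:
    def carbon_at_origin(self):
        chain = Chain(
            "A", [Residue(1, "GLY", [AtomRecord("C", "C", np.zeros(3))])]
        )
        return Structure([chain])

    def test_single_atom_peak_at_centre(self):
        m = dm.simulate_map(self.carbon_at_origin(), voxel_size=0.5, box=24.0, resolution=3.0)
        peak = np.unravel_index(np.argmax(m.grid), m.grid.shape)
        centre = ((np.zeros(3) - m.origin) / m.voxel_size).round().astype(int)
        assert peak == tuple(centre)

    def test_linearity(self):
        st1 = self.carbon_at_origin()
        chain2 = Chain("B", [Residue(1, "GLY", [AtomRecord("C", "C", np.array([3.0, 0, 0]))])])
        both = Structure([st1.chains[0], chain2])
        origin = np.full(3, -12.0)
        m1 = dm.simulate_map(st1, 0.5, 24.0, 3.0, origin=origin)
        m2 = dm.simulate_map(Structure([chain2]), 0.5, 24.0, 3.0, origin=origin)
        m12 = dm.simulate_map(both, 0.5, 24.0, 3.0, origin=origin)
        np.testing.assert_allclose(m12.grid, m1.grid + m2.grid, atol=1e-12)

    def test_fourier_half_amplitude_at_resolution(self):
        """The atom form factor drops to half its DC value at s = 1/resolution."""
        res = 4.0
        m = dm.simulate_map(self.carbon_at_origin(), voxel_size=0.5, box=32.0, resolution=res)
        amps = np.abs(np.fft.fftn(m.grid))
        freqs = np.fft.fftfreq(m.grid.shape[0], d=0.5)
        i = int(np.argmin(np.abs(freqs - 1.0 / res)))
        ratio = amps[i, 0, 0] / amps[0, 0, 0]
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_atoms_outside_box_rejected(self):
        chain = Chain("A", [Residue(1, "GLY", [AtomRecord("C", "C", np.array([100.0, 0, 0]))])])
        st2 = Structure([self.carbon_at_origin().chains[0], Chain("B", chain.residues)])
        with pytest.raises(GeometryError, match="1 atom"):
            dm.simulate_map(st2, 1.0, 20.0, 3.0, origin=np.full(3, -10.0))


class TestShellCurves:
    def test_self_fsc_is_one(self):
        m = noise_map(1)
        curve = dm.shell_fsc(m, m)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_negated_map_fsc_minus_one(self):
        m = noise_map(2)
        neg = dm.DensityMap(-m.grid, m.voxel_size)
        curve = dm.shell_fsc(m, neg)
        np.testing.assert_allclose(curve.values, -1.0, atol=1e-12)

    def test_independent_noise_fsc_near_zero(self):
        """|FSC| of two independent white-noise maps stays within the
        3/sqrt(n_voxels_in_shell) null band."""
        a, b = noise_map(3), noise_map(4)
        n_shells = 16
        curve = dm.shell_fsc(a, b, n_shells)
        idx, _, _ = dm._shell_index(a.grid.shape, a.voxel_size, n_shells)
        counts = np.bincount(idx.ravel(), minlength=n_shells + 1)[:n_shells]
        populated = counts > 20
        bound = 3.0 / np.sqrt(counts[populated])
        assert np.all(np.abs(curve.values[populated]) <= bound)

    def test_fsc_scale_invariant_and_symmetric(self, small_map_pair):
        a, b, _ = small_map_pair
        c1 = dm.shell_fsc(a, b)
        scaled = dm.DensityMap(7.5 * b.grid, b.voxel_size)
        c2 = dm.shell_fsc(a, scaled)
        c3 = dm.shell_fsc(b, a)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-10)
        np.testing.assert_allclose(c1.values, c3.values, atol=1e-10)

    def test_self_rfactor_zero_and_scale_invariance(self):
        m = noise_map(5)
        np.testing.assert_allclose(dm.shell_rfactor(m, m).values, 0.0, atol=1e-10)
        doubled = dm.DensityMap(2.0 * m.grid, m.voxel_size)
        np.testing.assert_allclose(dm.shell_rfactor(m, doubled).values, 0.0, atol=1e-10)

    def test_rfactor_matches_direct_recomputation(self):
        """Shell R on noise maps equals a from-scratch evaluation of the
        scaled-L1 definition."""
        a, b = noise_map(6), noise_map(7)
        n_shells = 8
        curve = dm.shell_rfactor(a, b, n_shells)
        fa = np.abs(np.fft.fftn(a.grid.astype(np.float64)))
        fb = np.abs(np.fft.fftn(b.grid.astype(np.float64)))
        idx, _, _ = dm._shell_index(a.grid.shape, a.voxel_size, n_shells)
        for shell in range(n_shells):
            sel = idx == shell
            if not np.any(sel):
                continue
            c = np.sum(fa[sel] * fb[sel]) / np.sum(fb[sel] ** 2)
            r = np.sum(np.abs(fa[sel] - c * fb[sel])) / np.sum(fa[sel])
            assert curve.values[shell] == pytest.approx(r, abs=1e-10)

    def test_geometry_mismatch(self):
        with pytest.raises(ValidationError):
            dm.shell_fsc(noise_map(8, box=32), noise_map(8, box=16))


class TestResolution:
    def test_band_limited_pair_recovers_truth(self, small_map_pair):
        a, b, truth = small_map_pair
        curve = dm.shell_fsc(a, b, n_shells=24)
        est = dm.estimate_resolution(curve, 0.143)
        ds = a.nyquist / 24
        assert abs(1.0 / est.resolution - 1.0 / truth) <= ds

    def test_constant_curve_above_threshold_is_nyquist_limited(self):
        curve = dm.ShellCurve(s=np.linspace(0.01, 0.25, 10), values=np.full(10, 0.9))
        est = dm.estimate_resolution(curve, 0.143)
        assert est.nyquist_limited

    def test_step_at_shell_centre(self):
        s = np.array([0.05, 0.10, 0.15, 0.20])
        v = np.array([1.0, 0.143, 0.0, 0.0])
        est = dm.estimate_resolution(dm.ShellCurve(s=s, values=v), 0.143)
        assert est.resolution == pytest.approx(1.0 / 0.10)

    def test_noise_monotonicity(self):
        """Adding noise to one map never yields a finer FSC-0.143 resolution."""
        a, b, _ = synthetic.make_map_pair(box=48, seed=9)
        rng = np.random.default_rng(10)
        prev = None
        for extra in (0.0, 1.0, 3.0):
            noisy = dm.DensityMap(
                b.grid + extra * rng.standard_normal(b.grid.shape) * b.grid.std(),
                b.voxel_size,
            )
            est = dm.estimate_resolution(dm.shell_fsc(a, noisy, 24), 0.143)
            if prev is not None:
                assert est.resolution >= prev - 1e-9
            prev = est.resolution

    def test_r_half_matches_fsc_0143(self, small_map_pair):
        """The R = 0.5 and FSC = 0.143 crossings land within one shell of
        each other on a matched signal+noise pair."""
        a, b, _ = small_map_pair
        n_shells = 24
        fsc_est = dm.estimate_resolution(dm.shell_fsc(a, b, n_shells), 0.143)
        r_est = dm.estimate_resolution(dm.shell_rfactor(a, b, n_shells), 0.5)
        ds = a.nyquist / n_shells
        assert abs(1.0 / fsc_est.resolution - 1.0 / r_est.resolution) <= ds


class TestFilters:
    def test_sharpen_zero_is_identity(self):
        m = noise_map(11)
        out = dm.sharpen(m, 0.0)
        np.testing.assert_allclose(out.grid, m.grid, atol=1e-12)

    def test_sharpen_inverse_pair(self):
        m = noise_map(12)
        back = dm.sharpen(dm.sharpen(m, -200.0), 200.0)
        rel = np.abs(back.grid - m.grid).max() / np.abs(m.grid).max()
        assert rel < 1e-5

    def test_sharpen_closed_form_factor(self):
        """On a Gaussian blob, reverse-B sharpening multiplies the amplitude
        at s = 0.25 per A by exp(200 * 0.25^2 / 4)."""
        n, voxel = 48, 1.0
        x = np.arange(n) - n // 2
        r2 = x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
        blob = dm.DensityMap(np.exp(-r2 / (2 * 4.0)), voxel_size=voxel)
        sharp = dm.sharpen(blob, -200.0)
        f0 = np.abs(np.fft.fftn(blob.grid))
        f1 = np.abs(np.fft.fftn(sharp.grid))
        freqs = np.fft.fftfreq(n, d=voxel)
        i = int(np.argmin(np.abs(freqs - 0.25)))
        expected = np.exp(200.0 * 0.25**2 / 4.0)
        assert f1[i, 0, 0] / f0[i, 0, 0] == pytest.approx(expected, rel=0.01)

    def test_parseval_preserved(self):
        m = noise_map(13)
        for out in (dm.sharpen(m, -50.0), dm.lowpass(m, 0.1, 2.0)):
            real_power = np.sum(out.grid.astype(np.float64) ** 2)
            four_power = np.sum(np.abs(np.fft.fftn(out.grid)) ** 2) / out.grid.size
            assert real_power == pytest.approx(four_power, rel=1e-6)

    def test_lowpass_kills_stopband_keeps_passband(self):
        m = noise_map(14)
        cutoff = m.nyquist / 2
        out = dm.lowpass(m, cutoff, edge_width=2.0)
        f_in = np.fft.fftn(m.grid.astype(np.float64))
        f_out = np.fft.fftn(out.grid)
        _, _, s = dm._shell_index(m.grid.shape, m.voxel_size, 1)
        w = 2.0 / (m.grid.shape[0] * m.voxel_size)
        stop = s > cutoff + w
        passband = s < cutoff - w
        total = np.sum(np.abs(f_in) ** 2)
        assert np.sum(np.abs(f_out[stop]) ** 2) / total < 1e-10
        np.testing.assert_allclose(f_out[passband], f_in[passband], rtol=1e-6)

    def test_lowpass_at_nyquist_is_identity(self):
        m = noise_map(15)
        out = dm.lowpass(m, m.nyquist, edge_width=0.0)
        np.testing.assert_allclose(out.grid, m.grid, atol=1e-6 * np.abs(m.grid).max())

    def test_cutoff_above_nyquist_rejected(self):
        m = noise_map(16)
        with pytest.raises(ValidationError):
            dm.lowpass(m, m.nyquist * 1.5)


class TestAverageSubunits:
    @staticmethod
    def _blob(n, centre, width=3.0):
        x = np.arange(n)
        r2 = (
            (x[:, None, None] - centre[0]) ** 2
            + (x[None, :, None] - centre[1]) ** 2
            + (x[None, None, :] - centre[2]) ** 2
        )
        return np.exp(-r2 / (2 * width**2))

    def test_identity_transform_masked_copy(self):
        m = noise_map(17)
        mask = np.zeros(m.grid.shape, dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        out = dm.average_subunits(m, [RigidTransform.identity()], mask)
        np.testing.assert_allclose(out.grid[mask], m.grid[mask], atol=1e-12)
        assert np.all(out.grid[~mask] == 0)

    def test_noise_variance_reduced_by_n(self):
        """Averaging N exact copies leaves residual noise variance sigma^2/N."""
        n_copies, sigma = 6, 0.5
        rng = np.random.default_rng(18)
        shape = (96, 32, 32)
        grid = np.zeros(shape)
        for i in range(n_copies):
            grid += self._blob(96, (8 + 16 * i, 16, 16))[:, :32, :32]
        grid += rng.normal(scale=sigma, size=shape)
        dmap = dm.DensityMap(grid, voxel_size=1.0)
        mask = np.zeros(shape, dtype=bool)
        mask[2:14, 10:23, 10:23] = True
        transforms = [
            RigidTransform(np.eye(3), np.array([16.0 * i, 0.0, 0.0]))
            for i in range(n_copies)
        ]
        avg = dm.average_subunits(dmap, transforms, mask)
        truth = self._blob(96, (8, 16, 16))[:, :32, :32]
        resid = (avg.grid - truth)[mask]
        assert resid.var() == pytest.approx(sigma**2 / n_copies, rel=0.15)

    def test_averaged_fsc_beats_single_copy(self):
        """Against the noiseless ground truth, the average of 4 noisy copies
        correlates better than a single copy in every shell. The truth is a
        full-band random field so every shell carries signal."""
        rng = np.random.default_rng(19)
        tile = rng.standard_normal((16, 32, 32))
        truth_grid = np.tile(tile, (4, 1, 1))  # 4 exact copies along x
        noisy = truth_grid + rng.normal(scale=0.8, size=truth_grid.shape)
        dmap = dm.DensityMap(noisy, voxel_size=1.0)
        mask = np.zeros(truth_grid.shape, dtype=bool)
        mask[0:16, :, :] = True
        transforms = [
            RigidTransform(np.eye(3), np.array([16.0 * i, 0.0, 0.0])) for i in range(4)
        ]
        avg = dm.average_subunits(dmap, transforms, mask)
        ref = dm.DensityMap(tile, 1.0)
        avg_c = dm.DensityMap(avg.grid[:16], 1.0)
        one_c = dm.DensityMap(noisy[:16], 1.0)
        f_avg = dm.shell_fsc(ref, avg_c, 8).values
        f_one = dm.shell_fsc(ref, one_c, 8).values
        assert np.all(f_avg >= f_one - 1e-9)

    def test_transform_outside_grid_rejected(self):
        m = noise_map(20)
        mask = np.ones(m.grid.shape, dtype=bool)
        bad = RigidTransform(np.eye(3), np.array([1000.0, 0.0, 0.0]))
        with pytest.raises(GeometryError, match="transform 0"):
            dm.average_subunits(m, [bad], mask)
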