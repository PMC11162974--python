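import numpy as np
import pytest

from seedspectra.io_envi import Hypercube
from seedspectra.synthetic import make_endmember_library, make_mixture_cube
from seedspectra.unmixing import (AbundanceStack, EndmemberSet,
                                  consolidate_endmembers, estimate_abundances,
                                  estimate_num_endmembers, mnf_transform,
                                  ppi_extract, reconstruct, rrmse,
                                  spectral_mse)
from seedspectra.spectral_similarity import sam


class TestSpectralMse:
    def test_identical_is_zero(self):
        assert spectral_mse([0.1, 0.2], [0.1, 0.2]) == 0.0

    def test_unit_difference(self):
        assert spectral_mse([1, 1], [0, 0]) == 1.0

    def test_reference_pair_sits_at_cutoff(self):
        assert spectral_mse([0.2, 0.4], [0.2, 0.41]) == pytest.approx(5e-5)

    def test_cutoff_boundary_excluded(self):
        # Binary-exact boundary: diff 2^-7 gives MSE exactly 2^-15; the
        # strict '< cutoff' rule must not merge the pair.
        a, b = 0.5, 0.5 + 2.0 ** -7
        assert spectral_mse([0.25, a], [0.25, b]) == 2.0 ** -15
        merged = consolidate_endmembers(
            [EndmemberSet(spectra=np.array([[0.25, a], [0.25, b]]),
                          wavelengths=np.array([500.0, 600.0]))],
            mse_cutoff=2.0 ** -15)
        assert len(merged) == 2

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            spectral_mse([1, 2], [1, 2, 3])


class TestConsolidate:
    wl = np.linspace(400, 1000, 30)

    def test_noisy_copies_merge_to_mean(self, rng):
        base = np.linspace(0.2, 0.6, 30)
        copies = base + rng.normal(0, 1e-4, size=(10, 30))
        ems = EndmemberSet(spectra=copies, wavelengths=self.wl)
        out = consolidate_endmembers([ems])
        assert len(out) == 1
        np.testing.assert_allclose(out.spectra[0], copies.mean(axis=0))

    def test_distant_spectra_stay_separate(self):
        a = np.full(30, 0.2)
        b = np.full(30, 0.2 + np.sqrt(1e-3))  # MSE 1e-3 > cutoff
        out = consolidate_endmembers(
            [EndmemberSet(spectra=np.array([a, b]), wavelengths=self.wl)])
        assert len(out) == 2

    def test_three_clusters_against_bruteforce(self, rng):
        centers = [np.full(30, 0.2), np.full(30, 0.5), np.full(30, 0.8)]
        cands = np.array([c + rng.normal(0, 5e-4, 30)
                          for c in centers for _ in range(4)])
        out = consolidate_endmembers(
            [EndmemberSet(spectra=cands, wavelengths=self.wl)])
        assert len(out) == 3
        for c in centers:
            assert min(spectral_mse(c, s) for s in out.spectra) < 1e-6

    def test_count_non_increasing_in_cutoff(self, rng):
        cands = EndmemberSet(spectra=rng.uniform(0.2, 0.8, (8, 30)),
                             wavelengths=self.wl)
        counts = [len(consolidate_endmembers([cands], mse_cutoff=c))
                  for c in (1e-6, 1e-4, 1e-2, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            consolidate_endmembers([])


class TestAbundances:
    def setup_method(self):
        self.ems = make_endmember_library(3, n_bands=40, seed=7)

    def _cube_from(self, ab):
        data = ab @ self.ems.spectra
        side = int(np.sqrt(ab.shape[0]))
        return Hypercube(data=data.reshape(side, side, -1),
                         wavelengths=self.ems.wavelengths)

    def test_pure_pixel_one_hot(self):
        ab = np.tile(np.eye(3), (3, 1))[:9]
        est = estimate_abundances(self._cube_from(ab), self.ems)
        np.testing.assert_allclose(est.maps.reshape(-1, 3), ab, atol=1e-6)

    def test_half_half_mixture(self):
        ab = np.tile([0.5, 0.5, 0.0], (9, 1))
        est = estimate_abundances(self._cube_from(ab), self.ems)
        np.testing.assert_allclose(est.maps.reshape(-1, 3), ab, atol=1e-6)

    def test_full_constraint_sums_to_one(self, rng):
        ab = rng.dirichlet(np.ones(3), size=16)
        est = estimate_abundances(self._cube_from(ab), self.ems)
        np.testing.assert_allclose(est.maps.sum(axis=2), 1.0, atol=1e-6)
        assert est.maps.min() >= -1e-6

    def test_unconstrained_matches_normal_equations(self, rng):
        ab = rng.dirichlet(np.ones(3), size=16)
        cube = self._cube_from(ab)
        cube.data += rng.normal(0, 0.01, cube.data.shape)
        est = estimate_abundances(cube, self.ems, constraint="none")
        e = self.ems.spectra
        oracle = np.linalg.solve(e @ e.T, e @ cube.pixels().T).T
        np.testing.assert_allclose(est.maps.reshape(-1, 3), oracle, atol=1e-10)

    def test_rank_deficient_errors(self):
        spectra = np.vstack([self.ems.spectra[0], self.ems.spectra[0]])
        bad = EndmemberSet(spectra=spectra, wavelengths=self.ems.wavelengths)
        data = np.tile(bad.spectra[0], (3, 3, 1))
        cube = Hypercube(data=data, wavelengths=bad.wavelengths)
        with pytest.raises(ValueError, match="rank"):
            estimate_abundances(cube, bad)


class TestReconstructAndRrmse:
    def test_one_hot_reproduces_endmembers(self):
        ems = make_endmember_library(2, n_bands=30, seed=1)
        maps = np.zeros((1, 2, 2))
        maps[0, 0, 0] = 1.0
        maps[0, 1, 1] = 1.0
        cube = reconstruct(ems, AbundanceStack(maps=maps, endmembers=ems))
        np.testing.assert_allclose(cube.data[0, 0], ems.spectra[0])
        np.testing.assert_allclose(cube.data[0, 1], ems.spectra[1])

    def test_noiseless_roundtrip(self, rng):
        ems = make_endmember_library(3, n_bands=30, seed=2)
        ab = rng.dirichlet(np.ones(3), size=25).reshape(5, 5, 3)
        cube = reconstruct(ems, AbundanceStack(maps=ab, endmembers=ems))
        est = estimate_abundances(cube, ems)
        recon = reconstruct(ems, est)
        assert rrmse(recon, cube) < 1e-4
        np.testing.assert_allclose(recon.data, cube.data, atol=1e-6)

    def test_rrmse_hand_value(self):
        wl = np.array([500.0, 600.0])
        ref = Hypercube(data=np.array([[[0.0, 1.0]]]), wavelengths=wl)
        rec = Hypercube(data=np.array([[[0.1, 0.9]]]), wavelengths=wl)
        assert rrmse(rec, ref) == pytest.approx(10.0)

    def test_rrmse_identical_zero_and_constant_error(self, tiny_cube):
        assert rrmse(tiny_cube, tiny_cube) == 0.0
        const = Hypercube(data=np.full((2, 2, 3), 0.4),
                          wavelengths=tiny_cube.wavelengths)
        with pytest.raises(ValueError):
            rrmse(tiny_cube, const)

    def test_rrmse_scale_covariant(self, rng):
        wl = np.linspace(400, 1000, 8)
        ref = Hypercube(data=rng.uniform(0, 1, (4, 4, 8)), wavelengths=wl)
        rec = Hypercube(data=ref.data + rng.normal(0, 0.05, ref.data.shape),
                        wavelengths=wl)
        base = rrmse(rec, ref)
        a, b = 3.7, 0.2
        scaled = rrmse(Hypercube(data=a * rec.data + b, wavelengths=wl),
                       Hypercube(data=a * ref.data + b, wavelengths=wl))
        assert scaled == pytest.approx(base, rel=1e-10)


class TestMnf:
    def test_known_rank_eigen_gap(self, rng):
        # Signal confined to a rank-2 band subspace + tiny noise.
        rows, cols, n_bands, k = 24, 24, 12, 2
        basis = rng.normal(0, 1, (k, n_bands))
        coef = np.stack([_smooth_field(rng, rows, cols) for _ in range(k)], -1)
        data = coef.reshape(-1, k) @ basis + rng.normal(0, 1e-3, (rows * cols, n_bands))
        cube = Hypercube(data=data.reshape(rows, cols, n_bands),
                         wavelengths=np.linspace(400, 1000, n_bands))
        res = mnf_transform(cube)
        ev = res.eigenvalues
        # Signal components dominate the noise floor by a wide margin; the
        # shift-difference noise estimate absorbs some signal gradient, so the
        # gap is large but not unbounded.
        assert ev[k - 1] / ev[k] > 5
        assert ev[k] < 2.0

    def test_full_inverse_recovers_cube(self, rng):
        cube = Hypercube(data=rng.uniform(0.1, 0.9, (8, 8, 6)),
                         wavelengths=np.linspace(400, 1000, 6))
        res = mnf_transform(cube)
        back = res.inverse()
        np.testing.assert_allclose(back.data, cube.data, atol=1e-8)

    def test_components_uncorrelated(self, rng):
        cube = Hypercube(data=rng.uniform(0.1, 0.9, (10, 10, 5)),
                         wavelengths=np.linspace(400, 1000, 5))
        comps = mnf_transform(cube).cube.pixels()
        cov = np.cov(comps.T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-6 * np.max(np.abs(cov))

    def test_constant_cube_errors(self):
        cube = Hypercube(data=np.full((4, 4, 3), 0.5),
                         wavelengths=np.array([500.0, 600.0, 700.0]))
        with pytest.raises(ValueError, match="constant"):
            mnf_transform(cube)


def _smooth_field(rng, rows, cols):
    from scipy.ndimage import zoom
    return zoom(rng.normal(0, 1, (6, 6)), (rows / 6, cols / 6), order=1)


class TestNwhfc:
    def test_pure_noise_at_most_one(self):
        counts = []
        for s in range(5):
            r = np.random.default_rng(s)
            cube = Hypercube(data=r.normal(0, 1, (32, 32, 20)),
                             wavelengths=np.linspace(400, 1000, 20))
            counts.append(estimate_num_endmembers(cube))
        assert all(c <= 1 for c in counts)

    def test_three_sources_detected(self):
        cube, _, _ = make_mixture_cube(3, snr_db=40, seed=11)
        assert estimate_num_endmembers(cube) == 3

    def test_pfa_zero_errors(self, tiny_cube):
        with pytest.raises(ValueError):
            estimate_num_endmembers(tiny_cube, pfa=0.0)


class TestPpi:
    def test_recovers_planted_endmembers(self):
        cube, ems, _ = make_mixture_cube(3, snr_db=40, seed=5)
        rec = ppi_extract(cube, p=3, seed=0)
        worst = max(min(sam(t, r) for r in rec.spectra) for t in ems.spectra)
        assert worst < 0.05

    def test_identical_pixels_degenerate(self):
        cube = Hypercube(data=np.full((5, 5, 10), 0.3),
                         wavelengths=np.linspace(400, 1000, 10))
        out = ppi_extract(cube, p=2, n_skewers=200, seed=0)
        assert len(out) == 2
        np.testing.assert_allclose(out.spectra, 0.3)

    def test_stable_under_more_skewers(self):
        cube, _, _ = make_mixture_cube(3, snr_db=40, seed=5)
        a = ppi_extract(cube, p=3, n_skewers=2000, seed=0)
        b = ppi_extract(cube, p=3, n_skewers=4000, seed=0)
        worst = max(min(sam(s, t) for t in b.spectra) for s in a.spectra)
        assert worst < 0.02

    def test_p_larger_than_pixels_errors(self, tiny_cube):
        with pytest.raises(ValueError):
            ppi_extract(tiny_cube, p=5, n_skewers=200)


def test_abundance_recovery_on_dirichlet_scene():
    """SNR >= 35 dB smooth mixtures: per-pixel abundance RMSE below 0.05."""
    cube, ems, truth = make_mixture_cube(4, snr_db=35, seed=3)
    est = estimate_abundances(cube, ems)
    rmse = np.sqrt(np.mean((est.maps - truth.maps) ** 2))
    assert rmse < 0.05
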