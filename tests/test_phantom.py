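"""Count-domain phantom generation, thinning and calibration."""

import numpy as np
import pytest

from petdose.phantom import (
    AcquisitionMeta,
    CountVolume,
    LesionSpec,
    counts_to_suv,
    generate_phantom,
    liver_rate,
    load_suv_nifti,
    save_suv_nifti,
    thin_counts,
)
from petdose.metrics import region_snr, sphere_voi

MODEL = (19.6, 0.95)


class TestAcquisitionMeta:
    def test_dtp_is_exact_product(self):
        meta = AcquisitionMeta(activity=129.75, mbp=6.0)
        assert meta.dtp == 129.75 * 6.0

    @pytest.mark.parametrize("activity, mbp", [(0, 6), (-5, 6), (100, 0), (100, -1)])
    def test_rejects_nonpositive(self, activity, mbp):
        with pytest.raises(ValueError):
            AcquisitionMeta(activity, mbp)


class TestLiverRate:
    def test_closed_form_reference_subject(self):
        # λ = (a·m^(−d))²·DTP for the mean-habitus subject at 1.5 MBq/kg, 6 mbp
        lam = liver_rate(86.5, MODEL, 129.75 * 6.0)
        assert lam == pytest.approx(62.4367, abs=1e-3)
        assert np.sqrt(lam) == pytest.approx(7.90, abs=0.02)  # expected SNR

    def test_mass_independent_when_d_zero(self):
        dtp = 500.0
        assert liver_rate(55.0, (19.6, 0.0), dtp) == liver_rate(120.0, (19.6, 0.0), dtp)


class TestGeneratePhantom:
    def test_liver_suv_mean_calibrated(self, small_geometry, reference_meta):
        vol = generate_phantom(
            86.5, reference_meta, MODEL, liver_suv=5.8, seed=1,
            geometry=small_geometry,
        )
        suv = counts_to_suv(vol)
        measured = suv.grid[vol.organ_masks["liver"]].mean()
        assert measured == pytest.approx(5.8, rel=0.02)

    def test_expected_snr_matches_model(self, small_geometry, reference_meta):
        vol = generate_phantom(
            86.5, reference_meta, MODEL, seed=2, geometry=small_geometry
        )
        suv = counts_to_suv(vol)
        voi = sphere_voi(suv, small_geometry.liver_voi_center, 30.0)
        snr = region_snr(suv, voi)
        expected = 19.6 * 86.5**-0.95 * np.sqrt(reference_meta.dtp)
        assert snr.snr == pytest.approx(expected, rel=0.15)

    def test_poisson_mean_variance_equality(self, small_geometry, reference_meta):
        vol = generate_phantom(
            86.5, reference_meta, MODEL, seed=3, geometry=small_geometry
        )
        counts = vol.grid[vol.organ_masks["liver"]]
        # dispersion index ≈ 1 for Poisson; n ≈ 2e4 liver voxels
        assert counts.var(ddof=1) / counts.mean() == pytest.approx(
            1.0, abs=5.0 / np.sqrt(counts.size)
        )

    def test_masks_disjoint_and_lesion_scaled(self, small_geometry, reference_meta):
        lesion = LesionSpec(center=(30.0, 96.0, 52.0), diameter=24.0,
                            suv_mean_target=30.0)
        vol = generate_phantom(
            86.5, reference_meta, MODEL, lesions=[lesion], seed=4,
            geometry=small_geometry,
        )
        masks = vol.organ_masks
        assert not (masks["liver"] & masks["lesions"]).any()
        assert not (masks["liver"] & masks["background"]).any()
        assert not (masks["lesions"] & masks["background"]).any()
        suv = counts_to_suv(vol)
        assert suv.grid[masks["lesions"]].mean() == pytest.approx(30.0, rel=0.05)

    def test_low_rate_raises(self, small_geometry):
        with pytest.raises(ValueError, match="dose-time product"):
            generate_phantom(
                120.0, AcquisitionMeta(activity=5.0, mbp=1.0), MODEL,
                seed=0, geometry=small_geometry,
            )

    def test_deterministic_per_seed(self, small_geometry, reference_meta):
        a = generate_phantom(86.5, reference_meta, MODEL, seed=9,
                             geometry=small_geometry)
        b = generate_phantom(86.5, reference_meta, MODEL, seed=9,
                             geometry=small_geometry)
        assert np.array_equal(a.grid, b.grid)


class TestThinCounts:
    def _flat_volume(self, rng, lam=60.0, n=100_000):
        grid = rng.poisson(lam, size=(n, 1, 1))
        return CountVolume(
            grid=grid,
            voxel_size=(4.1, 4.1, 3.0),
            calibration=5.8 / lam,
            meta=AcquisitionMeta(100.0, 6.0),
        )

    def test_fraction_one_is_identity(self, rng):
        vol = self._flat_volume(rng)
        thinned = thin_counts(vol, 1.0, seed=0)
        assert thinned.grid is vol.grid
        assert thinned.meta == vol.meta

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_invalid_fraction(self, rng, fraction):
        with pytest.raises(ValueError):
            thin_counts(self._flat_volume(rng), fraction, seed=0)

    def test_marginals_are_thinned_poisson(self, rng):
        # Binomial thinning of Poisson(60) at f = 1/6 gives Poisson(10)
        vol = self._flat_volume(rng, lam=60.0)
        thinned = thin_counts(vol, 1.0 / 6.0, seed=rng)
        counts = thinned.grid.ravel()
        sem = np.sqrt(10.0 / counts.size)
        assert counts.mean() == pytest.approx(10.0, abs=4 * sem)
        assert counts.var(ddof=1) == pytest.approx(10.0, rel=0.05)

    def test_meta_and_calibration_rescaled(self, rng):
        vol = self._flat_volume(rng)
        thinned = thin_counts(vol, 0.5, seed=0)
        assert thinned.meta.mbp == 3.0
        assert thinned.meta.dtp == pytest.approx(vol.meta.dtp * 0.5)
        assert thinned.calibration == vol.calibration / 0.5

    def test_expected_suv_invariant_under_thinning(self, rng):
        vol = self._flat_volume(rng)
        thinned = thin_counts(vol, 1.0 / 3.0, seed=rng)
        suv_parent = counts_to_suv(vol).grid.mean()
        suv_thin = counts_to_suv(thinned).grid.mean()
        assert suv_thin == pytest.approx(suv_parent, rel=0.01)

    def test_snr_scales_with_sqrt_fraction(self, small_geometry, reference_meta):
        """Simulation oracle: SNR(thinned)/SNR(parent) ≈ √f over many seeds."""
        fraction = 0.25
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            parent = generate_phantom(
                86.5, reference_meta, MODEL, seed=rng, geometry=small_geometry
            )
            thinned = thin_counts(parent, fraction, seed=rng)
            voi = sphere_voi(
                counts_to_suv(parent), small_geometry.liver_voi_center, 30.0
            )
            snr_p = region_snr(counts_to_suv(parent), voi).snr
            snr_t = region_snr(counts_to_suv(thinned), voi).snr
            ratios.append(snr_t / snr_p)
        mean_ratio = np.mean(ratios)
        sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean_ratio - np.sqrt(fraction)) < max(3 * sem, 0.01)

    def test_snr_norm_invariant_under_thinning(self, small_geometry, reference_meta):
        """Normalization premise: SNR/√DTP matches between parent and subset."""
        deltas = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            parent = generate_phantom(
                86.5, reference_meta, MODEL, seed=rng, geometry=small_geometry
            )
            thinned = thin_counts(parent, 0.5, seed=rng)
            voi = sphere_voi(
                counts_to_suv(parent), small_geometry.liver_voi_center, 30.0
            )
            np_parent = region_snr(counts_to_suv(parent), voi).snr_norm
            np_thin = region_snr(counts_to_suv(thinned), voi).snr_norm
            deltas.append(np_thin - np_parent)
        sem = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * sem + 1e-3


class TestSuvConversion:
    def test_identity_calibration(self, rng):
        grid = rng.poisson(20.0, size=(8, 8, 8))
        vol = CountVolume(grid, (4.1, 4.1, 3.0), 1.0, AcquisitionMeta(100, 6))
        assert np.array_equal(counts_to_suv(vol).grid, grid)

    def test_zero_counts_zero_suv(self):
        vol = CountVolume(
            np.zeros((4, 4, 4), dtype=int), (4.1, 4.1, 3.0), 0.1,
            AcquisitionMeta(100, 6),
        )
        assert not counts_to_suv(vol).grid.any()

    def test_expected_suv_mean(self, rng):
        lam = 62.4
        grid = rng.poisson(lam, size=(40, 40, 40))
        vol = CountVolume(grid, (4.1, 4.1, 3.0), 5.8 / lam, AcquisitionMeta(129.75, 6))
        assert counts_to_suv(vol).grid.mean() == pytest.approx(5.8, rel=0.01)


def test_nifti_round_trip(tmp_path, small_geometry, reference_meta):
    vol = generate_phantom(
        86.5, reference_meta, MODEL, seed=5, geometry=small_geometry
    )
    suv = counts_to_suv(vol)
    path = tmp_path / "scan.nii.gz"
    save_suv_nifti(suv, path, seed=5)
    loaded = load_suv_nifti(path)
    np.testing.assert_allclose(loaded.grid, suv.grid, rtol=1e-6)
    assert loaded.meta.dtp == pytest.approx(suv.meta.dtp)
    assert loaded.voxel_size == pytest.approx(suv.voxel_size)
    assert np.array_equal(loaded.organ_masks["liver"], suv.organ_masks["liver"])
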