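import numpy as np
import pytest
from scipy.spatial.distance import pdist

from petmr_concordance.segmentation import (
    AdaptiveThresholdConfig,
    HistogramRefineConfig,
    SegmentationError,
    max_diameter,
    refine_adc_roi,
    segment_dwi_lesion,
    segment_pet_voi,
    transfer_mask,
    tumor_volume,
)
from petmr_concordance.volumes import ImageVolume, LesionMask


def ball_volume(value=10.0, bg=1.0, radius=15.0, spacing=(2.0, 2.0, 2.0), n=32):
    g = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2.0
    r2 = sum(((gi - c) * sp) ** 2 for gi, sp in zip(g, spacing))
    vals = np.where(r2 <= radius**2, value, bg)
    return ImageVolume(vals, spacing, (0, 0, 0), "SUV"), (c * spacing[0],) * 3


class TestAdaptivePetVoi:
    def test_uniform_sphere_volume_recovered(self):
        vol, center = ball_volume()
        mask = segment_pet_voi(vol, center)
        analytic = 4.0 / 3.0 * np.pi * 1.5**3  # cm^3
        assert tumor_volume(mask) == pytest.approx(analytic, rel=0.15)
        assert mask.converged

    def test_threshold_formula_beta_041(self):
        """Peak 10 over background 1 puts the cutoff at 1 + 0.41*9 = 4.69:
        a 5-shell survives, a 4-shell does not."""
        n = 40
        g = np.ogrid[:n, :n, :n]
        c = (n - 1) / 2.0
        r2 = sum(((gi - c) * 2.0) ** 2 for gi in g)
        vals = np.full((n, n, n), 1.0)
        vals[r2 <= 20.0**2] = 4.0   # below the 4.69 cutoff
        vals[r2 <= 14.0**2] = 5.0   # above it
        vals[r2 <= 8.0**2] = 10.0
        vol = ImageVolume(vals, (2, 2, 2), (0, 0, 0), "SUV")
        mask = segment_pet_voi(vol, (c * 2,) * 3)
        assert mask.mask[vals == 5.0].all()
        assert not mask.mask[vals == 4.0].any()

    def test_seed_in_background_fails(self):
        vol, _ = ball_volume()
        with pytest.raises(SegmentationError):
            segment_pet_voi(vol, (1.0, 1.0, 1.0))

    def test_output_contains_seed_and_is_connected(self, noisefree_pair_offset20):
        from scipy import ndimage

        suv = noisefree_pair_offset20[0]
        idx = np.unravel_index(np.argmax(suv.values), suv.shape)
        seed = suv.origin + np.array(idx) * suv.spacing
        mask = segment_pet_voi(suv, seed)
        assert mask.mask[idx]
        _, ncomp = ndimage.label(mask.mask, structure=np.ones((3, 3, 3)))
        assert ncomp == 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AdaptiveThresholdConfig(beta=1.5)
        with pytest.raises(ValueError):
            AdaptiveThresholdConfig(max_iterations=0)


class TestMaskTransfer:
    def test_same_grid_identity_and_idempotent(self, noisefree_pair_offset20):
        _, adc, dwi, _ = noisefree_pair_offset20
        idx = np.unravel_index(np.argmax(dwi.values), dwi.shape)
        seed = dwi.origin + np.array(idx) * dwi.spacing
        dm = segment_dwi_lesion(dwi, seed)
        once = transfer_mask(dm, adc)
        assert np.array_equal(once.mask, dm.mask)
        twice = transfer_mask(once, adc)
        assert np.array_equal(twice.mask, once.mask)

    def test_covers_ellipsoid_interior(self, noisefree_pair_offset20):
        """Noise-free delineation covers ~all analytic ellipsoid voxels."""
        _, adc, dwi, truth = noisefree_pair_offset20
        idx = np.unravel_index(np.argmax(dwi.values), dwi.shape)
        seed = dwi.origin + np.array(idx) * dwi.spacing
        m = transfer_mask(segment_dwi_lesion(dwi, seed), adc)
        ax = [adc.origin[a] + np.arange(adc.shape[a]) * adc.spacing[a] for a in range(3)]
        gx = np.meshgrid(*ax, indexing="ij", sparse=True)
        phys = [g + t for g, t in zip(gx, truth.translation.as_array)]
        inside = sum((p / s) ** 2 for p, s in zip(phys, (30.0, 24.0, 21.0))) <= 1.0
        assert m.mask[inside].mean() >= 0.99


class TestHistogramRefinement:
    def _mask_volume(self, values):
        values = np.asarray(values, float).reshape(-1, 1, 1)
        vol = ImageVolume(values, (1, 1, 1), (0, 0, 0), "ADC")
        mask = LesionMask.from_volume(vol, np.ones_like(values, bool))
        return vol, mask

    def test_low_outliers_removed_by_gap_rule(self, rng):
        cluster = rng.normal(1300, 100, 400).clip(900, 1700)
        vol, mask = self._mask_volume(np.concatenate([[0, 10, 40], cluster]))
        refined, removed = refine_adc_roi(vol, mask, HistogramRefineConfig(p_low=0.0))
        assert removed == 3
        assert vol.values[refined.mask].min() >= 900

    def test_no_outliers_unchanged(self, rng):
        vals = rng.uniform(1000, 1400, 500)
        vol, mask = self._mask_volume(vals)
        refined, removed = refine_adc_roi(vol, mask, HistogramRefineConfig(p_low=0.0))
        assert removed == 0
        assert np.array_equal(refined.mask, mask.mask)

    def test_constant_values_unchanged(self):
        vol, mask = self._mask_volume(np.full(50, 1200.0))
        refined, removed = refine_adc_roi(vol, mask)
        assert removed == 0

    def test_pure_filter_property(self, rng):
        """Refined mask is a subset and can only raise the masked minimum."""
        for _ in range(10):
            vals = np.concatenate(
                [rng.uniform(0, 100, rng.integers(0, 8)), rng.normal(1200, 150, 300)]
            ).clip(0, None)
            vol, mask = self._mask_volume(vals)
            refined, removed = refine_adc_roi(vol, mask)
            assert refined.mask.sum() + removed == mask.mask.sum()
            assert not (refined.mask & ~mask.mask).any()
            assert vol.values[refined.mask].min() >= vol.values[mask.mask].min()

    def test_mode_never_removed(self, rng):
        vals = np.concatenate([[0.0] * 2, rng.normal(1300, 60, 300)]).clip(0, None)
        vol, mask = self._mask_volume(vals)
        refined, _ = refine_adc_roi(vol, mask)
        counts, edges = np.histogram(vals, bins=np.arange(0, vals.max() + 100, 50))
        mode_lo = edges[np.argmax(counts)]
        in_mode = (vol.values >= mode_lo) & (vol.values < mode_lo + 50)
        assert refined.mask[in_mode.reshape(vol.shape) & mask.mask].all()


class TestMaskMetrics:
    def test_volume_arithmetic(self):
        m = np.zeros((20, 20, 20), bool)
        m.flat[:1000] = True
        assert tumor_volume(LesionMask(m, (1, 1, 1), (0, 0, 0))) == pytest.approx(1.0)
        m2 = np.zeros((10, 10, 10), bool)
        m2.flat[:10] = True
        assert tumor_volume(LesionMask(m2, (5.0, 5.0, 3.27), (0, 0, 0))) == pytest.approx(0.8175)

    def test_ellipsoid_volume_recovered(self):
        g = np.ogrid[:40, :32, :24]
        c = [(s - 1) / 2.0 for s in (40, 32, 24)]
        inside = sum(((gi - ci) * sp / ax) ** 2 for gi, ci, sp, ax in
                     zip(g, c, (1.3, 1.3, 1.3), (20.0, 15.0, 10.0))) <= 1.0
        v = tumor_volume(LesionMask(inside, (1.3, 1.3, 1.3), (0, 0, 0)))
        assert v == pytest.approx(4 / 3 * np.pi * 20 * 15 * 10 / 1000, rel=0.1)

    def test_diameter_trivial_cases(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert max_diameter(LesionMask(m, (1, 1, 1), (0, 0, 0))) == 0.0
        m[2, 2, 2] = False
        m[0, 0, 0] = m[3, 0, 0] = True
        assert max_diameter(LesionMask(m, (10, 1, 1), (0, 0, 0))) == pytest.approx(30.0)

    def test_digitized_sphere_diameter(self):
        g = np.ogrid[:40, :40, :40]
        c = 19.5
        inside = sum(((gi - c) * 1.4) ** 2 for gi in g) <= 25.0**2
        mask = LesionMask(inside, (1.4, 1.4, 1.4), (0, 0, 0))
        assert max_diameter(mask) == pytest.approx(50.0, abs=np.linalg.norm([1.4] * 3))

    def test_hull_shortcut_matches_bruteforce(self, rng):
        blob = rng.random((16, 16, 16)) > 0.35  # > 500 voxels: hull path
        blob[0, 0, 0] = True
        mask = LesionMask(blob, (1.7, 2.1, 0.9), (0, 0, 0))
        pts = mask.origin + np.argwhere(mask.mask) * mask.spacing
        assert max_diameter(mask) == pytest.approx(float(pdist(pts).max()))
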