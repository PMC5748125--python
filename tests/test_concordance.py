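import numpy as np
import pytest

from petmr_concordance import SyntheticLesionSpec, make_lesion_pair
from petmr_concordance.concordance import (
    classify_match,
    extrema_distance,
    lesion_report,
    locate_extremum,
    sphere_radius_mm,
    sphere_stats,
)
from petmr_concordance.pipeline import analyze_lesion_pair
from petmr_concordance.volumes import (
    ImageVolume,
    LesionMask,
    TranslationVector,
    voxel_diagonal,
)


def vol(values, spacing=(1, 1, 1), origin=(0, 0, 0), modality="SUV"):
    return ImageVolume(np.asarray(values, float), spacing, origin, modality)


class TestLocateExtremum:
    def test_single_voxel_mask(self, rng):
        v = vol(rng.random((5, 5, 5)))
        m = np.zeros((5, 5, 5), bool)
        m[3, 1, 4] = True
        locus = locate_extremum(v, LesionMask.from_volume(v, m), "max")
        assert locus.index == (3, 1, 4)
        assert locus.tie_count == 1
        assert locus.value == v.values[3, 1, 4]

    def test_tie_break_lowest_x_fastest_linear_index(self):
        v = vol(np.zeros((3, 3, 3)))
        vals = v.values
        vals[0, 0, 1] = 5.0
        vals[1, 0, 0] = 5.0  # x-fastest linear index 1 < index of (0,0,1)
        locus = locate_extremum(v, LesionMask.from_volume(v, np.ones((3, 3, 3), bool)), "max")
        assert locus.index == (1, 0, 0)
        assert locus.tie_count == 2

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            shape = tuple(rng.integers(4, 20, 3))
            v = vol(rng.normal(size=shape), spacing=rng.uniform(0.5, 5, 3))
            m = rng.random(shape) > 0.4
            if not m.any():
                m[0, 0, 0] = True
            for kind, fn in (("max", np.max), ("min", np.min)):
                locus = locate_extremum(v, LesionMask.from_volume(v, m), kind)
                assert locus.value == fn(v.values[m])

    def test_empty_mask_error(self, rng):
        v = vol(rng.random((4, 4, 4)))
        m = LesionMask.from_volume(v, np.ones((4, 4, 4), bool))
        object.__setattr__(m, "mask", np.zeros((4, 4, 4), bool))  # bypass ctor guard
        with pytest.raises(ValueError):
            locate_extremum(v, m, "max")


class TestDistanceAndMatch:
    def _locus(self, world):
        from petmr_concordance.concordance import ExtremumLocus

        return ExtremumLocus(index=(0, 0, 0), world=np.asarray(world, float), value=0.0, tie_count=1)

    def test_identical_points_zero(self):
        assert extrema_distance(
            self._locus((1, 2, 3)), self._locus((1, 2, 3)), TranslationVector(0, 0, 0)
        ) == 0.0

    def test_pythagorean(self):
        assert extrema_distance(
            self._locus((0, 0, 0)), self._locus((-3, -4, 0)), TranslationVector(0, 0, 0)
        ) == pytest.approx(5.0)

    def test_global_frame_shift_invariance(self, rng):
        for _ in range(20):
            p, q = rng.normal(0, 30, 3), rng.normal(0, 30, 3)
            t = rng.normal(0, 8, 3)
            shift = rng.normal(0, 50, 3)
            d0 = extrema_distance(self._locus(p), self._locus(q), TranslationVector(*t))
            d1 = extrema_distance(
                self._locus(p + shift), self._locus(q + shift), TranslationVector(*t)
            )
            assert d0 == pytest.approx(d1)

    @pytest.mark.parametrize(
        "distance,expected",
        [(5.3, "match"), (19.5, "mismatch"), (12.0, "match"), (12.0001, "mismatch")],
    )
    def test_threshold_rule_at_12mm(self, distance, expected):
        assert classify_match(distance, 12.0) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_match(-1.0, 12.0)
        with pytest.raises(ValueError):
            classify_match(5.0, 0.0)


class TestSphereStats:
    def test_radius_of_one_cm3(self):
        assert sphere_radius_mm(1.0) == pytest.approx((3000.0 / (4 * np.pi)) ** (1 / 3))
        assert sphere_radius_mm(1.0) == pytest.approx(6.2035, abs=1e-3)

    def test_constant_volume(self):
        v = vol(np.full((10, 10, 10), 3.3), (2, 2, 2))
        m = LesionMask.from_volume(v, np.ones((10, 10, 10), bool))
        s = sphere_stats(v, m, (9, 9, 9))
        assert s.min_in_sphere == s.max_in_sphere == 3.3
        assert s.mean_in_sphere == pytest.approx(3.3, rel=1e-12)
        assert s.value_at_center == 3.3

    def test_matches_bruteforce_oracle(self, rng):
        """Exhaustive all-voxel scan reproduces sphere_stats exactly."""
        shape = (22, 19, 17)
        spacing = np.array([2.6, 2.6, 5.0])
        v = vol(rng.normal(size=shape), spacing)
        m = rng.random(shape) > 0.3
        m[0, 0, 0] = True
        mask = LesionMask.from_volume(v, m)
        idx = np.argwhere(np.ones(shape, bool))  # C order, matches reshape(-1)
        pts = idx * spacing
        flat_vals, flat_mask = v.values.reshape(-1), m.reshape(-1)
        radius = sphere_radius_mm(1.0)
        for _ in range(50):
            center = rng.uniform(0, np.array(shape) * spacing - spacing)
            s = sphere_stats(v, mask, center)
            sel = (np.sum((pts - center) ** 2, axis=1) <= radius**2) & flat_mask
            if not sel.any():
                continue
            vals = flat_vals[sel]
            assert s.min_in_sphere == vals.min()
            assert s.max_in_sphere == vals.max()
            assert s.mean_in_sphere == pytest.approx(vals.mean(), rel=1e-12)
            assert s.n_voxels == int(sel.sum())

    def test_center_outside_volume_error(self, rng):
        v = vol(rng.random((5, 5, 5)))
        m = LesionMask.from_volume(v, np.ones((5, 5, 5), bool))
        with pytest.raises(ValueError):
            sphere_stats(v, m, (100, 0, 0))

    def test_empty_intersection_falls_back_to_nearest(self):
        v = vol(np.arange(1000).reshape(10, 10, 10).astype(float), (2, 2, 2))
        m = np.zeros((10, 10, 10), bool)
        m[9, 9, 9] = True
        with pytest.warns(UserWarning, match="nearest in-mask"):
            s = sphere_stats(v, LesionMask.from_volume(v, m), (0, 0, 0))
        assert s.n_voxels == 1
        assert s.fallback_nearest
        assert s.min_in_sphere == v.values[9, 9, 9]


class TestLesionReport:
    def test_coincident_foci_match(self, noisefree_pair_coincident):
        suv, adc, dwi, truth = noisefree_pair_coincident
        rec = analyze_lesion_pair(suv, adc, dwi, [truth.translation], threshold_mm=12.0)[0]
        assert rec.distance_mm <= max(voxel_diagonal(suv), voxel_diagonal(adc))
        assert rec.match

    def test_large_offset_is_mismatch(self):
        spec = SyntheticLesionSpec(
            semi_axes=(32, 26, 22),
            suv_focus=(12.5, 0, 0),
            adc_trough=(-12.5, 0, 0),
            noise_sd_suv=0.0,
            noise_sd_adc=0.0,
            noise_sd_dwi=0.0,
            rim_outlier_fraction=0.0,
            seed=3,
        )
        suv, adc, dwi, truth = make_lesion_pair(spec)
        rec = analyze_lesion_pair(suv, adc, dwi, [truth.translation], threshold_mm=12.0)[0]
        assert not rec.match
        assert rec.suv_max_at_adcmin < rec.suv_max

    def test_record_invariants_on_random_phantoms(self, rng):
        """Sphere-in-VOI construction forces the cross-parameter orderings."""
        for i in range(40):
            off = rng.uniform(0, 30)
            spec = SyntheticLesionSpec(
                semi_axes=tuple(rng.uniform(18, 32, 3)),
                suv_focus=(off / 2, 0, 0),
                adc_trough=(-off / 2, 0, 0),
                rim_outlier_fraction=float(rng.uniform(0, 0.2)),
                seed=int(rng.integers(2**31)),
            )
            if spec._ellipsoid_coord(spec.suv_focus) > 0.9:
                continue
            suv, adc, dwi, truth = make_lesion_pair(spec)
            rec = analyze_lesion_pair(suv, adc, dwi, [truth.translation], threshold_mm=12.0)[0]
            assert rec.adc_min <= rec.adc_min_at_suvmax
            assert rec.suv_max >= rec.suv_max_at_adcmin
            assert rec.suv_mean <= rec.suv_max
            assert rec.adc_min <= rec.adc_mean
            assert rec.distance_mm >= 0
            assert rec.v_pet_cm3 > 0 and rec.v_mri_cm3 > 0

    def test_classification_agreement_with_reader_noise(self, rng):
        """With 2 mm per-axis reader error, match/mismatch at 12 mm agrees
        with the truth labels for >= 90% of offsets away from the boundary."""
        agree = n = 0
        for i in range(80):
            off = rng.uniform(0, 30)
            if 9.0 <= off <= 15.0:
                continue
            spec = SyntheticLesionSpec(
                semi_axes=(30, 25, 21),
                suv_focus=(off / 2, 0, 0),
                adc_trough=(-off / 2, 0, 0),
                noise_sd_suv=0.0,
                noise_sd_adc=0.0,
                noise_sd_dwi=0.0,
                rim_outlier_fraction=0.0,
                reader_noise_sd=2.0,
                reader_noise_scale_sigma=0.0,
                seed=int(rng.integers(2**31)),
            )
            suv, adc, dwi, truth = make_lesion_pair(spec)
            reader_t = truth.reader_translations[0]
            rec = analyze_lesion_pair(suv, adc, dwi, [reader_t], threshold_mm=12.0)[0]
            n += 1
            agree += int(rec.match == (truth.offset_mm <= 12.0))
        assert n >= 40
        assert agree / n >= 0.90
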