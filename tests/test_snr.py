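import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scanqc.image import VoxelImage
from scanqc.simulate import PhantomSpec, make_phantom
from scanqc.snr import (
    build_roi_geometry,
    center_of_intensity,
    compute_snr_features,
    compute_tsnr,
    estimate_noise_chang,
    snr_chang,
    snr_standard,
)

from conftest import make_exact_snr_image


class TestCenterOfIntensity:
    def test_point_mass(self):
        vol = np.zeros((8, 8, 8))
        vol[3, 4, 5] = 7.0
        assert center_of_intensity(vol) == (3, 4, 5)

    def test_uniform_symmetry(self):
        assert center_of_intensity(np.ones((11, 11, 11))) == (5, 5, 5)

    def test_two_point_masses_midpoint(self):
        vol = np.zeros((11, 11, 11))
        vol[0, 0, 0] = vol[10, 0, 0] = 1.0
        assert center_of_intensity(vol) == (5, 0, 0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="no signal mass"):
            center_of_intensity(np.zeros((8, 8, 8)))


class TestRoiGeometry:
    def test_relative_size_rules(self):
        vol = np.zeros((64, 64, 32))
        vol[24:40, 24:40, 12:20] = 1.0
        geom = build_roi_geometry(vol)
        # radius = floor(0.1 * min(dims)); cuboid edges floor(0.15 * dim)
        assert geom.sphere_radius_vox == 3
        # each corner cuboid is 9 x 9 x 4
        assert geom.n_cuboid == 8 * 9 * 9 * 4

    def test_disjointness(self, small_phantom):
        geom = build_roi_geometry(small_phantom.intensities)
        assert not (geom.sphere_mask & geom.cuboid_mask).any()

    def test_minimum_dims_boundary(self):
        geom = build_roi_geometry(np.ones((8, 8, 8)))
        assert geom.sphere_radius_vox >= 1
        assert not (geom.sphere_mask & geom.cuboid_mask).any()

    def test_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            build_roi_geometry(np.ones((4, 4, 4)))


class TestSnrStandard:
    @pytest.mark.parametrize("ratio,expected", [(1, 0.0), (10, 20.0), (100, 40.0)])
    def test_closed_form_db(self, ratio, expected):
        img = make_exact_snr_image(ratio)
        assert snr_standard(img) == expected

    def test_phantom_oracle(self, phantom):
        """Value equals 20 log10(mu/sigma) measured brute-force on the masks."""
        geom = build_roi_geometry(phantom.intensities)
        mu = phantom.intensities[geom.sphere_mask].mean()
        sigma = phantom.intensities[geom.cuboid_mask].std()
        assert snr_standard(phantom) == pytest.approx(20 * math.log10(mu / sigma))
        assert snr_standard(phantom) == pytest.approx(20.0, abs=0.5)

    def test_zero_noise_sentinel(self):
        img = make_phantom(PhantomSpec(background_noise_sd=0.0, seed=0))
        notes = []
        assert snr_standard(img, notes=notes) == math.inf
        assert any("zero-noise" in n for n in notes)

    def test_4d_uses_first_b0(self, small_phantom):
        clean = small_phantom.intensities
        stack = np.stack([clean, np.roll(clean, 5, axis=0)], axis=3)
        img = VoxelImage(stack, bvalues=[0.0, 1000.0])
        assert snr_standard(img) == snr_standard(small_phantom)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(k=st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, k):
        img = make_phantom(PhantomSpec(dims=(32, 32, 16), seed=4))
        scaled = VoxelImage(img.intensities * k)
        assert snr_standard(scaled) == pytest.approx(snr_standard(img), abs=1e-9)


class TestChangNoise:
    def test_gaussian_slice_accuracy(self, rng):
        sigma = 3.0
        sl = rng.normal(0, sigma, (128, 128))
        est = estimate_noise_chang(sl)
        assert est == pytest.approx(sigma, rel=0.15)

    def test_constant_slice_zero(self):
        assert estimate_noise_chang(np.full((64, 64), 7.0)) == 0.0

    def test_scale_equivariance(self, rng):
        sl = rng.normal(0, 2.0, (96, 96))
        base = estimate_noise_chang(sl)
        for k in (0.5, 3.0, 10.0):
            assert estimate_noise_chang(sl * k) == pytest.approx(k * base, rel=0.05)

    def test_small_slice_raises(self):
        with pytest.raises(ValueError):
            estimate_noise_chang(np.ones((4, 4)))


class TestSnrChang:
    def test_known_ratio(self, rng):
        """Slices of mean ~100 and noise sigma 1 give ~40 dB."""
        vol = 100.0 + rng.normal(0, 1.0, (64, 64, 8))
        img = VoxelImage(np.clip(vol, 0, None))
        assert snr_chang(img) == pytest.approx(40.0, abs=1.5)

    def test_duplicated_directions_match_3d(self, small_phantom):
        stack = np.stack([small_phantom.intensities] * 2, axis=3)
        img4 = VoxelImage(stack, bvalues=[1000.0, 1000.0])
        assert snr_chang(img4) == pytest.approx(snr_chang(small_phantom))

    def test_all_constant_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            snr_chang(VoxelImage(np.full((32, 32, 4), 5.0)))


class TestTsnr:
    def test_closed_form(self):
        img = make_phantom(
            PhantomSpec(dims=(48, 48, 16), tissue_intensity=100,
                        background_noise_sd=10, n_volumes=200, seed=2)
        )
        _, value = compute_tsnr(img)
        assert value == pytest.approx(20.0, abs=0.5)

    def test_intensity_scale_invariance(self):
        img = make_phantom(PhantomSpec(dims=(32, 32, 16), n_volumes=20, seed=3))
        doubled = VoxelImage(img.intensities * 2.0)
        assert compute_tsnr(doubled)[1] == pytest.approx(
            compute_tsnr(img)[1], abs=1e-9
        )

    def test_halved_noise_adds_six_db(self):
        """Halving temporal noise raises tSNR by 20 log10(2) ~ 6.02 dB."""
        rng = np.random.default_rng(7)
        base = make_phantom(PhantomSpec(dims=(32, 32, 16), tissue_intensity=100,
                                        background_noise_sd=0, n_volumes=1, seed=5))
        signal = base.intensities[..., None]
        noise = rng.normal(0, 10.0, signal.shape[:3] + (300,))
        img_full = VoxelImage(np.clip(signal + noise, 0, None))
        img_half = VoxelImage(np.clip(signal + 0.5 * noise, 0, None))
        delta = compute_tsnr(img_half)[1] - compute_tsnr(img_full)[1]
        assert delta == pytest.approx(20 * math.log10(2), abs=0.3)

    def test_constant_voxels_excluded_and_flagged(self):
        img = make_phantom(PhantomSpec(dims=(32, 32, 16), n_volumes=6, seed=9))
        data = img.intensities.copy()
        geom = build_roi_geometry(data.mean(axis=3))
        cx, cy, cz = geom.coi
        data[cx, cy, cz, :] = data[cx, cy, cz, 0]  # temporally frozen voxel
        notes = []
        tsnr_map, value = compute_tsnr(VoxelImage(data), notes=notes)
        assert np.isinf(tsnr_map[cx, cy, cz])
        assert np.isfinite(value)
        assert any("constant" in n for n in notes)

    def test_3d_input_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            compute_tsnr(small_phantom)


class TestFeatureOrchestration:
    def test_anatomical_features(self, small_phantom):
        res = compute_snr_features(small_phantom, "anatomical")
        assert np.isfinite(res.snr_standard_db)
        assert np.isfinite(res.snr_chang_db)
        assert res.tsnr_db is None

    def test_functional_features(self):
        img = make_phantom(PhantomSpec(dims=(32, 32, 16), n_volumes=12, seed=6))
        res = compute_snr_features(img, "functional")
        assert np.isfinite(res.tsnr_db)
        assert res.snr_standard_db is None

    def test_failure_becomes_note_not_crash(self):
        img = VoxelImage(np.full((32, 32, 8), 3.0))  # constant: COI fine, noise 0
        res = compute_snr_features(img, "anatomical")
        assert res.notes  # degenerate flags recorded, no exception
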