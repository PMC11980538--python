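import numpy as np
import pytest

from scanqc.motion import ghost_curve, motion_severity, motion_trace
from scanqc.simulate import (
    ArtifactSpec,
    PhantomSpec,
    build_validation_cohort,
    inject_ghost,
    inject_motion,
    inject_noise,
    make_phantom,
)
from scanqc.snr import build_roi_geometry, snr_chang, snr_standard


class TestMakePhantom:
    def test_zero_noise_corners_exactly_zero(self):
        img = make_phantom(PhantomSpec(background_noise_sd=0.0, seed=0))
        geom = build_roi_geometry(img.intensities)
        assert (img.intensities[geom.cuboid_mask] == 0).all()

    def test_determinism(self):
        spec = PhantomSpec(seed=99)
        np.testing.assert_array_equal(
            make_phantom(spec).intensities, make_phantom(spec).intensities
        )

    def test_snr_matches_specification(self):
        """Tissue 50 over noise sd 5 lands near 20 dB, verified against a
        brute-force mean/std oracle over the generated voxels."""
        img = make_phantom(
            PhantomSpec(tissue_intensity=50, background_noise_sd=5, seed=21)
        )
        geom = build_roi_geometry(img.intensities)
        mu = img.intensities[geom.sphere_mask].mean()
        sigma = img.intensities[geom.cuboid_mask].std()
        value = snr_standard(img)
        assert value == pytest.approx(20 * np.log10(mu / sigma))
        assert value == pytest.approx(20.0, abs=0.5)

    def test_4d_frames_share_anatomy(self):
        img = make_phantom(PhantomSpec(dims=(32, 32, 16), n_volumes=4, seed=3))
        assert img.dims == (32, 32, 16, 4)
        frames = img.intensities
        # same ellipsoid support, independent noise
        assert not np.array_equal(frames[..., 0], frames[..., 1])
        assert np.corrcoef(frames[..., 0].ravel(), frames[..., 1].ravel())[0, 1] > 0.8

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(dims=(8, 8, 8))


class TestInjectNoise:
    def test_zero_variance_identity(self, phantom):
        out = inject_noise(phantom, ArtifactSpec(kind="gaussian", gaussian_variance=0))
        np.testing.assert_allclose(out.intensities, phantom.intensities)

    def test_salt_pepper_exact_count(self):
        from scanqc.image import VoxelImage

        rng = np.random.default_rng(0)
        img = VoxelImage(rng.uniform(0.2, 0.8, (20, 20, 20)))
        amount = 0.05
        out = inject_noise(img, ArtifactSpec(kind="salt_pepper", sp_amount=amount,
                                             seed=4))
        n_altered = int((out.intensities != img.intensities).sum())
        assert n_altered == int(amount * img.intensities.size)

    def test_noise_plus_gamma_lowers_both_snrs(self, phantom):
        noisy = inject_noise(phantom, ArtifactSpec(kind="gaussian", seed=5))
        shaded = inject_noise(noisy, ArtifactSpec(kind="gamma"))
        assert snr_standard(shaded) < snr_standard(phantom)
        assert snr_chang(shaded) < snr_chang(phantom)

    def test_monotone_degradation_gaussian(self, phantom):
        """SNR strictly decreases as injected noise variance grows."""
        std_curve, chang_curve = [], []
        for var in (0.0, 0.05, 0.1, 0.2):
            noisy = inject_noise(
                phantom,
                ArtifactSpec(kind="gaussian", gaussian_variance=var, seed=7),
            )
            std_curve.append(snr_standard(noisy))
            chang_curve.append(snr_chang(noisy))
        assert all(a > b for a, b in zip(std_curve, std_curve[1:]))
        assert all(a > b for a, b in zip(chang_curve, chang_curve[1:]))

    def test_speckle_determinism(self, phantom):
        spec = ArtifactSpec(kind="speckle", seed=8)
        np.testing.assert_array_equal(
            inject_noise(phantom, spec).intensities,
            inject_noise(phantom, spec).intensities,
        )

    def test_invalid_amount_rejected(self):
        with pytest.raises(ValueError):
            ArtifactSpec(kind="salt_pepper", sp_amount=1.5)


class TestInjectMotion:
    @pytest.fixture
    def series(self):
        return make_phantom(PhantomSpec(dims=(48, 48, 16), n_volumes=20, seed=11))

    def test_zero_amplitude_identity(self, series):
        out = inject_motion(series, ArtifactSpec(kind="motion",
                                                 motion_amplitude_vox=0))
        np.testing.assert_array_equal(out.intensities, series.intensities)

    def test_motion_raises_severity(self, series):
        still = motion_severity(motion_trace(series))
        moved = inject_motion(
            series, ArtifactSpec(kind="motion", motion_amplitude_vox=3, seed=13)
        )
        assert motion_severity(motion_trace(moved)) > still

    def test_3d_rejected(self, phantom):
        with pytest.raises(ValueError):
            inject_motion(phantom, ArtifactSpec(kind="motion"))


class TestInjectGhost:
    def test_zero_fraction_identity(self, small_phantom):
        out = inject_ghost(small_phantom, ArtifactSpec(kind="ghost",
                                                       ghost_fraction=0.0))
        np.testing.assert_array_equal(out.intensities, small_phantom.intensities)

    def test_detectable_at_half_fov(self, small_phantom):
        out = inject_ghost(small_phantom, ArtifactSpec(kind="ghost",
                                                       ghost_fraction=0.3))
        ev = ghost_curve(out)
        n = small_phantom.dims[1]
        assert ev.is_ghost
        assert min(abs(p - n // 2) for p in ev.peak_shifts) <= 2

    def test_prominence_grows_with_fraction(self, small_phantom):
        proms = []
        for frac in (0.1, 0.2, 0.4):
            out = inject_ghost(
                small_phantom, ArtifactSpec(kind="ghost", ghost_fraction=frac)
            )
            ev = ghost_curve(out)
            proms.append(max(ev.peak_prominences, default=0.0))
        assert all(a <= b for a, b in zip(proms, proms[1:]))
        assert proms[-1] > 0


class TestValidationCohort:
    def test_file_counts_and_labels(self, tmp_path):
        truth = build_validation_cohort(
            tmp_path, n_clean=10, contaminate_index=2,
            phantom_spec=PhantomSpec(dims=(32, 32, 16)), seed=5,
            classes=("anatomical", "diffusion"),
        )
        import pandas as pd

        labels = pd.read_csv(truth)
        assert len(labels) == 22  # 11 scans per class
        assert labels["contaminated"].sum() == 2
        niftis = list(tmp_path.rglob("*.nii.gz"))
        assert len(niftis) == 22
        bvals = list(tmp_path.rglob("*.bval"))
        assert len(bvals) == 11

    def test_byte_identical_reruns(self, tmp_path):
        import hashlib

        for sub in ("a", "b"):
            build_validation_cohort(
                tmp_path / sub, n_clean=10,
                phantom_spec=PhantomSpec(dims=(32, 32, 16)), seed=6,
                classes=("anatomical",),
            )
        digest = lambda d: [
            hashlib.md5(p.read_bytes()).hexdigest()
            for p in sorted(d.rglob("*") ) if p.is_file()
        ]
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_too_small_cohort_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_validation_cohort(tmp_path, n_clean=3)
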