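"""Synthetic brain-like phantoms and artifact injection.

The phantom is an ellipsoidal "brain" of roughly uniform tissue intensity
(with mild smooth internal texture) centred in an air background whose noise
floor mimics magnitude-reconstructed MR data: the corners stay pure noise so
the automatic SNR geometry sees a realistic signal/air partition.  Artifact
families mirror the degradations seen in practice: additive Gaussian noise,
salt-and-pepper speckles, multiplicative speckle noise, gamma shading,
frame-wise translational motion, and half-FOV ghost copies.

Noise parameters act on intensities normalized to [0, 1] (so a Gaussian
variance of 0.2 is meaningful regardless of scanner scaling) and the
original intensity scale is restored afterwards.  Every operation is
deterministic under its seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .image import VoxelImage

ARTIFACT_KINDS = ("gaussian", "salt_pepper", "speckle", "gamma", "motion", "ghost")


@dataclass(frozen=True)
class PhantomSpec:
    """Reproducible description of one synthetic scan.

    tissue_intensity / background_noise_sd default to a ~20 dB scan, a
    mid-range small-animal acquisition; n_volumes > 1 produces a 4D series
    repeating the same anatomy with independent temporal noise.
    """

    dims: tuple[int, int, int] = (64, 64, 32)
    tissue_intensity: float = 50.0
    background_noise_sd: float = 5.0
    n_volumes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 16 for d in self.dims):
            raise ValueError("phantom dims must be 3 axes of >= 16 voxels")
        if self.tissue_intensity <= 0 or self.background_noise_sd < 0:
            raise ValueError("invalid intensity/noise parameters")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")


@dataclass(frozen=True)
class ArtifactSpec:
    """Parameters of one artifact family.

    Defaults follow the validation protocol: Gaussian variance 0.2 and gamma
    0.6 (shading) for noise contamination; salt-and-pepper amount 0.05 and
    speckle variance 0.2; ghost fraction 0.3 at half the field of view.
    """

    kind: str = "gaussian"
    gaussian_variance: float = 0.2
    gamma_value: float = 0.6
    sp_amount: float = 0.05
    speckle_variance: float = 0.2
    motion_amplitude_vox: float = 3.0
    ghost_fraction: float = 0.3
    ghost_shift: int | None = None  # default: half the shift-axis extent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.gaussian_variance < 0 or self.speckle_variance < 0:
            raise ValueError("noise variances must be >= 0")
        if not 0 <= self.sp_amount <= 1:
            raise ValueError("sp_amount must be a proportion in [0, 1]")
        if self.gamma_value <= 0:
            raise ValueError("gamma must be > 0")
        if self.motion_amplitude_vox < 0:
            raise ValueError("motion amplitude must be >= 0")
        if not 0 <= self.ghost_fraction < 1:
            raise ValueError("ghost_fraction must be in [0, 1)")


def make_phantom(spec: PhantomSpec) -> VoxelImage:
    """Generate the ellipsoidal brain phantom described by ``spec``.

    The background noise floor sits at 3 sigma above zero so that clipping
    to non-negative magnitudes leaves the corner standard deviation at the
    requested value (as in magnitude MR data, where air is a positive noise
    floor, not zero-mean).  ``background_noise_sd = 0`` gives exactly zero
    corners.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.dims
    grids = np.ogrid[:nx, :ny, :nz]
    center = [(d - 1) / 2 for d in spec.dims]
    semi = [0.32 * d for d in spec.dims]
    ellipse = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi)) <= 1.0

    # mild smooth internal texture (+-5%), seeded
    texture = gaussian_filter(rng.standard_normal(spec.dims), sigma=4, mode="wrap")
    peak = np.abs(texture).max()
    if peak > 0:
        texture = texture / peak * 0.05
    base = np.where(ellipse, spec.tissue_intensity * (1.0 + texture), 0.0)

    sd = spec.background_noise_sd
    floor = np.where(ellipse, 0.0, 3.0 * sd)

    def one_frame() -> np.ndarray:
        noise = rng.normal(0.0, sd, spec.dims) if sd > 0 else 0.0
        return np.clip(base + floor + noise, 0.0, None)

    if spec.n_volumes == 1:
        return VoxelImage(one_frame())
    frames = np.stack([one_frame() for _ in range(spec.n_volumes)], axis=3)
    return VoxelImage(frames)


def _normalized(image: VoxelImage) -> tuple[np.ndarray, float]:
    vmax = float(image.intensities.max())
    if vmax <= 0:
        raise ValueError("cannot normalize an all-zero image")
    return image.intensities / vmax, vmax


def inject_noise(image: VoxelImage, spec: ArtifactSpec) -> VoxelImage:
    """Apply one intensity artifact (gaussian / salt_pepper / speckle / gamma).

    Compose multiple families by chaining calls.  Intensities are processed
    on a [0, 1] normalized copy, clipped back into range, and restored to
    the original scale.
    """
    x, vmax = _normalized(image)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "salt_pepper":
        # edit the original-scale array directly: the altered-voxel count is
        # then exact and untouched voxels stay bit-identical
        out = image.intensities.copy()
        n_alter = int(spec.sp_amount * out.size)
        if n_alter:
            flat = out.reshape(-1)
            idx = rng.choice(out.size, size=n_alter, replace=False)
            half = n_alter // 2
            flat[idx[:half]] = vmax  # salt
            flat[idx[half:]] = 0.0  # pepper
        return VoxelImage(out, image.voxel_size_mm, image.bvalues)
    if spec.kind == "gaussian":
        if spec.gaussian_variance > 0:
            x = x + rng.normal(0.0, np.sqrt(spec.gaussian_variance), x.shape)
    elif spec.kind == "speckle":
        if spec.speckle_variance > 0:
            x = x * (1.0 + rng.normal(0.0, np.sqrt(spec.speckle_variance), x.shape))
    elif spec.kind == "gamma":
        x = np.power(x, spec.gamma_value)
    else:
        raise ValueError(
            f"inject_noise handles intensity artifacts, not {spec.kind!r}"
        )
    x = np.clip(x, 0.0, 1.0)
    return VoxelImage(x * vmax, image.voxel_size_mm, image.bvalues)


def inject_motion(image: VoxelImage, spec: ArtifactSpec) -> VoxelImage:
    """Translate every frame after the first by random in-plane offsets.

    Offsets are integers drawn uniformly from [-amplitude, +amplitude] per
    frame and axis (circular shift, so no intensity is lost).  Amplitude 0
    is the identity.
    """
    if not image.is_4d:
        raise ValueError("inject_motion requires a 4D image")
    amp = int(round(spec.motion_amplitude_vox))
    if amp == 0:
        return image
    rng = np.random.default_rng(spec.seed)
    data = image.intensities.copy()
    for t in range(1, image.n_volumes):
        dx, dy = rng.integers(-amp, amp + 1, size=2)
        data[..., t] = np.roll(data[..., t], (int(dx), int(dy)), axis=(0, 1))
    return VoxelImage(data, image.voxel_size_mm, image.bvalues)


def inject_ghost(image: VoxelImage, spec: ArtifactSpec) -> VoxelImage:
    """Add an attenuated circularly shifted copy of the object (a ghost).

    The copy is weighted by ``ghost_fraction`` and shifted along the second
    in-plane axis, by half its extent unless ``ghost_shift`` overrides —
    the EPI Nyquist-ghost geometry.  The result is rescaled to the original
    intensity maximum.
    """
    if spec.ghost_fraction == 0:
        return image
    data = image.intensities
    shift = spec.ghost_shift if spec.ghost_shift is not None else data.shape[1] // 2
    out = data + spec.ghost_fraction * np.roll(data, shift, axis=1)
    vmax = data.max()
    omax = out.max()
    if omax > 0 and vmax > 0:
        out = out * (vmax / omax)
    return VoxelImage(out, image.voxel_size_mm, image.bvalues)


# ---------------------------------------------------------------------------
# validation cohorts
# ---------------------------------------------------------------------------

_CLASS_LAYOUT = {
    # class -> (BIDS modality folder, filename suffix)
    "anatomical": ("anat", "T2w"),
    "diffusion": ("dwi", "dwi"),
    "functional": ("func", "bold"),
}


def _contaminate(image: VoxelImage, cls: str, artifact: ArtifactSpec) -> VoxelImage:
    """Standard contamination recipe: noise + shading for 3D-like classes,
    injected motion for functional series."""
    if cls == "functional":
        return inject_motion(image, replace(artifact, kind="motion"))
    noisy = inject_noise(image, replace(artifact, kind="gaussian"))
    return inject_noise(noisy, replace(artifact, kind="gamma"))


def build_validation_cohort(
    outdir: str | Path,
    n_clean: int = 30,
    contaminate_index: int = 0,
    phantom_spec: PhantomSpec | None = None,
    artifact_spec: ArtifactSpec | None = None,
    seed: int = 0,
    classes: tuple[str, ...] = ("anatomical", "diffusion", "functional"),
) -> Path:
    """Write a BIDS-like fixture tree of ``n_clean`` + 1 scans per class.

    Subject ``contaminate_index`` (0-based) receives the class-appropriate
    artifact; everyone else stays clean.  Diffusion scans get a ``.bval``
    sidecar, functional scans a repetition axis.  Ground-truth labels are
    written as ``ground_truth.csv`` in ``outdir``; the path of that table
    is returned.  Same seeds → byte-identical trees.
    """
    if n_clean < 10:
        raise ValueError("need at least 10 clean scans for a meaningful cohort")
    if not 0 <= contaminate_index <= n_clean:
        raise ValueError("contaminate_index out of range")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phantom_spec = phantom_spec or PhantomSpec()
    artifact_spec = artifact_spec or ArtifactSpec()

    labels: list[tuple[str, str, int]] = []
    for ci, cls in enumerate(classes):
        folder, suffix = _CLASS_LAYOUT[cls]
        n_volumes = phantom_spec.n_volumes
        if cls != "anatomical" and n_volumes == 1:
            n_volumes = 10  # 4D classes need a 4th axis
        for i in range(n_clean + 1):
            sub = f"sub-{i + 1:02d}"
            spec = replace(
                phantom_spec,
                n_volumes=n_volumes if cls != "anatomical" else phantom_spec.n_volumes,
                seed=seed + 1009 * ci + i,
            )
            image = make_phantom(spec)
            bvalues = None
            if cls == "diffusion":
                bvalues = [0.0] + [1000.0] * (image.n_volumes - 1)
                image = VoxelImage(image.intensities, image.voxel_size_mm, bvalues)
            contaminated = i == contaminate_index
            if contaminated:
                image = _contaminate(
                    image, cls, replace(artifact_spec, seed=seed + 7919 * ci + i)
                )
            target = outdir / sub / folder
            target.mkdir(parents=True, exist_ok=True)
            stem = f"{sub}_{suffix}"
            nii = nib.Nifti1Image(
                image.intensities.astype(np.float32), affine=np.eye(4)
            )
            nib.save(nii, str(target / f"{stem}.nii.gz"))
            if bvalues is not None:
                (target / f"{stem}.bval").write_text(
                    " ".join(str(int(b)) for b in bvalues) + "\n"
                )
            labels.append((f"{sub}/{folder}/{stem}.nii.gz", cls, int(contaminated)))

    truth = outdir / "ground_truth.csv"
    with truth.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "sequence_class", "contaminated"])
        writer.writerows(labels)
    return truth
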