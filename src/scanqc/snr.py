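"""ROI-free spatial and temporal SNR estimation, reported in decibels.

Two spatial estimators are provided:

* the *standard* method anchors a signal sphere at the intensity-weighted
  centroid (center of intensity, COI) and pools the noise standard deviation
  over eight corner cuboids: ``SNR = 20 log10(mu_sphere / sigma_corners)``;
* the *Chang* method needs no region at all — per slice, the noise standard
  deviation is the mode of the distribution of local (sliding-window)
  standard deviations, and the slice SNRs are averaged.

Temporal SNR works per voxel on a 4D series (temporal mean over temporal
standard deviation, in dB) and is summarised as the mean of the map inside
the COI sphere of the time-averaged volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .image import VoxelImage

DB = 20.0  # magnitude ratios: dB = 20 * log10(ratio)


def db(ratio: float) -> float:
    """Decibel value of a positive magnitude ratio."""
    return DB * math.log10(ratio)


@dataclass
class RoiGeometry:
    """Automatically placed signal sphere and eight corner noise cuboids."""

    coi: tuple[int, int, int]
    sphere_radius_vox: int
    sphere_mask: np.ndarray
    cuboid_mask: np.ndarray  # union of the eight corner cuboids

    @property
    def n_sphere(self) -> int:
        return int(self.sphere_mask.sum())

    @property
    def n_cuboid(self) -> int:
        return int(self.cuboid_mask.sum())


@dataclass
class SnrResult:
    """Per-scan SNR features with degeneracy flags."""

    snr_standard_db: float | None = None
    snr_chang_db: float | None = None
    tsnr_db: float | None = None
    notes: list[str] = field(default_factory=list)


def center_of_intensity(volume: np.ndarray) -> tuple[int, int, int]:
    """Intensity-weighted mean coordinate, rounded to the nearest voxel."""
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("center_of_intensity expects a 3D volume")
    total = vol.sum()
    if total <= 0:
        raise ValueError("no signal mass: image is all zero")
    coords = []
    for axis in range(3):
        idx = np.arange(vol.shape[axis], dtype=np.float64)
        marginal = vol.sum(axis=tuple(a for a in range(3) if a != axis))
        coords.append(int(np.rint(float(idx @ marginal) / total)))
    return tuple(coords)


def build_roi_geometry(
    volume: np.ndarray,
    *,
    sphere_radius_frac: float = 0.1,
    cuboid_edge_frac: float = 0.15,
) -> RoiGeometry:
    """Place the COI sphere and the eight corner cuboids on a 3D volume.

    Sphere radius is ``floor(frac * min(dims))`` clipped to >= 2 and further
    clipped so the sphere never leaves the lattice; cuboid edges are
    ``floor(frac * dim)`` per axis, clipped to >= 2.  The sphere must end up
    disjoint from every cuboid, otherwise the volume is too small (or the
    COI sits in a corner) for a meaningful noise reference.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("build_roi_geometry expects a 3D volume")
    dims = vol.shape
    if min(dims) < 8:
        raise ValueError(
            f"volume {dims} too small for SNR geometry; need >= 8 voxels per axis"
        )
    coi = center_of_intensity(vol)
    radius = max(2, int(min(dims) * sphere_radius_frac))
    # keep the sphere inside the lattice
    margin = min(min(c, d - 1 - c) for c, d in zip(coi, dims))
    radius = max(1, min(radius, margin))

    grids = np.ogrid[: dims[0], : dims[1], : dims[2]]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, coi))
    sphere = dist2 <= radius**2

    edges = [max(2, int(d * cuboid_edge_frac)) for d in dims]
    cuboids = np.zeros(dims, dtype=bool)
    for cx in (slice(0, edges[0]), slice(dims[0] - edges[0], dims[0])):
        for cy in (slice(0, edges[1]), slice(dims[1] - edges[1], dims[1])):
            for cz in (slice(0, edges[2]), slice(dims[2] - edges[2], dims[2])):
                cuboids[cx, cy, cz] = True

    if (sphere & cuboids).any():
        raise ValueError(
            f"signal sphere (r={radius} at {coi}) overlaps the corner cuboids; "
            "volume too small or signal centred in a corner — need larger dims"
        )
    return RoiGeometry(coi, radius, sphere, cuboids)


def _first_b0_volume(image: VoxelImage, b0_threshold: float) -> np.ndarray:
    """First (near-)zero diffusion weighting, or the first frame without a table."""
    if not image.is_4d:
        return image.intensities
    if image.bvalues is not None:
        for i, b in enumerate(image.bvalues):
            if b < b0_threshold:
                return image.intensities[..., i]
    return image.intensities[..., 0]


def snr_standard(
    image: VoxelImage,
    *,
    sphere_radius_frac: float = 0.1,
    cuboid_edge_frac: float = 0.15,
    b0_threshold: float = 50.0,
    notes: list[str] | None = None,
) -> float:
    """Standard COI-sphere / corner-cuboid SNR in dB.

    For 4D diffusion input the first b0 volume represents the scan.  A
    zero-noise corner (sigma = 0) is flagged and reported as +inf.
    """
    vol = _first_b0_volume(image, b0_threshold)
    geom = build_roi_geometry(
        vol,
        sphere_radius_frac=sphere_radius_frac,
        cuboid_edge_frac=cuboid_edge_frac,
    )
    mu_s = float(vol[geom.sphere_mask].mean())
    sigma_c = float(vol[geom.cuboid_mask].std())  # pooled over all 8 cuboids
    if sigma_c == 0.0:
        if notes is not None:
            notes.append("snr_standard: zero-noise corners (sigma=0)")
        return math.inf
    if mu_s <= 0.0:
        if notes is not None:
            notes.append("snr_standard: non-positive sphere mean")
        return -math.inf
    return db(mu_s / sigma_c)


def estimate_noise_chang(
    slice2d: np.ndarray,
    *,
    window: int = 3,
    smooth_bins: int = 3,
) -> float:
    """Histogram-mode noise standard deviation of one slice (Chang method).

    A sliding ``window x window`` local standard deviation map is computed
    (unbiased n-1 divisor, so the chi-distribution mode of a pure-noise
    window sits near the true sigma); its histogram (``ceil(sqrt(n))`` bins,
    smoothed with a ``smooth_bins``-wide moving average) peaks at the noise
    level because background/air windows dominate the slice.  Returns 0 for
    a constant slice.
    """
    arr = np.asarray(slice2d, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("estimate_noise_chang expects a 2D slice")
    if arr.size < 64:
        raise ValueError("slice too small for histogram noise estimation")
    if arr.max() == arr.min():
        return 0.0
    n_win = window * window
    mean = uniform_filter(arr, size=window, mode="reflect")
    mean_sq = uniform_filter(arr * arr, size=window, mode="reflect")
    local_var = np.clip(mean_sq - mean * mean, 0.0, None) * (n_win / (n_win - 1))
    local_sd = np.sqrt(local_var).ravel()

    n_bins = int(math.ceil(math.sqrt(local_sd.size)))
    hist, edges = np.histogram(local_sd, bins=n_bins)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        hist = np.convolve(hist.astype(float), kernel, mode="same")
    peak = int(np.argmax(hist))
    sigma = float(0.5 * (edges[peak] + edges[peak + 1]))
    if sigma == 0.0:
        # mode landed in the zero bin (large constant background patches):
        # fall back to the first strictly positive populated bin
        positive = np.nonzero((hist > 0) & (edges[:-1] > 0))[0]
        if positive.size:
            k = int(positive[0])
            sigma = float(0.5 * (edges[k] + edges[k + 1]))
    return sigma


def _snr_chang_volume(
    vol: np.ndarray,
    *,
    window: int,
    smooth_bins: int,
    notes: list[str] | None,
) -> float:
    slice_values = []
    n_degenerate = 0
    for z in range(vol.shape[2]):
        sl = vol[:, :, z]
        mu = float(sl.mean())
        sigma = estimate_noise_chang(sl, window=window, smooth_bins=smooth_bins)
        if sigma <= 0.0 or mu <= 0.0:
            n_degenerate += 1
            continue
        slice_values.append(db(mu / sigma))
    if n_degenerate and notes is not None:
        notes.append(f"snr_chang: {n_degenerate} degenerate slice(s) excluded")
    if not slice_values:
        raise ValueError("snr_chang: all slices degenerate (constant or zero)")
    return float(np.mean(slice_values))


def snr_chang(
    image: VoxelImage,
    *,
    window: int = 3,
    smooth_bins: int = 3,
    b0_threshold: float = 50.0,
    notes: list[str] | None = None,
) -> float:
    """Chang-method SNR in dB: slice-wise ``20 log10(mean / sigma_mode)``,
    averaged over slices; for 4D diffusion input, additionally averaged over
    all non-b0 directions."""
    if not image.is_4d:
        return _snr_chang_volume(
            image.intensities, window=window, smooth_bins=smooth_bins, notes=notes
        )
    if image.bvalues is not None:
        indices = [i for i, b in enumerate(image.bvalues) if b >= b0_threshold]
    else:
        indices = list(range(1, image.n_volumes))  # first volume assumed b0
    if not indices:
        indices = list(range(image.n_volumes))
        if notes is not None:
            notes.append("snr_chang: no non-b0 volumes, using all frames")
    per_direction = [
        _snr_chang_volume(
            image.intensities[..., i],
            window=window,
            smooth_bins=smooth_bins,
            notes=notes,
        )
        for i in indices
    ]
    return float(np.mean(per_direction))


def compute_tsnr(
    image: VoxelImage,
    *,
    sphere_radius_frac: float = 0.1,
    cuboid_edge_frac: float = 0.15,
    notes: list[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Temporal SNR map and its sphere-mean summary in dB.

    The COI sphere is placed on the time-averaged volume with the same
    radius rule as the spatial estimators.  Voxels that are temporally
    constant (sigma_t = 0) carry a +inf sentinel in the map and are excluded
    from the sphere mean.
    """
    if not image.is_4d or image.n_volumes < 2:
        raise ValueError("compute_tsnr requires a 4D series with >= 2 frames")
    data = image.intensities
    mean_t = data.mean(axis=3)
    sd_t = data.std(axis=3)

    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr_map = DB * np.log10(mean_t / sd_t)
    tsnr_map = np.where((sd_t == 0) & (mean_t > 0), np.inf, tsnr_map)

    geom = build_roi_geometry(
        mean_t,
        sphere_radius_frac=sphere_radius_frac,
        cuboid_edge_frac=cuboid_edge_frac,
    )
    in_sphere = tsnr_map[geom.sphere_mask]
    usable = in_sphere[np.isfinite(in_sphere)]
    n_dropped = in_sphere.size - usable.size
    if n_dropped and notes is not None:
        notes.append(f"tsnr: {n_dropped} temporally constant voxel(s) excluded")
    if usable.size == 0:
        raise ValueError("tsnr: no usable voxels inside the signal sphere")
    return tsnr_map, float(usable.mean())


def compute_snr_features(
    image: VoxelImage,
    sequence_class: str,
    *,
    sphere_radius_frac: float = 0.1,
    cuboid_edge_frac: float = 0.15,
    chang_window: int = 3,
    chang_smooth_bins: int = 3,
    b0_threshold: float = 50.0,
) -> SnrResult:
    """Compute the SNR feature set appropriate for a sequence class.

    Anatomical and diffusion scans get both spatial estimators; functional
    scans get temporal SNR.  Per-feature failures are recorded as notes and
    leave the other features intact.
    """
    result = SnrResult()
    if sequence_class in ("anatomical", "diffusion"):
        try:
            result.snr_standard_db = snr_standard(
                image,
                sphere_radius_frac=sphere_radius_frac,
                cuboid_edge_frac=cuboid_edge_frac,
                b0_threshold=b0_threshold,
                notes=result.notes,
            )
        except ValueError as exc:
            result.notes.append(f"snr_standard failed: {exc}")
        try:
            result.snr_chang_db = snr_chang(
                image,
                window=chang_window,
                smooth_bins=chang_smooth_bins,
                b0_threshold=b0_threshold,
                notes=result.notes,
            )
        except ValueError as exc:
            result.notes.append(f"snr_chang failed: {exc}")
    elif sequence_class == "functional":
        try:
            _, result.tsnr_db = compute_tsnr(
                image,
                sphere_radius_frac=sphere_radius_frac,
                cuboid_edge_frac=cuboid_edge_frac,
                notes=result.notes,
            )
        except ValueError as exc:
            result.notes.append(f"tsnr failed: {exc}")
    return result
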