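"""Ghosting and motion quantification via normalized mutual information.

Ghosting: a representative slice is compared with circularly shifted copies
of itself over a full cycle along the phase-like axis.  A clean scan gives a
smooth bowl-shaped mutual-information curve (high at zero shift, dipping in
between, returning to the start at a full cycle); a displaced attenuated
copy of the object — a ghost — produces an interior peak where the shifted
object lands on its ghost (half the field of view for EPI Nyquist ghosts).

Motion: for 4D series, mutual information between a reference repetition and
every repetition forms a trace; translational motion shows up as drops, and
its standard deviation is the scan's motion-severity index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .image import VoxelImage

_EPS = 1e-12


@dataclass
class MiTrace:
    """Ordered mutual-information values of a scan against a reference.

    ``reference_index`` is 1-based (the field convention for counting
    repetitions); for shift curves it is 1 (the zero-shift self-comparison
    stored first).
    """

    values: list[float]
    reference_index: int
    axis: str  # shift | time | direction
    slice_index: int

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("MiTrace needs at least 2 values")
        if self.axis not in ("shift", "time", "direction"):
            raise ValueError(f"unknown trace axis {self.axis!r}")
        if any(v < -1e-9 or v > 1 + 1e-9 for v in self.values):
            raise ValueError("mutual-information values must lie in [0, 1]")
        self.values = [float(min(1.0, max(0.0, v))) for v in self.values]


@dataclass
class GhostEvidence:
    """Outcome of the shift-curve ghost analysis for one scan."""

    curve: MiTrace
    peak_shifts: list[int]
    peak_prominences: list[float] = field(default_factory=list)

    @property
    def is_ghost(self) -> bool:
        return bool(self.peak_shifts)


def mutual_information(
    a: np.ndarray,
    b: np.ndarray,
    *,
    bins: int = 64,
    notes: list[str] | None = None,
) -> float:
    """Normalized mutual information of two equally shaped 2D images.

    ``NMI = 2 I(a;b) / (H(a) + H(b))`` from a joint intensity histogram over
    each image's own min-max range: 1 for identical images, near 0 for
    independent ones, symmetric in its arguments.  Constant (zero-entropy)
    images are defined as 1 if both are constant and equal, else 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    a_const = a.max() == a.min()
    b_const = b.max() == b.min()
    if a_const or b_const:
        if notes is not None:
            notes.append("mutual_information: constant (zero-entropy) input")
        return 1.0 if (a_const and b_const and a.flat[0] == b.flat[0]) else 0.0

    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p_ab = joint / joint.sum()
    p_a = p_ab.sum(axis=1)
    p_b = p_ab.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > _EPS]
        return float(-(p * np.log(p)).sum())

    h_a, h_b, h_ab = entropy(p_a), entropy(p_b), entropy(p_ab.ravel())
    mi = h_a + h_b - h_ab
    nmi = 2.0 * mi / (h_a + h_b)
    return float(min(1.0, max(0.0, nmi)))


def representative_slice(
    image: VoxelImage, mode: str = "ghost"
) -> tuple[np.ndarray, int]:
    """Pick the 2D slice the MI analyses operate on.

    Ghost mode: the middle z slice (of the 4th-axis average for 4D input) —
    it most likely covers the object.  Trace mode (4D only): the z slice
    with the highest mean intensity over the 4th axis, where signal — and
    hence motion sensitivity — is strongest; the returned array is the
    4th-axis average at that slice.
    """
    if mode == "ghost":
        vol = image.time_average()
        z = vol.shape[2] // 2
        return vol[:, :, z], z
    if mode == "trace":
        if not image.is_4d:
            raise ValueError("trace mode requires a 4D image")
        per_slice = image.intensities.mean(axis=(0, 1, 3))
        z = int(np.argmax(per_slice))
        return image.intensities[:, :, z, :].mean(axis=2), z
    raise ValueError(f"unknown mode {mode!r}")


def ghost_curve(
    image: VoxelImage,
    *,
    bins: int = 64,
    peak_prominence_frac: float = 0.1,
) -> GhostEvidence:
    """Shift-cycle MI curve and peak-based ghost decision for one scan.

    The representative slice is compared with itself circularly shifted by
    n = 0 … N voxels along the second in-plane axis (N its extent; shift N
    closes the cycle and returns to the self-comparison).  Interior local
    maxima whose prominence exceeds ``peak_prominence_frac`` of the curve
    range indicate a ghost; the trivial self-matches at 0 and N never count.
    """
    ref, z = representative_slice(image, mode="ghost")
    n = ref.shape[1]
    if n < 8:
        raise ValueError(f"image too small for shift analysis (axis extent {n})")
    values = [
        mutual_information(ref, np.roll(ref, shift, axis=1), bins=bins)
        for shift in range(n + 1)
    ]
    curve = MiTrace(values, reference_index=1, axis="shift", slice_index=z)
    arr = np.asarray(values)
    span = float(arr.max() - arr.min())
    if span <= 0:
        return GhostEvidence(curve, [], [])
    peaks, props = find_peaks(arr, prominence=peak_prominence_frac * span)
    interior = [(int(p), float(pr)) for p, pr in zip(peaks, props["prominences"])
                if 0 < p < n]
    return GhostEvidence(
        curve,
        [p for p, _ in interior],
        [pr for _, pr in interior],
    )


def reference_repetition(n_volumes: int, *, threshold: int = 20) -> int:
    """1-based reference frame for MI traces.

    Short series use the 1st repetition; longer ones (>= ``threshold``
    repetitions) the 10th, past the initial transient before the signal
    reaches steady state.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 repetitions")
    return 10 if n_volumes >= threshold else 1


def motion_trace(
    image: VoxelImage,
    *,
    bins: int = 64,
    reference_threshold: int = 20,
) -> MiTrace:
    """MI of every repetition against the reference, in acquisition order.

    Computed on the single z slice with the highest mean intensity over the
    4th axis.  The trace axis is ``direction`` when a b-value table is
    present (diffusion), else ``time`` (functional).
    """
    if not image.is_4d or image.n_volumes < 2:
        raise ValueError("motion_trace requires a 4D image with >= 2 frames")
    per_slice = image.intensities.mean(axis=(0, 1, 3))
    z = int(np.argmax(per_slice))
    frames = image.intensities[:, :, z, :]
    ref_1based = reference_repetition(image.n_volumes, threshold=reference_threshold)
    ref = frames[:, :, ref_1based - 1]
    values = [
        mutual_information(ref, frames[:, :, t], bins=bins)
        for t in range(image.n_volumes)
    ]
    axis = "direction" if image.bvalues is not None else "time"
    return MiTrace(values, reference_index=ref_1based, axis=axis, slice_index=z)


def motion_severity(trace: MiTrace) -> float:
    """Population standard deviation of the MI trace: 0 for a static scan,
    growing with the amount and variability of inter-repetition motion."""
    return float(np.std(np.asarray(trace.values)))
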