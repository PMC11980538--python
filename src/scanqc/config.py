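"""Run configuration: every tunable of the pipeline in one flat structure."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

#: Keyword evidence for sequence classification, matched case-insensitively
#: as substrings of the acquisition name.  The core list follows common
#: small-animal protocol naming (TurboRARE, DTI_EPI, rsfMRI, ...).
ANATOMICAL_KEYWORDS = ("turbo", "rare", "anat", "struc", "t1", "t2")
DIFFUSION_KEYWORDS = ("diff", "dwi", "dti")
FUNCTIONAL_KEYWORDS = ("rest", "rs-", "func", "bold")


@dataclass
class QcConfig:
    """Flat bag of pipeline parameters; CLI flags and config files override.

    SNR geometry
    ------------
    sphere_radius_frac : sphere radius = floor(frac * min(spatial dims)), >= 2.
    cuboid_edge_frac   : corner cuboid edge per axis = floor(frac * dim), >= 2.

    Chang noise estimation
    ----------------------
    chang_window      : sliding-window edge (voxels) for local std maps.
    chang_smooth_bins : moving-average width over the local-std histogram.

    Motion / ghosting
    -----------------
    mi_bins              : joint-histogram bins per axis for mutual information.
    peak_prominence_frac : ghost peak threshold, relative to the MI-curve range.
    reference_threshold  : series with >= this many repetitions use the 10th
                           repetition as MI reference, shorter ones the 1st.

    Outlier detection
    -----------------
    Detector parameters for the four multivariate methods plus the review
    threshold applied to the 0-5 majority vote.
    """

    # classification
    anatomical_keywords: tuple[str, ...] = ANATOMICAL_KEYWORDS
    diffusion_keywords: tuple[str, ...] = DIFFUSION_KEYWORDS
    functional_keywords: tuple[str, ...] = FUNCTIONAL_KEYWORDS
    functional_min_volumes: int = 10
    b0_threshold: float = 50.0  # s/mm^2; below this a volume counts as b0

    # SNR geometry
    sphere_radius_frac: float = 0.1
    cuboid_edge_frac: float = 0.15

    # Chang noise estimator
    chang_window: int = 3
    chang_smooth_bins: int = 3

    # mutual information
    mi_bins: int = 64
    peak_prominence_frac: float = 0.1
    reference_threshold: int = 20

    # outlier detection
    ocsvm_nu: float = 0.05
    iforest_contamination: float = 0.05
    iforest_n_estimators: int = 100
    lof_n_neighbors: int = 20
    lof_contamination: float = 0.05
    ee_contamination: float = 0.05
    review_threshold: int = 3
    include_ghost_in_features: bool = False

    mode: str = "per_dataset"  # or "collective"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "QcConfig":
        """Load overrides from a flat JSON key-value file."""
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("anatomical_keywords", "diffusion_keywords", "functional_keywords"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        """Write the full parameter snapshot next to the run outputs."""
        d = self.to_dict()
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
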