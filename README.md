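# scanqc

Automated, ROI-free quality control for small-animal MR neuroimaging.

Small-animal MRI studies accumulate hundreds of anatomical, diffusion, and
functional scans across scanners, coils and labs, and the usual way of
finding the bad ones — eyeballing slices and hand-drawing regions of
interest for SNR — does not scale and is notoriously subjective. `scanqc`
computes per-scan quality features without any manual region placement and
flags likely poor-quality scans within a cohort by an ensemble vote of five
outlier detectors, so a researcher can review a short, ranked list instead
of every scan.

## What it computes

**Spatial SNR, two ways** (both in decibels, `20·log₁₀(μ/σ)`):

- *standard*: a signal sphere is centred automatically on the image's
  centre of intensity (COI), the noise standard deviation σ is pooled over
  eight cuboids in the volume corners (air), and `SNR = 20 log₁₀(μ_sphere /
  σ_corners)`;
- *Chang*: fully region-free — per slice, the noise σ is the mode of the
  histogram of local (3×3 sliding-window) standard deviations, the slice
  SNRs `20 log₁₀(mean/σ)` are averaged over slices (and, for diffusion
  scans, over all non-b0 directions).

**Temporal SNR** for 4D series: the per-voxel `20 log₁₀(μ_t/σ_t)` map,
summarised as its mean inside the COI sphere of the time-averaged volume.

**Motion severity**: normalized mutual information (NMI, in [0, 1]) between
a reference repetition and every repetition on the brightest slice; the
standard deviation of that MI trace is the severity index (0 for a
perfectly still scan).

**Ghosting**: the MI curve between a representative slice and circularly
shifted copies of itself over a full cycle is bowl-shaped for a clean scan;
a displaced attenuated copy of the object (e.g. an EPI Nyquist ghost half
the field of view away) produces an interior peak, detected by prominence.

**Outlier voting**: per sequence class, the cohort feature table is scored
by one univariate rule (quartiles ± 1.5·IQR, one-sided in the bad-quality
direction) and four multivariate detectors (one-class SVM, isolation
forest, local outlier factor, elliptic envelope). Each scan receives a 0–5
majority vote; scans at or above a user-chosen threshold are listed for
review.

## Worked example

```python
from scanqc import PhantomSpec, QcConfig, run_pipeline
from scanqc.simulate import build_validation_cohort

# 12 synthetic anatomical + functional scans, subject 4 contaminated
build_validation_cohort("cohort", n_clean=11, contaminate_index=3,
                        phantom_spec=PhantomSpec(dims=(32, 32, 16)), seed=9,
                        classes=("anatomical", "functional"))
report = run_pipeline("cohort", "qc_out", QcConfig(seed=1))
print(report.voting_tables["anatomical"]["majority_vote"].tolist())
```

prints

```
[0, 1, 0, 3, 0, 0, 0, 1, 0, 0, 0, 0]
```

— the contaminated scan (index 3) is the only one with a high vote (3 of 5
detectors), everything else sits at 0–1. `qc_out/` then contains
`voting.csv` (per scan: the five algorithm decisions, the vote, the review
flag), `features_<class>.csv` (SNR/tSNR/motion values with degeneracy
notes), a `manual_slice_inspection/` gallery of middle-slice PNGs, and
distribution figures with IQR outliers highlighted.

The same pipeline runs from the shell:

```sh
qc run --input cohort --output qc_out --threshold 3 --seed 1
qc parse --input cohort            # stage I only
qc features --input cohort --output feats
qc vote --features-dir feats --output votes   # stage III (needs stage II)
qc simulate --output cohort2 --n-clean 30     # synthetic validation cohort
```

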