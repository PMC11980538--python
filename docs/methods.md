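# Methods

This note documents the models and procedures behind `scanqc`, the
parameters that matter, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline model

Quality control runs in three stages over a cohort of scans:

1. **Parsing.** The input tree is searched recursively for NIfTI files and
   Bruker reconstructions. Each candidate is classified as anatomical,
   diffusion, or functional from three pieces of evidence, in order of
   priority: a multi-entry b-value table (decisive for diffusion),
   case-insensitive keyword substrings of the acquisition name
   (diffusion > functional > anatomical precedence, since echo-planar
   protocols reuse anatomical-sounding tokens more often than the
   reverse), and a repetition-count fallback (a 4D series of ≥ 10 volumes
   without other evidence is treated as functional). Localizers and scans
   without the minimal metadata (matrix, voxel size, class evidence) are
   excluded with a recorded reason; the manifest partitions every
   candidate into exactly one of records/excluded.
2. **Feature computation** (below), per scan, with per-feature failures
   recorded as notes rather than dropped rows.
3. **Outlier voting** per sequence class and cohort.

## SNR estimators

All ratios are reported on the decibel scale for magnitude data,
`20·log₁₀(ratio)`.

**Standard (COI) method.** The centre of intensity is the
intensity-weighted mean coordinate, rounded to the nearest voxel. The
signal mask is a sphere at the COI with radius `⌊0.1·min(dims)⌋`, clipped
to ≥ 2 voxels and to stay inside the lattice; the noise mask is the union
of eight corner cuboids with per-axis edge `⌊0.15·dim⌋`, clipped to ≥ 2.
The fractions keep the sphere inside tissue for brain-filling fields of
view and the cuboids inside air; both are configurable
(`sphere_radius_frac`, `cuboid_edge_frac`). σ is the population standard
deviation pooled over the cuboid union (one σ, not a mean of eight
per-cuboid values). For 4D diffusion input the first b0 volume (b < 50
s/mm², or the first frame when no table exists) represents the scan. A
zero-variance corner yields a +inf sentinel plus a degeneracy note, never
a silent drop. Known limitation: when the subject fills the corners of the
field of view, the "noise" cuboids contain tissue and the estimate drops.

**Chang (histogram) method.** Per slice, a 3×3 sliding-window local
standard deviation map is computed with the unbiased (n−1) divisor, chosen
so the mode of the chi-distributed window statistic sits near the true σ
(for 9-voxel windows the mode is ≈ 0.94 σ, inside the estimator's
documented ±15% band). The histogram of local standard deviations uses
`⌈√n⌉` bins smoothed with a 3-bin moving average; its peak is σ(z), which
works because background/air windows dominate a typical slice. Slice SNR
is `20 log₁₀(mean(slice)/σ(z))`; the scan value is the mean over
non-degenerate slices, and for diffusion, additionally the mean over all
non-b0 directions. Window and bin parameters are config-exposed
(`chang_window`, `chang_smooth_bins`); the estimator's sensitivity to them
has not been mapped. Known limitation: when little air is present, the
histogram mode tracks tissue variability and overestimates SNR.

**Temporal SNR.** Per voxel, `20 log₁₀(μ_t/σ_t)` over the 4th axis
(population σ). The summary is the mean of the map inside the COI sphere
built on the time-averaged volume with the same radius rule as the spatial
estimators (the sharing of that rule is a design choice). Temporally
constant voxels are +inf in the map, excluded from the mean, and counted
in the notes.

## Mutual information, ghosting, motion

MI uses a 64×64-bin joint histogram over each image's own min–max range
and the normalization `NMI = 2·I(a;b)/(H(a)+H(b))`, so self-comparison
gives exactly 1 and independent images give ≈ 0 (the small positive bias
of histogram MI at finite n stays below 0.05 for 128² images). Both bin
count and normalization are conventions, config-exposed; constant
(zero-entropy) inputs are defined as 1 iff both are constant and equal,
else 0, with a flag.

**Ghost curve.** The representative slice (middle z slice; for 4D, of the
4th-axis average — index `⌊N/2⌋` for even counts) is compared with itself
circularly shifted by 1…N voxels along the second in-plane axis (the
phase-encode direction is unknown for plain NIfTI; the circular wrap makes
shift N return the curve to its self-comparison value). Interior local
maxima with prominence ≥ 0.1 of the curve range flag a ghost; the relative
prominence rule is scale-free and configurable
(`peak_prominence_frac`). Discriminating Nyquist from discrete
(physiology-driven) ghost subtypes is out of scope. Ghost evidence is
report-only by default and excluded from the outlier feature matrix
(`include_ghost_in_features` switches it on), since it is a binary flag on
a different scale from the continuous features.

**Motion.** On the z slice with the highest mean intensity over the 4th
axis, MI is computed between a reference repetition and every repetition
in order. Series of ≥ 20 repetitions use the 10th repetition as reference
(past the initial transient before steady state), shorter ones the 1st;
the cutoff is a choice (`reference_threshold`). Diffusion traces include
the b0 frames — they carry motion evidence like any other frame. Motion
severity is the population standard deviation of the trace. Limitation:
the index cannot distinguish animal motion from hardware-induced drifts
with similar image effects.

## Outlier ensemble

Per class, the feature columns are anatomical {snr_standard_db,
snr_chang_db}, diffusion {those + motion_severity}, functional {tsnr_db,
motion_severity}.

- **IQR rule** (univariate): linear-interpolation quartiles; one-sided in
  the bad-quality direction (SNR-like below Q1 − 1.5·IQR, motion above
  Q3 + 1.5·IQR), because unusually *good* quality is not a defect.
- **Multivariate detectors** (scikit-learn): one-class SVM (RBF,
  ν = 0.05), isolation forest (100 trees, contamination 0.05), local
  outlier factor (k = min(20, n−1), contamination 0.05), elliptic envelope
  (contamination 0.05). Parameters are defaults of convenience,
  config-exposed, and should be revisited for unusual cohorts. Features
  are z-scored per cohort first (dB and MI-std scales differ by orders of
  magnitude). The standardized matrix is fitted in a canonical
  (lexicographically sorted) row order and decisions mapped back, so
  permuting input rows permutes flags identically despite order-dependent
  fitting internals (SMO working-set selection, subsampling, FastMCD).
  Rows with missing/non-finite features are excluded from fitting and
  never flagged; a failed detector (e.g. singular covariance) contributes
  all-false flags with a log entry, keeping the 0–5 scale intact.
- **Vote**: the number of detectors flagging the scan, 0–5; the review
  threshold defaults to 3 (a majority) and trades sensitivity against
  precision — 1 catches almost everything a single method dislikes, 5
  lists only unanimous outliers.

A known marginal case: a single isolated far point can become its own
support vector in the one-class SVM when ν·n is small (around 1–2), making
its decision value hover near zero; the other four detectors flag it
reliably and the majority vote absorbs the occasional SVM miss.

In `collective` mode all datasets of a class are pooled into one cohort
before detection; in `per_dataset` mode (default) each dataset is its own
cohort, which keeps detection specific to each dataset's hardware and
protocol.

## Synthetic phantoms and artifact injection

The phantom is an ellipsoid (semi-axes 0.32 of each dimension) of tissue
intensity 50 with ±5% smooth seeded texture, in an air background with a
Gaussian noise floor of σ = 5 centred at 3σ (as in magnitude MR data, air
is a positive noise floor; the offset keeps the clipped-at-zero corner
standard deviation at the requested σ, and σ = 0 gives exactly zero
corners). These defaults put the clean scan near 20 dB, a mid-range
small-animal acquisition. 4D phantoms repeat the same anatomy with
independent temporal noise. The phantom deliberately models only the
signal/air partition the QC geometry relies on — no anatomy, coil shading,
Rician bias, k-space artifacts, or physiological noise — so passing tests
demonstrate the metrics' behaviour under controlled degradations, not
performance on real data.

Artifact families and defaults: Gaussian noise variance 0.2 and gamma
shading 0.6 (the contamination recipe used in the validation
experiments); salt-and-pepper amount 0.05 (exactly `⌊amount·n⌋` voxels
set half to the maximum, half to zero); speckle variance 0.2; motion as
per-frame integer in-plane translations uniform in [−amplitude,
+amplitude] (default 3 voxels, circular); ghosts as a
`ghost_fraction`-weighted copy (default 0.3) shifted half the field of
view. Noise parameters act on [0, 1]-normalized intensities so the
variances are scanner-scale-free; whether such variances should differ
per noise family is not established, so the salt-and-pepper and speckle
defaults are explicit choices. All injections are identity maps at
zero-magnitude parameters and deterministic under their seed.

## Validation experiments (desk scale)

The acceptance suite and `scripts/acceptance.py` run on phantoms of
48×48×16 voxels (20 frames for 4D), sizes chosen to keep a full run in
tens of seconds while leaving the SNR geometry non-degenerate:

- closed-form checks: constructed images with exact sphere/corner ratios
  {1, 10, 100} must give exactly {0, 20, 40} dB; a 200-frame series with
  10% temporal noise gives 20 dB tSNR within ±0.5;
- strict monotonicity of both SNR estimators over Gaussian variance
  {0, 0.05, 0.1, 0.2} and of motion severity over amplitudes {0, 1, 3, 5};
- Welch tests between 30 clean and 30 contaminated phantoms per metric;
- thirty repetitions of the planted-outlier experiment (30 clean + 1
  contaminated per cohort, a different contaminated scan each repetition),
  scoring how often the contaminated scan attains the cohort-maximum vote;
- ghost detection and false-positive rates over 100 seeded trials each,
  with the peak offset checked against the injected shift.

## Numerical conventions

Decibels use base-10 logarithms throughout. Standard deviations of fixed
vectors (MI traces, noise masks, tSNR) are population form. Quantiles use
linear interpolation between order statistics. Even-length middle slices
take index `⌊N/2⌋`. Degenerate inputs (all-zero volumes, constant slices,
zero-noise corners, temporally frozen voxels) produce explicit errors or
flagged sentinels, never silent omissions. Suspected x-z-y-permuted
matrices (slice axis in the middle) are rejected with an instruction to
reorient manually — silent reordering would corrupt the geometry
assumptions. No spatial reorientation is ever performed; non-coronal data
pass through with their features computed as-is.
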