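# Methods

This note documents the models, conventions and numerical choices behind
`blockbold`, and what the synthetic-data tests do and do not demonstrate
about real infant data.

## Acquisition model

A block-design run alternates two conditions (C1, C2) in equal 21-s blocks,
six periods per run, sampled at TR = 3 s, preceded by 4 dummy volumes:
88 acquired and 84 analysed time points, with a 14-TR (42-s) period and the
fundamental stimulus frequency at 6 cycles/run. Resting runs have 124
volumes (120 analysed). Voxels are 3 mm isotropic. These constants live in
`ConditionSchedule`; nothing downstream hard-codes them. (The rest-run
duration is 124 × 3 s = 6 min 12 s.)

## Motion QC

Framewise displacement is the sum of absolute frame-to-frame translation
increments plus the three rotation increments converted from degrees to
radians and multiplied by a 50 mm head radius (the approximate distance
from head centre to occipital cortex in an infant), yielding millimetres of
arc length. Conventions:

- FD at the first time point is 0 (FD is undefined there).
- The suprathreshold count uses a strict inequality at 0.5 mm.
- Run exclusion uses the range (max − min) of each cumulative translation
  axis against 4 mm, and of the rotation arc length at 50 mm against 5 mm.
  A millimetre limit on rotation is only meaningful as an arc length, so
  the screening radius is explicit and configurable.
- Segmentation: time points with FD > 0.5 mm mark movement spans; maximal
  still spans of at least 28 TRs (two full stimulus periods, so period
  averaging stays possible) are retained as independent series.

## HRF and GLM

The hemodynamic response is a single gamma variate
`h(t) ∝ ((t−δ)/τ)^(k−1) e^{−(t−δ)/τ}` with shape k = 3 and dispersion
τ = 1.5 s, integrated over each TR bin and normalised to unit area (so
convolution preserves the plateau of a sustained input). The onset delay δ
is not assumed: it is calibrated once, by root-finding, so that the
fundamental-frequency phase of the convolved 21 s/21 s boxcar equals
exactly 64° relative to the boxcar under the same discrete pipeline used
everywhere else — the phase a standard hemodynamic model produces for this
stimulus timing. The calibrated default is δ ≈ 4.50 s (time to peak
≈ 7.5 s), consistent with the slow infant hemodynamics the phase anchor
encodes. Calibration is deterministic and cached.

The design matrix holds the interest regressor (C1 boxcar coded 1/0,
convolved with the HRF, truncated to run length), six motion parameters
(demeaned; constant columns dropped with a warning), sine/cosine pairs at 1
and 2 cycles/run (the GLM-Fourier high-pass), and a constant — 12 columns
at the default layout. With no rest blocks, 1/0 coding makes the interest
beta the C1 − C2 response difference directly. The fit is ordinary least
squares per voxel with t = estimate/SE, df = rows − rank, two-sided p, and
a standard-normal equivalent z (sign-preserving). The contrast estimate is
rescaled to percent of the voxel temporal mean over analysed points.
No prewhitening is applied, matching the single-subject analyses of the
era; AR(1) noise therefore inflates nominal significance, which the
null-calibration tests quantify on white noise rather than hide.
Noiseless voxels (zero residual variance) are flagged p = 0 instead of
failing on division.

## Seed, lagged correlation maps, labelling

The V1 seed is the largest 6-connected component of positive activation at
p ≤ 0.01 (motion-vs-blank GLM) inside a calcarine prior region. The seed
mean time course is correlated with every voxel at delays of 0 s and 3 s
(one TR; the voxel trailing the seed), p from the r→t transform with
df = overlap − 2; constant voxels record r = 0, p = 1. The analysis mask is
the union of the two maps at p < 0.05, admitting either correlation sign by
default: cortex that responds with opposite polarity (PIVC) is
anti-correlated with the seed yet belongs in the stimulus-driven mask; a
positive-only mode is available. ROI labelling takes 6-connected
suprathreshold components of either sign inside the mask and assigns each
to the prior region with maximal overlap ("unassigned" if none); in
synthetic mode the priors are the generator's ground-truth regions, for
real data they are user-supplied. No multiple-comparison correction is
applied inside the mask — a faithful-reproduction choice, not a statistical
recommendation.

## Spectral and circular statistics

ROI time courses are spatial means converted to percent of the ROI temporal
mean. Periods fully inside one retained still interval are "good"; good
periods are concatenated in order before the FFT so the fundamental stays
on an exact bin (one cycle per period); partial periods contribute to
period averaging only. The windowed mean response averages TRs 3–6 of the
period (1-based inclusive; 9–18 s after C1 onset).

SNR is `|A(f₀)| / RMS(|A(f₀−1)|, |A(f₀+1)|)`. Significance compares the
fundamental power with the mean neighbour power: under Gaussian noise each
bin power is a scaled χ²(2), so SNR² is F(2, 4)-distributed under the null
and p = F₂,₄.sf(SNR²) — a reconstruction, since the original report marks
significance levels without naming a test. Phase is reported relative to
the C1-onset boxcar, positive = later response, mapped to [0°, 360°), so a
canonical response reads 64° and a delay of k TRs adds k·360/14°. At least
two periods are required (the neighbour bins must exist).

Group phase statistics are circular: the mean is the angle of the resultant
of the phase unit vectors (optionally SNR-weighted; unweighted by default)
and the SD is the RMS of wrapped deviations in (−180°, 180°]. A zero
resultant raises an error. Group comparisons: amplitudes by two-sample
two-tailed t test; phases by linearising each group as its circular mean
plus wrapped deviations and forming a pooled-variance t on the wrapped mean
difference (a small-dispersion approximation chosen over Watson–Williams
for transparency at these group sizes).

## Connectivity

Per subject, the seven ROI mean series (dummy-stripped, high-passed with
constant + linear + 2-cycle Fourier projection) give a 7×7 Pearson matrix
in the fixed order MT+ R, MT+ L, V1, V6 R, V6 L, PIVC R, PIVC L. Missing
ROIs produce NaN rows/columns and drop out pairwise at the group stage.
Group matrices are element-wise means. Significance uses the aggregate
subject: each subject's series is z-scored with the population SD and
concatenated; for equal-length runs the correlation of the concatenation
equals the mean of per-subject correlations exactly (the z-scoring uses
ddof = 0 precisely so this identity holds), and p follows from r→t with
df = total points − 2. Group differences are per-cell two-tailed two-sample
t tests, by default on Fisher-z transformed correlations (variance
stabilisation; raw-r mode available). No global-signal regression or
ICA-based denoising is applied — such steps require segmentation or atlas
projection unavailable at these ages — only the high-pass.

## Synthetic generator

The generator is the package's test bed and defines its study conditions:

- Grid 24×24×12 at 3 mm; baseline 1000 a.u.; seven spherical ROIs
  (radius 2 voxels) — bilateral MT+, V6, PIVC and midline V1 — disjoint and
  inside the grid. Real ROIs are irregular clusters; sphericity affects no
  tested statistic.
- Amplitudes (percent signal change) follow the infant group means:
  coherent-vs-random MT+ 0.40, V6 0.23, PIVC −0.30, V1 0 (not
  motion-selective); stimulus-vs-blank MT+ 0.17, V6 0.11, PIVC −0.11,
  V1 0.30.
- The percent amplitude is defined relative to the run-mean intensity: the
  convolved regressor is demeaned before the modulation is applied, so a
  voxel's temporal mean equals its baseline and the GLM's
  percent-of-temporal-mean scaling recovers the programmed amplitude
  exactly in the noiseless case.
- Noise per voxel: white Gaussian with stationary SD 0.2% of baseline,
  AR(1) filtered (φ = 0.3, innovations scaled to keep the stationary SD),
  plus a random linear drift (SD 0.5%/run) — enough structure for the
  high-pass and the null-calibration tests to have something real to do.
- Dummy volumes carry a decaying brightness transient to exercise dummy
  discarding.
- Motion traces: Gaussian-smoothed stationary wander (0.03 mm translations,
  equivalent arc for rotations) plus optional persistent 2 mm position
  steps with alternating sign; step indices are ground truth.
- Rest runs: latent ROI signals from a Cholesky factor of the target
  correlation matrix (PSD-checked), AR(1)-filtered with a common filter
  (which preserves the imposed correlation), driving all voxels of each
  ROI at 1% SD; independent white voxel noise attenuates observed ROI-mean
  correlations by `σ_s² / (σ_s² + σ_n²/K)` for a K-voxel ROI, and this
  factor is reported with the ground truth so tests can correct for it.
  The default target imposes strong homotopic coupling (MT+ 0.7, V6 0.7,
  PIVC 0.6), moderate V1–V6 (0.4) and weak V1–MT+/PIVC (0.1) correlations.

What the generator does not emulate: spatially correlated physiological
noise, partial-volume and vascular effects, eye movements or sleep-state
changes, scanner artifacts, and anatomical variability. Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to every real-data pathology.

## Validation design notes

- **Problem sizes.** Monte-Carlo suites use the default 24×24×12 grid with
  10–50 replicates per check and 150–400 replicates for power
  comparisons — sizes chosen to pin each statistic well inside its
  tolerance while keeping the whole suite interactive.
- **Null calibration** uses white noise, where the OLS p-values are exact;
  with AR(1) noise they are anticonservative by construction (documented
  above).
- **Amplitude recovery** is measured on a held-out replication run:
  ROIs are labelled by the full pipeline on one dataset and the mean
  contrast beta is taken over those voxels in an independently simulated
  run with the same ground truth. Measuring on the same run would fold
  threshold-selection ("double-dipping") bias — a property of
  threshold-defined ROIs, roughly +10% at the weakest default ROI — into
  the estimator check; the held-out design isolates estimator bias, which
  lands within a few percent (slightly negative, from false-positive halo
  voxels diluting the labelled set).
- **Mask coverage.** At the study's stimulus-vs-blank response sizes
  (0.1–0.2%) the per-voxel seed-correlation detection rate sits near the
  p < 0.05 boundary, so the union mask covers associative ROIs only
  partially (V1 near-completely). This is a power statement about 84-point
  runs, not a defect; ROI labelling and amplitude recovery remain reliable
  because clusters, not single voxels, are labelled.

## Known limitations

- OLS inference without prewhitening is anticonservative under serial
  correlation (quantified, not corrected).
- The spectral significance test and the Z* equivalent are reconstructions
  of under-specified originals.
- The phase group test assumes small circular dispersion.
- Half periods are excluded from spectral analysis (bin alignment) and
  enter period averaging only.
- Anatomical labelling is replaced by region priors; no atlas registration
  or surface analysis is provided.
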