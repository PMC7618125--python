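# Methods

This note documents what `voicersa` computes, the assumptions baked into
its synthetic generator, the numerical choices that matter, and what the
passing test suite does and does not establish about real data.

## The analysis chain

**Item patterns.** Brain responses to 24 items (3 voice identities × 8
clips) are represented as T-statistic patterns from an event-related GLM.
All stimulus, null and response events are modelled as instantaneous
impulses convolved with the canonical double-gamma HRF (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot ratio 6, 32 s
kernel, unit peak) and sampled at scan times (TR 1 s; 16× oversampling
before decimation).  Items get one regressor per run; null events one
regressor per run; correct and incorrect responses one regressor each
(timeout trials contribute an event at response-screen onset plus the
run's mean response time, assigned to the incorrect-response regressor,
since a timeout is a non-correct response).  Runs are fitted jointly as a
block-diagonal OLS model with per-run intercepts; the item-versus-null
contrast weights each run 1/n_runs, implementing "averaged across runs"
as a fixed-effects contrast.  T = contrast / SE with dof = scans − rank.
With exactly zero simulated noise the SE vanishes and T is 0/0, so
`TPatternMap` also exposes the raw contrast estimates; exact-recovery
tests use those, T-level recovery is tested at moderate noise.  No
prewhitening or drift regressors are fitted — the synthetic noise is
white by construction — but `build_design_matrix(extra_regressors=...)`
is the hook for drift/motion columns on real data.

**Dissimilarity.** The ONDM cell for items i, j is 1 − Pearson r between
their patterns over the voxels of the current searchlight.  Patterns are
used as-is (no mean-centering across items; only Pearson's own per-vector
centering).  Voxels non-finite in either pattern are dropped pairwise;
constant patterns yield an undefined correlation and propagate as missing
cells with a warning.  One canonical vectorization is used everywhere:
row-major upper triangle over items sorted by identity (Familiar, Lab,
New) then clip index.  The ordering is a package convention — any
consistent order gives identical results, it only has to be shared by
observed, model and acoustic vectors.

**Model RDMs.** Seven identity-contrast codings (between-speaker pairs 1,
within-speaker pairs 0; the all-voices variant plus six voice-pair
variants) and four familiarity-graded codings (within-speaker cells 1/2/3
across all voices, or 0/1 for a voice pair; between-speaker cells always
excluded).  Excluded pair classes are NaN and are removed listwise before
correlation.  Because the downstream correlation is rank-based, any
monotone recoding of the graded values is equivalent; the printed codes
are used verbatim and the equivalence is verified by a test, not
exploited.

**Acoustic nuisance RDM.** For each clip, the long-term average spectrum
(LTAS) is the STFT power spectrum (squared magnitude) averaged across
windows; acoustic dissimilarity is 1 − cosine similarity between LTAS
vectors, which for nonnegative spectra lies in [0, 1] and is invariant to
global loudness.  1 − cos is the minimal monotone choice of "dissimilarity
deduced from cosine similarity" and is an assumption of this package.
STFT defaults are n_fft 2048, hop 512, Hann window at 44100 Hz —
conventional analysis defaults, all config-overridable; power rather than
magnitude averaging is likewise exposed as the `compute_ltas` contract.
One acoustic RDM is built per subject, mirroring per-participant stimulus
sets.

**Searchlight.** Neighborhoods are the k = 100 nearest in-mask voxels by
Euclidean distance in voxel units, center included, with deterministic
tie-breaking by flat (C-order) voxel index; masks smaller than k use all
voxels and are flagged.  Per center, the ONDM vector is correlated with
the model over the model's coded cells by a partial Spearman correlation
controlling the acoustic RDM: average ranks, then the first-order formula
ρ_xy·z = (ρ_xy − ρ_xz ρ_yz)/√((1−ρ_xz²)(1−ρ_yz²)).  A constant control
reduces to the plain Spearman correlation; a control collinear with
either variable yields a missing value with a warning; centers with fewer
than 4 complete cells are NaN.  Coefficients are Fisher-z transformed
(atanh, with |r| = 1 clamped to 1 − 1e−15).  The production path
vectorizes the per-center computation across neighborhoods and is tested
for exact agreement with the scalar reference implementation.

**Group inference.** Voxel-wise one-sample t against 0 over subjects,
using only subjects with finite values at each voxel (dof = n_observed −
1, recorded per voxel; fewer than 3 observations → NaN; zero variance →
largest finite t with a warning).  t maps are converted to z by
probability matching, z = Φ⁻¹(F_t(t; dof)), computed through log survival
functions so extreme t stays accurate.  TFCE integrates e(h)^0.5 · h² ·
dh over 6-connected supra-threshold components with dh = z_max/100 per
map; the negative tail is the TFCE of the negated map.  The FWE null is
built by sign-flipping: each permutation negates each subject's map with
probability ½, recomputes t → z → TFCE, and records the maximum TFCE over
the mask per tail; per-voxel p = (1 + #{null max ≥ observed})/(n_perm + 1)
(exact enumeration of all 2^n sign patterns, with a warning, when that is
smaller than the requested count).  Corrected z = Φ⁻¹(1 − p/2) with the
observed sign restored: the two-sided normal scale is used so that the
±1.96 threshold corresponds to FWE p < .05 within each tail, and p = 1
maps to 0 so a voxel nonsignificant in its own tail cannot appear as
evidence for the opposite sign.  Max-statistic FWE over the mask (rather
than a per-voxel null) is this package's stated choice; peaks are
tabulated from the uncorrected group map within each suprathreshold
region because corrected maps can plateau at the permutation resolution.

**Behavior.** Confusion tables count stimulus-category × response-category
trials with timeouts tracked separately.  Hu = (hits/trials presented) ×
(hits/responses to the category); timeouts count as presented trials but
not as responses (a timeout is neither a hit nor a response to any
category — the package's resolution of a case the formula leaves open).
Hu = 0 whenever hits = 0.  The arcsine transform is arcsin(√x), the
standard variance stabiliser for proportions.  Counts are pooled across
runs before the ratios are taken; with equal trial counts per run the
order is immaterial.  Mixed-model fitting of the Hu table is out of
scope; the per-subject, per-condition CSV export is ready for any such
tool.

## The synthetic generator

The generator's defaults *are* the study conditions: 3 identities × 8
clips × 3 repetitions plus 24 null trials per run (96 trials), 4 runs,
TR 1 s, stimuli 2–3 s, onset jitter normal(0.375 s, 0.125 s) truncated at
0, 0.5 s pre-response fixation, 2 s response window, 0.25–1 s inter-trial
fixation, null trials ~5 s on average, audio at 44100 Hz, and group
simulations of up to 26 subjects.  Where only a mean was stated
(null-trial duration) the duration is drawn uniformly at ±20% around it;
where only "pseudorandomised" was stated, the order is a uniform random
permutation constrained so no experimental item repeats back-to-back.
These distribution-family choices are this package's, flagged here rather
than inferred as anyone's intent.

**Planted geometry.** A target matrix of 1 − r dissimilarities (per-
identity within-speaker targets, per-pair or scalar between-speaker
targets, all in [0, 2]) is converted to a target correlation matrix
C = 1 − D, repaired to the nearest positive semidefinite matrix by
eigenvalue clipping at 1e−8 with diagonal renormalisation (rejected if
the repair moves any cell by more than 0.1), and sampled as X = A·G with
A·Aᵀ = C and G i.i.d. standard normal over voxels, plus optional i.i.d.
measurement noise of scale σ.  Empirical 1 − r then converges to the
targets as voxel count grows; noise attenuates correlations by the known
factor 1/(1 + σ²), which recovery tests and the acceptance script account
for explicitly.  Group simulations place planted geometry in a signal
region and independent per-item noise (every pairwise target 1) in a
disjoint null region; the two cuboids are separated so no 100-voxel
neighborhood straddles them.

**What the generator does not emulate.** Temporal autocorrelation, scanner
drift, motion, physiological noise, spatial smoothness of activation or
noise, realistic voice acoustics (clips are sums of sinusoids), and
response-time structure.  Noise is i.i.d. Gaussian over voxels and
timepoints — the simplest model under which GLM recovery is exact in
expectation.  Consequently the passing suite demonstrates that the
*analysis chain* is correct (it recovers what was planted, controls
family-wise error under its null, and matches independent oracles), not
that the method is robust to the structured noise of real fMRI; on real
data the prewhitening/drift hooks should be used and the searchlight mask
should come from an actual localiser.

## Numerical choices

- Nearest-k tie-breaking: squared voxel distances are exact integers, so
  (distance², flat index) sorting is deterministic and reproduces an
  exhaustive sort exactly (oracle-tested up to 12³ masks).
- TFCE is a union-find sweep over descending thresholds (numba-compiled),
  exact against direct threshold summation at the same dh; dh adapts per
  map as z_max/100.
- Permutation t statistics are computed for all sign patterns at once
  from sufficient statistics (Σx and Σx², which is sign-invariant).
- Fisher z clamps |r| ≥ 1 to atanh(1 − 1e−15) with a warning; partial
  correlations are clipped to [−1, 1] before the transform.
- Degenerate inputs fail loudly: empty masks, silent audio clips,
  zero-norm spectra, rank-deficient designs (the offending columns are
  named), probability rows that exceed 1, geometry with no PSD repair.
- NIfTI artifacts are written uncompressed so pipeline-manifest
  checksums are byte-stable across reruns.

## Problem sizes in the shipped checks

The test suite and the acceptance script run at desk scale, chosen so the
statistical claims are sharp while the whole suite remains quick: the
parameter-recovery check plants Familiar/Lab/New within-speaker targets
of 0.8/0.4/0.4 (between 1.0, noise 0.5) in a 500-voxel region for 20
subjects with 1000 sign-flips, and the family-wise-error check runs 200
pure-noise simulations of 12 subjects over a 1000-voxel mask with 500
sign-flips.  The 10,000-iteration permutation setting of a full analysis
is a single config value (`group.n_perm`).

## Known limitations

- The pseudorandomisation constraint and jitter distribution families are
  package choices (see above); alternative constraints would change trial
  sequences but not the planted-geometry analyses.
- The acoustic RDMs of group simulations are random nonnegative spectra —
  a nuisance control with the right marginal structure but no relation to
  the simulated "audio"; `compute_ltas`/`acoustic_rdm` accept real
  waveforms for end-to-end use.
- Searchlights are volumetric nearest-k only (no radius or surface-based
  neighborhoods beyond the config hook); distances ignore anisotropic
  voxel sizes.
- Cross-validated distance measures (crossnobis/Mahalanobis) are out of
  scope: the pipeline deliberately uses plain 1 − r.
- With very few subjects the exhaustive sign-flip null bounds the
  smallest achievable FWE p at 1/2^n, so small pilots cannot reach the
  1.96 threshold; this is a property of the test, not a bug.
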