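# Methods

This note documents the models, estimators and numerical choices behind
`srcconn`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Synthetic data model

Each subject's source activity is built per (ROI, band) from an independent
**carrier**: white noise band-pass filtered with a zero-phase 4th-order
Butterworth filter and standardised to unit variance.  Bands sum to the
broadband ROI signal.  Three effect families act on the carriers:

* **Envelope co-modulation.**  Every carrier is multiplied by
  `exp(σ·m(t))` where `m` is a unit-variance Gaussian process synthesised
  in the Fourier domain with support below `modulator_cutoff` (default
  0.1 Hz, i.e. ~10-s bursts; σ defaults to 0.75).  A planted envelope
  correlation ρ on an edge makes both ROIs' modulators share a common
  component: `m_i = √ρ·s + √(1−ρ)·u_i`, so the *modulators* correlate at
  exactly ρ and the measured log-envelope correlation approaches ρ up to
  the attenuation described below.  The per-subject realised modulator
  correlation is recorded as ground truth.
* **Phase coupling.**  A planted coupling t with phase lag φ adds to ROI j
  a copy of ROI i's carrier delayed by `φ/(2π f_c)` seconds (FFT
  fractional delay at the band centre `f_c`), mixed at amplitude
  `κ = t/|sin φ|` with `√(1−κ²)` of j's own carrier, which makes the
  band-averaged imaginary coherence ≈ t.  φ ∈ {0, π} is rejected because
  zero-lag or antiphase coupling is invisible to iCoh by construction.
* **Band power.**  A relative power change d scales the carrier amplitude
  by `√(1+d)`.

The toy forward model places 128 sensors on a Fibonacci lattice over the
unit sphere and one current dipole per ROI at the packaged atlas centroid
(rescaled inside the sphere), with a fixed, seeded radial/tangential
orientation.  Gain columns are the homogeneous-medium dipole potential
`q·(r−r₀)/|r−r₀|³` at the sensors, mean-referenced and unit-normalised; no
sphere-boundary correction term is applied — the model is meant to provide
realistic *spatial correlation structure* (hence testable leakage), not
electromagnetically accurate topographies.  Sensor noise is spatially
white Gaussian scaled to a requested signal/noise variance ratio.

The packaged AAL-90 table carries hand-placed, approximate MNI centroids;
they serve the toy geometry and the lobe/network groupings only and are
documented as replaceable (any 90-label table with coordinates works).

**What the generator does not emulate:** 1/f background spectra, realistic
artifact morphology (eye blinks, EMG — only amplitude scaling), volume
conduction from non-modelled sources, non-stationary band structure, or
individual head geometry.  Passing tests therefore demonstrate estimator
and inference correctness under the assumed statistical structure, not
parity with any human dataset.

## Preprocessing

Artifact rejection segments the recording into fixed 1-s windows and
computes, per window and channel, the peak-to-peak range, variance and
line length.  These are **log-transformed** before robust z-scoring
(median/MAD across windows): amplitude artifacts act multiplicatively, and
the slow envelope fluctuation of genuine oscillatory activity is
near-Gaussian on the log scale, where it would otherwise be heavy-tailed
and cause wholesale over-rejection.  A window is rejected when more than
`channel_fraction` (default: any) of channels exceeds the z-threshold
(default 4).  On clean Gaussian data this rejects ~0% of windows; on
bursty simulated EEG ~10–15%, inside the 2–24% range reported for
comparable recordings; 20× amplitude segments are detected essentially
always.  Parity with any specific published rejection tool is not claimed.

Bad channels are interpolated with Perrin spherical splines (stiffness
m = 4, 50 Legendre terms, ridge 1e-5, constant term unpenalised so
constant fields are reproduced exactly); a test pins the interpolation
matrix against mne's implementation.  Filtering is zero-phase (sosfiltfilt)
4th-order Butterworth band-pass 1–97 Hz plus a 49–51 Hz band-stop; then
common-average referencing (idempotent).

## Beamformer

Sample covariance over valid samples with diagonal loading
`reg·mean(diag)·I` (default 5% — conventional for 128-channel EEG, exposed
in config).  With a 3-orientation gain the max-power orientation is the
eigenvector of the smallest eigenvalue of `LᵀC⁻¹L` (equivalently the
dominant eigenvector of the projected-power matrix), sign-fixed for
determinism.  One covariance over the broadband cleaned data; the same
filter serves all bands.  The beamformer output is arbitrary-units by
design; all downstream measures are scale-invariant.

## Connectivity measures

* **Band power**: 2-s non-overlapping epochs (0.5 Hz resolution), Hann
  taper by default (a documented dialect; the toy-oracle tests disable
  it), epochs overlapping rejected samples dropped entirely, band value =
  sum of retained bins; 48–52 Hz never contributes to any band.
* **AEC**: both signals band-filtered; orthogonalisation
  `y⊥ = y − (⟨y,x⟩/⟨x,x⟩)x` applied in both directions and the two
  absolute Pearson correlations of log envelopes averaged (symmetry is
  required for an undirected matrix).  "Power envelope" is the squared
  magnitude of the analytic signal; downsampling to 0.5 Hz uses
  non-overlapping 2-s block means; zero blocks are floored at the smallest
  positive float with a warning.  Collinear pairs (residual power below
  1e-12 of the signal's) are recorded as missing.  The full-matrix path is
  algebraically identical to the pairwise function: because the Hilbert
  transform is linear, `|A_y − cA_x|² = |A_y|² + c²|A_x|² − 2c·Re(A_yĀ_x)`,
  so per-block cross terms are precomputed once with batched matrix
  products (tested equal to the pairwise path to ~1e-9).
* **iCoh**: cross- and auto-spectra averaged over 2-s epochs;
  `|Im S_xy|/√(S_x S_y)` per bin, band value = mean over retained bins
  (mean rather than sum keeps the value in [0, 1]).
* **Node strength**: algebraic mean of a ROI's off-diagonal weights,
  missing edges excluded; diagonal excluded by convention.

### Estimator noise floors and a known leakage limitation

With finite data the absolute-correlation AEC has a positive floor
(≈ 0.8/√B for B envelope samples: ~0.06–0.09 at 3×2 min), and iCoh's floor
is ≈ 0.03.  Orthogonalisation removes zero-lag leakage exactly for
stationary sources, but when sources carry strong slow envelope
modulation, symmetric mixing leaves residual envelope correlation that
pairwise orthogonalisation cannot eliminate (both mixtures retain both
sources' envelopes).  The leakage verification study therefore uses
stationary carriers; on bursty data AEC should be read as
leakage-*suppressed*, not leakage-free.  iCoh is immune either way.

## Group statistics

The per-feature statistic is the AUC (normalised Mann–Whitney U, ties at
½, missing values dropped pairwise).  Pooled midranks are invariant under
label permutation, so data are ranked once and each of the `n_perm`
permutations (default 500 at desk scale) is a row sum — exact and fast.

Observed and null AUCs map to z-scores through the pooled null's empirical
CDF (`z = Φ⁻¹(p̂)` with a ½-count continuity correction).  Densities f
(observed) and f₀ (null) are Gaussian-kernel estimates evaluated on a
512-point grid via a smoothed histogram (Silverman plug-in bandwidth,
floor 1e-3); π₀ is the central-matching ratio of f to f₀ mass over
|z| ≤ 1, capped at 1.  Local fdr(z) = min(1, π₀f₀/f); the discovery mask
is the largest fdr-ordered prefix whose running mean fdr stays ≤ q
(q = 0.10 by default), making the reported tail-averaged FDR the
controlled quantity; P₁ = 1 − fdr; power is the share of estimated
non-null mass `Σ(1−fdr)` captured by the mask.  Degenerate inputs (all
observed identical) yield π₀ = 1 and no discoveries.

Power and node strength are concatenated across bands into one run per
quantity; edges run per (measure, band).  The subgroup comparison applies
the Blom inverse-normal transform `z = Φ⁻¹((r−0.375)/(n+0.25))` and a
type-II two-way ANOVA with interaction (statsmodels); a single-level
factor leaves its effects undefined.

## Connectivity modules

Edges with two-sided Mann–Whitney p < .05 (asymptotic, tie-corrected) form
the non-negative V (subjects × edges).  The inner solver is
multiplicative-update NMF from seeded uniform initialisation, stopping at
relative error change < 1e-6 or 500 iterations; its monotone error trace
is a tested invariant, and a test checks it reaches sklearn's MU solver
objective.  Rank is the minimiser of
`BIC = nm·ln(RSS/nm) + k(n+m)·ln(nm)` over best-of-restarts fits (the
Gaussian-RSS form with k(n+m) parameters; configurable).

The ensemble draws balanced resamples (all of the smaller group plus an
equal random subset of the larger), fits best-of-restarts, aligns
components to the first resample's basis by greedy cosine matching (a
<0.01 margin logs an ambiguity warning), unit-normalises rows before
averaging (the NMF scale indeterminacy must not weight the mean), and
averages.  Final weights for *all* subjects — including never-resampled
ones — come from non-negative least squares onto the averaged basis; this
projection step is this package's interpretation of how every subject
acquires module weights.  Module maps min-max normalise each basis row to
[0, 1] and carry the sign of (AUC − ½) of patient vs control weights.
Module-weight significance uses label-permutation p-values and
within-group bootstrap power, with two-stage adaptive FDR at 5%.

Desk-scale defaults (50 resamples, 20 restarts, 2,000 bootstrap draws,
500 permutations) keep a full run interactive; `--protocol-scale` restores
the protocol counts (250/100/10,000).

## Clinical correlations

Partial Spearman is computed rank-then-residual with midranks; without
ties it equals `(ρ_xy − ρ_xz·ρ_yz)/√((1−ρ_xz²)(1−ρ_yz²))` (pinned to
1e-10 in tests).  Significance comes from y-permutation (two-sided, +1
correction), power from paired bootstrap against the null's 0.95 bound.
Adaptive FDR follows BKY Definition 6 — both stages use q′ = q/(1+q) —
and is pinned against statsmodels' `fdr_tsbky`.  The shipped motor /
frontal / frontoparietal / frontotemporal / occipital network tables are
editable label lists, not claimed to match any specific study's
supplementary definitions.

## Verification studies and problem sizes

The studies in `srcconn.evaluation` (run by `scripts/acceptance.py` and
the acceptance tests) use desk-scale conditions chosen once: 128 Hz
sampling with the band set restricted to the planted bands, 2–5 minutes
per subject, 20+20 subjects, 500 permutations.  Specifically: oracle
checks on ≤12-sample AUC instances and 8-sample spectra; leakage on 24
stationary source pairs at 300 s; null calibration on 20 independent
90-ROI datasets (4005 edges each, 60 s); effect recovery on 90 ROIs at
the full 3×2-min protocol length with 6 θ-AEC edges (+0.2), 6 β-iCoh
edges (−0.2) and −30% occipital power across δ–β; module recovery on 30
ROIs with two 6-edge phase-coupling modules (one expressed in each
group).  Generator defaults themselves stay at the emulated protocol
(512 Hz, 128 sensors, 3×120 s, 90 ROIs).

## Known limitations

* The AEC noise floor biases weak edges upward; group inference is
  unaffected (the bias is common to both groups) but absolute AEC values
  near the floor are not interpretable.
* Orthogonalisation does not remove leakage-shared envelope content of
  strongly amplitude-modulated sources (above).
* The centroid-dipole ROI representation and the homogeneous-medium gain
  are deliberate simplifications; no claim of parity with MRI-based head
  modelling.
* Local-fdr inference needs enough features to estimate densities
  (warning below 50) and cannot detect a handful of moderate effects among
  thousands of nulls — effects must move the statistic into the null's far
  tail.
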