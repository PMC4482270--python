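# Methods

This note documents the models and procedures implemented in `eegbm`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Preprocessing

Two parallel paths, by design asymmetric:

* **network path** — zero-phase (forward–backward) 3rd-order Butterworth
  band-pass 0.5–50 Hz plus a 3rd-order 58–62 Hz band-stop notch (skipped
  with a warning when the Nyquist frequency does not clear it; the notch
  width is a conventional clinical choice, the filter specification states
  only the center).  Each 2 s window is demeaned and scaled to unit
  variance per derivation, so correlation statistics are amplitude-free.
* **spectral path** — no filtering (the multitaper estimator handles
  broadband content); windows are demeaned only.

Both paths excise annotated artifact intervals and trim an additional
0.5 s on each side of every cut; windows never span a discontinuity
because epochs are aligned to each clean segment's start (this maximizes
usable epochs; no global epoch grid is imposed).  A clean stretch fully
consumed by trimming is dropped and logged.  Subjects with under 100 s of
artifact-free data are excluded from studies, with the reason logged.

Re-referencing is a single linear map per montage.  The canonical
longitudinal-bipolar ("double banana") order is fixed — left lateral,
left parasagittal, midline, right parasagittal, right lateral, each chain
front-to-back — giving a stable edge index ↔ pair-name mapping for all
network code and mask files.  The transverse and Hjorth-Laplacian montages
follow standard clinical conventions but are **not canonical** (no
published derivation list exists for this study's versions); the
neck-reference montage is supported only when a designated reference
channel is supplied, since the 10–20 set carries none.

## Spectral analysis

Multitaper PSD per 2 s epoch: DPSS tapers with TW = 3, K = 5
(K ≤ 2·TW − 1), half-bandwidth W = TW/T = 1.5 Hz, one-sided density
scaling (integral ≈ variance), native 0.5 Hz grid, frequencies below
0.5 Hz omitted.  Eigenspectra are averaged uniformly (Chronux-style unity
weights); MNE's eigenvalue-weighted estimator agrees to within a few
percent per bin and serves as a cross-check in the tests.

The **peak alpha ratio** uses epoch-averaged spectra: average linear power
over epochs first, then the posterior/anterior ratio per pair, then the
maximum over 8–14 Hz (endpoints inclusive), then the mean over the four
pairs.  A per-epoch variant (ratio and maximum per epoch, then averaged)
is exposed separately — the two orders are both defensible readings of
the original description; average-then-ratio is the default because
single-epoch spectra have only K = 5 tapers of stability and the per-epoch
maximum is more upward-biased.  All ratios are computed on linear power;
dB is for display only.  The statistic is invariant to any common
rescaling of a subject's channels.

Diagnostics: a 6 × 18 band-power grid (3 Hz bins centred 2.5…17.5 Hz) and
the log10-power vs log10-frequency OLS slope over 1–15 Hz (≈ −2 for
normal broadband background; flattening indicates EMG contamination).

## Edge statistics and their null model

The coupling statistic per derivation pair and epoch is the maximum
absolute biased normalized cross-correlation, r(τ) = Σₜ x(t)y(t+τ)/n, over
integer-sample lags within ±500 ms (biased normalization keeps the
variance bounded at extreme lags).  Ties break toward the smallest |τ|;
negative τ means the second signal leads.

Significance is the delicate part.  The variance of a sample
cross-correlation between *independent* signals depends strongly on their
autocorrelation: narrowband alpha-rich derivations fluctuate several times
more than broadband ones, so no single variance can rank 153 heterogeneous
pairs correctly.  The model fitted per subject therefore has two layers:

1. **Bartlett standardization.**  For each (pair, epoch),
   Var r(0) ≈ (1/n) Σₘ ρₓ(m) ρᵧ(m) is computed from the two epoch
   autospectra (an O(n_freq) sum per pair), with the biased-estimator
   factor (n−|τ|)/n applied per lag.  The standardized curve
   z(τ) = |r(τ)|/sd(τ) is exchangeable across pairs.  The edge statistic
   becomes max z; the zero-lag statistic z(0).
2. **Pooled cross-epoch empirical null.**  Correlating derivation i of
   epoch e against derivation j of epoch e+1 yields signals with the
   subject's own spectral content but no lag relation (consecutive 2 s
   epochs are 1.5–2.5 s apart at every lag in the ±500 ms window, far
   beyond the signals' correlation time).  The 153·(n_epochs−1)
   standardized null maxima form the subject's common null sample.
   P-values are the add-one empirical survival probability, extended
   beyond the 20th-largest null value by a Gaussian tail whose scale is
   the censored maximum-likelihood fit to all exceedances above the 95th
   percentile (the exceedance-tail of a Gaussian-maximum distribution
   depends on the single-trial scale but not on the number of effective
   trials, so one parameter suffices and the extension is well-posed).

This construction keeps null edge p-values uniform per pair — the property
the downstream Benjamini–Hochberg step carries to FDR control — across
sampling rates (200–512 Hz), filter settings, and heterogeneous spectra.
Simulations in the test suite verify uniformity (Kolmogorov–Smirnov) and a
mean null false-discovery proportion of ≈ 3–5 % at q = 0.05.

Two fallbacks remain available: the analytic form (Fisher-transformed
maximum referred to a zero-mean Gaussian with the subject-level common
variance σ̂² — the across-lag variance of r averaged over all pairs and
epochs — with a Šidák correction for L_eff effective lags, default
L_eff = lag-range × 2 × low-pass = 100), used when fewer than 500 null
samples exist; and a circular-shift surrogate p-value as an independent
calibration oracle.  Note the surrogate is conservative on 2 s epochs: a
circular shift can land a genuine coupling peak back inside the ±500 ms
window, which covers half the circle.

**Zero-lag test.**  The standardized z(0) referred to the pooled empirical
null of |z(0)| (uncorrected — no lag search).  This reliably flags
montage-induced correlations between derivations sharing an electrode
(genuine r(0) ≈ ±0.5) regardless of the subject's narrowband content,
which a common-variance Gaussian cannot.

## Per-epoch networks and statistics

Per epoch: (1) BH step-up at q over the 153 zero-lag p-values fixes the
excluded (volume-conduction suspect) set; (2) BH step-up at q = 0.05 over
the remaining pairs' edge p-values fixes the adjacency.  Density divides
the edge count by (153 − #excluded).  Degrees, regional densities (left,
right, anterior, posterior, and the two inter-hemispheric crossing
variants), subject template networks (per-pair fraction of epochs with the
edge), and group templates (subject-equal averaging, regardless of epoch
count) follow directly.  The anterior/posterior split — anterior
derivations end at or before the central electrode row — is a documented
package convention, not a published table.

**Mask density** is the fraction of a fixed edge mask present in an
epoch's adjacency (zero-lag-excluded mask edges count as absent; the
denominator is the mask size), averaged over epochs per subject.  The
alternative denominator (all 153 pairs) would change only the scale, not
any rank-based comparison; fraction-of-mask is the reading that reproduces
the published magnitudes (mask densities several times larger than global
densities).  The published 16-edge ASD-low and 23-edge control-high masks
(7 edges in common, union 32) ship as constants and as plain-text mask
files; within a pair, names are written in canonical chain order.

## Bootstrap edge selection

Under the null of no group difference, all epoch networks are pooled
across every subject of both groups; a surrogate cohort redraws, for each
real subject, that subject's exact epoch count with replacement from the
pool (per-subject counts are preserved by construction), and surrogate
group templates average surrogate subject templates subject-equally —
exactly as the observed templates are formed.  Repeating R times gives
per-edge bootstrap distributions of the group-mean weight for each group.
One-sided add-one empirical p-values (min attainable 1/(R+1)) select
ASD-low edges from the lower tail of the surrogate-ASD distribution and
control-high edges from the upper tail of the surrogate-control
distribution at p ≤ p_sel (default 1/R); the mask is their union (the
intersection, or either direction alone, are options).  The study scale is
R = 100,000 with p_sel = 10⁻⁵; the desk scale used throughout the tests is
R = 2,000, at which selection is resolution-limited, so the synthetic
cohorts plant effects large enough to be detected at that resolution.
This resampling scheme ignores subject-level random effects (it pools
epochs, not subjects), so edges whose appearance clusters within single
subjects can reach the tail at small R; the planted-cohort tests verify
that at the default effect sizes the selected mask coincides with the
planted differential edge set.

## Coherence and WPLI

Multitaper magnitude-squared coherence is computed per band-center from
the K eigenspectra (two layouts: 4 centers × 5 Hz bandwidth × 8 tapers,
ν₀ = 16; 8 centers × 3 Hz × 5 tapers, ν₀ = 10).  The conventionally
reported transform (ν₀−1)|C|²/(1−|C|²) is returned as the statistic; the
p-value, however, comes from the exact null of K-taper MSC,
|C|² ~ Beta(1, K−1) — equivalently (K−1)|C|²/(1−|C|²) ~ F(2, 2K−2) —
because referring the (ν₀−1)-scaled statistic to F(2, ν₀−2) inflates the
type-I rate about four-fold (verified by simulation; the suite checks the
empirical rate is 0.05 ± 0.02).  |C|² = 1 is reported as an infinite
statistic with p = 0.  Band p-values are FDR-corrected by the same BH
step as the correlation networks.

WPLI over 8–12 Hz: |E Im Sxy| / E |Im Sxy|, pooling epochs, tapers and
in-band bins; bounded in [0, 1], amplitude-invariant, exactly 0 for a
(numerically) real cross-spectrum, and insensitive to zero-lag coupling.

## Group tests and classification

The group test is Wilcoxon rank-sum by default (Welch's t is available);
every reported p carries the test's name, since the original analysis
never names its test.  Exploratory contrasts are two-sided; validation
contrasts are one-sided in the direction hypothesized on the training data
(ASD lower).  Multiple-comparison helpers provide the Bonferroni threshold
α/m (0.05/18 ≈ 0.0028 for the node-degree comparisons) and BH-FDR.

QDA fits one multivariate normal per class with class-specific covariance.
Priors default to equal (conservative for unbalanced groups; empirical
priors are an option) — the original MATLAB routine's prior convention is
not recoverable.  A singular class covariance (e.g. a feature constant
within a class) triggers a logged ridge (reg_param = 10⁻³); the ridge
breaks exact affine invariance, so it is applied only on failure.
Asperger's subjects are excluded from classification by default, matching
the study protocol; sensitivity is ASD recall, specificity control recall,
both recomputable exactly from the reported confusion counts and rounded
to integer percent for display.

## Synthetic cohorts

Each subject is built from four ingredients:

1. **background** — white noise spectrally shaped to f^slope (slope −2 by
   default, flat below 1 Hz), std 20 µV per channel; the fitted 1–15 Hz
   log-log slope recovers the target within ±0.3.
2. **alpha rhythm** — independent per channel, band-limited 8–12 Hz,
   amplitude linearly tapered from `anterior_alpha_amp` at the frontal
   pole to `posterior_alpha_amp` at the occiput.  Defaults: posterior
   30 µV in **both** groups; anterior 3 µV (control), 10 µV (ASD-like),
   6 µV (Asperger's-like).  Planting the group difference anteriorly keeps
   group-differential narrowband power off the alpha-rich posterior pairs,
   where it would otherwise produce group-differential false-edge rates;
   it also mirrors the observed higher anterior power in ASD.  The implied
   posterior/anterior derivation power ratios (≈ 14 control vs ≈ 5 ASD)
   are recorded in the ground truth.
3. **lagged shared sources** — band-limited 2–25 Hz, injected at the
   derivation level by mapping the desired derivation-space signal through
   the montage pseudoinverse.  The double-banana matrix has rank 16 (each
   hemisphere's two chains sum to the same Fp→O difference), so planting
   on one derivation leaks a −1/8 copy onto its same-hemisphere
   chain-mates; all default planted pairs couple derivations across
   hemispheres (or to the midline), whose mutual leakage is structurally
   zero.  The default lag is 50 ms — long enough that the source's
   autocorrelation has decayed and the planted edge is not caught by the
   zero-lag exclusion.  Five differential pairs get gain 40 µV (control)
   vs 8 µV (ASD-like); at 40 µV the planted standardized statistic sits
   near z ≈ 7 (detected in most epochs) while the residual leakage edges
   sit near z ≈ 1.5 (never detected); substantially larger gains push the
   leakage edges over the detection threshold and contaminate the
   bootstrap mask.  Three additional pairs are coupled equally in both
   groups (35 µV) as non-informative baseline.
4. **zero-lag common sources** — two cross-hemisphere pairs share a 90 µV
   common source with a notched band (2–6.5 ∪ 15.5–20 Hz): broad total
   bandwidth is required because a narrowband common source's own
   autocorrelation inflates the Bartlett variance of its pair's zero-lag
   correlation, capping the standardized statistic near the detection
   threshold however strong the source; the notch keeps the source out of
   the 8–14 Hz ratio-search window, since these pairs sit on ratio
   derivations.  At 90 µV the pairs are zero-lag-excluded in > 90 % of
   epochs and never enter the adjacency.

Artifacts (two 2 s intervals per subject by default) are overwritten with
high-amplitude noise and annotated — never silently deleted — so the
excision logic is exercised.  Cohort defaults mirror the clinical arms:
13 ASD (3 Asperger's) / 24 control training, 14 ASD (2 Asperger's) / 31
control validation, 120 s per subject at 200 Hz (≈ 57 usable epochs after
artifact excision, matching the low end of the clinical epoch counts and
keeping a full study run under a minute), per-subject lognormal jitter
(σ = 0.15) on amplitudes and gains.  Everything is reproducible from
(config, seed); subject seeds derive from the master seed.

**What passing tests do not show.**  The generator emulates second-order
statistics only: Gaussian signals, linear mixing, stationary sources,
independent epochs, no eye-blink/ECG/EMG morphology, no head-model forward
projection, no sleep architecture, no inter-electrode distance structure.
Recovery of planted effects therefore demonstrates the pipeline's
statistical correctness and calibration, not clinical validity on real
EEG; effect sizes are calibration choices (no quantitative coupling effect
sizes exist to copy), chosen so planted effects are detectable at the
desk-scale bootstrap resolution.

## Numerical choices

* Lag ties break toward the smallest |τ|; lag grids are symmetric with
  1/fs spacing.
* FFT sizes are the next power of two ≥ 2n (linear, not circular,
  correlation).
* Epoch counts per segment are floor(segment_seconds/2); segments shorter
  than 2 s contribute nothing.
* The empirical-null handover uses the 20th-largest null value; below 500
  null samples the analytic Šidák model is used instead.
* Add-one conventions everywhere an empirical p-value is formed (minimum
  p = 1/(N+1), never 0).
* EDF files are written with 1 s records, 16-bit samples against a
  per-channel symmetric physical range (round-trip correlation > 0.999);
  a trailing partial second is zero-padded.  Reading goes through MNE.
* Default problem sizes in the test suite: 500 null epochs for the FDR
  calibration check, R = 2,000 bootstrap replicates, the full 82-subject
  default cohort for end-to-end recovery.
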