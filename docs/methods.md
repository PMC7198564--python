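# Methods notes

This note records the modelling assumptions, default parameters, numerical
conventions and deliberately open design choices behind `mbsim`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Impulse-response models

**BOLD (Boynton gamma).** h(t) = (t/τ)^(n−1) e^(−t/τ), n = 3, τ = 1.2 s,
delay 0, peak-normalized to 1. The published macaque/human literature on
this kernel does not vary much around these values; all three parameters
are overridable. Analytic mode (n−1)τ = 2.4 s; FWHM on the default grid
3.9 s.

**MION.** The blood-volume-weighted MION response is represented as a gamma
density with **mean lag 6.0 s and SD 4.1 s**, peak-scaled to `peak_ratio`
(default 1.8, i.e. peaking 1.8× higher than BOLD at equal noise). The
literature gives the MION kernel only qualitatively at this level —
larger, wider, later than BOLD — so the two shape parameters were
calibrated once against the full set of constraints the comparison is known
to satisfy: peak later than BOLD's 2.4 s (3.2 s), FWHM well above BOLD's
(6.8 s vs 3.9 s), and full-spectrum dominance at equal onset smoothing
surviving exactly down to peak ratio 1.5 and failing at 1.4. A mean/SD of
6/4.0 s puts the boundary at 1.6, 6/4.2 s at 1.4; the boundary is the most
parameter-sensitive quantity in the package, which is why the sweep result
should be read as "≤ 1.5" rather than a sharp constant of nature. Both
parameters are exposed (`mion_model(mean_lag=…, sd=…)`).

**Smooth-onset splice.** "Replace the MION onset with the BOLD onset" is
implemented as: keep MION unchanged from its peak onward; before the peak,
use the BOLD rising limb time-rescaled so its peak lands at the MION peak
time and amplitude-rescaled to the MION peak. Among the possible readings
this one guarantees continuity at the splice point and preserves the peak;
it is idempotent by construction. The spliced onset is *slower* than the
raw gamma onset (t² vs t^1.25 near zero), so the splice is conservative: it
removes high-frequency energy from MION before the comparison.

**Extra onset smoothing.** A causal unit-area Hann kernel of total width
`width` (default 1.0 s in the paired comparison), applied identically to
both IRFs, followed by peak renormalization. A causal (lag ≥ 0) kernel is
used instead of a centred one so the response still starts at t = 0 with
h(0) = 0; the implied slight delay is part of the intended "smoother,
slower onset" behaviour. Because the same kernel multiplies both spectra,
smoothing mainly affects dominance through the differing peak-renormalization
factors; the sweep threshold is insensitive to widths in 0–1 s.

**Macaque HRF for the GLM.** Gamma with first moment 3 s and SD 1.5 s
(shape k = (mean/sd)² = 4, scale sd²/mean = 0.75 s), unit peak — the
faster macaque BOLD HRF. Grid dt 0.1 s, duration 30 s (mean + 4 SD fits
comfortably; a `TruncationError` guards shorter windows).

Default IRF grid: dt = 0.1 s, duration 60 s — more than 99.9% of both
responses' mass; `mion_model` verifies ≥ 99% mass analytically.

## Designs and convolution

* Rapid event-related run: 48 stimulus slots (0.5 s stimulus + 2.5 s ISI)
  and 30 null slots in one seeded permutation. **Null slots default to
  3.0 s**: with 2.5 s nulls the run would span 219 s, which is not a whole
  number of 2 s volumes and does not match the 117-volume run the design
  emulates; 3.0 s slots give exactly 234 s = 117 volumes. The parameter is
  exposed (`null_slot`) and the discrepancy is deliberate.
* Block design: 32 s ON / 16 s OFF; ON blocks pack 0.9 s
  stimulus-plus-ISI cycles (35 fit) plus one final bare 0.4 s stimulus
  (36 events per block).
* Alternating design: conditions 0/1 swap every 2 s (0.25 Hz fundamental),
  default run 480 s.
* Convolution: boxcars on the IRF's dt grid, **discrete** convolution with
  the sampled IRF (no dt scaling), volumes sampled at the END of each TR
  (t = TR, 2TR, …). A single event of duration dt therefore reproduces the
  IRF exactly at volume times. All dominance/energy/SE comparisons are
  ratios, so the scaling convention cancels. Slice-timing conventions are
  out of scope. Contrast boxcars are +1 for the first condition, −1 for the
  second.
* Schedules pad total duration up to the next TR multiple with trailing
  blank.

## Spectral comparison

Periodograms are one-sided with the convention Σ power = Σ signal²
(Parseval; checked to 1e−9 in tests), computed after zero-padding to 120 s
(1/120 Hz bins). Dominance is evaluated on 0 < f ≤ 0.25 Hz — the Nyquist
band of the TR = 2 s volume grid; DC is excluded because mean signal is not
an effect of interest. Ties count as dominance (the claim concerns
transmitted effect energy, not strict inequality). The peak-ratio sweep
runs 1.8 → 1.0 in 0.1 steps and stops at the first failure, since power
scales as ratio² and dominance is therefore monotone in the ratio.
Contrast standard errors use the analytic OLS form noise_sd·√(cᵀ(XᵀX)⁻¹c)
under i.i.d. volume noise; temporally correlated noise is deliberately out
of scope (it would rescale both contrasts through the same whitening).

## Censoring and GLM

* Fixation rule: a volume is excluded iff strictly more than half its gaze
  samples (>20 of 40 at 20 Hz, TR 2 s) fall strictly outside the ±5° box;
  exactly half keeps, and a sample exactly on the boundary counts inside.
* Motion rule: variance > mean + 2·SD of the series, moments over the full
  run (sample SD, ddof = 1), strict inequality. Per-run rather than
  per-session moments is a choice; the function accepts any series.
* Censored trials are removed by deleting their events from the condition
  boxcar before convolution (not by scrubbing regressors); an event is
  censored if any volume it overlaps is fixation-censored. Motion outliers,
  by contrast, get one one-hot nuisance column per flagged volume.
* Drift: the high-pass filtering a real pipeline would apply is replaced by
  Legendre polynomial drift regressors (default order 1, i.e. constant +
  linear), since the synthetic data carry configurable polynomial drift.
* OLS is fitted per voxel in one vectorized least-squares solve; dof =
  T − rank(X). t = β/SE; z is the sign-preserving two-sided tail match
  computed via log-tail quantiles (`scipy.special.ndtri_exp`), finite for
  |t| up to ~40.
* Percent signal change follows the Featquery-style convention: 100 × β ×
  (peak of an isolated single-event regressor) / baseline, with the
  fitted constant term as baseline.
* Spherical ROI masks include voxels whose centre is within the radius
  (inclusive): 7 voxels at r = 2 mm on a 1.5 mm grid, 171 at r = 5 mm.

## Crossnobis RSA

Σ = (1/T)RᵀR from the training half's stacked residuals, blended with
shrinkage s toward its own diagonal ((1−s)Σ + s·diag Σ, default s = 0.1).
The literal estimator (s = 0) is available but with ~150 voxels and limited
training volumes Σ can be ill-conditioned; a singular solve raises an error
that names the remedy. Fold loop: 50 seeded random split-halves, one random
run dropped when the count is odd; within each half, per-condition betas
are averaged across the half's runs (a concatenated-GLM refit would be the
alternative reading; the mean is assumed and flagged here). Pairs with a
condition unavailable (all events censored) in either half are skipped for
that fold and averaged over the remaining folds; never-available pairs are
NaN. Distances are not divided by the voxel count — units are squared
whitened amplitude. The test half's residuals are unused (Σ from training
only). All-pairs distances per fold are computed via the cross-Gram matrix
M = B_A Σ⁻¹ B_Bᵀ, d(k,j) = M_kk + M_jj − M_kj − M_jk, which is symmetric
with an exactly zero diagonal.

## Synthetic data

Per run: a fresh seeded schedule; signal = Σ_c (regressor_c × pattern_c);
noise is multivariate normal across voxels with covariance
sd²·exp(−|i−j|/ℓ) (default sd 1.0, ℓ 2 voxel indices) and white in time,
matching the GLM's i.i.d.-noise assumption — temporal autocorrelation,
saccade kinematics and image-space artefacts are deliberately not
simulated, so passing tests certify estimator correctness under the model's
own assumptions, not robustness to real-data violations. Patterns: 4
categories × 12 exemplars; pattern = amplitude·(√ρ·category + √(1−ρ)·
exemplar) with standard-normal components, so ρ is the expected
within-category correlation (default 0.3 — a placeholder for testing, not
an empirical claim). Broken-fixation volumes are Bernoulli(censor_rate,
default 0.163) per volume; motion spikes Bernoulli(0.03). Eye traces put
a random >half of a broken volume's 40 samples outside the window; motion
series put spikes at 8× baseline; both contracts (censor rules recover the
planted flags exactly) are validated at generation time, and a run with
zero planted spikes uses a constant baseline because the 2-SD rule would
otherwise flag its own jitter. All randomness flows through
`numpy.random.SeedSequence` substreams of one seed; derived integer seeds
stay below 2³¹.

Default session size 10 runs × 117 volumes × 60 voxels: enough volumes for
stable Σ estimation at the default shrinkage while keeping a full
workflow run in seconds on one core.

## Pipeline

One top-level seed deterministically spawns per-stage substream seeds
(synthesis, fold assignment), so changing one stage's parameters does not
perturb another's draws. Configs are nested dicts (YAML/JSON) with unknown
keys rejected by name; every run writes the fully resolved config and
package version next to its outputs. The `glm_rsa` workflow raises an
explicit empty-session error if censoring leaves fewer than two usable
runs.

## Known limitations

* The MION kernel is a calibrated stand-in for the (unpublished-here) fitted
  response; conclusions should be read through the sweep ("dominance down
  to ratio ≤ 1.5 under these shapes"), not as a property of a specific
  animal.
* No temporal autocorrelation or prewhitening; SEs are exact only under
  i.i.d. noise.
* The generator's categorical pattern structure and rates emulate the
  target study's reported magnitudes, not fitted values.
* Percent-signal-change scaling follows one (stated) convention; others
  differ by a constant factor.
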