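# mbsim — BOLD vs MION sensitivity simulation and a GLM → crossnobis-RSA pipeline for rapid event-related macaque fMRI

Rapid event-related (rER) fMRI presents stimuli faster than the hemodynamic
response evolves, which makes condition-rich pattern analyses possible but
pushes the effect energy of the design into high temporal frequencies.
Macaque fMRI can use either the endogenous BOLD contrast (fast but
low-amplitude impulse response) or the MION iron-oxide contrast agent
(slower, wider, but substantially larger response). `mbsim` answers, by
linear-systems simulation, which contrast mechanism transmits more effect
energy for fast designs, and provides the analysis pipeline such an
experiment needs — trial censoring, per-run GLM, and cross-validated
Mahalanobis (crossnobis) representational similarity analysis — exercised
end to end on synthetic ROI data with planted ground truth.

## The models

**Impulse responses.** BOLD uses the Boynton gamma kernel
h(t) = (t/τ)^(n−1) e^(−t/τ) with n = 3, τ = 1.2 s, peak-normalized to 1
(mode at (n−1)τ = 2.4 s). MION is a gamma density with mean lag 6.0 s and
SD 4.1 s — later peak, roughly twice the width — scaled so its peak is
`peak_ratio` times the BOLD peak (default 1.8), with its sharp onset
replaced by the time-rescaled BOLD rising limb (the conservative
smooth-onset variant); an optional causal Hann kernel smooths both onsets
identically. Signs are magnitudes only (the physical MION signal decrease
is represented positive).

**Dominance.** For any stimulus schedule s(t), the sampled regressor is
(s ∗ h)(kTR), so the transmitted effect energy per temporal-frequency bin
is |S(f)|²·|H(f)|². If |H_MION(f)|² ≥ |H_BOLD(f)|² at every f in
(0, 0.25 Hz] (the TR = 2 s Nyquist band), MION yields at least as much
effect energy — and hence contrast standard errors at most as large at
equal additive noise — for *every* design. `mbsim` computes
Parseval-consistent periodograms, tests this per-bin dominance, and sweeps
the MION/BOLD peak ratio downward to find the smallest ratio where
dominance still holds.

**GLM and RSA.** Volumes are censored when gaze left the ±5° fixation
window for more than half the volume (>20 of 40 samples at 20 Hz, TR 2 s);
motion-outlier volumes (variance > mean + 2 SD) become one-hot nuisance
regressors. Each of the 48 images is one regressor, convolved with the fast
macaque HRF (gamma, 3 s mean lag, 1.5 s SD). `RunGLM.fit()` returns betas,
standard errors, t and tail-matched z statistics per voxel. The crossnobis
distance between conditions k, j is

    d(k, j) = (b_kA − b_jA) Σ_A⁻¹ (b_kB − b_jB)ᵀ,   Σ = (1/T) RᵀR,

averaged over 50 random split-half folds of the runs (one run dropped when
odd), giving an unbiased (possibly negative) squared Mahalanobis distance;
`CrossnobisRSA.fit()` returns the condition × condition RDM.

## Worked example

```bash
mbsim sensitivity --out scratch/sens
```

prints (abridged):

```json
{
  "design": "alternating(switch=2s, tr=2s)",
  "effect_energy": {"bold": 4036.16, "mion": 9821.00},
  "contrast_se": {"bold": 0.01574, "mion": 0.01009},
  "dominant": true,
  "threshold_ratio": 1.5
}
```

Even for a two-condition design switching every 2 s — one volume per
condition, the fastest switching the volume grid can express — the MION
contrast regressor carries ~2.4× the effect energy of BOLD, so its contrast
standard error at equal additive noise is ~36% smaller, and MION's
periodogram dominates BOLD's at every frequency up to 0.25 Hz. The
`threshold_ratio` of 1.5 is the smallest peak ratio (swept 1.8 → 1.0 in 0.1
steps) at which that full-spectrum dominance survives.

The synthetic GLM → RSA workflow runs from one seed:

```bash
mbsim glm-rsa --seed 11 --out scratch/rsa_demo
```

generating a 10-run session (48 conditions, 60 voxels, ~16% censored
volumes, ~3% motion outliers), fitting per-run GLMs and writing the
fold-averaged crossnobis RDM (`rdm.csv`) plus QC (censored fraction per
run, dof, dropped conditions). With the default planted category structure
the RDM's off-diagonal mean is ≈ 91 (squared whitened amplitude units) and
no condition pair is missing.

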