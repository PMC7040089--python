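# Methods

`trbci` implements a complete time-resolved functional near-infrared
spectroscopy (TR-fNIRS) analysis for yes/no mental communication, together
with a physics-based generator of synthetic studies used to validate every
stage end to end. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data can and cannot show.

## Measurement model

A TR-fNIRS system records, every 300 ms and for each detection channel and
wavelength (760 and 830 nm), the distribution of times-of-flight (DTOF) of
single photons: a histogram over 1024 bins spanning the 12.5-ns window of an
80-MHz pulsed laser. The analysis observable is the first moment of that
histogram, the mean time-of-flight ⟨t⟩, computed after truncating the DTOF
at 10% of its peak on the ascending side and 1% on the descending side.
Late photons travel deeper, so ⟨t⟩ weights deep (cerebral) absorption
changes more heavily than superficial ones — the reason a ⟨t⟩-based
analysis suppresses scalp contamination that dominates continuous-wave
fNIRS.

**Truncation windows.** The peak-fraction thresholds are evaluated on the
raw histogram (no background subtraction; a toggle exists). By default the
pipeline computes the window once per run from the baseline-average DTOF
and holds it fixed; recomputing it per frame is available
(`processing.window_mode: per_frame`) but makes ⟨t⟩ a discontinuous
function of absorption — with 12.2-ps bins the descending threshold bin
jumps by whole bins as the tail attenuates, which injects
activation-correlated steps of ~0.3–0.5 ps into Δ⟨t⟩, comparable to the
~1-ps signals themselves. A frozen window keeps the estimator linear and is
standard moment practice.

## Photon transport and sensitivity factors

Photon propagation in the 10-layer head model (2-mm slabs, bottom layer
semi-infinite; defaults μa = 0.017 mm⁻¹, μs′ = 1.0 mm⁻¹, n = 1.4
everywhere) uses isotropic scattering at the reduced scattering rate (the
similarity relation). Absorption is *not* applied during flight; each
detected photon stores its per-layer geometric pathlengths l_k, and
absorption enters at evaluation time as exp(−Σ_k μa,k l_k), so one photon
ensemble serves every absorption configuration. Photons are terminated
exactly when their total pathlength exceeds v·t_max for the 12.5-ns
window — arrivals beyond the histogram are never recorded, so this
truncation is unbiased for any absorption and replaces survival-weight
roulette. Detection is exit through the top surface (Fresnel reflection
against external n = 1.0) within an annulus of half-width 2 mm around the
30-mm source–detector separation. Separation, annulus and n are
conventional adult-head values; the identity Σ_k l_k = (c/n)·t holds per
photon to 1e−9 and is asserted in the suite.

The engine is validated against the extrapolated-boundary dipole solution
for the time-resolved reflectance of a homogeneous half-space: with an
index-matched boundary (A = 1, removing the boundary-model degree of
freedom) the detected-photon ⟨t⟩ agrees with the annulus-integrated
diffusion moment within MC error at 10⁶ launched packets (typically
< 1 SE ≈ 10 ps on ⟨t⟩ ≈ 810 ps).

**MTSF.** The mean-time-of-flight sensitivity factor of layer k is
∂⟨t⟩/∂μa,k (ps·mm, negative). Two estimators are provided:

* *Raw-ensemble* (`compute_mtsf`): finite difference of the ensemble ⟨t⟩
  under exact per-photon reweighting, step 0.001 mm⁻¹, with batch-mean MC
  standard errors. For this estimator two identities hold and are tested
  within 3 SE: MTSF_k = −Cov_w(t, l_k), and Σ_k MTSF_k = −(c/n)·Var_w(t).
* *Measurement-matched* (`compute_measurement_mtsf`): the same finite
  difference pushed through the full measurement operator — binning,
  Gaussian instrument response (FWHM 400 ps), frozen truncation window,
  windowed ⟨t⟩ — with a step of 1e−4 mm⁻¹, the working point of
  hemodynamic absorption changes. Truncation and blur discard part of the
  late-photon sensitivity, so the matched factor is ~10–15% smaller in
  magnitude than the raw one; using the raw factor in the inversion would
  bias recovered concentrations high by the same amount. The pipeline
  inverts with the matched factor.

The brain factor is the sum over layers 5–10, as configured (the printed
index set; note that with 2-mm layers, "below 1 cm" would strictly be
layers 6–10 — the index set is exposed in `optics.brain_layers`).

## Hemodynamic inversion

Per channel and wavelength the cleaned Δ⟨t⟩ series is converted to a brain
absorption change, Δμa(λ) = Δ⟨t⟩/MTSF(λ), and the two wavelengths are
inverted through the molar extinction coefficients of oxy- and
deoxyhemoglobin (Prahl's compiled values, shipped as a versioned CSV;
decadic cm⁻¹ M⁻¹ converted by ln 10 to natural-log mm⁻¹ µM⁻¹):

    Δμa(λ) = ε_HbO2(λ) ΔC_HbO2 + ε_Hb(λ) ΔC_Hb

solved frame-wise as a 2×2 linear system (condition number ≈ 2.9 for the
760/830 pair; tables with condition number ≥ 100 are rejected). The forward
and inverse maps are exact inverses to numerical precision.

## Signal cleaning

Order fixed as motion correction → detrending → smoothing, applied to the
Δ⟨t⟩ series:

* **Motion**: moving-SD detection (window 1 s, threshold 3× the median
  moving SD, adjacent flagged runs merged) followed by MARA-style
  correction — within each flagged segment a smoothing spline
  (`make_smoothing_spline`, λ = 0.001 on the sample-index axis; small λ
  tracks the artifact closely) is subtracted and the segment re-anchored to
  the mean of its unflagged neighbours. λ = 0.001 keeps the residual of a
  step artifact below 5% of its amplitude; larger values leave edge
  overshoot.
* **Detrending**: projection onto the discrete-cosine basis, removing every
  component (including the constant) with period above 128 s. On a 330-s
  record this removes the 6 leading components; a 512-s-period drift loses
  > 90% of its RMS while a 10-s-period signal keeps > 95%. Projection is
  exactly linear and idempotent.
* **Smoothing**: convolution with a unit-area Gaussian of 4-s FWHM,
  reflect-padded (a causal gamma kernel is available by config). A
  symmetric unit-area kernel leaves baselines and plateau amplitudes
  unbiased, which a causal HRF-shaped kernel would not.

## Block averaging and features

Each question run (30-s baseline + five 30-s answer/rest cycles, 330 s) is
reduced to one 60-s epoch — 15 s pre-task, 30 s task, 15 s post-task; 200
samples — by averaging the per-cycle windows across cycles and channels and
re-zeroing to the pre-task mean. From the oxyhemoglobin epoch four features
are extracted: SM (median task change excluding the first 10 s, minus the
pre-task median), SS (least-squares slope of the first 16 s of the task; a
7-s variant is config-selectable), CNR (task−rest mean difference over the
pre-task SD; the full 30-s task window, since the 10-s exclusion is stated
only for SM), and r (Pearson correlation of the full 60-s epoch with the
theoretical model: the task boxcar convolved with the canonical HRF,
epoch-extracted identically). SM and SS scale with amplitude; CNR and r are
amplitude-invariant; all four are offset-invariant.

## Decoding

Question records are pooled across participants (72 records for 18×4) and
classified by leave-one-out cross-validation: for each held-out record the
classifier trains on the remaining 71 with features standardised by the
training fold's mean/SD. Classifiers: LDA (pooled covariance, equal
priors) and a linear SVM (C = 1); the kernel and hyperparameters are the
minimal choices for four features at this sample size. All 15 non-empty
feature subsets are evaluated and the argmax reported, ties resolved
fewest-features-first then SM < SS < CNR < r. Selecting the subset by its
own LOOCV accuracy is optimistically biased; `nested_subset_search`
re-selects inside each outer fold and reports the unbiased figure.
Secondary analyses rebuild epochs from the first k = 1…5 cycles
(accuracy-vs-cycles curve, with the subset fixed at the 5-cycle optimum)
and group LOOCV predictions by question-order position.

## Synthetic studies

The generator emulates the study conditions so the whole chain is testable
without recordings:

* **Cohort**: 18 virtual participants × 4 questions, 2 of 4 answered
  "yes", question order randomised per participant; responder status
  Bernoulli with a 12% non-responder fraction (non-responders have zero
  response amplitude). Responder amplitudes: ΔHbO₂ plateau ~
  N(0.5, 0.15) µM truncated at 0.1, ΔHb = −0.3 × ΔHbO₂; HRF time-to-peak ~
  N(7, 0.5) s clipped to [5, 9].
* **Activation**: answer-block boxcar convolved with a unit-area
  single-gamma kernel (shape 6, peak at the profile's time-to-peak),
  applied uniformly to the brain layers via the forward extinction map.
* **Forward DTOF model**: the binned photon ensemble is reweighted per
  frame with the per-bin mean brain/scalp pathlengths (first order; for the
  ≤1e−4 mm⁻¹ signals the neglected term is O((Δμa·σ_L)²) ≈ 1e−6
  relative), blurred with the 400-ps instrument response, scaled to 10⁵
  counts per frame (a plausible TCSPC rate, configurable), and Poisson
  sampled per bin.
* **Noise**: superficial systemic signals live in the scalp layer as
  hemoglobin oscillations — cardiac ~1.1 Hz (0.3 µM) and Mayer waves
  ~0.1 Hz (0.4 µM), independent phases and ±10–20% frequency jitter per
  channel; slow drift as a random linear ramp (±1 µM over the run) plus a
  random walk (0.02 µM/frame step); motion spikes at 0.01 events/s shift
  the DTOF time origin by ~±2 bins and scale its amplitude by ~±10% for
  ~1.2 s, with timing shared across channels (head movement) — amplitudes
  chosen once as physiologically plausible values of the right order for
  scalp hemodynamics and TCSPC acquisition.
* **Closed loop**: with noise off, the injected ΔHbO₂ plateau is recovered
  through the full pipeline to within ±10% (measured ≈ 1% low at the
  default configuration); at default noise the mean recovery over 10 seeds
  stays within ±25%.

What the generator does **not** emulate: afterpulsing, dead time and dark
counts; wavelength-dependent baseline optical properties; spatially
heterogeneous (focal) activation and partial-volume effects; correlated
systemic physiology across participants; EEG-cap/optode-coupling artifacts
beyond the listed motion model. Passing tests therefore demonstrate the
correctness and self-consistency of the analysis chain under the stated
physics, not performance on human recordings; in particular the synthetic
decoding accuracies (≈ 90% at the defaults) sit above the ~75% the
original human cohort reached, as expected for a generator whose responders
are genuinely block-locked.

## Problem sizes and determinism

Default problem sizes were chosen so a full study runs in minutes on one
core: 10⁶ launched packets (~10⁴ detected photons, effective sample size
~1.3×10³ under absorption weights, ~1–2% MC error on the brain MTSF — an
error that is common-mode across both wavelengths and largely cancels in
classification), 18 participants × 4 questions × 4 channels × 2
wavelengths × 1100 frames. Every stochastic entry point takes an explicit
seed: the Monte-Carlo kernel seeds its own generator, the cohort draw and
each run derive integer seeds from the master seed, and repeated runs are
bit-identical. The validation suite uses reduced cohorts (4–8 participants,
1–2 channels) where the full size adds nothing to the property under test.

## Known limitations

* The binned first-order forward model and the matched MTSF are mutually
  consistent; applying the pipeline to per-photon-exact (or real) data
  leaves a second-order bias, relevant only for perturbations ≫ 1e−4 mm⁻¹
  (at 0.002 mm⁻¹ the midpoint-evaluated sensitivity recovers the step to
  0.2%).
* Isotropic scattering reproduces moments of the anisotropic problem via
  similarity but not the early-time ballistic regime; comparisons are
  restricted to post-peak times.
* The spline motion correction reconstructs flagged segments; residual
  signal inside artifacts is not recovered, only replaced smoothly.
* LOOCV pools records across participants; per-participant fold grouping is
  available but not the default, matching the per-participant "out of 4"
  scoring convention.
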