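# trbci — time-resolved fNIRS mental communication

`trbci` is a Python library for decoding yes/no answers from time-resolved
functional near-infrared spectroscopy (TR-fNIRS) recordings of motor
imagery, and for generating the physics-based synthetic studies needed to
validate such a pipeline end to end.

The measurement: a picosecond laser (760 and 830 nm) illuminates the scalp
over motor-planning cortex and a photon-counting system records, every
300 ms, the distribution of times-of-flight (DTOF) of photons returning at
a 30-mm offset. The analysis observable is the DTOF's first moment, the
mean time-of-flight ⟨t⟩ — late photons travel deep, so ⟨t⟩ is selectively
sensitive to cerebral absorption. A participant answers "yes" to a question
by imagining playing tennis during five 30-s answer blocks, driving
oxyhemoglobin up and deoxyhemoglobin down in cortex; "no" means resting
throughout.

The pipeline chains:

1. **Photon transport** — layered Monte Carlo with per-photon, per-layer
   pathlengths; validated against the time-resolved diffusion closed form.
2. **Sensitivity factors** — MTSF = ∂⟨t⟩/∂μa per layer (ps·mm, negative),
   summed over the brain layers (5–10 of a 10 × 2 mm stack).
3. **DTOF moments** — per-frame ⟨t⟩ after truncating each DTOF at 10%
   (ascending) / 1% (descending) of its peak; Δ⟨t⟩ = ⟨t⟩ − ⟨t⟩₀ against the
   30-s baseline.
4. **Cleaning** — moving-SD motion detection with spline correction,
   discrete-cosine detrending (128-s cut-off), 4-s-FWHM smoothing.
5. **Hemodynamics** — Δμa(λ) = Δ⟨t⟩/MTSF, then the two-wavelength
   extinction system
   Δμa(λ) = ε_HbO₂(λ)·ΔC_HbO₂ + ε_Hb(λ)·ΔC_Hb solved per frame (µM).
6. **Epochs & features** — 60-s block averages (15 s rest / 30 s task /
   15 s rest) across five cycles and four channels; features SM, SS, CNR
   and r from the oxyhemoglobin epoch.
7. **Decoding** — LDA and linear-SVM leave-one-out cross-validation over
   all 15 feature subsets, with accuracy-vs-cycles and per-question
   analyses.

The synthetic-study generator reproduces the block protocol (30-s baseline
plus five 30-s answer/rest cycles: 5:30 min per question, 22 min per
four-question session), Poisson counting noise, instrument response,
systemic physiology, drift, motion spikes and a configurable non-responder
fraction. See `docs/methods.md` for models, defaults and limitations.

## Worked example

`examples/` holds one narrative script per capability. Decoding a reduced
synthetic cohort (`python examples/04_decode_cohort.py`):

```
32 question runs processed

participant  q  truth   SM(uM)    SS(uM/s)   CNR      r
  P01      1  no      0.153     0.0593    4.88    0.41
  P01      2  yes     0.307     0.0228    6.24    0.94
  ...

best feature subset: r (of 15 evaluated)
LOOCV accuracy:      81.2%
sensitivity:         93.8%   (correct 'yes' detections)
specificity:         68.8%   (correct 'no' detections)
per question-order position: {1: '88%', 2: '62%', 3: '75%', 4: '100%'}
```

Each row is one question run reduced to the four oxyhemoglobin features:
SM, the median task–rest shift in µM; SS, the early-task slope; CNR, the
contrast-to-noise ratio; and r, the correlation with the boxcar ⊗ HRF
model. The classifier answers every question from the other 31 runs;
accuracies above the 70% threshold are conventionally taken as sufficient
for basic communication. The misclassified runs here belong to a simulated
non-responder, whose imagery produces no hemodynamic signal by
construction.

The physics examples print, e.g. (`examples/01_photon_transport.py`):

```
MC <t>:                  807.5 +- 20.1 ps
diffusion-theory <t>:    802.5 ps
difference:              0.25 MC standard errors
```

A thin CLI mirrors the library for shell use:
`trbci simulate|sensitivity|features|classify|all|report`
(e.g. `trbci all --seed 1 --outdir out/` writes features, results JSON and
class-average epoch figures).

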