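# fluidsense

Analysis toolkit for detecting thoracic fluid accumulation — the hallmark
of acute decompensated heart failure — from two wearable-vest signal
streams: multi-frequency transthoracic bioimpedance spectra and
single-lead ECG. It is written for physiological-signal and wearable-
cardiology researchers who need the full chain from raw signals to
group statistics and subject-aware classification, exercised end to end
on synthetic data with known ground truth.

## What it computes

**Bioimpedance.** Tissue is modelled as an extracellular resistance R₀
in parallel with an intracellular branch (resistance R_I in series with
the cell-membrane capacitance C_m). Across frequency the impedance traces
a depressed circular arc (Cole–Cole plot):

```
Z(f) = R∞ + (R₀ − R∞) / (1 + (j f / f_c)^α),   R∞ = R₀ R_I / (R₀ + R_I)
```

with characteristic frequency f_c = 1/(2π C_m (R₀ + R_I)) and
heterogeneity exponent α ∈ (0, 1]. `ColeModel(spectrum).fit()` initialises
from a Taubin algebraic circle fit (real-axis intercepts → R₀, R∞; arc
depression → α) and refines all four parameters by Nelder–Mead on the
summed squared complex residual, returning the eight per-recording
parameters (R₀, R_I, R∞, R₀−R∞, f_c, C_m, α, fitting error) with
Gauss–Newton standard errors. Lower R₀ means more thoracic fluid.

**Heart rate variability.** The ECG is band-passed (0.05–40 Hz, zero
phase), R peaks are detected (derivative–square–integrate, adaptive
threshold, 0.2 s refractory), RR intervals are cubic-spline resampled at
4 Hz, and Blackman-windowed 256-point periodograms are averaged. Seven
indices result: mean heart rate, LF (0.045–0.15 Hz) and HF (0.15–0.4 Hz)
band powers, their normalized fractions nLF = LF/(LF+HF) and nHF, and two
principal-dynamic-mode indices that split the interval dynamics into
sympathetic- and parasympathetic-dominated components via a
Volterra–Laguerre kernel eigendecomposition.

**Statistics and classification.** Each of the 15 features is screened
for normality (Kolmogorov–Smirnov) per group and routed to one-way
ANOVA + Tukey HSD or to the Dunn rank test; classifiers (cubic/quadratic/
Gaussian-kernel SVM with C=1, γ=2.6; 1-NN; decision tree) are evaluated
with leave-one-subject-out cross-validation, uniform class priors and
exhaustive search over all 2¹⁵−1 feature subsets, reporting accuracy and
row-percentage confusion matrices.

A synthetic-data module generates all three input kinds with known ground
truth: Cole arcs at the 16 study frequencies (10–999 kHz), ECG/RR series
with controllable LF/HF modulation, and cohort tables drawn from the
published per-group feature means/SDs (control n=32, admission n=23,
discharge n=17, 12 subjects recorded twice).

## Worked example

Simulate one noisy spectrum and fit it:

```
$ fluidsense simulate spectrum --out spec.csv --seed 3 --noise-sd 0.2
$ fluidsense fit-cole --in spec.csv --out params.csv
Cole tissue-impedance model fit
==============================================
n frequencies                               16
iterations                                 172
fitting error (Ohm^2)             1.500543e+00
----------------------------------------------
param               estimate           std err
r0                   38.2479              0.53
r_inf                21.3394             0.272
alpha               0.592993            0.0241
fc                   44113.6          3.37e+03
----------------------------------------------
r_i (Ohm)                              48.2708
r0 - r_inf (Ohm)                       16.9085
C_m (F)                            4.17001e-08
```

The generator's truth was R₀ = 38.1 Ω, R∞ = 21.5 Ω, α = 0.609,
f_c = 45 kHz: every estimate sits within one standard error, and the
fitting error (1.5 Ω² over 16 complex residuals) matches the injected
0.2 Ω noise. `ColeResults.plot()` draws the measured points and fitted
arc in the resistance–reactance plane.

The whole pipeline — simulate a full cohort, fit every spectrum, extract
HRV indices, compare groups, classify — runs from one config:

```
$ fluidsense run-all --config examples/demo.yml
```

In the demo run the admission group's extracellular resistance is flagged
against controls (Tukey p ≈ 1.2e-5, matching the direction of the
clinical finding), and the two-class fluid/no-fluid cubic SVM on the
six-feature recipe reaches 78% LOSO accuracy on the synthetic cohort.
Re-running with the same config and seed reproduces every output file
byte for byte.

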