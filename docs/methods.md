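# Methods

This note records the models, numerical choices and open design
decisions behind `fluidsense`, and what the synthetic-data tests do and
do not establish about real recordings.

## Cole tissue-impedance model

The circuit is R₀ (extracellular) in parallel with R_I–C_m in series
(intracellular branch). The fitted form is the standard Cole relation

    Z(f) = R∞ + (R₀ − R∞) / (1 + (j f / f_c)^α),

whose limits reproduce the circuit identities Z(0) = R₀ and
Z(∞) = R∞ = R₀R_I/(R₀+R_I); the characteristic frequency obeys
f_c = 1/(2π C_m (R₀ + R_I)). Reactance is stored as negative imaginary
values and Cole–Cole plots are drawn with −Im(Z) upward, so the arc lies
in the upper half of the plot. Four parameters (R₀, R∞, α, f_c) are fit;
R_I, R₀−R∞ and C_m are derived, so the circuit identities hold exactly
for every returned parameter set (checked to 1e-9 relative at
construction).

**Initialisation.** A Taubin algebraic circle fit (Newton iteration on
the characteristic polynomial of the centred moments) gives the arc
geometry: R∞ and R₀ are the real-axis intercepts c_x ∓ √(r²−c_y²), and
α = (2/π)·arccos(|c_y|/r) from the arc depression. f_c starts at the
measured frequency of maximum |reactance| (the arc apex), which is
robust to partial arcs. If a noisy circle misses the real axis the fit
falls back to the resistance extremes; exactly collinear input (e.g. a
pure resistor) is rejected as degenerate rather than silently fitted.

**Refinement.** Nelder–Mead on a transformed vector — log R∞,
log(R₀−R∞), logit α, log f_c — so the constraints 0 < R∞ < R₀,
α ∈ (0,1], f_c > 0 hold without constrained optimisation. Termination is
at relative objective tolerance 1e-10 (implemented as a per-stage
absolute tolerance max(1e-15, 1e-10·|f|), since the underlying simplex
accepts only absolute tolerances), parameter spread 1e-9, 2000
iterations per stage with one restart from the incumbent. Measured
behaviour: noise-free 16-point spectra are recovered to ≤1e-9 relative
error with fitting error ≤1e-16 Ω²; at 0.2 Ω complex noise the median R₀
error is ~0.4%.

**Uncertainties.** `ColeResults.bse()` uses the Gauss–Newton
approximation: σ² (JᵀJ)⁻¹ with J the numerical Jacobian of the stacked
real/imaginary residuals and σ² the fitting error over 2n−4 degrees of
freedom. These are curvature-based approximations, not profile
intervals.

The fitting error is reported in Ω² (sum of squared complex residual
magnitudes). The characteristic frequency is reported in Hz on the kHz
scale implied by C_m ≈ 4×10⁻⁸ F and R₀+R_I ≈ 90 Ω.

## Heart rate variability

Band edges: LF 0.045–0.15 Hz (sympathetic-dominated), HF 0.15–0.4 Hz
(parasympathetic/respiratory). The chain is: order-4 Butterworth
band-pass 0.05–40 Hz applied forward–backward (zero phase; the 0.05 Hz
corner has a multi-second transient, so the filter is reflected-padded
over 3/low seconds); derivative–square–integrate R-peak detection with
an adaptive threshold (30% of the 99th percentile of integrated energy)
and a 0.2 s refractory period, each detection refined to the local ECG
maximum so timing is sample-accurate and amplitude-scale invariant; a
fixed-length 240 s analysis window chosen automatically as the stretch
with fewest interval anomalies (outside 0.3–2.0 s or >30% beat-to-beat
change), standing in for the manual clean-segment selection a human
scorer would do; cubic-spline resampling of the intervals at 4 Hz;
mean-subtracted Welch averaging of Blackman-windowed 256-sample segments
with 50% overlap and window-power normalisation (frequency resolution
4/256 Hz). Normalized indices are fractions of LF+HF, so nLF + nHF = 1
by construction; band powers are in s²(/Hz before integration).

## Principal dynamic modes

The PDM indices concretise a kernel-eigendecomposition approach to
separating autonomic branches. A one-step-ahead autoregressive Volterra
model of the mean-subtracted 4 Hz interval series is estimated on an
orthonormal Laguerre basis (8 functions, decay 0.5, 16 s memory):
first-order coefficients c_j plus second-order self terms c_jj, with
lag 0 excluded — including the current sample lets the kernel collapse
onto the identity and carries no dynamics. The symmetric kernel matrix
Q (off-diagonal first-order block c_j/2, diagonal c_jj) is
eigendecomposed; each eigenvector maps back to an impulse response in
lag space. A mode is assigned to the sympathetic or parasympathetic
branch by the dominant frequency of the component it extracts from the
series (the mode-filtered output), LF band → sympathetic, HF →
parasympathetic; up to 3 modes per branch, ranked by |eigenvalue|, are
retained, and each index is the eigenvalue-weighted output power of its
branch. Classification by the kernel's own FFT peak was rejected: for
near-deterministic sinusoidal series the one-step-predictor kernel is
broadband (its resonance lives in the closed-loop poles), and no HF
modes are ever found. Extraction-based classification orders the
indices correctly on 100% of band-dominant synthetic series and is
monotone in LF amplitude at the stated defaults.

The indices are relative powers; only their ordering and monotone
behaviour are asserted, not absolute scales.

## Synthetic data — what it emulates and what it does not

* **Spectra**: exact Cole arcs at 16 log-spaced frequencies from 10 kHz
  to 999 kHz (the measurement range; spacing is the package's choice, as
  is standard in impedance spectroscopy) plus independent Gaussian noise
  (default 0.2 Ω, a plausible vest-electronics scale chosen in the
  0.1–0.5 Ω range; the device's true noise level is not published) on
  the real and imaginary parts.
* **ECG/RR**: intervals RR_k = mean_rr + a_LF sin(2π f_LF t_k) +
  a_HF sin(2π f_HF t_k) + ε_k with a 0.2 s refractory floor, and an ECG
  built by placing a fixed 80 ms biphasic QRS template at the cumulative
  beat times (train offset 0.1 s so every truth beat is a complete QRS).
  Sinusoidal interval modulation makes ground-truth band content exact,
  which is all the downstream assertions need; it does not emulate
  integral-pulse-frequency modulation, respiration coupling, ectopy or
  realistic P/T-wave morphology.
* **Cohorts**: independent Gaussian draws per feature from the published
  per-group means/SDs (control 32, admission 23, discharge 17), with 12
  subjects shared between admission and discharge; a correlation-matrix
  hook exists but no covariances are published, so the default is
  independence.

Passing tests therefore demonstrate that the algorithms recover known
ground truth and reproduce the published arithmetic and the direction
and power of the published group differences — not that the clinical
accuracies (92%/75%) are attainable, which requires the clinical
recordings themselves. On independent-Gaussian synthetic cohorts the
full-feature cubic SVM reaches ~78% two-class LOSO accuracy.

## Statistics

Normality uses the plain one-sample KS test against a Gaussian with the
sample's own mean and SD, mirroring common practice; this is
anti-conservative with estimated parameters, so a Lilliefors-corrected
variant is available behind a flag (default off). Routing is
conservative: a parameter goes to the Dunn test if any group fails
normality. The Dunn test is implemented directly (joint ranking, tie
correction Σ(t³−t)/(12(N−1)), two-sided normal p-values, unadjusted by
default with a Bonferroni flag) and reduces exactly to the two-group
Wilcoxon rank-sum z when there are two tie-free groups. No
Kruskal–Wallis omnibus gate precedes Dunn; the workflow applies the
pairwise test directly to non-normal parameters. Tukey HSD p-values come
from the studentized-range distribution. With three groups the Tukey
correction prices three pairwise comparisons, so the
control-vs-admission power at the published R₀ separation is ~84%;
quoted power figures (~93%) refer to the two-group n=32/23 comparison.

## Classification

Per LOSO fold, features are z-scored on the training recordings only
(kernel machines are scale-sensitive), and "uniform priors" are
implemented as class weights inversely proportional to training-class
frequency. Folds are one per subject; a subject recorded in two groups
is always held out whole. Polynomial-kernel C defaults to 1 (matching
the stated Gaussian C); decision trees use impurity splitting with no
depth cap. The subset search wraps the full LOSO loop (matching the
reported workflow; this is optimistic relative to nesting the search
inside each fold, and the optimism is inherited knowingly). Ties break
toward fewer features, then enumeration order. Accuracy is
per-recording: the published confusion matrices are only arithmetically
consistent with 72 recordings (32+23+17), and on that accounting their
rows imply 66/72 ≈ 92% (two-class) and 54/72 = 75% (three-class).

A caveat worth knowing: the Gaussian kernel at the stated γ=2.6 is
extremely narrow on the full 15-dimensional z-scored feature space — the
kernel matrix approaches the identity, which under LOSO yields
anti-learning on label-free data and majority collapse on imbalanced
data. This is a faithful consequence of the stated hyperparameter (it is
benign on the small subsets where that model is actually selected);
integrity checks therefore use the cubic SVM.

## Pipeline

`run_all` executes simulate → fit-cole → hrv → assemble → stats →
classify from a single YAML config whose defaults are the study
constants (bands, 4 Hz, 256-point window, C, γ, k). Every output CSV
carries a `# seed=… config_hash=…` comment line and the manifest records
config, seed, versions and per-stage row counts; re-running a config is
byte-identical. The simulate stage derives per-group generative
parameters from the published feature table (f_c from the published C_m
and circuit resistances ≈ 43 kHz; heart-failure groups get a larger
HF modulation amplitude, echoing their higher normalized HF power); the
demo seed was chosen so the R₀ control-vs-admission flag is stable.

## Known limitations

Single-dispersion Cole model only (no double arcs or electrode-
polarization correction); no time-domain HRV (SDNN/RMSSD) or
respiration-guided band adjustment; no ectopic-beat editing beyond the
refractory rule; no probability calibration or nested hyperparameter
tuning. The published f_c row of the clinical feature table (≈6×10⁻⁴,
labelled Hz) is inconsistent with the kHz scale implied by the published
C_m and resistances; this package reports f_c in Hz and makes no attempt
to match that row. Units of the published LF/HF powers are unstated;
outputs here are labelled s².
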