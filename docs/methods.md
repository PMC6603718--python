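# Methods

This note documents the models implemented in `hydrofuse`, the choices
made where the underlying methodology was open, and what the synthetic
data generator does and does not emulate.

## The calibration problem

The target is the PO₄³⁻ concentration *c* (mg/L, 10–1300) of a
hydroponic nutrient solution, estimated from two channels measured on
the same sample: a transmission NIR spectrum over 904–1700 nm and the
EMF of one or more cobalt electrodes against a reference electrode.
Neither channel is sufficient alone — the phosphate NIR signature
(bands in the 930–960 and 1020–1120 nm windows) is weak and overlapped
by other solutes, while cobalt electrodes are sensitive but poorly
repeatable because their CoO surface layer evolves over a measurement
session. The package implements both single-channel calibrations and
two feature-level fusions, and compares them under a fixed 56/24
calibration/test split.

## Electrode channel

Each electrode is calibrated by ordinary least squares in the
log-linear (Nikolsky–Eisenman) form,
`EMF_k = E0_k + S_k · log10(c)`, with `S_k < 0` for an anion and
concentration (not activity) as the regressor; activity-coefficient and
interfering-ion corrections are out of scope, though the simulator's
config accepts selectivity terms. Inverse prediction is
`ĉ_k = 10^((EMF_k − E0_k)/S_k)`; multi-electrode aggregation uses the
geometric mean, i.e. the arithmetic mean on the log scale where the
model is linear. Predictions outside the calibration range are logged,
never clipped: for a monitoring application a wild value is more useful
visible than silently truncated. An optional two-point normalization
maps each electrode's readings at two known standards onto the
electrode-mean target line, removing offset and sensitivity spread
exactly for affine disturbances; the default workflow uses raw EMF.

## Spectral channel

Pretreatments are composable from a spec string (`"raw"`, `"ma:11"`,
`"ma:11+snv"`, `"ma:11+msc"`):

* moving average — centered window, truncated (shrinking) at the edges
  so no data are fabricated and the length is preserved; window 11 is
  the conventional choice at this spectral resolution;
* SNV — per-spectrum `(x − mean)/sd` with the n−1 denominator;
* MSC — per-spectrum affine regression on a reference; the reference is
  the **calibration-set** column mean, stored and reused unchanged for
  test spectra. Refitting it on test data would leak information.

Regression uses mean-centered but not variance-scaled predictors (all
wavelengths share one intensity unit, and variance scaling would
amplify dead detector channels). PCR regresses the centered response on
the leading SVD scores; PLSR is the classical NIPALS recursion for a
univariate response (tolerance 1e−10, ≤500 inner iterations per
component — for one response the power step converges in a single
pass), with the regression vector folded back to feature space as
`β = W(PᵀW)⁻¹q`. Both reduce exactly to OLS at full rank, which the
tests verify against independent oracles.

Component counts are chosen by k-fold cross-validation (default 10
folds, seeded shuffle, pooled out-of-fold predictions). Selection
minimises CV RMSE by default (CV R² is also reported and selectable);
ties go to the smaller k, where "tie" means within 1e−9·sd(y) of the
minimum — on noiseless data every k at or above the true latent
dimension reaches floating-point-level error and the parsimonious k
should win.

**Metrics.** R² is always 1 − SSE/SST on the evaluated set, not a
squared correlation, so biased predictors are penalised; RMSE is in
mg/L with the 1/n denominator; the predicted-vs-actual OLS slope and
offset are reported alongside.

## Network

A four-layer perceptron (input, two hidden layers, linear output) with
logistic, tanh and ReLU hidden activations. The tanh derivative is
1 − f(x)² and the ReLU derivative at exactly 0 is defined as 1 (a
measure-zero tie-break). Inputs and response are z-standardized inside
the model and the scalers stored with it. Weights initialise as
N(0, 1/fan-in), biases zero, under a seeded generator; all training is
bit-reproducible.

Two trainers:

* **Levenberg–Marquardt** (default): residual Jacobian by vectorised
  reverse-mode, update `Δw = −(JᵀJ + λI)⁻¹Jᵀr`, λ starting at 1e−3,
  ×10 after a rejected step, ×0.1 after an accepted one, abandoned at
  λ > 1e12. Only strictly improving steps are accepted, so the accepted
  loss trace is non-increasing by construction.
* **Back-propagation** with learning rate and momentum (full batch), the
  classical alternative; a loss that turns non-finite or grows by 12
  orders of magnitude raises a training error carrying the trace.

Defaults: `max_epochs` 1000 with early stop when the loss improves by
less than 1e−9 over 20 epochs. In the comparison protocol the fused
networks instead run with a small accepted-step budget (default 5): on
56 calibration samples LM interpolates the data within ~20 steps, and a
limited iteration count is the implicit regulariser standing in for the
validation-based stopping the original workflow left unspecified. The
budget is a protocol parameter (`net_max_epochs`).

## Fusion

* **Method A (concatenation)** — the (optionally pretreated) spectral
  matrix and the raw EMF columns side by side, into PLSR or PCR
  (default 11 latent components).
* **Method B (PC-NN)** — PCA fit on calibration spectra (raw by
  default; the fused workflow skips pretreatment), the leading `n_pc`
  scores (default 11) joined with the EMF columns, into the network.
  Architecture cases 1–7 cover the screened hidden-layer grid; case 6
  (30 logistic + 25 tanh, rate 0.001) is the default.

Fused columns are z-standardized using calibration statistics because
PC scores and mV-scale EMF differ by orders of magnitude; `scale=False`
reproduces the literal unscaled concatenation. A known consequence,
visible on near-noiseless simulations: score columns beyond the true
spectral rank are pure detector noise, and per-column standardization
inflates them to unit variance, degrading the network's test
performance. The remedy is choosing `n_pc` by cross-validation rather
than fixing it — the default 11 is itself the CV choice under the
default noise regime, not a universal constant.

Leakage protection is structural: MSC references, PCA, column scalers
and network scalers are all fit on calibration rows only, and
`evaluate_split` refuses to score a test set whose ids overlap the
rows used for fitting (an identical set is allowed as a deliberate
resubstitution check). A permutation-null test confirms that shuffled
responses carry no transferable signal.

## Synthetic data generator

The simulator defines the study conditions for every test.

**Spectra**: absorbance `A(λ) = baseline(λ) + Σ_b g_b·c·G(λ; μ_b, σ_b)
+ Σ_j u_j·G(λ; μ_j, σ_j)`, transmitted intensity
`I = (m·i0)·10^(−A) + a + ε`. Defaults: 128 points over 904–1700 nm;
phosphate bands at 945 nm (σ 15) and 1070 nm (σ 30) with gains 1e−5 and
1.5e−5 absorbance/(mg/L); a water-like baseline peaking near 1450 nm;
three interfering-ion bands (950/1080/1000 nm, σ 18/33/60) with
per-sample uniform amplitudes up to ~0.01–0.015 absorbance;
multiplicative scatter sd 0.03, additive 0.005, detector noise 0.005.
The interferent bands model the other dissolved nutrient salts whose
absorption overlaps the phosphate windows; they are what keeps
scatter correction from trivialising the problem, since SNV/MSC remove
multiplicative/additive effects exactly but not spectral confounders.

**EMF**: `EMF[i,k] = E0_k + S_k·log10(c_i) + d_k·i + ε`, defaults
E0 = (402, 388, 415) mV, S = (−54, −51, −58) mV/decade, linear drift
0.3 mV per sample index (a proxy for oxide-layer ageing over a
measurement session; samples are assumed measured in table order) and
10 mV noise.

Noise defaults were set so that the *baseline* single-channel models
behave like the real instruments this class of study reports: NIR-only
PCR/PLSR with CV-selected components reaches test R² roughly 0.4–0.65,
and single electrodes give concentration-space test R² roughly
0.3–0.85 with line-fit R² near 0.9. Under these conditions the fused
PC-NN typically reaches test R² 0.7–0.9, and the qualitative ordering
PC-NN ≥ PCR-fusion ≥ NIR-only PCR holds in the large majority of
seeded replicates.

What the generator does **not** emulate: electrode-surface chemistry
(conditioning, abrasion, pH speciation of phosphate, temperature),
non-Gaussian detector artefacts, wavelength miscalibration, and any
correlation between the two channels' errors. Passing tests therefore
demonstrate the correctness and internal consistency of the calibration
machinery under a plausible noise model — not field performance of a
physical sensor.

## Problem sizes and numerical choices

The standard experiment is 80 samples (log-uniform in 10–1300 mg/L),
split 56/24 by rank stratification: samples are ordered by
concentration, divided into 24 blocks, and one test sample drawn per
block, so both sets span the range. The comparison protocol derives all
stage seeds from one master seed via a seed sequence, making the full
21-row report byte-identical across runs. Monte-Carlo checks use 25–100
replicates as noted in the tests; these sizes keep the whole suite and
the acceptance script within a few minutes on one core while leaving
the statistical margins (e.g. ≥20/25, ≥95/100) comfortably wide.

Degenerate inputs fail loudly and specifically: zero-variance spectra
name the offending sample, MSC refuses near-zero scatter slopes
(|b| < 1e−12), calibration with fewer than two distinct concentrations
raises a rank error, constant responses make R² undefined rather than
NaN, and diverging training raises with the loss trace attached.

## Known limitations

* PLSR is univariate-response only (PLS1); no VIP scores or interval
  selection.
* The network is a fixed two-hidden-layer regression topology — no
  minibatching, no explicit regularisation beyond iteration budget and
  early stopping.
* The electrode model fits concentration, not activity; ionic-strength
  effects fold into the empirical slope.
* Simulator realism is calibrated at the level of summary statistics
  (R² ranges), not instrument physics.
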