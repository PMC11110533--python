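# Methods

`fnirsglu` implements an end-to-end analysis linking prefrontal-cortex
fNIRS signals to blood glucose: a synthetic cohort generator with a known
glucose→HbO coupling, a Homer2-style preprocessing chain, windowed
λ-features of the mean-HbO signal, a class-aware PCA variant (decreasing
rule, "DR-PCA") and nested leave-one-subject-out (LOSO) prediction of
reference glucose.  This note records the models, the defaults and why,
the numerical choices, and what the synthetic experiments do and do not
show.

## Study design emulated by the generator

Each synthetic subject is monitored continuously through two states: a
10 min fasting block and a 60 min block after a glucose load, at 10 Hz
over 21 source–detector channels (30 mm separation) and two wavelengths
(760/830 nm); fifteen subjects per cohort.  Fingertip reference glucose is
sampled every 5 min with 0.1 mmol/L meter noise.

**Glucose curve** (mmol/L).  A stationary fasting level F ~ N(5.0, 0.3²),
then a sin²-shaped rise to F + Δ with Δ ~ N(3.0, 0.5²) peaking at
t_peak ~ N(1500, 200²) s after the load, then exponential decay
(τ = 800 s) toward a plateau at F + 0.3Δ.  The curve is continuous at the
state boundary and carries 0.05 mmol/L jitter.  The family (constant →
smooth rise → decay to an elevated plateau) encodes the qualitative
post-load kinetics the analysis is meant to detect; the sin² rise makes
the noise-free peak land exactly at F + Δ at t_peak, which the tests
exploit.

**Hemodynamic coupling** (μM).  On a fixed subset of channels
({7, 12, 15, 18, 19}) the oxygenated-hemoglobin change follows
ΔHbO(t) = β·(G(t) − G_fast) plus cardiac (1.1 Hz, 0.05 μM), respiratory
(0.25 Hz, 0.04 μM) and Mayer-wave (0.1 Hz, 0.05 μM) sinusoids and
0.03 μM white noise; uncoupled channels have β = 0.  ΔHbR is
anti-correlated scaled ΔHbO (ratio 0.3) plus independent noise, the
canonical hemodynamic relationship.  One β per subject,
β ~ N(0.08, 0.02²) μM per mmol/L truncated at zero.  The scale was fixed
so that window-level squared amplitudes stay below 1/e μM², which keeps
the un-normalised energy entropy −Σx²ln(x²)dt inside its monotone
regime; larger couplings would make that feature fold back on itself and
no longer behave as an "energy-like" correlate (see λ10 below).

**Forward optics and artifacts.**  The modified Beer–Lambert law (MBLL)
maps (ΔHbO, ΔHbR) to ΔOD at each wavelength via tabulated extinction
coefficients (Gratzer values, 1/(mM·cm)), DPF = 6.0 at both wavelengths
and d = 3.0 cm; intensity is I₀·10^(−ΔOD) with I₀ = 0.1 (inside the
pruning range).  Motion artifacts are injected in the intensity domain at
Poisson times: multiplicative exponential-decay spikes (5–20% amplitude,
τ = 0.3 s, 0.5/min) and step baseline shifts (2–5%, 0.1/min), logged as
ground truth.

An optional very-low-frequency drift term (random-phase sinusoids in
0.002–0.02 Hz, `vlf_amp`, off by default) lets users stress-test analyses
against slow vasomotor variability; it is not part of the reference noise
model because such drift violates the independence assumption of the
state-contrast t-tests and real analyses control for it explicitly.

**What the generator does not emulate.**  No photon-transport physics,
scalp/skull layering, optode-coupling drift, serial correlation in the
measurement noise, inter-channel crosstalk, or any systemic confounder
(blood pressure, arousal) that co-varies with glucose.  Passing the
recovery tests therefore shows that the chain is correct and has
statistical power under the planted model — not that real prefrontal
fNIRS carries a causal glucose signal of this form.

## Preprocessing

Order: channel pruning → optical density → motion-artifact detection →
wavelet correction → filtering → MBLL inversion → CBSI.  Every stage can
be disabled; provenance records the stages run and per-stage counts.

- **Pruning**: keep a channel iff, at both wavelengths, mean intensity ∈
  [10⁻², 10⁰] and mean/std ≥ 2 (a constant channel counts as infinite
  SNR).  Pruned channels are masked, never deleted.
- **Optical density**: ΔOD = −log₁₀(I/Ī).  The op default takes Ī as the
  recording's temporal mean.  The *pipeline* default references Ī to the
  pre-load fasting block (block-design baselining): with whole-session
  mean referencing every recovered series is mean-centred, which erases
  the fasting-vs-glucose level contrast and makes window energy
  non-monotone in glucose; fasting-baseline referencing recovers
  ΔHbO ≈ β·(G − G_fast) ≥ 0, which is what the state t-tests and the
  energy features analyse.  For the same reason each subject's fasting and
  glucose blocks are preprocessed as one concatenated session.
- **Motion detection**: sliding 1 s windows; flag when peak-to-peak ΔOD
  exceeds 0.02 or windowed std exceeds 5× the channel's median windowed
  std; flags dilated by 1 s.  The mask is diagnostic (recorded in
  provenance); correction is done by the wavelet stage so that downstream
  windows stay contiguous.
- **Wavelet correction**: per-channel DWT (Daubechies-2, level
  ⌊log₂(fs/0.01)⌋ capped by the data length); detail coefficients outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] at each level are zeroed; the
  approximation band is untouched.  An in-band sinusoid has an arcsine
  coefficient distribution whose extremes sit inside the Tukey fences, so
  smooth signal survives (RMS change ≤ 10%) while isolated spike
  coefficients are removed (≥ 80% attenuation on fixtures).
- **Filtering**: zero-phase 3rd-order Butterworth (SOS, forward–backward).
  Configured as a 0.01–0.1 Hz band-pass the filter meets the classical
  contract (gain ≥ 0.9 at 0.05 Hz, ≤ 0.1 at DC and 0.5 Hz).  The
  *pipeline* default applies only the 0.1 Hz low-pass: the
  glucose-coupled trend has its fundamental near 3·10⁻⁴ Hz, so a 0.01 Hz
  high-pass would remove the very signal (and every state-mean
  difference) the downstream analysis measures.  Users analysing
  event-locked activations rather than slow metabolic trends should
  re-enable the high-pass edge.
- **MBLL inversion**: exact 2×2 linear solve per sample; round-trips the
  forward model to <10⁻⁸ μM.
- **CBSI**: with α = std(ΔHbO)/std(ΔHbR), ΔHbO′ = (ΔHbO − α·ΔHbR)/2 and
  ΔHbR′ = −ΔHbO′/α, enforcing corr = −1 exactly; zero-variance channels
  are skipped and flagged.

## Channel screening

Unit of replication: the per-subject, per-window (600 s) mean ΔHbO of a
channel, giving 15 fasting and 90 glucose samples per channel per cohort.
Welch's unequal-variance t-test compares the states.  The default p-value
is the one-sided tail of |t| (`p = sf(|t|)`), the convention that
published per-channel tables in this setting are numerically consistent
with; a two-sided option is exposed.  Channels with p < 0.05 are selected
(no multiplicity correction by default, matching the reference analysis;
Benjamini–Hochberg available).  Under the one-sided-|t| convention the
per-channel null selection rate is 2α, so the expected false-selection
budget on 16 null channels is ≤ 16·α·2 = 1.6.

## λ features

Ten statistics of a channel-averaged HbO window x₁..x_T (μM, step dt):
mean λ1, population std λ2, first-difference mean λ3 and std λ4,
second-difference mean λ5 and std λ6, peak λ7, peak-to-peak λ8, energy
λ9 = Σx²·dt and energy entropy λ10 = −Σx²·ln(x²)·dt with 0·ln 0 = 0.
Population (divide-by-count) denominators are used throughout; integrals
are rectangle sums.  λ10 is applied to the raw squared amplitude, i.e.
not a normalised probability distribution, so it is only
"entropy-monotone in energy" while x² < 1/e; a normalised Shannon-entropy
variant is behind a flag.  Windows are non-overlapping 600 s segments per
state (7 per subject, ~105 pooled windows per cohort), each paired with
the nearest-in-time reference glucose (dropped if none within half a
window).  Channel-averaged analysis is the default; T ≥ 4 is required so
the second differences have a spread.

## DR-PCA

Eigen-decomposition of the training scatter matrix (b = 10, symmetric
`eigh`, descending eigenvalues, largest-magnitude entry of each vector
made positive for reproducibility).  With within-class Π_ICS and
between-class Π_IS scatter (fasting vs glucose labels), each eigenvector
is scored by ξ(C) = CᵀΠ_IS C/(CᵀΠ_ICS C + ridge), ridge =
10⁻¹²·tr(Π_ICS)/b; vectors are re-ordered by non-increasing ξ, ties
broken by descending eigenvalue then index.  Data-null eigenvectors
(eigenvalue ≈ 0, possible when samples < features) get ξ = 0 — their
quadratic forms are 0/0 noise — and so sort last in eigenvalue order.
When Π_IS = 0 the ordering reduces to plain PCA.  Retention is either an
explicit d or the smallest d whose cumulative normalised score (ξ for
DR-PCA, eigenvalues for PCA) reaches 90%.  Projection always centres by
the training mean.  At full dimension DR-PCA and PCA span the same
subspace; they differ only in ordering and truncation, which is what the
adversarial two-class fixture demonstrates (class separation on
low-variance axes: DR-PCA is strictly better at d = 1 and its accuracy is
non-decreasing over the 1–6 component range used in the comparison
table).  With two classes Π_IS has rank 1, so most of the separation
enters through the top-ξ component and later components add the residual
carried by eigenvector misalignment.

## Association and prediction

Per-feature Pearson r is computed in the centred-covariance matrix form
R = S_xy/√(S_xx·S_yy), with a two-sided p from t = r·√(n−2)/√(1−r²);
z-scoring uses the population σ.  Windows from all subjects and both
states are pooled into one n ≈ 105 analysis, the sample-size regime in
which printed p-values of this kind of study are coherent.

Prediction uses nested LOSO: the outer loop holds each subject out once;
within a training fold, features are z-scored by training statistics,
reduced by DR-PCA/PCA fitted on the fold, and the hyperparameter is
chosen by an inner LOSO over the 14 training subjects.  Fixed grids:
KNN k ∈ {1,3,5,7,9}; random forest trees ∈ {100, 300}; RBF-SVM C ∈
{0.1, 1, 10}; gradient-boosted trees depth ∈ {2, 3} (xgboost when
importable, sklearn's GradientBoosting otherwise).  Metrics are pooled
over out-of-fold predictions: RMSE (mmol/L), MARD (%), Pearson r for
glucose regression; fasting-vs-glucose accuracy (%) for the state task
("accuracy" in the component-count comparison is operationalised as this
binary state classification).  A predict-the-training-mean baseline under
the same outer loop anchors the regression metrics.

## Numerical and reproducibility choices

- All randomness descends from one root seed through `SeedSequence`
  substreams (one per subject), so cohorts are bit-identical under the
  same config and stages can be re-run in isolation.
- Serialization uses 17-significant-digit text and round-trip float
  parsing, so write→read→write is byte-identical.
- Degenerate inputs: constant channels prune as infinite-SNR keepers;
  zero-variance series raise (z-score) or are skipped with a flag (CBSI);
  constant feature columns are flagged NaN rather than aborting the
  association table; a constant-reference MARD request raises.
- Problem sizes in the test suite: recovery properties use 20 cohorts at
  the full study design (15 subjects, 21 channels, 70 min at 10 Hz);
  formula oracles use 100 random small inputs each; the DR-PCA fixture
  uses 400 samples per class so that 1-NN accuracy means are stable.

## Known limitations

- The synthetic coupling is linear and instantaneous; real neurovascular
  coupling has dynamics and saturation the generator omits, so reported
  RMSE/MARD values characterise the pipeline under the planted model
  only and are not comparable to clinical CGM accuracy figures.
- The energy-entropy feature's usefulness depends on the amplitude
  regime (see above); on data with window amplitudes above 1 μM its sign
  relationship with glucose can invert.
- With two states the between-class scatter is rank 1; DR-PCA's
  advantage therefore concentrates in the leading components, and it
  cannot out-perform PCA at full dimension by construction.
- Per-channel (rather than channel-averaged) feature extraction is
  available but untuned; group-level averaging before preprocessing is
  not implemented (features and LOSO require per-subject series).
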