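# fnirsglu

Analysis pipeline linking prefrontal-cortex fNIRS signals to blood
glucose.  Functional near-infrared spectroscopy (fNIRS) measures cortical
hemodynamics through dual-wavelength light attenuation; during a
fasting → glucose-load protocol, oxygenated-hemoglobin (HbO) changes on a
subset of prefrontal channels track the glucose excursion.  `fnirsglu`
implements the full computational chain for that experiment — and,
because such datasets are rarely shareable, a seeded synthetic cohort
generator with a known glucose→HbO coupling so every stage can be tested
for parameter recovery.

The package is for researchers in biomedical optics / physiological
signal analysis who want a tested, reproducible reference implementation
of:

1. **Preprocessing** — Homer2-style chain: channel pruning (dRange
   10⁻²–10⁰, SNR ≥ 2), optical density ΔOD = −log₁₀(I/Ī), motion-artifact
   detection, wavelet (DWT + Tukey-fence) artifact correction, zero-phase
   Butterworth filtering, modified Beer–Lambert inversion
   ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ), and
   correlation-based signal improvement (CBSI).
2. **Channel screening** — Welch t-tests of fasting-vs-glucose window
   means per channel, p < 0.05 selection.
3. **λ features** — ten statistics of windowed mean-HbO: mean, std,
   first/second-difference mean and std, peak, peak-to-peak, energy
   Σx²dt and energy entropy −Σx²ln(x²)dt.
4. **DR-PCA** — PCA eigenvectors re-ranked by the Fisher-style ratio
   ξ(C) = CᵀΠ_IS C / CᵀΠ_ICS C of between- to within-class scatter
   (the "decreasing rule"), so low-variance but discriminative directions
   are retained first.
5. **Association & prediction** — matrix-form Pearson r of each feature
   with glucose, and nested leave-one-subject-out (LOSO) evaluation of
   KNN/RF/SVM/gradient-boosting regressors on the projected features,
   reporting RMSE (mmol/L), MARD (%) and Pearson r.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

`examples/` contains one short script per capability.  The end-to-end
one:

```bash
python examples/05_loso_evaluation.py
```

prints (seeded, so exactly reproducible):

```
KNN + PCA   : RMSE 0.722 mmol/L, MARD 9.01%, r 0.725
KNN + DRPCA : RMSE 0.801 mmol/L, MARD 10.01%, r 0.643
mean baseline : RMSE 1.056 mmol/L, MARD 14.01%
```

Reading: on a 15-subject synthetic cohort, the nested-LOSO KNN model
predicts held-out subjects' reference glucose with ~9–10% mean absolute
relative deviation — well below the predict-the-training-mean baseline —
with an out-of-fold correlation of r ≈ 0.6–0.7 against true glucose.
DR-PCA's edge over plain PCA is in *state discrimination at small
component counts* (its ranking criterion is the fasting-vs-glucose
scatter ratio), not in full-dimension regression:
`examples/04_drpca_vs_pca.py` prints the 1-NN accuracy table on an
adversarial two-class dataset, where DR-PCA reaches 0.74 with one
component while PCA sits at chance until its third.
`examples/03_features_association.py` prints the feature–glucose
correlation table (level/energy features λ1, λ7–λ10 positive and
significant; derivative features null), and
`examples/02_preprocess_recovery.py` shows a coupled channel's recovered
HbO correlating at r ≈ 0.81 with the planted glucose trend while an
uncoupled channel sits at r ≈ 0.00.

A thin CLI wraps the same library calls:

```bash
fnirsglu simulate --seed 1 --outdir runs/cohort
fnirsglu evaluate --seed 1 --outdir runs/eval
fnirsglu report --rundir runs/eval
```

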