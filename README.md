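# cellfp

Metabolic fingerprinting of intact cells from 1D ¹H NMR spectra.

Cell suspensions give poorly resolved proton spectra: broad, overlapping
envelopes dominated by sample-inhomogeneity broadening, with a
macromolecular baseline unless a CPMG T₂ filter suppresses it.  Even so,
the pattern of metabolite intensities (lactate, creatine, choline
compounds, fatty acids, glutathione, …) is a reproducible fingerprint of a
cell phenotype.  `cellfp` implements the complete analysis workflow for
classifying such spectra — and a synthetic spectrum generator with full
ground truth, so every stage of the workflow is testable without access to
spectrometer data.

## What is implemented

- **Synthetic in-cell spectra** (`cellfp.synth`): Lorentzian multiplets with
  field-invariant ppm inhomogeneity broadening and Hz-invariant J-splittings
  and natural widths, class-specific log-normal concentration fingerprints,
  CPMG-attenuated macromolecular humps, per-sample dilution, field-dependent
  signal-to-noise, and two-class mixtures; every latent variable is returned
  in a truth table.
- **Preprocessing** (`cellfp.preprocess`): clip to −0.1…8.6 ppm, zero the
  4.6–5.1 ppm water window, integrate uniform 0.04-ppm buckets (217
  features), probabilistic quotient normalization (PQN) against the
  unit-mean median spectrum, and train-only standard scaling.
- **PLS-DA** (`cellfp.plsda`): NIPALS PLS2 on the centered one-hot class
  matrix, written from scratch: weights `W`, loadings `P`, `Q`, mutually
  orthogonal scores `T`, coefficients `B = W(PᵀW)⁻¹Qᵀ`, plus a PCA baseline
  and 95 % confidence ellipses for score plots.
- **Diagnostics** (`cellfp.diagnostics`): VIP scores
  `VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a)`, per-class target-projection
  selectivity ratios, 5-fold jackknife confidence intervals on `B`,
  label-permutation testing of cross-validated macro-F1, and VIP-removal
  sensitivity curves.
- **Classifiers**: an SVM on the PLS-DA latent scores with stochastic
  hyperparameter search and one-vs-one Platt-calibrated, pairwise-coupled
  probabilities (`cellfp.latent_svm`); Boruta all-relevant feature selection
  (shadow features + Bonferroni binomial decision) feeding a tuned random
  forest with Gini ranking (`cellfp.forest`).
- **Evaluation** (`cellfp.evaluate`): macro F1, confusion matrices, top-2
  pair assignment for two-class mixtures, cross-field transfer scoring, and
  Monte-Carlo Shapley attributions with exact local accuracy.
- **Orchestration** (`cellfp.pipeline`, `cellfp.cli`): config-driven
  simulate → preprocess → split → train → diagnose → evaluate runs with a
  single root seed and a JSON report.

## Worked example

```python
import cellfp

design = cellfp.four_class_design(seed=1, n_per_class=30)
spectra, truth = cellfp.simulate_dataset(design)
matrix = cellfp.preprocess(spectra).normalized          # 120 x 217, PQN state
labels = {s: spectra.meta[s].label_str for s in spectra.sample_ids}
train, valid = cellfp.split_train_validation(
    spectra.sample_ids, [labels[s] for s in spectra.sample_ids], 0.7, seed=1)

model = cellfp.PLSDASVMClassifier(n_components=3, seed=1)
model.fit(matrix.rows(train).values, [labels[s] for s in train])
pred = model.predict(matrix.rows(valid).values)
print(cellfp.f1_macro([labels[s] for s in valid], pred))
```

prints `1.0`: on the four-phenotype benchmark (30 samples per class, 70/30
stratified split) the held-out macro F1 of both model families reaches
0.9–1.0, the same regime as classification of real cell-line spectra.  The
`examples/` directory holds one short script per capability (simulation,
preprocessing, diagnostics, mixtures, cross-field transfer, attributions),
each printing the numbers it computes and what they mean.

A thin CLI mirrors the pipeline: `cellfp simulate`, `cellfp preprocess`,
`cellfp run` (see `cellfp --help`).

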