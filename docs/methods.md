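# Methods

## The spectrum model

A synthetic in-cell ¹H spectrum on a descending ppm grid (default 4096
points over −0.5…9.4 ppm) is

    I(δ) = d · [ Σ_m c_m Σ_peaks a_p Σ_k b_k L(δ; δ_p + k·J/ν₀, γ) + w·H(δ) ] + ε

- `L` is a unit-area Lorentzian with HWHM `γ = γ_inhom + w_nat/ν₀`.
  `γ_inhom` (default 0.02 ppm) models susceptibility broadening of packed
  cells, which scales with B₀ and is therefore **constant on the ppm axis**
  across fields; the natural width `w_nat` (Hz) and the scalar coupling `J`
  (Hz) shrink on the ppm axis as the proton frequency `ν₀` (MHz) grows.
  Intact-cell lineshapes are envelope-dominated, so a Lorentzian with the
  inhomogeneity term folded into the HWHM is used rather than a Voigt
  profile; only relative class structure matters downstream.
- Multiplets are first order: `m` lines with binomial weights `b_k`.
  Strong-coupling distortions are not modeled.
- `H` is a sum of broad Lorentzian humps (the mobile macromolecule
  baseline).  Its weight `w` equals the class's `macro_level` for
  excitation-sculpting spectra and `macro_level × 0.05` for CPMG — the T₂
  filter passes ~5 % of slow-tumbling signal.  The attenuation factor is a
  free parameter chosen so CPMG spectra are metabolite-dominated.
- Concentrations `c_m` are log-normal per sample around a class fingerprint
  (`log_mean` per metabolite, default intra-class log-sd 0.2); the dilution
  `d` is log-normal (default log-sd 0.3); ε is white Gaussian noise with
  sd = (max clean signal)/SNR, with SNR defaults 200/120/60 at 950/700/400
  MHz.
- One *biological replicate* draws its latents once and is re-rendered at
  every requested field and experiment with fresh noise, mirroring one
  physical sample measured on several spectrometers.  This makes the
  noise-free, zero-J, zero-natural-width limit exactly field-invariant — a
  property the cross-field tests exploit.

The bundled metabolite library holds textbook shifts/couplings for the
abundant intracellular metabolites plus a deliberately crowded 3.2–4.0 ppm
sugar/amine region; class fingerprints are built from fixed marker panels
(each phenotype up/down-regulates 3–4 metabolites by `separation × shift`
in log-concentration, default separation 1.0).

What the generator does **not** emulate: chemical-exchange and relaxation
effects, pH-dependent shift drift, peak misalignment between samples,
baseline/phase errors, and water-suppression artifacts.  Passing tests
therefore demonstrate the correctness and statistical behavior of the
analysis chain under the stated model, not robustness to those real-data
pathologies (bucketing at 0.04 ppm absorbs small misalignments by design).

## Preprocessing

Fixed order: clip/mask → bucket → PQN → scale.

- Clip to −0.1…8.6 ppm; water window 4.6–5.1 ppm zeroed in place (default)
  so the bucket grid spans the full kept range: `floor(8.7/0.04) = 217`
  buckets, a trailing 0.02-ppm partial bucket being dropped.  The
  alternative `water_buckets="drop"` removes the 12 fully-masked buckets
  (205 features).
- Bucket value: exact trapezoid integral of the linear interpolant over the
  half-open ppm interval (robust to grid density); a grid-point mean is
  available for comparison.
- PQN: reference = per-bucket median over samples, rescaled to unit mean;
  per sample, the dilution estimate is the median of bucket quotients over
  buckets with reference above machine scale and positive sample values,
  and the row is divided by it.  The unit-mean reference makes the output
  invariant to any global positive rescaling of the input matrix; no prior
  total-area normalization is applied.  The median (not mean) quotient is
  used for robustness to class-specific peaks.
- Standard scaling learns means/sds on training rows only; zero-variance
  buckets (e.g. the zeroed water window) pass through as 0 with a logged
  warning.

## PLS-DA

NIPALS PLS2 against the column-centered one-hot indicator: per component,
iterate `w ∝ Xᵀu`, `t = Xw`, `q ∝ Yᵀt`, `u = Yq` until the unit-norm weight
moves by less than 1e-10 (cap 500 iterations; the cap matters only for
near-degenerate noise spectra), then deflate both blocks by the rank-one
fits.  Initialization is deterministic (u = centered Y column of maximal
variance, ties to the lowest index), so fits are reproducible and scores
come out mutually orthogonal by construction.  `SSY_a = ‖t_a‖²‖q_a‖²` is
the per-component Y-variance share used by VIP.  Default 2 components (the
score-plot convention); the benchmarks use K−1 components for K classes.
PCA (by SVD of the centered matrix, deterministic sign convention) provides
the unsupervised baseline with explained-variance ratios.

## Diagnostics

- **VIP**: `VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`; mean
  squared VIP is 1, so `ΣVIP² = p` is asserted on every fit.
- **Selectivity ratio**: target projection `t = X b_k/‖b_k‖`,
  `p_TP = Xᵀt/tᵀt`; `SR_j` = explained over residual squared norm per
  column; a perfectly explained column yields an `+inf` sentinel, capped at
  the largest finite value in exported tables.  SR is invariant to
  rescaling of `b_k`.
- **Jackknife**: stratified 5-fold delete-one-fold refits;
  `SE = sqrt(((m−1)/m) Σ (B_i − B̄)²)`; normal-approximation CI around the
  full-data coefficient; "stable" ⇔ CI excludes zero.
- **Permutation test**: observed = pooled stratified-CV macro F1 with the
  whole pipeline (scaling included) refit per fold; null = the same under
  global label permutation; `p = (1 + #{null ≥ obs})/(1 + n_perm)` (999
  permutations by default).  Under a true null the p-values are uniform;
  the calibration test verifies this by KS across 200 simulated runs.
- **VIP-removal sensitivity**: CV F1 as top-VIP buckets are removed, order
  frozen at the baseline ranking by default (recomputation optional).

## Classifiers

- **PLSDA+SVM**: scaling → PLS-DA projection → SVM on the scores.  A seeded
  random search (default 60 draws; kernels linear/rbf, C log-uniform on
  1e-2…1e3, gamma log-uniform on 1e-3…1e1) is scored by stratified-CV macro
  F1; first best wins on ties.  Probabilities use the classic one-vs-one
  construction: one binary SVC per class pair, Platt sigmoid fitted to
  cross-validated decision values with regularized targets, pairwise
  probabilities coupled by the Wu–Lin–Weng iteration.  This keeps
  probabilities monotone in each pairwise decision value, sums rows to one,
  and behaves symmetrically at class-boundary midpoints, which matters for
  top-2 mixture assignment.
- **Boruta+RFC**: scaling → Boruta → tuned forest.  Boruta appends a
  column-permuted shadow copy of the whole matrix each iteration, fits a
  fresh 100-tree forest (depth 5), and scores a hit when a real feature
  beats the chosen percentile (default 100 = max) of shadow importances;
  after `max_iter` iterations a two-sided binomial test against
  Bin(n, 1/2) with Bonferroni correction over features yields
  confirmed/rejected/tentative.  Tentative features are excluded downstream
  by default.  The forest search (15 draws over tree count, depth, minimum
  impurity decrease, features-per-split) is scored by stratified-CV macro
  F1; CV ties — common on separable data — are broken toward the richer
  ensemble (more trees, then deeper, then laxer impurity threshold), whose
  vote fractions resolve probabilities more finely.

## Evaluation

Macro-averaged F1 over the classes present in the truth (imbalance-
sensitive; a weighted variant would hide minority-class failures).
Mixtures are assigned as the unordered pair of the two largest predicted
pure-class probabilities, exact ties broken by class order and logged.
Cross-field transfer trains one model on the 950-MHz training split and
scores held-out replicates at each field with the training-field scaler.
Monte-Carlo Shapley uses permutation sampling with one random background
row per permutation, which makes local accuracy (base + Σφ = prediction)
exact by construction; per-feature Monte-Carlo standard errors are
reported, and a full-enumeration oracle exists for small feature counts.

## Benchmark designs and problem sizes

- *Four-class*: 4 phenotypes × 30 samples at 950 MHz, 70/30 stratified
  split, K−1 = 3 components.
- *Mixtures*: 3 phenotypes × 30 pure samples plus 3 × 10 mixtures with
  fractions uniform on 0.2–0.8 (the mixing protocol is otherwise
  unquantified).  One class carries log-sd 0.45 (vs 0.2): real cell panels
  contain one high-variability line whose inflated probability region
  degrades top-2 assignment from latent-space SVM probabilities far more
  than forest vote fractions — the benchmark reproduces that ordering, and
  both families' misassignments concentrate on pairs involving that class.
- *Cross-field*: 3 phenotypes × 20 replicates rendered at 400/700/950 MHz
  with matched latents; training at 950 MHz only.
- Calibration simulations use deliberately small matrices (40 × 20) and a
  60-iteration NIPALS cap — under a pure-noise null the power iteration has
  nothing to converge to, and the permutation p-value is valid for any
  fixed pipeline.  Boruta runs use 50 iterations in the benchmarks (default
  100), which the binomial decision rule comfortably supports.

## Numerical choices and degenerate inputs

Bucket edges are half-open `[upper, lower)` on the descending axis; a
partial trailing bucket is dropped.  PQN refuses an all-zero reference or a
sample with no usable buckets.  NIPALS refuses single-class input,
out-of-range component counts, and a fully deflated X.  SVM probability
coupling clips pairwise probabilities to [1e-7, 1−1e-7] to keep the
coupling system solvable.  Argmax ties anywhere are broken by lexicographic
class order.  All stochastic procedures take explicit seeds; dataset
simulation is bit-reproducible given the design seed.

## Known limitations

The generator's idealizations (above) are the main one.  Boruta status
labels for *noise* features can flip between rejected and tentative under
column reordering (per-column shadow streams are positional); confirmed
decisions on real signal are stable.  Boruta's binomial decision rule
assumes the per-iteration hit indicator is an independent fair coin under
the null; in reality a noise feature's chance in-sample correlation with
the labels is fixed across iterations while the shadows redraw theirs, so
the feature with the largest chance correlation in a given dataset can
beat the shadow maximum persistently.  Measured over repeated pure-noise
datasets (n = 60–120, p = 30, 50 iterations) about one dataset in ten
confirms a single such feature — a false positive relative to the
population, though the feature genuinely separates the classes within
that sample.  Interpret confirmations on small cohorts accordingly.  The jackknife uses a normal
approximation with m = 5 replicates — its CIs are indicative, not exact.
Platt scaling on perfectly separable pairs relies on the regularized
targets to stay finite; probabilities saturate near (but never at) 0/1.
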