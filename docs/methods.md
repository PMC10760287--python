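# Methods

`nnprs` studies whether small dense neural networks can (i) reproduce
human-programmed polygenic risk scores (PRSs) that contain pairwise
interaction terms, (ii) compensate for missing input SNPs, and (iii) be
shipped as plain-text matrices with a forward pass that needs nothing but
matrix arithmetic.  This note records the models, the synthetic study
conditions, and the numerical choices behind them.

## The score model

A PRS over SNPs `i = 1..p` with effect-allele counts `g_i ∈ [0, 2]` is

    score = c + Σ_i w_i g_i + Σ_t contribution_t

where each interaction term `t` references two distinct SNPs and is either

* **product**: `w_t · g_a · g_b`, or
* **state_indicator**: `w_t · 1{g_a = s_a ∧ g_b = s_b}` with required
  genotype states `s ∈ {0, 1, 2}` — the form taken by HLA interaction
  scores, where specific genotype combinations (e.g. the DR3/DR4
  heterozygote) carry their own risk weight.

Imputed dosages are fractional; a state indicator matches after rounding
each dosage to the nearest integer genotype, consistent with treating
{0, 1, 2} as the underlying SNP states.  The intercept defaults to 0.
Missing genotype entries are set to 0 before scoring or training.

The published T1D/Celiac weight tables are not redistributed here.  The
four templates (`T1D10-like`, `T1D30-like`, `T1D67-like`, `CD42-like`) are
structural stand-ins: correct SNP counts (10/30/67/42), one interaction
term for the two small T1D scores, and a set of state-indicator terms
(10 and 6 respectively) confined to a designated correlated block of 14
(T1D67-like) or 10 (CD42-like) SNPs emulating HLA-DQ.  Additive weights are
drawn U(0.02, 0.6), interaction weights U(1.0, 3.5) (large relative to
single-SNP effects, as HLA terms are), states mostly heterozygous, all
reproducibly from a seed.  Real published weights can be supplied through
the tab-delimited weight-file format.

## Synthetic cohorts

The original experiments used ~487k imputed biobank samples; the simulator
emulates the features of those data that the experiments actually exercise
and nothing more.

* **Genotypes.** Each genotype is the sum of two independent haplotypes.
  Per haplotype, a latent standard-normal vector has equicorrelation `rho`
  within a block (identity elsewhere); an allele is carried when its latent
  coordinate falls below the Φ⁻¹(MAF) quantile.  This Gaussian-copula
  threshold model gives exact marginal allele frequencies and a single
  controllable LD knob.  Defaults: MAF ~ U(0.1, 0.5) per SNP, `rho = 0.9`
  for the template block — tight enough that block SNPs are mutually
  predictable, the mechanism under study.  Not emulated: recombination-map
  LD decay, population structure, imputation uncertainty (simulated
  genotypes are integer counts), allele-frequency spectra.  Passing tests
  therefore show the *mechanisms* (interaction learning, LD-driven
  imputation, information limits) transfer to data with these statistical
  features, not that real-biobank metric values are reproduced.
* **Disease labels.** P(case | score) = logistic(α + β·z) with `z` the
  standardized PRS; α is solved by bisection to hit a target prevalence
  (tolerance 1e-4).  Defaults β = 1.5, prevalence 1%, which yield a
  case/population AUC around 0.85 for a well-recreated score — the regime
  of the published T1D/Celiac discrimination values.
* **Splits.** All case samples are held out into case test sets (a sample
  with two diagnoses appears in both); the remaining `m` samples split
  into floor(0.70·m) training, floor(0.15·m) validation, remainder test.
  This floor/floor/remainder convention is the unique rounding that
  reproduces all three published biobank split-count triples
  (340,915/73,053/73,054; 340,357/72,933/72,935; 340,092/72,876/72,878).

## Models and training

* **Standard MLP**: hidden layers 50/30/20, ReLU, linear output neuron
  (one per score for the multi-predictor variant), trained on minibatch MSE
  with Adam (β = 0.9/0.999, ε = 1e-8), learning rate 1e-4, batch size 5.
* **Autoencoder**: retained SNPs → two ReLU hidden layers of `n_full`
  neurons → `n_full` outputs through sigmoid×2, so predictions lie in
  (0, 2); target is the intact SNP vector; learning rate 5e-5, batch 5.
  **AE-MLP** composes the AE's reconstruction with the full-SNP MLP.
* **Linear predictor**: least squares with intercept (reweighting
  baseline); optionally elastic net `‖y − Xw‖² + λ1‖w‖₁ + λ2‖w‖²` over a
  validation-selected grid, default λ ∈ {0} ∪ 7 log-spaced points in
  [1e-4, 1].  The penalised path runs through scikit-learn's coordinate
  descent under the exact (λ1, λ2) → (alpha, l1_ratio) reparameterisation;
  λ1 = λ2 = 0 uses a direct `lstsq` solve (minimum-norm, with a warning,
  when rank-deficient).
* **Implementation.** Forward, backprop and Adam are written directly in
  numpy: the models are four small dense layers, and keeping them as
  explicit (matrix, bias) lists is what makes the text export and the
  matrix-arithmetic forward pass exact by construction rather than an
  after-the-fact conversion.  Initialisation is uniform fan-in
  (U(±1/√fan_in)) for weights and biases, seeded; training is bit-for-bit
  reproducible from the seed.
* **Stopping.** Epoch counts are not part of the published setup.  Default:
  validation MSE evaluated every 2,000 iterations, early stop after 3
  evaluations without improvement, cap 30 epochs, and the parameters with
  the lowest validation loss seen (including the initial state) are
  restored — so a returned model is never worse on validation than its
  initialisation.  The study recipes in `nnprs.studies` raise the cap to 80
  epochs with patience 15: at desk-scale cohort sizes the 67-SNP task is
  still improving at 30 epochs, and the larger cap reaches its convergence
  plateau (the 10-SNP task plateaus much earlier; the shared cap is
  harmless there since early stopping ends training).
* **No input scaling**: raw counts in [0, 2] feed the network directly.
* The output neuron is linear everywhere.  The export format nonetheless
  records an activation tag per layer, so a bundle is unambiguous about
  what its final layer applies.

## Missing-SNP experiments

A removal permutation (optionally restricted to a block) defines nested
retained-SNP sets, one SNP removed per step.  At each evaluated step —
default every 5th step plus endpoints — the linear predictor, MLP and AE
are retrained from scratch on the retained SNPs with the *full*-SNP PRS as
the label (no warm starts, matching independent per-subset training), and
compared against the PRS evaluated without the removed SNPs: removed
dosages contribute nothing additively and any interaction term touching a
removed SNP contributes zero.  Metrics are test-split Spearman and RMSE
against the full-SNP score and case-vs-population AUC, with 95% percentile
bootstrap CIs (default 1,000 resamples; AUC resamples cases and non-cases
independently to preserve class sizes; method comparisons share resample
indices so deltas are paired).

Leave-one-SNP-out predictability trains one AE per SNP on the remaining
SNPs and reports the test-split Pearson correlation for the held-out SNP; a
constant column is reported as r = 0 with a degeneracy flag.  Block SNPs
come out highly predictable and independent SNPs unpredictable, which is
exactly when the networks do and do not beat the reduced PRS.

## Variant catalogue

The limitation study fixes one retained-SNP subset and trains: the standard
MLP (`Orig`); a learning-rate × batch-size grid (default
{1e-3, 1e-4, 1e-5} × {5, 20, 100}, winner by validation MSE — the published
study searched a grid without listing its values, so the grid brackets the
default hyperparameters); capacity variants with hidden layers (50,30,20),
(200,), (55,50,40,30,25,15,5), (200,160,120,90,70,50,10); a skip model
whose last hidden layer output is concatenated with the raw input
(unweighted passthrough, final matrix 20+p wide); and a pairwise model
whose input is expanded to `p + p(p−1)/2` features by appending all
products `x_i x_j`, i < j, in lexicographic order.  Ensembling averages
predictions elementwise.  The catalogue converging in fidelity *and* in
per-sample predictions is the evidence that inputs, not models, limit
performance.

## Text export

A bundle is line-oriented UTF-8: a version header, a `[SNPS]` section with
the ordered (snp_id, effect_allele) pairs, an optional `[OUTPUTS]` section
naming output columns, then one `[LAYER k rows cols activation]` block per
layer holding the weight matrix (one row per line) and the bias row.
Values use 17 significant digits, which round-trips IEEE doubles exactly;
the loader validates header-vs-body shapes and the dimension chain.  The
forward pass is `v_l = act_l(v_{l−1} M_l + b_l)`.  A skip layer carries a
`concat_input` flag meaning its input is the previous output concatenated
with the raw input.  `scripts/eval_bundle_minimal.py` — pure Python, no
shared code, no numpy — re-implements the evaluation from the format
description and agrees with the package to 1e-8, which is the portability
claim made testable.

## Study sizes

Desk-scale defaults, chosen once as realistic analogues of the original
regime given the published finding that performance degrades only modestly
above a few thousand training samples: PRS recreation at n = 100,000
(67-SNP) and 50,000 (10-SNP); missing-SNP and variant studies at
n = 20,000; reduced bootstrap counts (100–200) in examples and harness
tests.  Default seeds make every figure-like output reproducible end to
end.

## Known limitations

* Equicorrelated single-block LD is a caricature of real haplotype
  structure; predictability inside the block is near-uniform rather than
  the mixed HLA/HLA-DQ/non-HLA spectrum of real scores.
* Training cost scales linearly with batch count: batch size 5 on very
  large cohorts is slow in pure numpy; the study recipes cap cohort sizes
  instead of batching up, to keep the published hyperparameters.
* The elastic-net grid search refits the unpenalised model for λ = 0
  rather than warm-starting along a path.
* Case labels depend on the PRS only through the logistic model; real
  diagnoses carry non-genetic risk the simulator does not model.
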