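# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the design decisions behind `bfreg`, in the order the pipeline
runs.

## Synthetic cohorts

`gen_cohort` draws log-normal expression: per-gene baselines ~ N(5, 1) on
the log2 scale with within-group noise SD 1.0 (log2 units).  Differential
genes receive a fixed tumor-group shift (default +2 log2 units).  Survival
for tumor samples follows an exponential proportional-hazards model: the
linear predictor is Σ_g β_g z_g over per-gene standardized log2 expression,
with baseline hazard 0.02 events/month, so median event times sit at a few
dozen months for an average patient.  Planted prognostic coefficients
default to β = 2.5 per module gene — deliberately strong, because the
cohort exists to test whether the learning machinery can find a signal that
is unambiguously there.  Censoring is independent: C ~ Uniform(0, W) with W
calibrated by root-finding on the realized event times so that P(C < T)
equals the stated rate (default 0.2).  Every generator takes a single
`numpy` seed and touches no global state, so outputs are bit-reproducible.

What the generator does *not* emulate: array platform effects, batch
structure, gene–gene expression correlation beyond the planted module,
non-proportional hazards, or informative censoring.  Green tests therefore
certify the estimators and the learning machinery under a well-specified
proportional-hazards world, not robustness to real TCGA messiness.

`gen_hierarchy` builds random intra-level graphs at edge density 0.08 and
plants each functional module as a ring-connected gene set mapping to a
dedicated protein block that shares one dedicated pathway, giving the
module a clean multi-level route to the outcome node.  `gen_drug_panel`
splits one planted module between the two drugs of each planted synergistic
pair; all other drugs target genes outside modules.  `gen_dose_response`
produces exact median-effect curves (optionally with Gaussian noise on the
logit(fa) scale, clipped to (1e-6, 1−1e-6)); combination points are built
on the Loewe-additive isobole at chosen effect levels and scaled by the
interaction factor κ, which makes the true combination index exactly κ.
`gen_dilution` draws Binomial(wells, 1 − e^{−f·dose}) well counts;
`gen_metabolites` draws log-normal intensities and shifts the planted
pathway's metabolites in the treatment-combination group.

## Cohort screen

Differential expression is a per-gene Welch t-test on log2 intensities with
Benjamini–Hochberg adjustment; the default thresholds are |log2FC| > 1 and
adjusted p < 0.05, both configurable.  Zero-variance genes get p = 1 and a
flag rather than an error.

The Cox model maximizes the Breslow partial likelihood by Newton–Raphson
with step-halving, so the log partial likelihood never decreases across
iterations; convergence is max |score| < 1e-8 or 100 iterations.  Standard
errors come from the observed information; intervals are Wald.  Monotone
likelihood (a coefficient escaping to ±∞ under perfect separation) is
detected by a |β| > 15 cap and flagged.  Ties use the Breslow
approximation, consistent with the training loss.  Stepwise selection is
greedy backward (forward available) on AIC = 2k − 2·logPL, with equal-AIC
ties resolved toward the smaller model and candidates visited in sorted-id
order so the search is deterministic.  Risk stratification splits at the
median score via ordinal ranks (group sizes differ by at most one, ties
broken by sample order); Kaplan–Meier curves and the log-rank test come
from lifelines, cross-checked in tests against hand computation.

## The hierarchical survival network

Topology is exactly the biological hierarchy: binary adjacency A^l per
level, binary map M^l between adjacent levels, one survival node.  Design
choices where the architecture was genuinely open:

- **Embedding**: H_i^0 = x_i·e_i with a learned per-node direction e_i.
  This preserves zero (x = 0 ⇒ H = 0) and homogeneity, and keeps toy
  forward passes hand-checkable.
- **Messages/update**: message(H_i, H_j) = w_msg·H_j with a per-level
  scalar; update is a single σ layer over w_self·H_i plus the aggregated
  messages.  One round per level by default.
- **Cross-level weights**: one free weight per (target, source) node pair,
  shared across embedding channels, so the elementwise mask M ⊙ W is
  literal and masked positions are provably inert (a unit test perturbs a
  masked weight and asserts bit-identical output).
- **Learnable adjacency**: a two-layer perceptron (hidden width 8, tanh) on
  concatenated pair embeddings produces β_ij; the effective weight is β_ij
  on known edges and 0.005·β_ij on unknown ones.  Enabled at the gene level
  only by default.
- **Readout**: learned linear map from the survival-node embedding to a
  scalar risk.
- **Activation**: `BFRegNN` defaults to the logistic σ.  The
  *training-facing* default (`TrainConfig`) is the exposed half-identity /
  half-logistic mix: a pure logistic chain attenuates the input signal by
  ≤ 1/4 per layer and can saturate into a regime where validation loss
  never improves; the mix keeps a linear path open while retaining the
  nonlinearity.
- **Width and initialization**: `TrainConfig` defaults to embedding width
  d = 8 and initialization scale 0.05 for embeddings and cross-level
  weights (readout 0.01).  Rationale: Adam moves each parameter by at most
  ~lr per step, so over a training run the learned component can dominate
  only if the random initialization is comparably small; and at these
  sample sizes a narrower embedding lowers the stochastic-optimization
  noise floor without losing expressiveness (each gene's effective
  coefficient is carried by its own cross-level weight, so per-gene linear
  functions remain representable at any width).  Both were selected by
  validating held-out concordance across several seeds on the default
  planted cohort.

Training minimizes the Cox loss over minibatches with risk sets computed
within each batch (full-cohort risk-set mode is available by flag for
exactness checks); the loss is stabilized by a max-shift inside the
log-sum-exp, making it exactly invariant to adding a constant to all
scores.  The 80/20 split is a seeded shuffle; early stopping watches the
full validation loss with patience 10, and the parameters from the best
validation epoch are returned.  An optional Polyak/EMA parameter average
exists but is off by default (it did not help at these conditions).
Divergence (non-finite loss) aborts with diagnostics.

**Scaled schedules.**  The reference optimizer schedule is 200 epochs at
learning rate 1e-4.  `TrainConfig.scaled_to(max_epochs=50)` shortens the
run while preserving the total optimization length by raising the learning
rate in proportion (50 epochs at 4e-4): simply truncating to 50 epochs at
1e-4 traverses only a quarter of the reference schedule's parameter
distance and undertrains.  The default study (n = 500 tumor samples, one
planted 10-gene module, seed 42, scaled 50-epoch run) reaches held-out
c-index ≈ 0.94, against a ceiling of ≈ 0.95 for the true linear predictor
on the same split.

Problem sizes used throughout the shipped analyses and tests — 50 genes,
30 proteins, 8 pathways, 500 tumor samples — are the package's desk-scale
defaults: large enough for the planted module to dominate sampling noise,
small enough that a full training run completes in well under a minute on
one CPU.

Integrated gradients attribute the risk score to gene inputs along the
straight path from a baseline (default zero): IG_g = (x_g − x0_g) ·
mean_k ∂F/∂x_g at the k/steps interpolants.  Completeness (Σ IG →
F(x) − F(x0)) is tested at 512 steps to 1e-3.

## Drug-pair scoring and the screen

A drug multiplies each target gene's expression by (1 − inhibition),
default full inhibition; a pair acts on the union of target sets, so
overlapping targets are inhibited once.  The synergy score of a pair is the
mean over evaluation samples of risk(untreated) − risk(treated); ranking is
by descending score with lexicographic tie-break on the pair id, and
ceil(0.30·n) pairs are retained.  The tie rule makes the retained set
invariant to input order.

## Median-effect analysis

The median-effect equation fa/(1−fa) = (D/Dm)^m is fitted by ordinary least
squares on log10(fa/(1−fa)) vs log10 D; points with fa ∈ {0, 1} are
excluded with a warning because the transform is undefined there.  Dx
inversion is exact: Dx = Dm·(fa/(1−fa))^{1/m}.  The combination index uses
the two-term (mutually exclusive) form CI = d1/DxA + d2/DxB, the
conventional reported CI; the three-term variant is not implemented.
Additivity is declared within 1e-9 of CI = 1, since exact equality is
measure-zero.  Percent-viability inputs convert as fa = 1 − v/100.

## Downstream assays

Limiting dilution fits the single-hit Poisson model P(negative) =
exp(−f·dose) as a complementary log-log binomial regression with log-dose
offset (statsmodels GLM); the intercept is log f, with a Wald 95% interval
on log f by default and a profile-likelihood interval by flag.  All-positive
plates leave f unbounded (error); all-negative plates return f̂ = 0 with
only an upper bound, from the exact likelihood of zero positives.  TGI uses
group means: (1 − mean treated / mean control)·100.  Tumor volume is
length·width²/2.  Relative expression is 2^−ΔΔCt with group-mean ΔCt;
per-sample fold changes are also emitted for dispersion reporting.

## Metabolomics pathway logic

Differential metabolites use the Welch t-test on log2 intensities with the
conventional joint filter p < 0.05 (raw p by default — adjusted mode behind
a flag) and |log2FC| > 1; both conditions are required.  Pathway
over-representation is the one-sided hypergeometric tail with the
background restricted to measured metabolites; ranking is by ascending p
with alphabetical tie-break, and the top 25 pathways per comparison are
kept.  Per-context common sets are exact intersections (case-insensitive
after trimming), and the cross-context core set is the intersection of the
two common sets.  With fewer than 25 enrichable pathways in a library the
top-25 rule keeps never-enriched members too; discrimination then comes
from the ranks, as the shipped analysis prints.

## Known limitations

- The survival generator is exponential-PH with independent censoring;
  estimator behavior under misspecification is untested.
- Minibatch Cox training optimizes within-batch partial likelihoods, a
  noisier objective than the full likelihood; a directly fitted linear Cox
  model remains slightly better on the default cohort (≈ 0.95 vs ≈ 0.94
  held-out c-index).
- Validation loss and validation concordance can disagree late in training
  (the loss rewards confident margins as score scale grows); early stopping
  follows the loss, as specified.
- The learnable adjacency leaks a small α-weighted signal between
  unconnected genes by construction, so "no path to survival" guarantees
  exact invariance only with the learnable adjacency disabled.
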