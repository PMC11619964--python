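# Methods

This note documents the models, numerical choices and limitations of the
`moals` package: a multi-omics pipeline for ALS-style cohorts that selects
pathway-associated genes from expression profiles, builds rare-variant
gene burdens, and trains a multi-task variational-autoencoder model for
disease classification, onset-age regression and discrete-time survival.

## Pathway-level gene selection

Genes (not samples) are the clustered observations: each gene's feature
vector is its expression across samples, standardized per gene to zero
mean and unit variance so Euclidean distance compares profile *shape*
rather than absolute abundance. Fuzzy k-means assigns soft memberships

    u_ij = 1 / Σ_k (‖x_i − v_j‖ / ‖x_i − v_k‖)^(2/(m−1))

and updates centroids by the fuzzy-weighted mean
v_j = Σ_i u_ij^m x_i / Σ_i u_ij^m, alternating until the maximum centroid
displacement falls below `tol` (default 1e-5, `max_iter` 300). The
fuzziness exponent defaults to the field-standard m = 2. A point
coincident with one or more centroids receives membership 1 split equally
among the coincident centroids. The fuzzy objective
J = Σ_ij u_ij^m ‖x_i − v_j‖² is recorded each iteration and is
non-increasing by construction of the alternating minimization. An
infinite tolerance stops after one iteration without certifying
convergence. Initialization draws `n_clusters` distinct data points
(seeded); cluster counts of 6–12 are the typical scan range at genome
scale.

Each cluster is then tested for enrichment in every gene set of a GMT
collection with a one-sided hypergeometric tail (overlap k of a set of
size K in a cluster of size n drawn from a background of N genes),
Benjamini–Hochberg-corrected jointly across all cluster × set tests. The
selected gene list is the union of genes assigned (argmax membership) to
any cluster whose adjusted p-value falls below the FDR cutoff (default
0.05) for at least one target set. This is a deliberately local,
offline replacement for web-service enrichment tools; combined scores and
odds ratios are out of scope.

## Rare-variant prioritization and gene burden

VEP-annotated variants (VCF with CSQ-style annotation, or a flat TSV
dialect) are filtered to records that are on a canonical transcript,
carry a recognised gene symbol, and have population allele frequency
below 0.01 **or absent** — absence from reference populations is
evidence of rarity and is never imputed to zero. Surviving records are
scored by the most severe of their consequence terms under a
three-tier map: frameshift, stop-gained and transcript-ablation score 5;
stop-lost, start-lost and transcript-amplification score 3; splice donor
and acceptor variants score 2; everything else scores 0 and is excluded.
The tier-to-consequence pairing follows the listed order of the
prioritized classes and is fully config-overridable, since published
descriptions of such schemes rarely pin the exact assignment.

The burden of gene g in sample s is Σ score × allele-count over that
gene's qualifying records (`weighted` mode, default) or the plain
allele-count sum over positively scored records (`count` mode). Burden is
additive over record partitions and reduces to the count mode when all
scores are 1; genes with an all-zero column are dropped.

## Deep embedding

All omics blocks are min-max scaled per feature into [0,1] on training
samples only (unseen values clipped; constant features map to 0.5, the
cross-entropy-neutral midpoint), concatenated, and encoded by a fully
connected ReLU network (default hidden widths 512/256) into a Gaussian
posterior N(μ(x), diag(σ(x)²)), σ = exp(½ logvar) for strict positivity.
Sampling uses the reparameterization z = μ + σ⊙ε, ε ~ N(0, I). A
mirrored decoder produces logits whose sigmoid gives the reconstruction.

The embedding loss is (1/M) Σ_j BCE(x_j, x_j′) + KL(N(μ,σ) ‖ N(0,I)),
with M omics blocks and the exact closed-form Gaussian KL
½ Σ_d (μ_d² + σ_d² − 1 − ln σ_d²), batch-averaged. Each block's BCE is
the Bernoulli negative log-likelihood **summed over the block's features**
and averaged over the batch. The reduction matters: the variational
bound's reconstruction term is a log-likelihood over all dimensions, and
an element-averaged BCE (a 1/d smaller gradient) is dominated by the KL
and provably drives the posterior to collapse (we observed latent μ with
standard deviation ~3e-4 and chance-level downstream performance under
element averaging at realistic widths). `embedding_loss` exposes both
reductions; training uses the sum.

Two further safeguards: the KL weight is annealed linearly from 0 to 1
over the first half of the unsupervised epochs (the final objective is
unchanged), and the σ link guards only against overflow — earlier
experiments with a hard logvar clip that masked gradients at the boundary
trapped saturated units permanently and are the reason no such clip
exists.

## Downstream heads

All heads are small ReLU MLPs (default one hidden layer of 64) reading
the posterior mean μ; reconstruction uses the sampled z, prediction is
deterministic. Classification uses softmax cross-entropy with optional
inverse-frequency class weights (off by default) for imbalanced cohorts.
Regression uses mean squared error on an internally standardized onset
age (stored mean/sd restore the year scale at prediction); R² and
rank-based quantities are unaffected by this linear rescaling.

Survival uses multi-task logistic regression (MTLR). The time axis is cut
into m intervals (default 10) with boundaries at empirical quantiles of
the observed event times (`uniform` available), t_0 = 0 and t_m just
above the largest observed time; duplicate quantile boundaries collapse
with a warning, shrinking m. Each subject's outcome becomes a monotone
0/1 vector switching from 0 to 1 in the event's interval. With interval
scores y′ ∈ R^m, the probability of the configuration switching at s is a
softmax over the suffix sums A_s = Σ_{i=s}^m y′_i (A_{m+1} = 0 is the
no-event-in-grid configuration), evaluated with a log-sum-exp guard.
Observed events contribute −log P of their configuration; censored
subjects contribute the marginal −log Σ over all configurations with
switch index at or after the censoring interval — the standard MTLR
censoring treatment, since ignoring censored subjects would bias the
head. Note that the configuration probabilities are invariant to a
uniform shift of the A_s but **not** to a uniform shift of the raw
interval scores (which adds (m+1−s)c to configuration s and moves mass
toward earlier events).

The survival curve is S(t_i) = Σ_{s>i} P(s); the risk score is the sum of
discrete hazards r = Σ_i (S(t_{i−1}) − S(t_i))/S(t_{i−1}) with S(t_0)=1
and h_i pinned to 1 once the survival mass is exhausted. Higher risk
means an earlier expected event.

## Three-stage training and GradNorm

Stage 1 trains the autoencoder alone on the embedding loss (default 50
epochs). Stage 2 freezes every embedding parameter — verified bitwise in
tests — and trains the heads on L_down = (1/K) Σ_k W_k L_k (default 100
epochs). Stage 3 fine-tunes everything on L_embed + L_down (unit
weighting between the two totals; default 50 epochs) while GradNorm
re-balances the task weights each iteration: with G_k the norm of the
gradient of W_k L_k at the μ-producing (last encoding) layer, r_k the
relative inverse training rate (current/initial loss, normalized across
tasks), the weight update descends L_grad = Σ_k |G_k − Ḡ r_k^α| treating
the target Ḡ r_k^α as constant, then clips weights positive and
renormalizes to Σ W_k = K. α defaults to 1.5; GradNorm runs in stage 3
only (config-switchable). The optimizer is Adam throughout (lr 1e-3,
batch 32); an alternate schedule (lr 0.02, decay 2e-4, 200 epochs) is
config-expressible but not the default. Samples missing an onset age or
survival time are masked out of that task's loss, not dropped from the
batch. A non-finite loss aborts with stage/epoch context.

Since no deep-learning framework is part of the dependency set, the
forward and backward passes (affine/ReLU layers, the VAE step, all task
losses and the GradNorm probe) are written out by hand in numpy and
verified against central finite differences in the test suite.

## Synthetic cohorts

The generator emulates the statistical skeleton the model assumes, not
any real dataset. A latent matrix Z ∈ R^{n×q} (default q = 4, standard
normal) drives everything:

* **Expression** — genes split into co-expression blocks, each loading on
  one factor with magnitude `block_effect_size` (jittered ±20%, same sign
  within a block so a block maps onto one recoverable cluster);
  expression = exp(ZΛ + ε), ε ~ N(0, noise_sd). Log-normal positive
  abundances, not counts: the model consumes normalized abundances.
* **Label** — cases are drawn *without replacement* with probability
  proportional to exp(label_logit_scale · z_1) via Gumbel-top-k, so the
  requested case/control split (default 593/79 of 672) is hit exactly
  while preserving the latent-label association.
* **Burden** — per-gene Poisson counts at `burden_base_rate` (0.05),
  multiplied by `burden_signal_rate` (6) for the designated signal genes
  (default 50) in cases only.
* **Onset age** — 55 + 5·z_2 + N(0, 2.5²) years; with these defaults the
  attainable R² is 25/31.25 = 0.8.
* **Survival** — exponential event times with log-hazard
  log(1/900) + 1.5·z_1 per day; censoring is an independent uniform time
  whose upper limit is calibrated by bisection so the expected censored
  fraction matches the target (default 0.3). Random censoring matches the
  IPCW estimator's assumption.

One shared factor (z_1) drives label, burden enrichment and hazard, so
classification and survival performance have a common, tunable ceiling;
onset age is deliberately on a separate factor so the regression head
must extract a second direction. Setting all effect sizes to zero yields
a null cohort whose features carry no outcome information.

What the generator does **not** emulate: count noise (negative binomial
overdispersion), linkage structure among variants, batch effects,
covariate-dependent censoring, and correlated missingness. Passing tests
therefore demonstrate correct recovery of the planted structure, not
performance on real sequencing data.

## Evaluation

Stratified k-fold (default 5) keeps class proportions within one sample
per fold; scalers and the time grid are learned inside each training
fold. Classification reports accuracy, precision, recall, F1 and ROC-AUC
(positive class = case); regression reports RMSE, MAE, MedAE, R².
Survival uses Harrell's C over censoring-comparable pairs (earlier time
must carry an observed event; risk ties count ½) and the integrated Brier
score with inverse-probability-of-censoring weights from a Kaplan–Meier
estimate of the censoring distribution, trapezoid-integrated over the
grid and normalized by the time span (truncated with a warning if the
censoring survival reaches zero). Across-fold 95% confidence intervals
use the t distribution on fold metrics; Cohen's d on predicted case
probabilities uses the pooled-SD denominator. Both survival metrics are
hand-implemented to these exact conventions and cross-checked in the test
suite against lifelines and scikit-survival.

## Benchmark problem sizes

The end-to-end recovery benchmark (`moals.benchmarks`) uses 600 samples
(500 cases / 100 controls), 500 expression genes in 4 blocks, 100 burden
genes with 50 signal genes, and a reduced network (latent 32, hidden
128/64, head hidden 32) so a full 5-fold run completes in about a minute
on one CPU; epoch counts (50/100/50) and optimizer settings are the
standard schedule. The null benchmark re-runs matched zero-effect cohorts
over 10 seeds with 3 folds and shortened epochs (10/20/10) — no amount of
training can manufacture signal in a null cohort, so only the collapse to
the majority rate and C ≈ 0.5 is at stake. Gene selection is bypassed for
null cohorts (no cluster can be enriched by construction); the model
trains on the full feature set.

## Known limitations

* The full-size architecture (latent 128, hidden 512/256) is supported
  but slow in pure numpy; the benchmarks use the reduced widths above.
* The MTLR head shares one time grid across folds of equal data but
  re-derives it per training fold; very heavy ties can shrink m.
* The enrichment step assumes the background contains every clustered
  gene and treats gene sets as unweighted memberships.
* Checkpoints store architecture + parameters + scaler state; optimizer
  state is not serialized, so training cannot be resumed mid-stage.
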