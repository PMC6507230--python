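# Methods

## Overview

`regimenet` implements a discretization-first workflow for integrating
tumor expression profiles with mutation and copy-number data. The chain
is: (1) each gene's cross-sample expression distribution is modeled as
a univariate Gaussian mixture and every sample is assigned to a mixture
component ("expression regime"); (2) pairs of discrete events — regimes,
mutations, copy-number states, or sample subgroups — are scored with an
exact one-sided binomial co-occurrence test; (3) binary regimes are
screened for prognostic value with an age-adjusted Cox model; (4) a
query defining a sample subgroup is expanded into the set of events that
significantly co-occur with it and mapped onto a reference interaction
network with directed, attribute-decorated edges.

## Regime discretization

For each gene, mixtures with k = 1..k_max components are fit by EM
(scikit-learn `GaussianMixture`; 5 restarts with k-means++
initialization, log-likelihood tolerance 1e-6, at most 500 iterations).
A variance floor of 1e-6 times the gene's total variance prevents
components from collapsing onto single points. The Bayesian Information
Criterion selects k, with parameter count 3k − 1 (k − 1 free weights, k
means, k variances); ties go to the smaller k, so for k = 1 the BIC
reduces to the closed-form single-Gaussian −2 log L + 2 ln n. Components
are sorted by ascending mean and samples hard-assigned to their
maximum-posterior component (posterior ties to the lower-mean
component), so regime 0 is always the low-expression regime. The default
k_max is 2: in breast-cancer cohorts the clinically salient genes are
bimodal, and binary regimes keep co-occurrence counting interpretable;
the machinery supports general k.

Each gene's fit is seeded from a `SeedSequence` over (global seed, gene
index), so results are independent of fit order and reproducible.
A gene needs at least 10 observed values; genes failing this are flagged
and carry the missing code −1 rather than aborting the run.
Zero-variance genes return a k = 1 profile directly.

A naive baseline discretization (`naive_std_bins`) standardizes a
profile and bins it into (−∞, −1.5), [−1.5, 1.5], (1.5, ∞); it exists
for comparison only and plays no role in the main workflow.

The occupancy filter keeps genes whose every regime contains at least
⌈f·N⌉ samples (default f = 0.10, N = the gene's observed samples);
unimodal genes are dropped since they carry no contrast.

## Co-occurrence statistics

For events A_i (support n_a out of n samples) and B_j (support n_b),
the null hypothesis is independence: P(A_i ∩ B_j) = n_a·n_b/n². The
p-value is the one-sided binomial tail P(X ≥ n_ab), X ~ Binomial(n,
n_a·n_b/n²) — only enrichment is tested, depletion is out of scope.
Because cohort-scale associations reach p ≈ 10⁻⁵⁰..10⁻³⁰⁰ and beyond,
the tail is evaluated in log space: the log pmf at k = n_ab uses the
exact log binomial coefficient (lgamma above n = 2000), and the tail
accumulates through the ratio recursion pmf(k+1)/pmf(k) =
(n−k)p₀/((k+1)(1−p₀)) with compensated (Kahan) summation. Above the
null mean the terms decrease monotonically, so the relative truncation
error is below 1e-19. When n_ab is at or below the null mean the
p-value exceeds ~0.25 and the linear-space survival function is exact
enough. All-pairs scans use a vectorized survival-function bulk path
with a fallback to the exact log-space scalar path wherever the linear
result underflows (below 10⁻²⁸⁰); both paths agree to ≥ 8 digits in
the overlap. Tests verify exhaustive agreement with an exact
rational-arithmetic tail for n ≤ 30 and on deep-tail spot checks
(p ≈ 10⁻¹²⁵).

Conditional probabilities are the plug-in estimates P(A_i|B_j) =
n_ab/n_b. Mutual information between two discretized profiles is the
plug-in sum Σᵢⱼ (n_ab/n)·ln(n_ab·n/(n_a·n_b)) in nats, with 0·log 0 ≡ 0;
each term is itself a co-occurrence quantity, which is the link between
the two measures. Pearson correlation on the continuous data is the
third comparison measure.

All-pairs scans consider only multimodal genes for the discrete
measures. For co-occurrence, every regime combination (i, j) of a gene
pair is scored and the pair-level score is the minimum log₁₀ p over
combinations; the full per-combination table is emitted alongside. The
"best combination" summary is a deliberate choice: per-sample subgroup
reasoning downstream always needs a concrete regime pair. Rankings are
deterministic: ascending log₁₀ p (descending MI/|r|), ties broken on
the lexicographic sorted gene-pair key.

Multiple testing uses the Bonferroni bound θ = α/(N·n_reg·M·m_reg) as a
conservative lower bound with default α = 0.001; FDR control is
intentionally not implemented — the significance level is left as a
user-facing parameter.

Cross-cohort reproducibility is measured by agreement at depth:
walking two cohorts' ranked pair lists simultaneously and recording
|top-d(A) ∩ top-d(B)|/d, after restricting to genes bimodal in both
cohorts.

Missing values are handled pairwise-complete throughout: any statistic
between two features uses only the samples observed for both, with n
adjusted accordingly.

## Survival screening

Per bimodal gene, a Cox proportional-hazards model with covariates
(age in raw years, binary regime indicator with regime 1 coded 1) is
fit on the clinically matched samples. Fitting goes through lifelines'
`CoxPHFitter` (Efron tie handling, Newton-Raphson with step-halving);
an independent dense-grid partial-likelihood maximizer cross-checks the
coefficient in the tests. The reported hazard ratio is
max(exp(γ), exp(−γ)) — the ratio for the poorer-prognosis regime,
always ≥ 1, with `poor_regime` the regime whose indicator carries the
positive adjusted coefficient. Genes with either regime below ⌈0.10·N⌉
samples are excluded (ratios on tiny regimes are not representative);
non-converged or separated fits are flagged and never ranked.

The permutation null shuffles each gene's regime codes across samples
independently per gene per round, preserving occupancy while severing
any survival link, and pools the resulting HRs. Because HR ≥ 1 by
construction, the null distribution concentrates just above 1.

## Subgroup integration

A query is a conjunction of (gene, regime/aberration) conditions; its
indicator is the intersection of the condition supports over the
intersection of the involved modalities' sample sets. Every candidate
event — the best regime per multimodal gene, each mutation with ≥ 3
carriers, each DEL/AMP copy-number state (NEUT is never tested) — is
scored against the subgroup on the samples observed for both the
subgroup's modalities and the candidate's modality. Defaults keep
expression regimes at log₁₀ p ≤ −50 and genomic events at ≤ −20; both
thresholds were display-driven choices at ~2000-sample cohort scale and
are plain configuration here — at the 500-sample demo scale, maximal
self co-occurrence only reaches log₁₀ p ≈ −36, so demo queries use
correspondingly scaled thresholds.

Copy-number events additionally record cis consistency: whether the
event co-occurs (below the same threshold) with an expression regime of
its own gene.

Passing genes are mapped onto the reference interaction network
(BioGRID-style input; self-loops and duplicate edges dropped at load).
Edges are kept only if the link filter holds — P(A_i|B_j) > 0.5 or
P(B_j|A_i) > 0.5 for the two genes' achieving regimes — and oriented by
the heuristic "if P(A_i|B_j) > P(B_j|A_i) then B_j → A_i"; with a
shared overlap count this is equivalent to pointing from the rarer
event to the commoner one (verified exhaustively on all small count
tables), and equal supports leave the edge undirected. The filter is
applied to mapped edges only. Query genes appear in all outputs flagged
`is_query_gene`. Outputs are SIF, GraphML (direction as an edge
attribute) and a node-attribute TSV for Cytoscape-style rendering.

## Synthetic cohorts

The simulator generates what the workflow is designed to detect, with
ground truth attached. Per sample: background genes draw from a single
standard Normal; each bimodal gene has a latent regime z ~
Bernoulli(1 − low_weight) and expression ~ Normal(Δ·z, 1), so Δ is the
mode separation in within-regime SD units and maps directly to GMM
recoverability (Bayes error Φ(−Δ/2)). Clique members share one latent
Bernoulli(prevalence) draw flipped independently with probability ε.
A driver's carriers are drawn at the stated frequency and force each
target's latent regime to the driven state (1, or 0 for deletions) with
the stated penetrance; the aberration is recorded on the first target
gene itself so cis-consistency is exercised. Driver targets get a 5%
baseline occupancy of the driven regime: an "aberration-driven regime"
means carriers, not background fluctuation, populate the regime (as for
amplification-driven ERBB2 high expression); with frequency 0.2 and
penetrance 0.9 this puts the expected driver association near
log₁₀ p ≈ −28 at n = 500, safely below the −20 working threshold.
Survival times are exponential with rate λ₀·exp(β·z + 0.01·(age − 60)),
age ~ Normal(60, 10); the weak age effect keeps the age-corrected Cox
stage non-trivial. Censoring is independent exponential with its rate
solved (Brent) so the expected censored fraction matches the request
given the drawn event times.

Presets: `null` (200 independent bimodal genes, n = 500 — no planted
structure beyond bimodality), `cliques` (one 5-gene clique, prevalence
0.4, ε = 0.05, among 60 bimodal + 140 background genes), `driver` (one
mutation driver, frequency 0.2, penetrance 0.9), `survival` (one gene
with HR = 2, 20% censoring, n = 1000), and `full` (clique + MUT driver
+ DEL driver + survival gene, 200 genes, n = 500).

What the simulator does **not** emulate: platform effects
(microarray vs RNA-seq), batch structure, correlated background
co-expression, subtype mixtures, non-Gaussian regime shapes, and ties
in survival time. Passing tests therefore demonstrate correctness and
calibration of the machinery under the generative model, not
performance on real cohorts.

## Problem sizes and numerical choices

Verification runs use cohorts of 200-400 genes and 500-1000 samples,
100 replicates for calibration and bias estimates — sizes at which
every targeted property (k-selection rates, Bayes-agreement, null FPR,
HR bias, driver recovery) has comfortable Monte-Carlo resolution. The
null-calibration run scores ground-truth regime codes directly: it
isolates the binomial test's calibration, while discretization accuracy
is established separately. Assignment accuracy is reported against the
Bayes-optimal partition under the generating parameters, because at
Δ = 4 the latent draws themselves are only ~97.7% recoverable by any
rule.

Known limitations: per-gene EM restarts make discretization the
dominant cost (~0.15 s/gene) and it is embarrassingly parallel but run
serially here; the co-occurrence test treats samples as exchangeable
(no covariates); the direction heuristic is a heuristic — it encodes
only support-size asymmetry, not causality; and Bonferroni with the
full regime-combination count is deliberately conservative.
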