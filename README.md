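# regimenet

Expression-regime discretization and co-occurrence association networks
for tumor cohorts.

Many clinically important cancer genes (ERBB2, ESR1, ...) show bimodal
expression across a cohort: a low and a high "regime", often driven by
an underlying genomic change such as an amplification. `regimenet`
turns this observation into a workflow for people analyzing matched
expression / mutation / copy-number / survival data:

1. **Discretize** — each gene's expression profile is fit with
   univariate Gaussian mixtures (k = 1..k_max components, EM); the BIC
   −2 log L + (3k−1) ln n selects k, and samples are hard-assigned to
   the maximum-posterior component. Regime 0 is always the low-mean
   regime.
2. **Associate** — for two events A_i ("gene A in regime i", support
   n_a of n samples) and B_j, the co-occurrence p-value is the
   one-sided binomial tail P(X ≥ n_ab), X ~ Binomial(n, n_a n_b / n²),
   evaluated exactly in log space (valid down to p ≈ 10⁻¹⁰⁰⁰).
   Conditional probabilities P(A_i|B_j) = n_ab/n_b, plug-in mutual
   information and Pearson correlation are computed alongside, with
   Bonferroni thresholds θ = α/(N n_reg M m_reg) and agreement-at-depth
   curves for cross-cohort comparison.
3. **Screen survival** — per gene, an age-adjusted Cox model on the
   binary regime indicator; the reported hazard ratio is
   max(exp γ, exp −γ) for the poorer-prognosis regime (always ≥ 1),
   with a ≥10% regime-occupancy requirement and a per-gene
   sample-permutation null.
4. **Integrate** — a subgroup query (e.g. "MLPH low and FOXA1 low")
   defines a sample set; all regimes, mutations and DEL/AMP copy-number
   states that significantly co-occur with it are collected,
   cis-checked (CNV vs own-gene expression), mapped onto a BioGRID-style
   interaction network, filtered by max conditional > 0.5 and oriented
   from the rarer to the commoner event.

A simulator generates multi-omics cohorts with known ground truth
(bimodal genes, co-occurring cliques, penetrant drivers, a prognostic
regime) so the whole chain is testable without any controlled-access
cohort.

## Worked example

```
regimenet simulate --preset full --seed 7 --out-dir demo/
regimenet discretize --expr demo/expression.tsv --k-max 2 --seed 7 \
    --out demo/regimes.tsv --profile-out demo/profiles.tsv
regimenet associate --regimes demo/regimes.tsv --out demo/assoc.tsv
regimenet integrate --regimes demo/regimes.tsv \
    --mutations demo/mutation.tsv --cnv demo/cnv.tsv \
    --query "BM0010:high" --expr-logp -25 --genomic-logp -20 \
    --out-prefix demo/bm0010
```

which reports on stderr:

```
62/200 genes multimodal
1891 ranked pairs
```

All 60 simulated bimodal genes are found multimodal (plus two
background genes the BIC borderline-splits). The association table
`demo/assoc.tsv` has one row per regime combination per gene pair
(columns gene_a, regime_a, gene_b, regime_b, n, n_a, n_b, n_ab,
expected, log10_p, p_a_given_b, p_b_given_a, mi); the planted 5-gene
clique occupies the top of the ranking. The query "samples with BM0010
in its high regime" recovers the planted driver in
`demo/bm0010.mutation.tsv`:

```
gene	category	n	n_sub	n_event	n_both	log10_p	is_query_gene
BM0010	MUT	500	105	93	83	-27.7193	True
```

i.e. 83 of the 93 mutation carriers fall in the 105-sample subgroup,
log₁₀ p ≈ −27.7 against independence — the simulated mutation drives
the high regime. (Exact counts vary with the seed.) The expression
threshold is set to −25 here because at n = 500 even perfect
self-co-occurrence only reaches log₁₀ p ≈ −36; the −50 default matches
~2000-sample cohorts.

Python API mirroring the same run:

```python
import regimenet as rn
expr, mut, cnv, clin, truth = rn.simulate_cohort(rn.preset_spec("full", seed=7))
rm = rn.discretize(expr, k_max=2, seed=7)
ranked, table = rn.all_pairs_associations(rm, measure="cooccurrence")
hazards = rn.screen_hazards(rm, clin)   # age-adjusted HR per bimodal gene
```

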