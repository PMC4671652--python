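# Methods

## Data model and counting conventions

A *catalog* holds, per gene, the relative de novo mutation rates `p_trunc`
(stop-gain + frameshift) and `p_syn` (synonymous), and observed counts of
distinct rare variants. Only rate ratios enter the models, so the absolute
scale of the rate table is irrelevant as long as it is shared across genes.
Counting conventions:

- Each variant record counts once per gene regardless of how many carriers
  it has: a rare variant is treated as a single de novo mutational event.
  Variants annotated to several genes contribute one record per gene,
  because all downstream quantities are per-gene.
- "Rare" means allele frequency strictly below 1% (0.01 itself is
  excluded); "singleton" means allele count exactly 1 in the pooled
  dataset.
- When genotype counts are available, variants failing an exact
  Hardy–Weinberg test (conditioned on the allele count, p < 1e-8) are
  removed; without genotypes the filter is skipped with a logged warning.
- A gene is *included* when its rates are available and it carries at
  least one variant of any class (synonymous, missense, stop-gain or
  frameshift) — a crude capture indicator.
- Splice-site variants are classified separately and count as
  protein-truncating only when `include_splice` is set; default off,
  because their functional consequences are less predictable.

## Synonymous scale and coverage filter

Model B needs the scale `M` converting rates into expected counts. It is
the no-intercept least-squares slope of observed synonymous counts on
synonymous rates, `M = Σ o_syn·p_syn / Σ p_syn²` — the intercept is omitted
because a gene with zero synonymous rate should show zero synonymous
variants. Genes whose regression residual lies more than 3 sample standard
deviations from the residual mean are excluded as coverage outliers and
`M` is refit once on the survivors. Two deliberate choices:

- The filter is two-sided on centered residuals (configurable). The
  motivating failure mode — shallow coverage — produces count *deficits*,
  i.e. negative residuals, so a purely "too many synonymous variants"
  reading would miss it; two-sided captures both deficits and excesses.
- One refit, not iteration to convergence: a single pass stabilizes the
  scale without risking oscillation, and both pre- and post-filter values
  are recorded in provenance.

## Monte Carlo null

Under neutrality, `V` observed PTVs are assigned to genes as independent
multinomial draws with probabilities `q_g ∝ p_trunc`. Draws are i.i.d.
(with replacement): recurrent mutation at the same gene is possible and
its expected contribution is what the closed form captures. The statistic
is the number of distinct genes hit; its exact expectation
`Σ_g [1 − (1 − q_g)^V]` serves as an independent oracle for the simulator.
The one-sided empirical p-value uses the add-one estimator
`(1 + #{hits ≤ observed}) / (n_reps + 1)`, so it is never zero; the default
10,000 replicates give a floor just below 1e-4. The 95% interval is the
percentile interval of replicate counts. Accumulation curves sample
sequentially within a replicate so each replicate's curve is nondecreasing
and the endpoint distribution matches the single-shot simulator.

## Mixture estimation

The marginal count distribution is
`P(X = k) = mean_g [f_hi·Pois(k, λ_HI(g)) + (1−f_hi)·Pois(k, λ_HS(g))]`.
The default estimator minimizes `Σ_{k=0}^{K} [F_model(k) − F_emp(k)]²` on
the unweighted grid `k = 0..K`, `K` = largest observed per-gene count, with
the Nelder–Mead simplex. Numerical choices:

- Parameters are optimized unconstrained: logit transforms for `f_hi` and
  `e`, log transforms for `s_HI`, `s_HS`. Model B fits are relabelled after
  optimization so `s_HI ≤ s_HS` (swapping classes maps `f_hi ↦ 1 − f_hi`),
  which resolves label switching.
- Multi-start from `f_hi ∈ {0.05, 0.1, 0.2, 0.3, 0.4}` with `e = 0.05` and
  moment-matched `s` starts (`s_HS` from the mean count over the mean
  neutral expectation, `s_HI` a tenth of it); the best objective wins and
  exact ties go to the smaller `f_hi`.
- Simplex tolerances: 1e-8 on the objective, 1e-6 on the transformed
  parameters, at most 10,000 evaluations across starts.
- The gene-averaged model CDF is evaluated by the Poisson pmf recurrence
  `pmf(k+1) = pmf(k)·λ/(k+1)` accumulated over the grid (JIT-compiled, with
  a pure-numpy reference path that the tests compare against
  `scipy.stats.poisson`). `exp(−λ)` underflows only beyond λ ≈ 745, where
  the true CDF on the grid is itself below double precision.
- Degenerate inputs: `λ = 0` uses the convention `Pois(0, 0) = 1`;
  `f_hi = 1` is rejected in model A unless `e = 1` (division by the
  tolerant rate mass `1 − f_hi`).

A maximum-likelihood fitter over the same transformed space is provided
for method comparison. It is not the default for data analysis — the CDF
fit is — but on synthetic data generated exactly from the Poisson mixture
it is the more efficient estimator, and the model B recovery check uses it
for that reason; the CDF fit is validated separately on model A, where the
two-parameter surface is well identified.

Uncertainty: 500 gene-resampling bootstrap replicates (genes drawn with
replacement carrying their rates and counts), recomputing `V` (model A) or
`M` (model B) on each replicate before refitting. Replicate fits
warm-start from the point estimate with a single simplex start and a
looser x-tolerance of 1e-4 — percentile CIs need parameter precision far
below their own Monte Carlo width. CIs are type-7 (linearly interpolated)
percentiles; failed replicate fits are excluded and counted.

Posteriors use Bayes' rule in log space with a shared max subtraction, so
genes with large counts and small `λ_HI` do not underflow.

## Projection curves

Under model A, the probability a gene is truncated at least once after `v`
cumulative PTVs follows Poisson thinning: `1 − exp(−v·r_g)` with per-PTV
hit rate `r = e·q_g` for intolerant genes and
`r = q_g·(e + (1−e)/(1−f_hi))` for tolerant ones. Class components weight
genes by `f_hi` and `1 − f_hi`. The conditional probability that a newly
truncated gene is intolerant is the ratio of the analytic derivatives of
those components; it rises toward 1 because tolerant genes saturate first,
and its 50% crossing is located by bisection. Curves are computed
analytically (deterministic, fast); a sequential Monte Carlo simulator of
the same generative process is kept as the test oracle. With `e = 0` the
conditional is identically zero and the crossing is undefined (raised as
an error).

## Gene-set tests

One-tailed hypergeometric tests (enrichment `P(X ≥ k)`, depletion
`P(X ≤ k)`) within the analysis universe of included genes — the
comparison the per-gene counts were computed on — not all annotated genes.
Sets are intersected with the universe before sizing and sets below 100
members are skipped. Benjamini–Hochberg is applied jointly across all
performed tests (both directions); the joint-vs-per-direction choice is
recorded in the output metadata.

## Synthetic data generator

The generator emulates the statistical regime the estimators assume, not
sequence-level reality:

- ~16,000 genes with heavy-tailed relative rates: `log10 p_trunc ~
  Normal(−4.8, 0.4)`. The spread is calibrated so that ~74–75% of genes
  receive at least one PTV at `V = 40,000` under neutral assignment, the
  fraction-truncated regime of the cohort-scale datasets the package
  targets. `p_syn` is `p_trunc` times a lognormal ratio with median 3.
- Latent labels `z_g ~ Bernoulli(f_hi)`; model A counts place exactly
  `round(V·e)` noise variants over all genes and the remainder over
  tolerant genes (both multinomial), making `Σ o_ptv = V` a hard invariant
  mirroring a fixed observed total. Model B counts are independent
  Poissons, `o_ptv ~ Pois(M·p_trunc·s_class)`, `o_syn ~ Pois(M·p_syn)`,
  with defaults `M = 1e5` (mean synonymous count ≈ 10, matching the yield
  of a cohort of ~10⁴ exomes) and `(s_HI, s_HS) = (0.1, 1.0)` — intolerant
  genes retaining a tenth of the neutral yield through noise and rescue.
- Variant tables expand counts into records with allele counts
  `1 + Geometric(0.5) − 1` capped below the rare threshold (most variants
  singletons), optional common decoys the rare filter must remove, and an
  optional severe-flag fraction. The table round-trips exactly through
  filtering and aggregation.

What the generator does *not* emulate: per-gene coverage variation,
trinucleotide-context rate structure, linkage between variants, population
structure, genotype-level data, and correlated annotation errors. Passing
recovery tests therefore demonstrates the estimators are correct and well
calibrated *under the model's own assumptions* at realistic scale; they do
not certify robustness to the misspecifications real cohorts carry.

## Problem sizes used in validation

The validation suite runs parameter recovery at the documented study scale
(16,000 genes, 40,000 PTVs, 20 count realizations for model A) and scales
the bootstrap-coverage study down to 4,000 genes carrying 10,000 PTVs
(same per-gene rate regime) with 500 bootstrap replicates in each of 20
outer simulations. Null-model agreement uses 10,000 Monte Carlo replicates
on catalogs up to 1,000 genes; projection oracles use several hundred
replicates on 300-gene catalogs.

## Known limitations

- Model A treats the observed total `V` as fixed, so it cannot see false
  negatives; `e` absorbs every source of spurious observation without
  separating technical from biological noise (neither can model B's
  `s_HI`).
- The CDF least-squares estimator's precision for `(f_hi, s_HI, s_HS)` in
  model B is limited by a ridge along which `f_hi` and `s_HI` trade off;
  at 16,000 genes its `s_HI` sampling error is of order 20–30% relative,
  which is why the likelihood fitter exists alongside it.
- The intolerant fraction is identified from depletion relative to *rate
  expectations*; systematic rate-table errors propagate directly into
  `f_hi`.
- The HWE filter requires genotype counts, which pooled public summary
  tables often lack; it degrades to a no-op there.
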