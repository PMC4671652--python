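# haplomix

Inference of the haploinsufficient fraction of the genome from rare
heterozygous protein-truncating variants (PTVs).

## The problem

Most stop-gain and frameshift variants found in population sequencing are
heterozygous. If a gene cannot tolerate losing one of its two copies
(haploinsufficiency), new truncating mutations in it are removed by
selection before they can be observed, so the gene appears *depleted* of
PTVs relative to its de novo mutation rate. `haplomix` is for statistical
geneticists who have (a) a per-gene table of relative de novo mutation
rates (truncating and synonymous, Samocha-style) and (b) a cohort variant
table or annotated VCF, and who want to:

- test whether fewer distinct genes carry PTVs than a neutral de novo model
  predicts (Monte Carlo multinomial null);
- estimate the fraction `f_hi` of genes intolerant to heterozygous
  truncation with a two-component Poisson mixture, including per-gene
  posterior probabilities of intolerance and bootstrap confidence
  intervals;
- project how truncated-gene discovery will accumulate as more PTVs are
  sampled, split into intolerant and tolerant components;
- characterize gene subsets (e.g. genes never seen truncated) with
  one-tailed hypergeometric set tests under Benjamini–Hochberg FDR control.

## The model

Let `p_g` be gene *g*'s relative de novo truncation rate and `x_g` its
observed count of distinct rare PTVs (each rare variant counted once, as a
single mutational event). A latent label `z_g ∈ {HI, HS}` with
`P(z_g = HI) = f_hi` marks intolerant genes, and

```
x_g | z_g ~ Poisson(λ_{z_g}(g))
```

Two parameterizations of the class means are provided:

- **Model A** (relative rates): the observed PTV total `V` splits into a
  noise fraction `e` (sequencing artefacts, incomplete penetrance,
  low-impact truncations) spread over *all* genes, and a signal fraction
  `1 − e` confined to tolerant genes:
  `λ_HI = V·e·q_g` and `λ_HS = V·e·q_g + V(1−e)·q_g/(1−f_hi)`, with
  `q_g = p_g / Σ p`. Setting `e = 0` gives the single-parameter
  first-stage model.
- **Model B** (synonymous anchor): a no-intercept regression of observed
  synonymous counts on synonymous rates yields the scale `M`; then
  `λ_class = M·p_g·s_class` with class multipliers `s_HI ≤ s_HS`.

Parameters are estimated by least squares between the model's marginal
cumulative count distribution and the empirical one (Nelder–Mead simplex),
with gene-resampling bootstrap CIs; a maximum-likelihood fitter is included
for method comparison. Per-gene posteriors follow from Bayes' rule:
`P(z_g = HI | x_g) = f_hi·Pois(x_g, λ_HI) / P(x_g)`.

Estimators follow the scikit-learn protocol (`ModelAMixture`,
`ModelBMixture`: `fit` / `predict_proba` / `get_params`), with plain
functions (`fit_cdf_ls`, `posterior_hi`, …) as thin wrappers.

## Worked example

Generate a synthetic cohort at the documented study scale, test for
depletion, and fit model A:

```python
from haplomix import (generate_catalog, simulate_counts_model_a,
                      simulate_neutral_assignment, fit_cdf_ls)

catalog = generate_catalog(n_genes=16_000, seed=0)
data, truth = simulate_counts_model_a(catalog, f_hi=0.25, e=0.10,
                                      V=40_000, seed=1)

observed = int((data.included["o_ptv"] > 0).sum())
null = simulate_neutral_assignment(data, V=40_000, n_reps=2_000, seed=2,
                                   observed=observed)
print(f"observed {observed} truncated genes, "
      f"expected {null.analytic_expectation:.0f}, "
      f"depletion {null.depletion_pct:.1f}%, p = {null.empirical_p:.1e}")

fit = fit_cdf_ls(data, model_tag="A")
print(f"f_hi = {fit.params.f_hi:.3f}, e = {fit.params.e:.3f}")
```

prints

```
observed 10407 truncated genes, expected 11976, depletion 13.1%, p = 5.0e-04
f_hi = 0.265, e = 0.107
```

The neutral null expects 11,976 of the 16,000 genes to be hit by 40,000
PTVs; with a quarter of genes intolerant and 10% noise only 10,407 are
observed — a 13.1% depletion whose one-sided Monte Carlo p-value sits at
the add-one floor of the 2,000 replicates. The mixture fit recovers the
generating intolerant fraction (0.25) and noise level (0.10) from counts
alone, to within its sampling error.

The same pipeline runs from the shell on real inputs:

```
haplomix synth --n-genes 16000 --f-hi 0.25 --noise-e 0.10 --out data/
haplomix null  --rates data/rates.tsv --variants data/variants.tsv --out null/
haplomix fit   --catalog data/catalog.tsv --model A --boot 500 --out fit/
haplomix project --catalog data/catalog.tsv --fit-json fit/fit.json --out proj/
haplomix enrich --catalog data/catalog.tsv --sets pathways.gmt --out enrich/
```

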