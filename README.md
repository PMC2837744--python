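# hapmet

Tests of the metabolic rate hypothesis at the intra-specific level: does an
individual's mass-specific metabolic rate track the mutational history of
its mitochondrial lineage?

`hapmet` is aimed at population geneticists and physiologists with paired
data per individual — an intraspecific mtDNA alignment (e.g. *cox1*
haplotypes from a springtail population) and a continuous trait
(mass-specific metabolic rate, µlO₂·µg⁻¹·hr⁻¹). It asks two questions:

1. **Is the trait structured by the genealogy?** Individuals carrying
   similar haplotypes should have similar metabolic rates.
2. **Does the trait trend with mutational distance from the ancestor?**
   Under the metabolic rate hypothesis (oxygen radicals from respiration
   are mutagenic), higher rates should accompany greater root-to-tip
   distance.

## Methods at the core

**Haplotype-network permutation statistics.** The alignment is collapsed
into haplotypes and joined into a unit-mutation minimum-spanning network
with inferred intermediates, rooted at the most prevalent haplotype with
edges directed away from the root. Two statistics are computed:

- T1(k) = Σ_{pairs i<j, dist(i,j) ≤ k} |m(i) − m(j)| — similarity of rates
  among individuals at most k mutational steps apart (k = 0: identical
  haplotypes);
- T2 = Σ_{directed edges (u,v)} ( mean m at v − mean m at u ) — directional
  change in rate moving away from the root.

Significance comes from shuffling the rates across individuals without
replacement (default 1000 shuffles), the network held fixed.

**Phylogenetic trait models.** On a posterior sample of trees, the trait
vector **m** is modelled as multivariate normal with covariance
σ²·C(λ), where C(1)_ij is the shared root-path length of tips i and j and
λ scales the off-diagonal (λ = 0: star phylogeny; λ = 1: full Brownian
structure). Model A is the constant-variance random walk, E[m_i] = α;
Model B is directional, E[m_i] = α + β·d_i with d_i the root-to-tip
distance. Metropolis–Hastings MCMC averages over the tree sample (the tree
as nuisance parameter); models are compared by Bayes factors from
harmonic-mean log marginal likelihoods, with > 2 / > 5 / > 10 read as
positive / strong / very strong evidence.

A coalescent + HKY + trait-model simulator generates complete synthetic
datasets with the shape of the motivating springtail study (45
individuals, 516 bp, ~9 mutational steps, rates 0.0009–0.0029
µlO₂·µg⁻¹·hr⁻¹), so the whole pipeline is testable without any downloads.

## Worked example

```python
import hapmet as hm

config = hm.PipelineConfig(
    simulation=hm.SimulationConfig(n_posterior_trees=300, length_jitter_cv=0.2),
    n_perm=1000,
    mcmc=hm.McmcConfig(n_iterations=20_000, sample_interval=20),
    max_trees=100,
    seed=1,
    out_dir="results/demo",
)
report = hm.run_full_analysis(config)
for name, res in report.permutation_tests.items():
    print(name, round(res["p_value"], 3))
print("BF(lambda est vs 0):",
      round(report.model_comparison["phylogenetic_signal"]["value"], 2))
print("BF(B vs A):",
      round(report.model_comparison["directional"]["value"], 2))
```

prints

```
T1(0) 0.001
T1(1) 0.669
T2 0.964
BF(lambda est vs 0): 69.93
BF(B vs A): 0.93
```

The synthetic traits were generated with full phylogenetic signal (λ = 1)
and no directional trend (β = 0), and the analysis recovers exactly that
pattern: T1(0) is far smaller than its permutation null (individuals
sharing a haplotype have very similar rates), the λ contrast is decisive
(BF ≈ 70, "very strong": the trait depends on the tree), while T2 and the
Model B vs A contrast show nothing (no trend away from the root). The same
joint pattern — strong tree-dependence, no direct trend — is the study
outcome this pipeline was built to probe.

The equivalent shell run is `hapmet all --config run.toml --out results/`;
`hapmet simulate`, `network`, `randtest`, `fitmodels` and `compare` expose
the individual stages.

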