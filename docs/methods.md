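# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions taken where the problem was genuinely
open. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Haplotype network

Individuals with identical sequences share a haplotype. Before collapsing,
every alignment column containing an ambiguity (`N` or `-`) in *any* record
is masked alignment-wide; this is conservative, symmetric and
order-independent, at the cost of discarding a column for all individuals
when one read is poor. Haplotype ids are `H1, H2, …` in descending
frequency (ties broken lexicographically by sequence).

The network is a **minimum-spanning network** on Hamming distances:
distance levels are processed in ascending order and, at each level, every
pair in different components (as the level opened) is joined, so co-minimal
alternative connections are retained and reticulations are possible. Edges
of length L > 1 are subdivided into L unit steps through L−1 inferred
(frequency-0) nodes; the intermediate sequences apply the differing sites
one per step in ascending column order starting from the lower-numbered
haplotype. The specific intermediate states never affect distances — only
path lengths matter. An optional connection limit (`max_connection_steps`)
leaves distant haplotypes unjoined and the components are reported
explicitly.

This construction stands in for statistical parsimony (TCS): on
low-diversity intraspecific data the two produce the same network, and the
MSN is deterministic and fully specified. The 95% connection-limit formula
is deliberately not reimplemented.

Rooting follows standard population-genetic practice: the most prevalent
haplotype is the putative ancestor (tie → lexicographically smallest id),
and every edge is oriented from the endpoint nearer the root
(breadth-first distance) to the farther one; equal-depth edges on retained
cycles go from smaller to larger node id. All tie-breaks are lexicographic,
making the construction bit-reproducible.

## Permutation statistics

- **T1(k)** sums |m(i) − m(j)| over unordered pairs of individuals whose
  haplotypes are **at most** k steps apart. The inclusive reading is forced
  by the statistic's intent: with a strict inequality T1(0) would be empty
  rather than "individuals with identical haplotypes". Pairs are counted
  once; doubling would rescale observed and null identically.
- **T2** sums (mean rate at child − mean rate at parent) over directed
  edges. Inferred nodes carry no individuals, so a mean rate is undefined
  there; chains of inferred nodes are contracted so every directed edge
  joins observed haplotypes. Contraction preserves orientation and
  observed-node adjacency. T2 is linear in the trait vector, invariant to
  adding a constant, and sign-flips under trait reflection.

The null shuffles the trait values across individuals without replacement,
network fixed. Defaults: lower tail for T1 (small T1 = neighbours similar),
upper tail for T2 (large T2 = increase away from root), ties counted as at
least as extreme, and add-one smoothing p = (1 + c)/(n_perm + 1) so p > 0.
Flags recover the plain proportion and a forced upper tail for both
statistics. Under exchangeability the smoothed p-value is exactly uniform
on its discrete support, so the test holds its nominal size (verified by a
500-replicate calibration test at the 5% level).

## Continuous trait models

With tip order fixed, C(1)_ij is the branch length shared by the root
paths of tips i and j (C_ii = root-to-tip distance d_i). Pagel's λ scales
the off-diagonal only: C(λ) = λ·C(1) off-diagonal, diag(d) on the
diagonal; λ = 0 is a star phylogeny (trait independent of the tree).

- **Model A** (constant-variance random walk): m ~ MVN(α·1, σ²C(λ)).
- **Model B** (directional): mean α + β·d. β is per unit branch length and
  is identifiable only on non-ultrametric trees; a guard rejects ML fits of
  Model B when var(d)/mean(d)² ≤ 1e-12.

**Singularity.** Identical haplotypes and retained zero-length branches
make C exactly singular routinely. When the Cholesky factorisation fails, a
diagonal nugget of `1e-8 × mean(diag C)` (configurable) is added once; if
factorisation still fails the fit errors out rather than silently
regularising further.

**ML fitting** profiles α (and β) by closed-form GLS and σ² by its ML
plug-in at fixed λ; λ, when estimated, is found by bounded scalar search on
[0, 1] (tolerance 1e-6) with the endpoints checked explicitly because the
profile is often flat near a boundary.

**MCMC** is Metropolis–Hastings with symmetric uniform proposal windows of
half-width `ratedev` (default 0.002) for α, β and λ, the same half-width on
log σ², and an independent uniform draw from the tree set each iteration —
averaging over the posterior tree sample treats the tree as a nuisance
parameter. Priors are flat: uniform on [−100, 100] for α and β (on the
scaled trait scale), log-uniform on [1e-8, 1e4] for σ², uniform on [0, 1]
for λ; all bounds configurable. Traits are multiplied by
`trait_scale_factor` (default 1000) before sampling so that rates of order
1e-3 become order 1, matching the small shared proposal width; the factor
is recorded in the chain. The chain is initialised at the ML fit on the
first tree, so even short chains sample near the posterior mode — with flat
priors the posterior mode and the ML optimum coincide, and this choice is
what makes desk-scale defaults (20 000 iterations, thinning 20, 10%
burn-in) usable. Longer, cold-started runs are a config change, not a code
change.

**Model comparison.** The log marginal likelihood is estimated by the
harmonic mean of sampled likelihoods, computed stably in log space:
−[logsumexp(−ℓ) − log S]. The harmonic-mean estimator's instability (its
infinite-variance pathology) is a known limitation accepted deliberately;
no stepping-stone or thermodynamic-integration estimator is provided. The
Bayes factor is reported as `multiplier × (log ML_better − log ML_worse)`
with bands > 2 / > 5 / > 10. Both the doubled test-statistic convention and
the raw difference are supported; the default multiplier is 1, which is the
convention under which the published table's factors equal the difference
of its harmonic means. Four variants are run: A and B at λ = 1 (the
directional contrast) and A with λ estimated vs λ = 0 (the
phylogenetic-signal contrast).

## Synthetic data generator

The generator emulates the structure of the motivating springtail dataset;
its defaults are the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| n_individuals | 45 | study sample size |
| seq_length | 516 bp | study *cox1* fragment |
| theta | 0.006 | calibrated so the expected maximum pairwise haplotype distance ≈ 9 steps at 516 bp |
| kappa | 4.0 | arbitrary (no estimate reported); typical mtDNA transition bias |
| base_freqs | 0.31/0.17/0.15/0.37 | arbitrary; AT-rich arthropod mtDNA |
| trait_range | 0.0009–0.0029 | observed metabolic-rate range, µlO₂·µg⁻¹·hr⁻¹ |
| lambda_true / beta | 1 / 0 | full signal, no trend — the pattern the study reported |
| n_posterior_trees | 900 | study posterior sample after 10% burn-in |

Stages: (1) Kingman coalescent genealogy via msprime (haploid samples,
population size 1, so pairwise coalescence has rate 1 and E[TMRCA(2)] = 1),
branch lengths rescaled by θ/2 into substitutions/site; (2) HKY sequence
evolution with the rate matrix normalised to one expected substitution per
unit branch length, sites independent, root drawn from the stationary
frequencies; (3) tip traits drawn from the generating MVN under Model A or
B with the chosen λ, then affinely rescaled into `trait_range` (the scale
and offset, and the effective β and σ² on the rescaled scale, go into
provenance); (4) a posterior tree sample emulated by unit-mean lognormal
branch-length jitter (CV default 0.1) plus optional random
nearest-neighbour interchanges.

What the generator does **not** emulate: sequencing error, indels or
missing data (alignments are gap-free); population structure, migration or
selection; generation-time or body-size covariates; real MCMC posterior
correlations between topology and branch lengths (the jitter is
independent across branches). A coalescent genealogy is ultrametric in
time, unlike trees estimated from sequences; non-ultrametric trees — needed
for the directional model to be identifiable — come from the branch-length
jitter. Passing tests therefore demonstrate correctness of the machinery
under a clean neutral model, not robustness to the messiness of real data.

## Pipeline conventions

A single global seed fans out to per-stage seeds by hashing the stage name
with the seed (SHA-256, reduced below 2³¹), so any stage can be reproduced
in isolation. For the comparative analysis the tree set is thinned evenly
to `max_trees` (default 100) and each retained tree is rerooted with a
designated individual from the commonest haplotype as outgroup
(lexicographically first member by default); a concordance mode repeats the
analysis with the next such member. Reports are JSON with sorted keys and
no timestamps, so identical (config, seed) gives byte-identical output.

## Experiment scales

The statistical experiments in the test suite use deliberately desk-scale
problem sizes, chosen as the package's own defaults for a laptop-class
machine: 100 five-tip trees for the dense-MVN likelihood oracle; all 720
permutations of a six-individual network against 10 000-shuffle Monte
Carlo; 500 calibration replicates (20 networks × 25 independent trait
draws, 199 shuffles each); 50 replicates of 200 tips for β recovery and
12 × 3 replicates of 100 tips for the λ grid; 20 study-shaped replicates
with 25-tree posteriors and 3000-iteration chains for the joint
model-comparison pattern.

## Known limitations

- The harmonic-mean marginal likelihood is noisy; Bayes factors near a band
  boundary should not be over-read.
- The MSN may retain co-minimal cycles where TCS would have broken them;
  reticulations are surfaced in the GraphML export rather than resolved.
- T2 on a network with a single observed haplotype is 0 by convention
  (with a warning).
- The ×1000 trait scaling plus shared `ratedev` mirrors the historical
  tool's tuning; it is a pragmatic coupling, not a principled adaptive
  scheme.
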