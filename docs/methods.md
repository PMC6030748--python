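# Methods

`hydropop` implements the population-genetic analysis stack used to ask
whether watershed divides structure riverine fish populations, and whether
individual populations that sit "on the wrong side" of a divide got there by
natural vicariance, human translocation, or admixture.  This note documents
the models, the estimators, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Data model

Genotypes are diploid microsatellite calls stored as integer allele sizes in
base pairs; a missing genotype blanks both allele slots (half-calls are not
representable, matching the Genepop interchange format).  Every statistic
that requires repeat counts (R_ST, the stepwise-mutation machinery, the
allele-size variance and (δμ)² summary statistics) converts sizes via the
per-locus motif length, using the minimum observed allele as the offset;
all such statistics depend only on repeat-count *differences*, so the choice
of offset is immaterial.  mtDNA is an equal-length nucleotide alignment;
population membership and geography live in a separate grouping scheme with
great-circle distances derived from coordinates unless an explicit
(hydrographic) distance matrix is supplied — both kinds are tagged, since
river-km and straight-line distances answer slightly different questions in
isolation-by-distance analyses.

## Diversity

* **Heterozygosity.** H_o is the fraction of scored genotypes that are
  heterozygous; H_e is Nei's unbiased gene diversity
  (2n/(2n−1))(1 − Σp²).  The unbiased form was chosen (over raw gene
  diversity) so that the estimator's expectation matches the population
  quantity at the small per-population sample sizes (9–46 diploids) the
  design uses; the test suite verifies unbiasedness by simulation.
* **Allelic richness.** Hypergeometric rarefaction to g genes,
  AR = Σ_a [1 − C(2n−c_a, g)/C(2n, g)], with g = 18 genes (9 diploids, the
  smallest population in the design) as default.  AR is monotone in g and
  equals the raw allele count at g = 2n; both properties are tested.
* **Exact Hardy–Weinberg test.**  The exact *probability* test on Levene's
  conditional distribution: the p-value sums the probabilities of all
  genotypic configurations (given the observed allele counts) no more
  probable than the observed one.  Configurations are enumerated exhaustively
  for ≤ 3 alleles and n ≤ 100; otherwise a Markov chain is used.  The chain
  exploits the fact that Levene's distribution is the push-forward of the
  uniform distribution over perfect matchings of the 2n allele copies, so a
  symmetric partner-swap move needs no Metropolis correction; p is the
  stationary fraction of states at or below the observed probability, with a
  batch-means standard error.  Defaults: 10 000 burn-in steps, 100 batches
  of 5 000 (the cited software's neighbourhood); tests use smaller chains.
  Exact-test p-values are discrete and slightly conservative; the
  calibration test therefore uses a 6-allele design where the support is
  dense enough for a Kolmogorov–Smirnov uniformity check to be meaningful.
* **Null alleles.**  EM maximum likelihood under HWE with one non-amplifying
  allele: apparent homozygotes are E-step-split into true homozygotes and
  visible/null heterozygotes.  Missing genotypes can optionally be counted
  as null homozygotes (off by default, since random dropout also produces
  blanks).  On the boundary f = 0 the EM map converges sublinearly, so at
  convergence the estimate is snapped to 0 whenever the boundary likelihood
  (conditioned on the genotype being visible) is at least as high as the
  interior iterate's.  The estimator is validated against a grid-search
  maximizer of the same likelihood and by parameter recovery on simulated
  null alleles.

## Differentiation

* **F_ST.** Weir–Cockerham θ: per locus and allele the a, b, c variance
  components; the multi-locus estimate is Σa / Σ(a+b+c).  Negative estimates
  are reported as-is.  Significance by permuting individuals between the two
  samples (1000 permutations by default) with the add-one p-value
  convention.  The permutation engine precomputes per-individual allele-copy
  and heterozygote profiles so all permutations are matrix products.
* **R_ST / pR_ST.**  R_ST is the ANOVA variance-component ratio on
  repeat-count allele values, components summed across loci (the cited
  implementation's pooling).  The allele-size permutation test shuffles
  sizes among allelic states *within* each locus — allele identities and
  frequencies stay put, only the size labels move — and recomputes R_ST
  (9000 permutations by default) to ask whether stepwise mutations
  contribute to differentiation beyond drift.  Global and pairwise modes are
  provided.  Under drift alone sizes are exchangeable labels, which the
  calibration test exploits.
* **AMOVA.**  Three-level decomposition on allele copies with the 0/1
  different-allele metric, which reduces every sum of squared differences to
  allele counts; variance components are computed per locus with the
  standard unequal-size coefficients and summed across loci.  F_CT
  significance comes from permuting whole populations among groups (10 000
  by default).  The phrase "bootstraps" that sometimes labels this test in
  the literature is implemented as permutation, since resampling populations
  with replacement does not give a null distribution for F_CT.
* **Isolation by distance.**  F_ST/(1−F_ST) regressed on ln distance;
  Mantel tests permute population labels of one matrix.  Pairs with
  F_ST = 1 (undefined transform) or zero distance are excluded and reported.

## Admixture clustering

The model is the standard Bayesian admixture model with correlated allele
frequencies: individual i has membership q_i ~ Dirichlet(α) over K
clusters; each allele copy draws a cluster of origin z from q_i, then an
allele from that cluster's frequency vector.  Cluster frequencies follow the
F-model, p_kl ~ Dirichlet(p_Al (1−F_k)/F_k), around ancestral frequencies
p_Al ~ Dirichlet(λ) with λ = 1.  z, q and p have conjugate Gibbs updates
(vectorized over all allele copies); α uses a Metropolis step of 0.025 under
a uniform(0, 10) prior, F_k a random-walk step under a truncated normal
prior (mean 0.01, sd 0.05), and p_A pairwise mass-transfer proposals — all
mirroring the cited program's defaults where it states them.  ln Pr(X|K) is
estimated as mean(logL) − var(logL)/2 over post-burn-in iterations.
Desk-scale defaults are 20 000 iterations with 5 000 burn-in; production
runs of 10⁶/10⁵ are available through the same parameters.  Missing allele
copies are dropped from the likelihood, not imputed.

Model-order diagnostics follow Evanno's ΔK (mean absolute second difference
of lnP over replicates divided by the replicate SD; infinite when the SD is
zero, undefined at the boundary K).  Replicate runs are label-aligned
greedily against the running average; the per-run column permutation is
solved exactly as an assignment problem, which coincides with the
exhaustive-search optimum at any K.  No automated choice of K is made — the
diagnostics are reported and the choice is left to the user, because
log-likelihood and ΔK criteria routinely disagree on real data.

FCA is classical correspondence analysis (chi-square-metric SVD) of 0/1/2
allele-count profiles with per-column mean imputation of missing genotypes.

## Haplotype networks

Sequences are collapsed to haplotypes after removing every column containing
N or a gap in any sequence (the simplest defensible ambiguity rule — a
column is either comparable for everyone or for no one).  The median-joining
network iterates: build the ε-relaxed minimum spanning network on Hamming
distances; for every connected triple propose the majority-consensus
(median) vector; add the cheapest new medians that reduce the triple's
connection cost; repeat until closure; finally prune unsampled median nodes
of degree ≤ 2.  ε defaults to 0 (most parsimonious network), ties are broken
lexicographically, so the output is independent of input order; with
homoplasy-free data the network provably collapses to the minimum spanning
tree, which the tests check.

## Coalescent simulation

Demographic scenarios are event programs — population splits, admixtures
and stepwise effective-size changes in generations before present
(generation time fixed at one year, so years equal generations).  Genealogies
are drawn per locus with msprime's exact continuous-time coalescent under
the scenario's demography (piecewise-constant Ne, no recombination within a
locus, free recombination between loci).  Mutations follow the generalized
stepwise model: a mutation moves the repeat count up or down with equal
probability by a geometrically distributed number of steps (parameter
p_geom; 0 recovers the strict SMM), reflected into a bounded range of 40
contiguous states by default (a common registry convention for bounded
microsatellite state spaces).  The transition matrix is built explicitly and
handed to msprime as a matrix mutation model with a point-mass root state at
the centre of the range.  Per-locus rates are Gamma-distributed around the
mean rate (shape 2, mean 5×10⁻⁴ by default — the canonical microsatellite
neighbourhood; the original study cites only "default settings" of its
simulation tool, so these are configurable, documented values, not asserted
study values).  The strict-SMM sanity anchor is the Ohta–Kimura equilibrium
heterozygosity 1 − 1/√(1+8Nμ), which the suite verifies within Monte-Carlo
error.

### The study fixture

`make_study_fixture` emulates the 27-population, three-watershed design:
688 genotyped diploids at the published per-population sample sizes, 12
loci (one tetranucleotide, eleven dinucleotides), and an 83-sequence
1124-bp mtDNA alignment from 26 sites.  The demographic scenario has
Danube, Elbe, Rhine and Baltic stems with two Morava sub-stems; each
sampled population splits from its stem 160–1000 generations ago with
recent Ne of 300–1500.  The two focal histories use the point estimates the
inference machinery is expected to recover: the Sázava sample is an
admixture of the Czech-Elbe and western-Morava stems 229 generations ago
(61.3 % Morava ancestry) through a 6-generation bottleneck of Ne = 69, and
the Czech Oder populations descend from the northern-Morava stem via a
founding event 130 generations ago through a bottleneck of Ne = 50.  Null
alleles at frequencies 0.069/0.079 ride on two loci, two loci are
hyper-variable (10× mutation rate), and 3.9 % of genotypes are blanked at
random (≈96 % genotyping success).  Stem divergence times and population
Ne values are the generator's own choices, set once to produce pairwise
F_ST in the 0.02–0.4 range typical of such surveys.

The mtDNA fixture is built by infinite-sites mutation on a fixed two-clade
topology (14 fixed differences), with a star-like western haplogroup —
a dominant central haplotype plus one-to-two-step satellites — and a
small structured eastern clade confined to the Polish Baltic sites.

What the fixture does *not* emulate: genotyping stutter and allele dropout,
linkage between loci, within-population substructure or family sampling,
geographic gene flow after founding (populations are isolated after their
split), and sequence-evolution complexities beyond infinite sites.  Passing
fixture tests therefore demonstrates that the estimators and the inference
machinery recover the histories *their own model class generated* at
realistic sample sizes — not that the original wet-lab results are correct.

## Approximate Bayesian computation

Summary statistics per group: mean allele number, mean unbiased gene
diversity, mean allele-size variance; per group pair: Weir–Cockerham F_ST,
the shared-allele distance DAS (1 − mean proportion of shared alleles
between cross-group individuals, computed in closed form from per-allele
carrier counts), and (δμ)² (squared difference of mean repeat counts).
Statistics are standardized by reference-table median absolute deviation
(robust to the heavy-tailed allele-size variance under the GSM).

Candidate scenarios ship as families — a builder mapping a parameter vector
to a concrete event program, uniform priors per parameter, and explicit
ordering constraints enforced by rejection.  The supplementary prior table
of the original study is not part of its main text, so the bundled priors
for the two focal analyses are broad uniforms (Ne 100–20 000, event times
10–1500, admixture rate 0.05–0.95, bottleneck size 2–100 lasting 0–30
generations) chosen once to bracket the published posteriors; they are
editable configuration, not transcriptions.  Mutation hyper-parameters are
drawn per simulated dataset (rate log-uniform on 10⁻⁴–10⁻³, geometric
parameter uniform on 0.1–0.3, the cited simulator's default neighbourhood).

**Model choice** retains the tolerance fraction (1 % by default) of
simulations closest to the observed statistics in Euclidean distance and
fits a multinomial logistic regression of the scenario indicator on
statistic deviations, evaluated at the observed point, with 95 % CIs from
the regression covariance by the delta method.  At desk-scale reference
sizes (thousands, not the printed 10⁶) the unregularized fit is prone to
quasi-separation; the implementation therefore weights retained rows by an
Epanechnikov kernel in distance and applies an L2 penalty, falling back to
weighted retained-set frequencies when the regression degenerates.

**Parameter estimation** uses local-linear regression adjustment: retained
parameters are logit-mapped to their prior bounds, regressed on statistic
deviations with Epanechnikov weights, adjusted to deviation zero and
back-transformed; point estimates and 95 % intervals are weighted
quantiles.  With tolerance 1 and no regression the prior is reproduced — a
property the tests use as a null check.

**Model checking** simulates from posterior parameter draws and reports
two-sided tail probabilities of held-out statistics.  The fitting/held-out
split is configurable; by default everything except the (δμ)² family is
used for fitting and (δμ)² is held out.  (δμ)² was chosen as the held-out
family because it is the noisiest of the three pairwise distances at these
sample sizes, so excluding it costs the least discriminatory power while
keeping the check honest; the between-group statistics carry most of the
signal about origin scenarios and belong in the fitting set.

### Problem sizes

Desk-scale defaults throughout were chosen as the package's own working
sizes: ABC reference tables of 10⁴ simulations per scenario for controlled
two-scenario designs and 1–2×10³ per scenario for the 27-population fixture
analyses; Gibbs runs of a few hundred to a few thousand iterations for the
strongly structured fixture; permutation counts of 200–2000 in pipelines
and tests, with the full 1000/9000/10 000 defaults on the public API.  The
printed full-scale settings (10⁶ ABC simulations per scenario, 10⁶ MCMC
iterations × 10 replicates) are supported through the same parameters.
ABC posterior accuracy improves with reference-table size; at desk scale
the scenario ranking on the fixture is reproducible but posterior
probabilities carry sampling noise of a few percentage points.

## Known limitations

* The admixture sampler uses a single α for all clusters and no LOCPRIOR or
  linkage extensions.
* The ABC machinery offers no linear-discriminant pre-projection or
  random-forest model choice; with highly collinear statistic sets the
  regularized logistic is the only guard against separation.
* The null-allele estimator assumes HWE within populations; in bottlenecked
  or inbred populations homozygote excess from other causes inflates it.
* Median-joining is implemented with consensus (majority) medians, not the
  full quasi-median construction, and without the maximum-parsimony
  post-processing step of the original software.
* The fixture's ABC group analyses treat pooled population groups as
  panmictic units, as the original analysis design does; internal
  substructure of the groups is a recognized source of model misfit and is
  why fixture-scale posterior *parameters* (times, rates) are recovered
  with wide intervals even when the scenario ranking is correct.
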