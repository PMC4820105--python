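# Methods

This note documents the statistical models implemented in `bandpop`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
results are compared across programs.

## Dominant-marker data model

A dominant locus has a marked allele `A` (band) and a null allele `a`
(no band); phenotypes collapse `AA` and `Aa`. With band-absence phenotype
frequency `x` in a sample of `N` diploids and Hardy–Weinberg proportions,
`x` estimates `q²`. All frequency-based statistics start from the
Lynch–Milligan corrected estimator

```
q̂ = √x · [1 − Var(x)/(8x²)]⁻¹ ,   Var(x) = x(1−x)/N ,
He = 2q̂(1−q̂) + 2Var(q̂) ,         Var(q̂) = (1−x)/(4N) .
```

Conventions: at `x = 0` the correction divides by zero, so `q̂ = 0` is
reported with `He = 2Var(q̂)` and the estimate flagged; `q̂` is clamped to
`[0, 1]` (the correction can exceed 1 when `x → 1` in small samples).
The locus filter excludes bands whose presence frequency exceeds
`1 − 3/N` — equivalently, loci seen band-absent in fewer than three
individuals — where `√x` is too unstable to correct. The filter can be
applied to the pooled sample (used for species-level statistics and by
the pipeline default) or per population; both emit an exclusion report.
A locus is *polymorphic* when its most common allele frequency is at
most 0.95.

The per-population mean `He` is `H_pop` (SE over loci, `L−1`
denominator); `H_sp` is the same computation with all individuals pooled
into one sample, not the mean of `H_pop` — pooling captures the
among-population (Wahlund) component.

## Weir–Cockerham θ for dominant data

θ is the ratio of summed per-locus variance components `Σa / Σ(a+b+c)`
(among / among+within), computed from the per-population corrected
frequencies with per-sample sizes in individuals. Genotypes are
unobserved, so the heterozygote-frequency term is replaced by its HWE
expectation `2p̂q̂`. Negative per-locus components are retained in the
sums; loci monomorphic everywhere contribute zero and are flagged.
Uncertainty: delete-one-locus jackknife (mean, SE) and a percentile
bootstrap over loci (default 5000 replicates, seeded).

Known bias: `q̂` carries sampling variance `≈ (1−x)/(4N)`, larger than
the allele-count variance `q(1−q)/(2N)` that the Weir–Cockerham
finite-sample terms subtract. The residual inflates the among-population
component; under the island conditions used in the tests (K=8, N=40,
π ~ U(0.1, 0.9)) the multi-locus θ overshoots a true F_ST of 0.2 by
about +0.03. This is a property of frequency-based θ on dominant data,
not of the resampling.

## Exact test of population differentiation

Each locus yields a 2 × K phenotype × population table. The null is the
multivariate hypergeometric distribution over tables with the observed
margins; the p-value is the total probability of tables no more probable
than the observed one. Small tables (≤ 10⁶ candidates) are enumerated
exactly. Larger tables use a Metropolis chain whose proposal adds ±1
around a uniformly chosen 2 × 2 sub-table; after a dememorization
burn-in (default 1000 steps) the p-value is estimated in batches
(default 10 × 2000 steps) whose spread gives its standard error. A locus
with a zero phenotype margin is monomorphic: p = 1 by convention,
flagged. Ties in table probability are compared with a 1e-9 log-scale
tolerance so the observed table always counts.

## AMOVA

Distances between individuals are mismatch counts of band profiles
(= squared Euclidean for 0/1 vectors). Sums of squares follow the
squared-distance formulation (`SS_total` = sum of all pairwise d² / N,
within-unit SS analogous per unit); variance components use the
unequal-sample-size coefficients, and for the hierarchical design
(groups / populations within groups / individuals) the three-coefficient
generalisation. For binary data these SS are identical to summed
per-locus one-way ANOVA sums of squares, which the test suite uses as an
independent oracle.

Negative variance components are reported as-is with a flag (never
truncated), and `%V` is computed over the signed total. Permutation
schemes per statistic: Φ_ST permutes individuals among populations;
Φ_SC permutes individuals among populations within their group; Φ_CT
permutes whole populations among groups. p = (count+1)/(n_perm+1),
default 1023 permutations.

Interpretation caveat: Φ computed from dominance phenotypes estimates
differentiation on the *phenotype* scale (band-absence probability `q²`),
which exceeds allelic F_ST — under the test conditions by ~+0.06 at
F_ST = 0.2. The estimator is consistent for the phenotype-scale quantity
(verified against its analytic value); users comparing Φ_ST with θ
should expect Φ_ST ≥ θ on the same data.

## Bayesian f-free model

Hierarchy (per population k, locus l):

```
x_kl ~ Binomial(N_k, q_kl² + f·q_kl(1−q_kl))
q_kl ~ Beta(π_l(1−θ)/θ, (1−π_l)(1−θ)/θ)
π_l, θ, f ~ Uniform(0,1)
```

so that E[q] = π and Var(q) = θ·π(1−π): θ is the Bayesian analogue of
F_ST. Dominant data are nearly uninformative about the inbreeding
coefficient `f`, so the *f-free* variant redraws `f` from its prior at
every sweep instead of estimating it, propagating the full prior
uncertainty into everything else.

Sampling: Metropolis-within-Gibbs with logit-scale Gaussian random-walk
proposals — element-wise for the `q_kl` matrix, per-locus for `π_l`,
scalar for θ. Proposal scales adapt every 100 sweeps during burn-in
toward 20–45% acceptance and are frozen afterward. Defaults: 5000
burn-in sweeps, 25 000 retained sweeps thinned by 5, four chains with
seeds spawned from the user seed. Convergence is checked per summary
parameter with the classic Gelman–Rubin PSRF
(`V̂ = (n−1)/n·W + B/n`, PSRF = √(V̂/W)); PSRF > 1.1 flags (never
suppresses) the result. Chains are concatenated for summaries.

Summaries: H_B per population is the posterior mean over loci of
`2q(1−q)`; H_BT the analogue from `π_l`; θ^B is reported as the mode of
a Gaussian-KDE density with a 95% highest-density region (samples whose
estimated density exceeds the 5% density quantile; a single interval for
unimodal posteriors).

Known behaviour: when the data are actually in HWE (f = 0), averaging
the likelihood over f ~ U(0,1) maps observed `x = q²` onto smaller, more
dispersed latent frequencies and inflates θ^B by roughly +0.05 at true
F_ST 0.2 under the test conditions (generating data at f = 0.5, the
prior midpoint, removes the shift). With a single population θ is not
identified by any among-population contrast; its posterior stays diffuse
and should not be interpreted.

## Distances, isolation by distance, trees

Pairwise θ for every population pair is linearized as `θ/(1−θ)`
(Rousset), the scale on which two-dimensional isolation by distance
predicts a linear increase with log geographic distance. Geographic
distances are great-circle (haversine, Earth radius 6371 km) from
decimal-degree coordinates; the DMS parser accepts `°`/`´`/`´´` and
unicode prime variants with hemisphere letters or column conventions.
The Mantel statistic is the Pearson correlation of off-diagonal upper
triangles; the null permutes rows and columns of the genetic matrix
jointly; the p-value is two-sided with +1 smoothing; the log transform
is the natural log (default on).

UPGMA is implemented directly (size-weighted average linkage, node
height = join distance / 2) so that ties are broken lexicographically by
the smallest leaf label of each cluster — deterministic output across
platforms — and verified against SciPy's average-linkage cophenetic
matrix. Neighbor-joining uses scikit-bio's classical NJ. Branch support
resamples loci with replacement; because Weir–Cockerham components are
additive over loci, each replicate's pairwise θ matrix is a resampled
sum of precomputed per-locus components. Support is the percentage of
replicate trees containing each original split (splits canonicalised
against the alphabetically first leaf, so rooted and unrooted trees
compare consistently). Newick output carries supports as internal node
labels.

## Synthetic data

`simulate_island` mirrors the inference hierarchy: `π_l` from
U(0.1, 0.9) by default (a "filter-friendly" spectrum; pass beta
parameters, e.g. `{"a": 0.35, "b": 0.35}`, for a U-shaped spectrum with
near-fixed bands that exercises the locus filter), `q_kl` from the beta
with Var = θ*·π(1−π), genotypes in HWE with optional inbreeding f, band
absent iff null homozygote. `simulate_stepping_stone` performs a
logit-scale random walk along a chain of populations with step SD
`0.9·(1 − neighbor_mix)`, so divergence grows linearly with chain
separation (Mantel power testbed); populations sit on the equator at a
configurable longitude spacing. Both return the truth (π, q, θ*, seed)
alongside the matrix and are bit-reproducible from the seed.

What the generator does *not* emulate: linkage between loci (all
analyses here assume independence), scoring error/band homoplasy,
null-allele frequency variation within primers, and spatially continuous
sampling. Passing tests therefore demonstrate statistical correctness of
the estimators under the stated model, not robustness to those artefacts.

`bandpop.study` carries the reference sampling design used for worked
examples and the acceptance script: eight organ-pipe-cactus populations
in Sonora, Mexico (sample sizes 44/45/42/30/30/43/40/43, DMS coordinates,
99 ISSR loci from three primers, a four-group genetic clustering).
`simulate_study_conditions` generates data on that layout with true
F_ST = 0.18 and the U-shaped Beta(0.35, 0.35) spectrum, chosen a priori
to land total gene diversity near 0.21 and ~two thirds polymorphic loci,
the regime such surveys report.

## Problem sizes and tolerances

Recovery tests use K = 8, N = 40, L = 300 with 10 replicates per
condition, and the statistical acceptance suite runs its MCMC at
shortened settings (2 chains, 300 + 1200 sweeps, thin 4) — the posterior
summaries stabilise well before the full published settings, which the
acceptance script uses as-is. Permutation p-values use +1 smoothing, so
their floor is 1/(n_perm+1). Ultrametricity of UPGMA trees is exact up
to floating-point accumulation (relative spread < 1e−9). The exact-test
chain compares log-probabilities with a 1e−9 tolerance; the enumerator
refuses designs beyond 10⁶ candidate tables.
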