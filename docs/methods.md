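# Methods

`trioscan` detects transmission ratio distortion (TRD) — systematic deviation
from the Mendelian 50:50 transmission expectation — from genotyped
sire–dam–offspring trios, SNP by SNP, with a Bayesian model-comparison scan.
This note documents the models, the estimators, the synthetic data the tests
run on, and the numerical choices.

## Models

At a biallelic SNP with alleles A and B (A is the A1 allele of the input
fileset; no re-polarisation to the minor allele is performed, and all signs
are reported relative to A), three parameterisations are fitted:

**Overall allelic.** A heterozygous parent transmits A with probability
P(A) = ½ + α, α ∈ [−0.5, 0.5], flat prior. α > 0 means over-transmission of A.

**Parent-specific allelic.** Separate stallion (α_s) and mare (α_d) effects,
each with the same space and flat prior. Distortion restricted to one
parental sex points at gametic mechanisms (sperm/ova fitness, meiotic drive,
parental imprinting).

**Genotypic.** Distortion acting on the offspring genotype, regardless of
parental origin, with an additive effect α_g and a dominance
(over-/under-dominance) effect δ_g. For a het × het mating the offspring
probabilities are

    P(AA) = (1 + α_g − δ_g)/4,  P(AB) = (1 + δ_g)/2,  P(BB) = (1 − α_g − δ_g)/4.

For het × hom matings only two offspring classes exist and the probabilities
are renormalised so they sum to one; e.g. for AA × AB,

    P(AA) = (1 + α_g − δ_g) / (2(1 + α_g/2)),  P(AB) = (1 + δ_g) / (2(1 + α_g/2)).

The BB × AB case is the exact mirror (labels swapped, α_g negated) — forced
by the symmetry of the parameterisation. δ_g > 0 is heterozygote excess
("heterosis" pattern), δ_g < 0 heterozygote deficit.

**Genotypic parameter space.** Two regions matter and are deliberately kept
distinct in the code:

* the *validity region* — all offspring probabilities in [0, 1]:
  |α_g| ≤ 1 and −1 ≤ δ_g ≤ 1 − |α_g|. The probability and likelihood
  functions are defined here.
* the *prior support* — additionally δ_g ≤ |α_g|, the coupled space used for
  the prior, the sampler and the Bayes-factor integration. The prior density
  is the product of the two conditional flat shapes, 2/(2 − 2δ_g) for
  δ_g > 0 (else ½) for α_g, and 1/(1 + |α_g|) for δ_g, renormalised
  numerically; only the shape matters because every use divides by the
  numerically integrated mass. (The |·| in the δ_g density makes the stated
  support and density mutually consistent for α_g < 0.)

One consequence worth knowing: a purely dominant distortion with α_g = 0 can
only be *negative* (heterozygote deficit) inside the prior support;
heterozygote excess requires |α_g| ≥ δ_g.

## Likelihoods share one observation space

All three models are scored on the same data: the offspring genotypes of
informative (het × het and het × hom) matings. Resolved transmissions enter
the allelic models as Bernoulli(½ + α) observations; the AB offspring of
het × het matings, whose parental origin is unresolvable without phase,
enter through their marginal probability p_s(1 − p_d) + (1 − p_s)p_d
(2p(1 − p) in the overall model). With no het × het AB observations this
reduces exactly to the familiar binomial over resolved counts. The genotypic
likelihood is the multinomial over het × het cells plus the renormalised
two-class terms per het × hom orientation (conditioning on mating
orientation). No combinatorial constants are included anywhere, so deviances
are directly comparable across models — the property the DIC pattern
classification depends on. Mendelian-inconsistent trios are excluded per SNP
(isolated inconsistencies indicate genotyping error at that marker); trios
with any missing member call are skipped at that SNP.

## Inference

**Sampler.** Random-walk Metropolis per SNP and model (Gaussian proposals,
default SD 0.05; proposals outside the constrained space carry zero prior and
are rejected). The spaces are 1–2 dimensional and bounded, so nothing fancier
is warranted. Two profiles: `study` (110,000 iterations, 10,000 burn-in) and
`desk` (11,000 / 1,000), the default for interactive work and tests; the
decision statistics (Bayes factor by quadrature, DIC from retained draws)
are iteration-robust, and the desk profile reproduces the conjugate solution
to Monte-Carlo error. Chains are seeded per SNP id (CRC32 mixed with the run
seed), so scan output is independent of SNP processing order. Point
estimates are posterior means; ESS is estimated by batch means.

**Bayes factor.** BF = (prior-integrated marginal likelihood of the TRD
model) / (likelihood at the Mendelian null). The overall-allelic marginal is
closed form: a flat prior on α is a uniform prior on p, giving
∫ p^kA (1−p)^kB (2p(1−p))^m dp = 2^m B(kA+m+1, kB+m+1) (the textbook
(1/(n+1)) / (C(n,k)·0.5^n) identity when m = 0). The parent-specific
marginal factorises into two such terms when no het × het AB offspring
couple the parents, and is otherwise a 201² midpoint quadrature over the
square; the genotypic marginal is a midpoint quadrature over the coupled
prior support. BF > 100 (log10 > 2) is "decisive" on Jeffreys' scale.
Explicit integration was chosen over Savage–Dickey density estimation for
exactness and testability.

**DIC.** DIC = 2·mean(D) − D(θ̂) with D = −2·loglik over retained draws and
θ̂ the posterior mean (componentwise median, then the best retained draw, if
the mean falls outside the constrained space near its boundaries). The model
with the lowest DIC wins a SNP if it beats the runner-up by more than 3
units; otherwise the simplest model within the margin is taken and the call
flagged as a tie. Within the allelic family the stallion/mare/overall
sub-label follows which parent-specific 95% interval excludes zero; genotypic
winners are labelled additive and/or heterosis the same way. The reported
|TRD| magnitude is the absolute posterior mean of the winning label's
parameter.

## Scan, empirical null, cascade, regions

SNPs enter the scan if they have ≥ 10 informative offspring and ≥ 2
informative parents of at least one sex ("informative parent" = heterozygous
with ≥ 1 Mendelian-consistent offspring observation at the SNP — the term is
defined here because the filter needs one; an "and" rule is available).
Informative-offspring counting is inclusive of het × het AB offspring by
default; a strict counter (resolved observations only) is provided.

The **empirical null** is built by gene-dropping: offspring genotypes are
re-drawn under Mendelian transmission conditional on the observed parent
genotypes of each informative SNP (replicates spread round-robin over SNPs),
preserving the informativeness structure the estimator sees. Each replicate
records the overall-allelic |TRD| posterior-mean magnitude, evaluated with
its exact conjugate closed form (a Beta posterior — the same estimand the
sampler approximates, computed exactly and cheaply). The threshold at margin
m is the (1 − m) empirical quantile; the default margin 0.001 requires
≥ 1,000 replicates and defaults to 10,000.

The **cascade** flags four gates separately so filtering is auditable:
decisive BF (> 100), magnitude above the null threshold, > 20 informative
offspring, and |TRD| > 0.2. A SNP must pass all four to seed a region.
Because the null threshold is derived from the overall-allelic estimator
while the compared magnitude belongs to the winning model (whose estimator
can be noisier — α_s uses only sire transmissions, α_g only genotype cells),
the raw exceedance fraction under the null runs above the nominal margin;
the decisive-BF gate is the primary chance control and the *joint*
chance-gate false-positive rate stays below the 0.1% margin (verified by the
calibration test at 10,000 null SNPs).

**Regions** are greedy chains of cascade-passing SNPs on one chromosome with
the same pattern label and inter-SNP gaps ≤ 1 Mb, keeping chains of ≥ 2
SNPs. The gap and minimum-size rules are explicit package decisions (linked
runs are reported in this field without a formal criterion); both are
configurable.

**Annotation** intersects a closed 1-based window of ± 250 kb (configurable)
around each candidate SNP with a BED (0-based half-open, converted on read)
or GFF3 gene table; genes containing the SNP are flagged "overlapping",
any-overlap counts as a hit (the common convention), strand is ignored.

## Synthetic data

The generator emulates the structure the analysis assumes: biallelic
autosomal SNPs with per-SNP allele frequencies drawn U[0.05, 0.5] (or
fixed), parents in Hardy–Weinberg proportions, and a mating design that
reuses 47 sires and 93 dams across 154 trios round-robin (a closed-studbook
structure; a random-mating mode exists). Null loci transmit Mendelian;
allelic-TRD loci bias each heterozygous parent's transmitted allele;
genotypic-TRD loci draw the offspring genotype directly from the
mating-type distribution of the genotypic model — exactly the likelihood
being tested, rather than a zygote-selection simulation. Optional stressors
set calls missing and perturb survivors to a uniformly chosen different
genotype. Pattern-assignment experiments fix the allele frequency at 0.35 so
injected loci have het × het matings — a dominance effect is unidentifiable
from het × hom matings alone, where it is confounded with allelic
distortion.

What the generator does *not* emulate: linkage disequilibrium between SNPs,
multi-generation pedigrees, allele-frequency spectra of real arrays, or
error processes correlated within samples. Passing tests therefore
demonstrate correctness of the estimators and the filtering logic under the
assumed sampling model, not robustness to LD-driven signal clustering or
systematic genotyping artefacts.

## Problem sizes and tolerances

Tests run the desk MCMC profile. The calibration check uses 10,000 null SNPs
over 150 trios with a 10,000-replicate null; parameter recovery uses 100
replicates per setting with 200 het × het offspring for the allelic
parameters and 4,000 for the genotypic pair (the additive parameter carries
half the per-observation precision, so the same ±0.05 band needs
proportionally more data). Monte-Carlo comparisons use 3-standard-error
bands at 95% required coverage with a 4-SE family-wise guard; the
closed-form Bayes factor is checked against adaptive quadrature at 1e-6
relative. Quadrature grids are midpoint rules (201 nodes per dimension in
the scan; finer grids change log10 BF by < 0.01 in spot checks).

## Known limitations

* Phase is never inferred; het × het AB offspring stay ambiguous.
* DIC comparability rests on the shared observation space; with no het × het
  matings the genotypic and allelic models describe the same data and are
  then distinguished mostly by their priors and dimension.
* The null threshold is calibrated for the overall-allelic magnitude only
  (see above).
* Parent-of-origin genotypic effects (imprinting-style terms) are not
  parameterised.
* Sample-level array QC, phasing and imputation are upstream of this
  package; marker-level QC (autosomes, call rate ≥ 0.95) is included.
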