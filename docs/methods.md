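# Methods

This package implements a complete, self-contained version of a
censoring/penalty study for the genetic evaluation of beef-cow longevity
with random regression models (RRM). Because real culling records of this
kind are proprietary, the study runs end-to-end on synthetic populations
whose generating parameters are known, which turns the pipeline into a
testable object: parameter recovery and scenario contrasts can be checked
against ground truth rather than against inaccessible data.

## Longevity indicators

Two longitudinal binary indicators are evaluated over whole-year ages
j = 2..15 (14 ages):

* **Traditional longevity (TL)** — 1 while the cow is alive, 0 from the
  culling age onward.
* **Functional longevity (FL)** — 1 at ages with a recorded calving, 0
  from the culling age onward, and a missing record at alive ages with no
  calving.

A *censored* cow has an unknown culling age; her information is truncated
at the last reported calving (TL: 1 up to that age, missing after; FL: 1
at calving ages, missing elsewhere). The culling-year code is 0 for both
indicators: "0 after culling" is ambiguous for the culling year itself,
and coding it 0 keeps TL monotone and TL/FL consistent on every age coded
0. Missing records simply drop out of the likelihood — the central
convenience of RRM for censored longevity data, since no cow is required
to have records at all time points.

## Model

For a record y_ij of cow i at age j,

    y = X b + H q + Z a + W p + e

where each random effect is a curve over age parameterized by k
coefficients on normalized Legendre polynomials of the standardized age
t* = 2(j - 2)/13 - 1:

* b — systematic effects: an embryo-transfer covariate plus fixed
  Legendre regressions per year-season of birth; prior N(0, Σb) with
  Σb = 10^10 I (vague).
* q — herd-year-season (HYS) curves, q ~ N(0, Rq ⊗ I). Contemporary
  groups are the concatenation herd x year x season and are random, so no
  constraint is placed on censored counts per group.
* a — additive genetic curves, a ~ N(0, G0 ⊗ A) with A the pedigree
  numerator relationship matrix.
* p — permanent-environment curves, p ~ N(0, Rp ⊗ I).
* e ~ N(0, I σe²), homogeneous across ages.

"Fourth order" polynomials are read as degree 4, i.e. k = 5 coefficients
per effect (the animal-breeding literature uses "order" for both k and
the degree; k is configurable and both conventions are supported).

Priors: Rq, G0, Rp ~ IW(ν=3, S) with small scale matrices (default
10⁻³ I; the exact scales are config-exposed because only "small prior
knowledge" is specified); σe² gets a scaled inverted chi-squared (default
ν=0, a proper posterior whenever records exist). ν=3 with k=5 is improper
as a prior; `PriorSpec.is_proper` reports this, and the prior-reproduction
test uses a proper configuration.

### Estimation

A Gibbs sampler updates location effects level-by-level from their
conditional normals (the single-site/blocked strategy of the gibbsf90
family, with a numba kernel; each animal's k-vector is one block, coupled
to pedigree neighbours through the sparse A⁻¹ assembled by Henderson's
rules with Meuwissen–Luo inbreeding). Covariance matrices are drawn from
their inverted-Wishart full conditionals (e.g. G0 | a ~ IW(ν + n_animals,
S + a'A⁻¹a)), the residual variance from its scaled inv-χ² conditional.
All randomness flows from one seeded numpy Generator, so chains are
bit-reproducible. Residuals are maintained incrementally and refreshed
from scratch every 250 iterations to prevent drift.

Two extra moves address the chain's slow directions, both exact:

* a **joint scale move** per random effect — a Metropolis proposal
  rescaling the effect and its covariance matrix together,
  (θ, M) → (√c θ, cM) with log c ~ N(0, 0.3²); the Gaussian prior ratio
  cancels the θ-Jacobian, leaving the likelihood ratio, a c^(−kν/2) term,
  and the inverted-Wishart scale term;
* an **interweaving sweep** for the additive / permanent-environment
  split — because Z and W carry identical covariates for recorded cows,
  the likelihood depends only on a_i + p_i, so the split is re-sampled
  from its prior-only Gaussian conditional (precision A⁻¹_ii G0⁻¹ + Rp⁻¹)
  each iteration.

Without these, independent chains disagree on the additive variance by
factors of 2–3 even after 80,000 iterations (the a/p split is identified
only through the pedigree, very weakly at low heritability). Exactness is
verified three ways: prior reproduction under an empty likelihood,
a conjugate closed-form toy posterior, and a brute-force grid integration
of the marginal variance posterior on a small half-sib model that the
sampler must match (test suite).

Chain presets: the published run lengths (150,000 / 50,000 burn-in /
thin 10) are preserved as `ChainConfig.paper()`; the default desk preset
is 5,000 / 1,000 / 5, which the recovery experiments below use. The
mixed-model equations (`assemble_mme` + `solve_blup`) provide the
deterministic oracle: with variance components held fixed the chain's
stationary mean is the BLUP solution, and the test suite verifies this to
Monte-Carlo error.

Convergence checking: Geweke's two-window z (first 10% vs last 50%,
spectral density at zero via Bartlett-windowed autocovariances with
~2·n^(1/3) lags) and Heidelberger–Welch (Cramér–von Mises on the Brownian
bridge of cumulative sums with iterative 10% discards, asymptotic 5%
critical value 0.4614, plus the halfwidth test at ε = 0.1).

### Age-scale quantities

With T the 14 x k Legendre covariate matrix over ages 2..15 and
posterior-mean coefficient covariances,

    Σ = T G0 T',  φ = T Rq T',  θ = T Rp T',
    h²_j = Σ_jj / (Σ_jj + φ_jj + θ_jj + σe²),
    EBV_i = T â_i.

Heritabilities use the posterior mean of the variance components (a
per-draw option exists for credible intervals). Negative diagonals from
numerical noise are clipped at zero and counted.

## Synthetic populations

The generator emulates the structure the model assumes plus the processes
the scenarios manipulate:

* **Pedigree** — `n_generations` discrete generations of `n_base_animals`
  each (default 5 x 850 ≈ 4,250 animals, ≈ 2,100 cows), random mating with
  dams drawn within herd and sires across herds, 15 herds, 2 seasons,
  birth years from 1990 with a 3-year generation interval.
* **True effects** — founders' a_i ~ N(0, G0); descendants get the parent
  average plus a Mendelian deviation with covariance
  (½ − ¼(F_s + F_d)) G0 (F = inbreeding, unknown parents treated as
  non-inbred base); p and q iid from Rp, Rq over animals / HYS classes.
* **Culling** — a latent annual score
  η_ij = μ_j + et_shift·ET_i + φ(t_j)'(a_i + p_i + q_h(i,j)) + e_ij on the
  same scale as the 0/1 codes; the cow is culled at the first age with
  η < 0.5. The per-age intercepts μ_j are set so an average cow's annual
  survival declines linearly from 0.93 (age 2) to 0.70 (age 15) — a
  herd-life pattern typical of beef cows, leaving ≈ 10% of cows alive past
  15. Survivors past 15 get a culling age uniform on (15, 20], emulating
  the natural-death inclusion rule. All random draws are made before the
  deterministic transform, so culling ages are monotone in μ under common
  random numbers.
* **Calving** — first calving at age 2 (22–29 months); each later year in
  production calves with probability 1 − `calving_skip_prob` (default
  0.15, i.e. ≈ 85% annual calving rate), allowing skip-and-reappearance
  patterns. Embryo-transfer cows (5%) get a small fixed shift on η so the
  systematic effect is estimable.
* **Quality control** — drops cows born before 1990, first calving at
  30 months or later, culling age above 20.

Default generating covariances use a structured coefficient matrix
(geometrically decaying weight on higher degrees, AR-type
cross-coefficient correlation) scaled to G0 = 0.016·M, Rq = 0.008·M,
Rp = 0.020·M with σe² = 0.09. On the age scale this gives additive
variance ≈ 0.006–0.015 over ages 2–12 with the late-age rise typical of
Legendre covariance functions, and latent heritabilities ≈ 0.06–0.12 —
deliberately low, matching what longevity/stayability traits show on the
observed scale.

**What the generator does not emulate**: the codes are deterministic
given the culling age (the fitted linear model's residual therefore
absorbs binomial-type noise rather than the latent σe², and estimated
σe² sits well below the generating value); culling reasons,
voluntary-vs-involuntary structure, genomic inheritance, and real
calving-interval dynamics are out of scope.

**Scale of the recovered parameters.** The linear model fitted to 0/1
codes estimates observed-code-scale quantities, not latent ones. The
package therefore provides a clone-pair simulation oracle
(`observed_scale_heritability`): pairs of cows share the additive
coefficients but draw independent PE/HYS/residual terms, so the
cross-pair covariance of the codes is exactly the generating additive
variance on the observed scale. For the default configuration the
observed-scale h² *rises* with age (≈0.01 at age 2 to ≈0.09 at age 12;
cumulative survival accumulates genetic signal) while the latent h² is
≈0.06–0.10. Converged fits at desk scale recover neither to within 0.05
at every age 2–12: the additive variance of the codes is attenuated
relative to the latent scale, and a 5-generation, ≈4,250-animal pedigree
separates additive from permanent-environment variance only weakly, so
the posterior mean of σ²_a undershoots at late ages. The recovery test
reports errors against both scales and is expected to fail at ages 10–12
at this population size; this is a property of the desk-scale design, not
of the estimator (which matches a brute-force posterior oracle on small
models).

## Censoring and penalties

Nested random censoring: one permutation of the base cows defines the
20/40/60/80% sets by prefix, so S20 ⊂ S40 ⊂ S60 ⊂ S80 by construction
and each level adds a uniform sample of the still-uncensored cows. Three
penalty criteria impute a culling age for censored cows from the last
reported calving: m1 — one year after, all cows; m2 — one year after for
cows older than nine years, younger cows stay censored; m3 — one year
after (older) / two years after (younger). "Older than nine years" is
the cow's age at the dataset reference date (evaluation year − birth
year, strictly greater than 9); an age-at-last-calving alternative is
config-exposed since the reference point is a genuine ambiguity. Imputed
ages are capped at 20 (the QC bound) with a warning. A censored cow with
no reported calving has no anchor: she stays censored (all-missing
records) rather than being dropped, keeping design counts exact.

Two designs decouple dataset size from censoring: D1 keeps a fixed pool
of U uncensored cows and adds level%·U censored/penalized cows (published
scale U = 55,000 → totals 55,000–99,000); D2 keeps the total fixed at N
with level%·N censored (N = 100,000 → 20,000–100,000 uncensored). The
percentage base for D1 is forced by the published totals. Sample counts
round to the nearest integer. Three replicates differ only in the
censoring permutation; the base population is fixed.

## Scenario contrasts

Per (trait, design, replicate), every scenario is contrasted against the
complete-data fit (COM): proportion of commonly selected animals among
the top 1% and 10% per age (reference-set denominator; ties broken by
EBV descending then animal id — the stable, documented convention),
Pearson EBV correlations over all animals and ages together, and age-4
correlations split by censoring status (age 4 is the recommended
selection age for these indicators; it is a parameter). Replicates are
aggregated as mean, sample SD, and SE; scenario differences use two-sided
paired t-tests at α = 0.05, uncorrected by default (a Bonferroni option
exists).

Two routes produce the scenario EBVs. The fully Bayesian route
(`run_study`) re-estimates the variance components inside every scenario,
as the original evaluations did; at desk scale its ranking contrasts
carry the chains' Monte-Carlo noise (see below). The fixed-components
route (`blup_scenario_ebvs`) solves the mixed-model equations at the
complete-data posterior-mean components — the way production evaluations
fix components at reference estimates — making scenario EBVs
deterministic, so COM-vs-scenario contrasts isolate the information
content of the censored or penalized records. The acceptance checks use
the Bayesian route for the variance contrast (which is inherently about
re-estimation) and the fixed-components route for ranking contrasts.
Large mixed-model systems are solved by Jacobi-preconditioned conjugate
gradients; small ones directly.

## Problem sizes and numerical choices

The published scale (100,000 cows, 150,000 iterations) is preserved in
configuration but the package's own experiments run scaled down:

* recovery experiments: the full default population (≈ 2,100 cows after
  QC, ≈ 4,250 animals in the pedigree), chains 12,000/5,000/5 (the
  5,000-iteration desk preset does not reach the variance components'
  stationary region and its estimates reflect the initialization); three
  replicates differing in population and chain seed. See "Scale of the
  recovered parameters" above for why the ±0.05 band fails at late ages.
* scenario grid: design 2 at scale 0.02 (N = 2,000), k = 3 basis, chains
  8,000/3,000/5, one replicate; censoring for both indicators, first
  penalty for FL. Chain-to-chain Monte-Carlo noise remains the limiting
  factor for scenario contrasts at this scale: two chains on identical
  data agree on EBVs only to r ≈ 0.89 (top-10% self-overlap ≈ 0.66), so
  directional patterns carry appreciable noise at a single replicate.
* solver tolerances: sparse LU for the MME oracle (residual norm
  reported); CG alternative at rtol 1e-10. A⁻¹ is exact on test pedigrees
  to 1e-10; Legendre orthonormality holds to 1e-6 under quadrature.
* ties in top-k selection and in censoring sampling are seed-stable;
  every stochastic step draws from `numpy.random.Generator` seeded via
  `SeedSequence` from user-visible integers.

## Known limitations

* The linear probability RRM on deterministic 0/1 codes is an
  approximation of the generating threshold process; recovered residual
  and age-specific variances are on the observed-code scale.
* k = 5 for both the fixed and random regressions (the fixed-regression
  order is unstated in the source design; sharing the basis is the
  conventional choice).
* No genomic relationships, heterogeneous residuals, threshold links, or
  survival-analysis codings; genetic correlations between TL and FL are
  not estimated (the indicators are fitted separately by design).
* Single-site Gibbs mixes slowly for G0 when censoring removes most
  late-age records; the desk presets are sized so the reported posterior
  means are stable at the scales above, not for publication-grade
  effective sample sizes.
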