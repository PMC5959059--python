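# Methods

## Model

Each race trait is a binary indicator that a pigeon's accumulated lifetime
race distance (TD, km) reached one of five thresholds (500, 1000, 2000,
3000, 4000 km; category 2 = reached, 1 = not).  TD equal to a threshold
codes as reached by default; the comparison operator is switchable
(`comparison="gt"`), since boundary handling at exact threshold values is a
convention, not a datum.  The five traits are analysed independently, each
under the liability-threshold animal model

    L_ij = SEX_i + u_j + e_ij,
    u ~ N(0, A σ²u),   e ~ N(0, I σ²e),   Y_ij = 1 ⟺ L_ij ≤ t.

`A` is the numerator relationship matrix of the full pedigree, so `u`
covers unphenotyped ancestors as genuine predictions.  A binary threshold
model is identified only up to location and scale; we fix the threshold at
t = 0 and the residual variance at σ²e = 1.  The km values therefore never
enter the likelihood — they act only in phenotype coding.  Heritability on
the liability scale is h² = σ²u / (σ²u + 1).

## Pedigree machinery

`A` is built densely by the tabular recursion (a_ij = mean of j's
relationships to i's parents; diagonal 1 + F with F from the parents'
relationship).  Unknown parents are unrelated, non-inbred founders;
referenced-but-unlisted parents are materialized as phantom founders.  The
inverse is assembled directly and sparsely by Henderson's rules with
Mendelian-sampling variances that account for parental inbreeding
(0.5 − 0.25(F_s + F_d) with both parents known, 0.75 − 0.25 F_p with one,
1 for founders).  The topological sort is a stable Kahn's algorithm, so
re-running on the same input reproduces the same animal order.  Dense `A`
is O(q²) memory — fine at the few-thousand-animal scale this pipeline
targets.

## Gibbs sampler

Classical single-trait data augmentation, per iteration:

1. **Liabilities** — truncated normals with mean `SEX + u`, variance σ²e,
   truncated to (−∞, 0] or (0, ∞) by the observed category.  Draws use
   inverse-CDF sampling in log space (`ndtri_exp` of `log_ndtr` tail
   masses), which stays finite and on the correct side even when the mean
   is tens of residual SDs from the threshold.
2. **Location** — sex effects and all breeding values as one joint draw
   from their conditional normal, via an exact block factorization of the
   mixed-model equations.  Writing A = L_A L_Aᵀ and diagonalizing
   G = (Z L_A)ᵀ(Z L_A) = Q S Qᵀ once per pedigree/phenotyped set, the
   breeding-value block becomes diagonal (S + λI, λ = σ²e/σ²u): sex
   effects are drawn from their marginal conditional with u integrated out
   (a Woodbury identity in the same eigenbasis), then the rotated breeding
   values given the drawn sex effects.  Because p(b, u | ·) =
   p(b | ·) p(u | b, ·), this is the same joint draw a dense Cholesky of
   the full coefficient matrix would give, at O(n·q) per iteration instead
   of O(q³).  A literal dense-MME draw (`sample_location`) is retained and
   the two are tested against each other.
3. **Additive variance** — scaled inverse chi-square with df ν_u + q and
   sum of squares uᵀA⁻¹u + ν_u S_u; in the rotated basis uᵀA⁻¹u = |w|².
   A floor of 1e-6 prevents absorption at zero.

Default schedule: 51,000 iterations, 1,000 burn-in, thinning 25 → 2,000
retained draws.  The original analysis's schedule (5,050,000 / 50,000 /
2,500, same 2,000 retained draws) is available via
`GibbsConfig.with_paper_schedule()` / `--paper-schedule`; the scaled
schedule was adopted as the default because the sampler's retained-draw
count and the parameter-recovery behaviour match at a fraction of the
cost.  Chains are fully reproducible given seed + config + data.
Diagnostics report effective sample size (arviz) and a Geweke z with
ESS-adjusted segment variances.

### Prior on σ²u

Default is the flat improper prior ν_u = −2, S_u = 0.  A caution that the
package's own experiments make concrete: with binary data whose incidence
is extreme (roughly < 10%) and strong full-sib family structure, whole
families can sit in one category and the likelihood then fails to bound
σ²u from above — under the flat prior the chain drifts upward without
bound (a long-chain check on such a trait showed quarter-means of h²
rising 0.70 → 0.99).  For such traits a proper, weakly informative scaled
inverse chi-square prior should be used; the acceptance script's
study-scale analysis uses ν_u = 4, S_u = 0.5 (prior mean σ²u = 1, i.e.
h² ≈ 0.5, worth ~4 records of information against 867 observations).
Moderate-incidence traits give essentially the same posterior under either
prior.

## EBV and DEBV

The EBV is the posterior mean of u_j over retained draws (posterior SD
reported alongside).  DEBV = 50 + 10 (EBV − mean_ref)/sd_ref with the
sample (n−1) SD, applied to all animals but centred and scaled on a
reference set.  The default reference is every animal in the fitted
pedigree; `phenotyped` and `genotyped` are selectable.  A proper subset of
the reference set generally has mean ≠ 50 — which is why a genotyped
subgroup can legitimately report trait means in the mid-40s.

## Microsatellite summary and association

Fragment sizes map to allele labels by exact match, else nearest bin
within ±2 bp (equidistant sizes are an error, or unassigned by config).
Missing genotypes are excluded from all denominators.  Hardy–Weinberg:
default asymptotic chi-square against expected counts from observed allele
frequencies, df = k(k−1)/2, flagged when any expected count < 5; a seeded
Monte-Carlo exact test (permutation of alleles into genotypes, tables
compared by conditional probability) is available and agrees with the
chi-square when expected counts are large.

Carrier status is S+ iff the genotype holds ≥ 1 copy of the target allele.
Association is OLS of DEBV on carrier group, F-test on the group contrast;
with two groups and no covariates this equals the pooled-variance t-test
exactly.  Sex is available as an optional covariate; no relatedness
correction is applied (the DEBV of genotyped birds is regressed directly),
and no multiple-testing correction belongs to the primary report — a
Bonferroni column is emitted as clearly supplementary.  Type-I calibration
of the raw regression is asserted for unrelated cohorts; in a pedigreed
cohort a neutral marker and the EBVs are both family-correlated, so raw
p-values there are not exactly calibrated.  That limitation is inherent to
the regress-DEBV-directly design this package reproduces.

## Synthetic-data generator

Defaults mirror the target study's scale: 237 founders plus 5 generations
of 60 random non-selfing matings × 6 offspring = 2,037 animals; the
youngest 867 are phenotyped and a random 127 of those genotyped.  Breeding
values are gene-dropped (founders N(0, σ²u); offspring parent-average plus
Mendelian deviation with inbreeding-adjusted variance), which gives
cov(u) = σ²u A exactly — the generator and the A-matrix builder therefore
validate each other by Monte Carlo.  Genotypes: founders at Hardy–Weinberg
proportions with allele frequencies defaulting to the characterized
cohort's (S 0.146, M 0.614, L 0.240), descendants by Mendelian
transmission.  The liability adds a sex effect
(±0.1, a 0.2-liability-unit male−female gap — modest, as sex gaps in race
performance typically are) and optionally β per target-allele copy.

TD is generated only to exercise phenotype coding faithfully: liability
cut-points are solved so that P(liability > c_k) equals the configured
incidence per threshold (under the exact normal-mixture marginal over sex
and allele count), the bird's band is chosen by how many cut-points its
liability exceeds, and TD is drawn uniformly inside the band.  The uniform
within-band distribution is arbitrary and carries no information; only the
band pattern matters, and re-encoding reproduces it exactly.  Default
incidences (0.55, 0.40, 0.25, 0.15, 0.08) are a plausible survival-like
decay; the real per-threshold incidences are unpublished.

What the generator does *not* emulate: race-by-race events, hazard
processes, loft/breeder effects, selection of mates by merit, overlapping
generations, genotyping error.  Passing recovery tests therefore show the
inference chain is self-consistent under its own model, not that the model
captures every feature of real racing data.

## Problem sizes and numerical choices

The recovery tests run ~1,000 phenotyped birds in a 1,400-animal pedigree
with the 51,000-iteration schedule (≈1 minute per fit on one CPU); the
acceptance script runs the full 2,037/867/127 scale for all five traits.
Posterior means at these sizes carry Monte-Carlo and small-sample error of
a few hundredths in h²; the recovery tolerance is ±0.10.  Cut-point
solving uses Brent's method on the mixture tail; incidences of exactly 0
or 1 map to infinite cut-points.  Eigenvalues of G are clipped at zero
before use; the degenerate identical-groups association reports effect 0,
p = 1 by convention.  Known limitations: single-trait analyses only (no
multi-trait or ordinal model), no REML cross-fit, dense A storage, and the
flat-prior caveat above.
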