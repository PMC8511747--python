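# Methods

This note documents the models behind each `coralqg` stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that affect results.

## The experimental design being modelled

A clonal-replicate factorial experiment: `G` coral genotypes (genets), each
fragmented into clone-mates, exposed to four treatments formed by crossing
elevated temperature with elevated pCO2 (`control`, `high_temp`,
`high_pco2`, `combined`).  Tanks are the unit of treatment replication —
`K` tanks per treatment, each holding exactly one clone-mate of every
genotype — so at the defaults (G = 12, K = 5) there are 20 tanks and
12 × 4 × 5 = 240 fragments.  Because genets are clones, genotype-associated
variance estimates *broad-sense* heritability: the summed contribution of
genetic, epigenetic and maternal effects, not the additive (narrow-sense)
component.

## Synthetic-data generator

One trait value for genotype *g* in tank *k* of treatment *j*:

    y_gjk = μ (1 + Δ_j) + a_gj + t_k + e_gjk

- μ is the control mean; Δ_j the relative treatment effect (Δ_control = 0).
- The genotype effect vector (a_g,control, …, a_g,combined) is multivariate
  normal with variance `v_genotype` and exchangeable cross-treatment
  correlation ρ_G.  ρ_G is a modelling construct of this package: it is the
  minimal structure that makes both heritability (shared genotype effect)
  and cross-treatment genotype correlations (tradeoff screening) meaningful
  in one generator.  Positive-semi-definiteness of the exchangeable 4 × 4
  covariance requires ρ_G ≥ −1/3; the generator rejects anything lower, so
  strong *negative* cross-treatment correlations cannot be simulated under
  this structure (the tradeoff-calling code is instead validated on
  directly constructed genotype-mean matrices).
- t_k ~ N(0, v_tank) and e ~ N(0, v_residual).
- The combined-treatment effect is derived from the additive null
  A = Δ_temp + Δ_pco2: `additive` mode uses A exactly; `synergistic` adds
  `interaction_magnitude` beyond A (further from control, in A's
  direction — extra decline when A < 0); `antagonistic` subtracts it.  The
  offset is additive on the relative-difference scale because that is the
  scale on which the additive-null comparison is defined.  When A = 0 the
  direction convention defaults to decline.
- Optional `value_floor` clips values (clip counts are reported in
  `table.attrs`); optional fragment-level dropout emulates mortality.

Ground truth per trait: `H² = v_genotype / (v_genotype + v_tank +
v_residual)`, the deltas, and the interaction mode — written to a sidecar
JSON for recovery tests.

### Default trait panel

Twelve traits emulate a holobiont/host/symbiont phenotype panel (buoyant
weight; light and dark calcification; P:R ratio; symbiont density; soluble
protein; the immune enzymes PPO, PO, POX; photochemical yield; maximum
electron transport rate; total chlorophyll).  Defaults were fixed once to
mirror the qualitative pattern such experiments report:

- declines of roughly 10–55 % under single stressors, with synergistic
  combined responses for cumulative traits (buoyant weight, symbiont
  density, protein, ETRm, chlorophyll) and antagonistic ones for
  calcification, P:R and the immune enzymes; P:R has opposing-sign single
  stressor effects (temperature decreases it, pCO2 increases it);
- H² ≈ 0.55–0.60 for buoyant weight and the immune enzymes, ≤ 0.2 for the
  rest;
- ρ_G = 0.7 for traits that show positive cross-treatment genotype
  correlations (P:R, protein, symbiont density, immune enzymes, ETRm,
  chlorophyll) and 0.2 elsewhere;
- total phenotypic coefficient of variation 10 % of the control mean, with
  5 % of the variance assigned to tanks;
- control means in plausible trait units (e.g. 0.8 g buoyant-weight gain,
  Fv/Fm of 0.65, 2.5 mg cm⁻² protein).

What the generator does **not** emulate: time series within the exposure,
carbonate-chemistry dynamics, non-Gaussian trait distributions, correlated
residuals among traits measured on the same fragment, and trait-specific
missingness patterns.  Passing recovery tests on these data therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data features.

## PERMANOVA

Distance-based one-way partition: with pairwise distances d_ij among n
observations, `SS_total = Σ_{i<j} d²_ij / n`, `SS_within` sums the same
quantity within each of k groups, and

    pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k)),   R² = SS_between/SS_total.

The p-value permutes group labels over observations with the estimator
`p = (1 + #{F* ≥ F}) / (1 + n_permutations)`, which can never return 0; 999
permutations by default, seeded.  Pairwise two-group tests multiply raw p by
the number of pairs (Bonferroni), so the smallest attainable adjusted p with
999 permutations and 6 pairs is 6/1000 = 0.006.

Choices: the default analysis unit is the genotype × treatment mean profile
(48 observations at the defaults, total df 47), with fragment-level profiles
by flag; the default metric is Euclidean distance on natural-log values,
with Bray–Curtis by flag — the metric is a package default, labelled as an
assumption in output, since it is rarely stated in this literature.
Non-positive values under the log raise an error with a hint to pass an
explicit `log_offset`; nothing is offset silently.  An exhaustive
enumerator over all distinct label assignments serves as the brute-force
oracle at small n.

## Linear mixed model

Per trait: fixed treatment, genotype and their interaction (sum-to-zero
coding), one random tank intercept, Gaussian errors.  REML estimation
profiles the criterion over the single variance ratio λ = V_tank/V_residual
(bounded scalar optimisation in log λ to a tolerance of 1e-8 on the ratio,
with the λ = 0 boundary checked explicitly and reported, never dropped);
because tanks partition the data, each evaluation uses per-tank Woodbury
identities.  Fixed effects are GLS at the REML optimum; on balanced data
they equal cell-mean contrasts and the variance components equal the ANOVA
method-of-moments estimators, which serve as an oracle in tests.

F-tests are Type-III Wald statistics.  Denominator df default to
*containment*: treatment effects are replicated at tank level, so
df = n_tanks − n_treatments (16 at the defaults); genotype and interaction
vary within tanks and use fragment-level residual df
(n − p − (n_tanks − n_treatments) = 176 on the balanced default).  A
Satterthwaite approximation (delta-method df per eigencontrast, combined
for multi-df terms; variance of the variance-component estimates from a
finite-difference REML Hessian) is available because the major mixed-model
packages default to it; on balanced data the two agree closely.

Tukey HSD p-values transform each pairwise treatment contrast to a
studentized range statistic `q = √2 |est|/se` and use the studentized range
distribution with k = 4 groups at the treatment test's denominator df.
Missing fragments are dropped listwise per trait with counts reported; a
genotype entirely absent from a treatment is a singular design and raises
an error naming the empty cell.

## Bayesian heritability

Gaussian mixed model with fixed temperature, pCO2 and their interaction
(2 × 2 indicator coding of the four treatments) and scalar random genotype
and tank intercepts.  All full conditionals are conjugate, so a plain Gibbs
sampler is exact: normals for β (improper flat prior) and the random-effect
vectors, inverse-gamma for the three variance components.  Priors default
to IG(0.001, 0.001) on each variance — a weakly informative, near-flat
choice matching common practice in this literature; it is configurable and
flagged as an assumption in output.  Defaults: one chain of 50 000
iterations, 10 000 burn-in, thinned every 20 → exactly 2000 retained draws
per parameter.

H² is computed per retained draw as V_genotype/(V_genotype + V_tank +
V_residual) and then summarised (mean, 2.5/50/97.5 % quantiles) — a
posterior of the ratio, not a ratio of posterior summaries.  Diagnostics
(effective sample size and split-chain R-hat on the H² chain, via arviz)
warn rather than fail.  `scope="per_treatment"` refits the model inside
each treatment subset with an intercept-only fixed part.

Interpretation caveat: the generative model draws genotype effects per
treatment with correlation ρ_G, while this estimator (by design) uses one
scalar genotype effect.  When ρ_G < 1 part of the genetic variance is
genotype × treatment variance, which the scalar model assigns to the
residual, so estimated H² is attenuated relative to the generator's
single-treatment ground truth.  Recovery and coverage tests therefore use
ρ_G = 1, where the estimator's model and the generator coincide; runs on
the default trait panel (ρ_G 0.2–0.7) show the expected attenuation.

## Interaction classification

Relative effects Δ_T = (mean_T − mean_control)/mean_control over fragments;
additive null A = Δ_temp + Δ_pco2; deviation reported both signed
(Δ_combined − A) and as the magnitude difference |Δ_combined| − |A| that
operationalises "exceeding the additive line" for declining traits.  The
three-way call uses a bootstrap CI of the magnitude deviation: fragments
are resampled with replacement within (treatment, tank) strata, preserving
the design structure; synergistic if the 95 % CI lies above the tolerance
band (default tolerance 0), antagonistic if below, additive otherwise.
`n_boot=0` gives a pure point-estimate reading of the deviation sign.
Traits whose two single-stressor effects have opposing signs are flagged
rather than force-classified — the magnitude comparison is genuinely
ambiguous there.  A numerical guard of 1e-9 keeps exact-zero deviations
from being classified by floating-point noise.

## Tradeoff correlations

Genotype means per trait × treatment (a complete cube is required; empty
cells raise with the offending genotype/treatment named).  Pearson r per
pair with the exact t transform `t = r √((n−2)/(1−r²))`, n−2 df, two-sided;
Spearman by flag.  Calls: *tradeoff* iff significant and r < 0,
*broad-spectrum* iff significant and r > 0, at unadjusted α = 0.05 by
default — matching how such matrices are usually read — with an optional
Holm adjustment reported alongside, never silently substituted.  The three
stressor-pair comparisons (high_temp–high_pco2, high_temp–combined,
high_pco2–combined) are tagged as key comparisons.  Zero-variance vectors
yield an `undefined` entry instead of a spurious call.

## Reproducibility and problem sizes

All randomness flows through explicit seeds; per-stage seeds in the
pipeline derive from one global seed via `numpy.random.SeedSequence`, so a
pipeline bundle is byte-reproducible from (config, seed).  Simulation-based
validation uses problem sizes chosen to give tight Monte-Carlo error at
interactive runtimes: 100 datasets per level (shortened 4000-iteration
chains) for H² interval coverage, 300–400 null datasets for type-I
calibration of the PERMANOVA and mixed-model tests, and 300 datasets for
the tradeoff false-positive rate, with acceptance bands of ±3 binomial
standard errors around the nominal values.

## Known limitations

- One random effect in the frequentist model (tank); no crossed or
  genotype-level random terms there — genotype is fixed in that framing and
  random only in the Bayesian variance partition, which matches how the two
  analyses are conventionally specified but means the two stages answer
  different questions about genotype.
- No genotype × treatment random interaction in the Bayesian model (scalar
  genotype effect); see the attenuation caveat above.
- The additive null is the only interaction reference implemented (no
  multiplicative or dominance nulls).
- Pearson/Spearman genotype-mean correlations, not model-based genetic
  correlations; with 12 genotypes their power is modest and |r| must exceed
  ≈ 0.58 for significance at α = 0.05.
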