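# coralqg

Quantitative-genetic analysis of factorial multi-stressor coral experiments.

`coralqg` implements the statistical chain used to analyse clonal-replicate
aquarium experiments in which fragments of `G` coral genotypes (genets) are
exposed to a 2 × 2 temperature × pCO2 design — `control`, `high_temp`,
`high_pco2`, `combined` — with tanks as the unit of treatment replication and
one clone-mate of every genotype in each tank.  It is written for coral
restoration scientists and quantitative geneticists who need to answer four
questions from such a design:

1. **Do treatments shift the multivariate phenotype?**  One-way PERMANOVA on
   log-transformed phenotype profiles: the pseudo-F ratio of between- to
   within-group distance-based mean squares, tested by label permutation,
   with Bonferroni-corrected pairwise follow-ups.
2. **Which traits respond, and where?**  Per-trait Gaussian mixed models
   `value ~ treatment * genotype + (1 | tank)` fitted by REML, F-tests with
   containment (or Satterthwaite) denominator df, Tukey HSD post hoc
   comparisons from the studentized range distribution.
3. **Is variation heritable?**  Broad-sense heritability by Gibbs-sampled
   Bayesian variance partitioning with random genotype and tank effects:
   `H² = σ²_genotype / (σ²_genotype + σ²_tank + σ²_residual)`, computed
   draw-wise and summarised as a posterior mean with 95 % credible interval.
4. **Do stressors interact, and do tolerances trade off?**  Each trait's
   combined-stressor response is compared with the *additive null*
   `Δ_temp + Δ_pco2` of relative effects and classified synergistic /
   additive / antagonistic with a stratified-bootstrap CI; genotype-mean
   Pearson correlations between treatments flag *tradeoffs* (significant
   negative r) vs *broad-spectrum resistance* (significant positive r).

A synthetic-data generator reproduces the experimental design (default: 12
genotypes × 4 treatments × 5 tank replicates = 240 fragments, 12 traits)
with known variance components, interaction modes and cross-treatment
genetic correlations, so every stage can be validated against ground truth.
See `docs/methods.md` for the models, priors and numerical choices.

## Worked example

```python
import coralqg as cq
from coralqg.heritability import ChainConfig

table = cq.generate(cq.DesignSpec(seed=42))      # 240 fragments × 12 traits
X, groups = cq.profile_matrix(table)             # 48 genotype×treatment log profiles
res = cq.permanova_test(X, groups, n_permutations=999, seed=1)
print(f"PERMANOVA: F_{res.df_between},{res.df_total} = {res.pseudo_F:.2f}, "
      f"R2 = {res.R2:.3f}, p = {res.p_perm:.3f}")

fit = cq.fit_lmm(table, "buoyant_weight")        # REML, tank random intercept
a = fit.anova_.set_index("term")
print(f"buoyant weight: treatment F_{a.loc['treatment','df_num']:.0f},"
      f"{a.loc['treatment','df_den']:.0f} = {a.loc['treatment','F']:.2f}, "
      f"p = {a.loc['treatment','p']:.2g}")

dec = cq.fit_h2(table, "buoyant_weight", ChainConfig(seed=1))
s = dec.summary
print(f"H2(buoyant weight) = {s['h2_mean']:.2f} [{s['h2_q2.5']:.2f}, "
      f"{s['h2_q97.5']:.2f}] ({s['n_draws']} draws)")

rep = cq.classify_interaction(table, "buoyant_weight", n_boot=2000, seed=1)
print(f"interaction: combined {rep.delta_combined:+.2f} vs additive null "
      f"{rep.additive_null:+.2f} -> {rep.label}")
```

prints

```
PERMANOVA: F_3,47 = 141.90, R2 = 0.906, p = 0.001
buoyant weight: treatment F_3,16 = 344.09, p = 9.8e-15
H2(buoyant weight) = 0.25 [0.11, 0.48] (2000 draws)
interaction: combined -0.47 vs additive null -0.23 -> synergistic
```

Reading the output: treatments explain 90.6 % of multivariate distance among
the 48 genotype × treatment mean profiles, and no permutation reached the
observed pseudo-F (p = 1/1000).  The treatment effect on buoyant weight is
tested against tank-level replication (16 denominator df = 20 tanks − 4
treatments).  The H² posterior mean of 0.25 on this simulated dataset sits
below the generating value (0.57) because the default generator gives this
trait a cross-treatment genetic correlation of only 0.2, so a scalar
genotype effect captures part of the genetic variance — see the methods
note.  The combined treatment's −47 % response exceeds the −23 % additive
null: a synergistic (amplifying) stressor interaction.

Every stage is also available from the shell:

```bash
coralqg simulate --seed 42 --out table.csv --truth truth.json
coralqg permanova --input table.csv --nperm 999 --seed 1 --out permanova.json
coralqg run --seed 42 --outdir results/   # all five stages, one report bundle
```

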