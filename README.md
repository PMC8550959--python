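# persnet

Deep-NMF set networks for temperament/character cohorts: bicluster a
subjects × features matrix into "sets", relate sets across data domains
through the subjects they share, and organize the significant relations
into a small number of near-disjoint genotype–phenotype–environment
networks scored against well-being and ill-being indices.

## The problem

Personality questionnaires such as the Temperament and Character
Inventory (TCI) measure four temperament scales (Novelty Seeking NS,
Harm Avoidance HA, Reward Dependence RD, Persistence PS) and three
character scales (Self-directedness SD, Cooperativeness CO,
Self-transcendence ST), each composed of subscales.  Subgroups of people
share distinctive multi-subscale configurations, and the same subgroups
tend to carry particular SNP combinations and environmental exposures.
`persnet` implements the full unsupervised analysis that uncovers this
architecture:

1. **Biclustering.** Each nonnegative subjects × features matrix
   (temperament subscales, character subscales, SNP dosages, coded
   environment variables) is factorized, `X ≈ WH` with `W ≥ 0, H ≥ 0`,
   at every rank in a range.  Each factor yields one *set* (bicluster):
   the subjects and features with high loadings on that factor.
   Consensus clustering over random restarts scores rank stability by
   the cophenetic correlation coefficient.
2. **Relations.** Every pair of sets from two collections is tested for
   shared subjects with the exact upper-tail hypergeometric probability
   `P(X ≥ k)` (computed in log space), Fisher's exact test, and an
   empirical permutation null; a relation is significant only when the
   BH-corrected analytic test *and* the permutation test agree.
3. **Networks.** The weighted bipartite relation matrix (−log₁₀ p,
   capped) is itself factorized at rank k = 3; each set joins its
   maximal factor, subjects join the weighted plurality network of
   their sets, and networks are numbered 1..3 by ascending mean
   well-being.
4. **Health.** Well-being = top decile of the product SD×CO×ST of
   character scale totals; ill-being = bottom decile of SD+CO.  Networks
   are compared by one-way ANOVA and Tukey HSD on set-level health
   probabilities, and cross-validated OLS measures the variance in
   network membership explained by genotype sets, environment sets, and
   both.
5. **Replication.** The whole pipeline reruns blindly on a second
   cohort; sets are matched across cohorts by shared *features*
   (subjects differ), and a discovery relation replicates when both
   endpoints match and the matched pair is significant in the
   replication run.

Because no real cohort ships with the package, a synthetic-cohort
generator with planted, fully known structure (three networks of
temperament/character/SNP/environment blocks, configurable effect size,
noise, disjointness, and a 5% unassigned background) provides the ground
truth every guarantee is tested against.

## Worked example

```python
import persnet as pn

cfg = pn.CohortConfig(seed=1)                    # 2000 subjects, 3 networks
phen, gen, env, truth = pn.generate_cohort(cfg)
result = pn.run_pipeline(phen, gen, env, pn.PipelineConfig(seed=1))
print(result.summary())
```

prints

```
{'n_temperament_sets': 33, 'n_character_sets': 34,
 'n_significant_relations': 276, 'network_sizes': {1: 628, 2: 633, 3: 638},
 'unassigned_fraction': 0.0505, 'n_genotype_sets': 28,
 'n_environment_sets': 22, 'env_direct': 19, 'env_indirect': 1, 'env_both': 0}
```

33 temperament and 34 character sets were pooled over NMF ranks 2–8; 276
of their pairings share significantly more subjects than chance, and the
relation graph splits into three networks of 628/633/638 subjects with
5.05% of subjects unassigned (the generator planted 5% background).
Health separates the networks:

```python
comp = result.comparisons["well"]
print({g: round(m, 3) for g, m in comp.group_means.items()},
      "F =", round(comp.f_statistic, 2), "p =", f"{comp.p_value:.2e}")
rep = result.variance["well"]
print("R2 well-being: genotype", round(rep.r2_genotype, 2),
      "environment", round(rep.r2_environment, 2),
      "joint", round(rep.r2_joint, 2))
```

```
{1: 0.068, 2: 0.094, 3: 0.196} F = 37.65 p = 5.01e-11
R2 well-being: genotype 0.65 environment -0.0 joint 0.65
```

Mean set-level well-being rises across networks 1 → 3 (the ordering is
by construction), the difference is highly significant, and genotype
sets alone explain about 65% of the cross-validated variance in network
membership for this cohort.

A console script mirrors the library:

```bash
persnet simulate --out cohort/ --seed 1
persnet pipeline --out result/ --seed 1
persnet bicluster --in cohort/phenotype.tsv --domain character --out sets/
```

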