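# rangediv

Range-wide population-genetic analysis for co-dominant markers — built for
the question "which factors and processes shape the distribution of genetic
variation across a species' range?" in patchily distributed, passively
dispersed organisms such as freshwater snails and other lentic
invertebrates.

Given microsatellite genotypes grouped by sampling site, aligned
mitochondrial sequences, and a per-site table of coordinates, climate
variables and curated factors, the package computes:

- **Per-site diversity** — unbiased expected heterozygosity
  `H_E = n/(n-1) · (1 − Σ p_i²)`, and allelic / haplotype richness
  standardized by hypergeometric rarefaction
  `E[A_g] = Σ_i [1 − C(N−N_i, g)/C(N, g)]`.
- **Mating system** — the g2 identity-disequilibrium estimator of the
  selfing rate: the standardized excess of joint heterozygosity over locus
  pairs, inverted through the mixed-mating equilibrium relation
  `g2(s) = s / ((4−s)(1−s))`, with a locus-permutation test of `g2 = 0`.
  Because g2 depends only on het/hom states it is robust to null alleles
  and partial dominance, unlike F_IS-based selfing estimates.
- **Bottlenecks** — the heterozygosity-excess test under a two-phase
  mutation model (TPM, 90% single-step, geometric multi-step variance 12):
  coalescent simulation of the equilibrium gene-diversity distribution
  conditioned on the observed allele count, summarized across loci by an
  exact one-tailed Wilcoxon signed-rank test. Applied only to populations
  with an estimated selfing rate of zero.
- **Differentiation** — multi-locus Weir–Cockerham θ (overall and
  pairwise), haplotype-frequency AMOVA F_ST, linearized F_ST = F/(1−F),
  Mantel tests of isolation by distance (10,000 permutations by default),
  and the minimum spanning tree of the linearized matrix.
- **Predictors** — distance to the range margin (convex hull of all
  sites), environmental marginality (distance from the origin of the
  Kaiser-retained axes of a correlation-matrix climate PCA),
  85%-quantile contrast groups, and the refugial/Holocene merge rule
  (classes merged when permutation tests find no diversity difference).
- **Model selection** — all-subsets additive OLS of each diversity measure
  on the predictors, scored by AIC or AICc and compared through Akaike
  weights `w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`.
- **Class contrasts** — permutation tests of mean within-class pairwise
  F_ST against the remaining sites (1000 label shuffles by default).

A forward-time metapopulation simulator (`rangediv.synth`) generates
genotype, haplotype and site tables with known ground truth — mixed mating,
distance-independent jump dispersal, serial founder events along a
SW–NE expansion axis — and backs the calibration and power tests.

## Worked example

```
$ python examples/02_differentiation_and_dispersal.py
overall F_ST (theta): 0.204
Mantel r = -0.053, one-sided p = 0.681 over 20 sites
first five MST edges (site_a, site_b, linearized F_ST):
  S01 -- S20  0.068
  S16 -- S20  0.074
  S07 -- S20  0.094
  S08 -- S20  0.103
  S01 -- S03  0.107
```

The overall θ of 0.204 says a fifth of the total variation lies among
populations; the Mantel p of 0.68 means genetic and geographic distance are
uncorrelated (no isolation by distance), so connectivity is better read
from the spanning-tree edges than from the map. The other scripts in
`examples/` cover diversity and rarefaction, selfing and bottleneck
inference, and all-subsets model selection, each printing the numbers it
computes with a line on what they mean.

The full pipeline is one call (or `rangediv run` from the shell):

```python
import rangediv as rd
geno, haps, sites, truth = rd.simulate_metapopulation(rd.scenario_range_expansion(), seed=1)
bundle = rd.run_pipeline(geno, sites, haps, rd.PipelineConfig(seed=1))
rd.report(bundle, "out/")
```

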