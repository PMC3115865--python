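# Methods

This note documents the statistical machinery, the defaults and the design
choices of `rangediv`, in the order the pipeline runs them.

## Inputs and thresholds

Genotypes are diploid multi-locus co-dominant calls (microsatellite allele
lengths), read from GENEPOP (2- or 3-digit) or a long-form CSV; a call is
either fully present or fully missing. Mitochondrial sequences arrive as a
pre-aligned FASTA plus an individual→site assignment; sequences with fewer
than 400 non-gap positions are dropped and haplotype identity is exact
string equality over the full aligned window, with `N` a mismatch. Exact
matching is deterministic and conservative: it can split haplotypes that
fuzzy matching would merge, never the reverse.

Sites with fewer than **7 genotyped individuals** are excluded from the
per-site diversity and selfing statistics but retained for differentiation
(F_ST uses per-locus sample sizes and tolerates unbalanced sites).

## Diversity

Expected heterozygosity per locus is the unbiased gene diversity
`n/(n−1)·(1−Σp̂²)` with `n` the non-missing gene copies at that locus; the
site value is the unweighted mean over loci with ≥2 copies. Across-site
summaries are unweighted means over sites.

Richness is rarefied hypergeometrically: `E[A_g] = Σ_i [1−C(N−N_i,g)/C(N,g)]`
is the exact expectation of the number of distinct alleles in a subsample
of `g` copies. The default depth is `g = 14` gene copies — twice the
7-individual inclusion floor — applied per locus with per-locus `N`, so
loci with missing data rarefy against their own sample. Mitochondrial
richness uses the same formula on haplotype counts at the minimum per-site
sequence total. The formula is tested against exhaustive enumeration of all
subsamples (≤1e−9 for N ≤ 12) and is non-decreasing in `g`.

The arcsin transform used for modelling H_E is `arcsin(√H_E)` in radians,
the standard variance stabilizer for proportions.

## Selfing (g2 identity disequilibrium)

Under partial selfing, heterozygosity is correlated across loci within
individuals. With `h_ik` the het indicator and `m_ik` the typed indicator,
the estimator aggregates over locus pairs k < l as a ratio of sums:

    ĝ2 = Σ_kl N_kl / Σ_kl D_kl − 1,
    N_kl = Σ_i h_ik h_il / Σ_i m_ik m_il,
    D_kl = Σ_{i≠j} h_ik h_jl / Σ_{i≠j} m_ik m_jl.

The numerator is the within-individual double-het rate; the denominator the
unbiased cross-individual product. The ratio-of-sums aggregation keeps
pairs with few informative individuals from dominating. Pairs with no
heterozygotes contribute nothing; if fewer than two loci carry both het and
hom calls the estimate is degenerate and reported as 0.

At inbreeding equilibrium with unlinked loci, the selfing-lineage age t is
geometric, `P(t) = (1−s)s^t`, and `1−F_t = 2^−t`, giving

    g2(s) = E[(1−F)²]/E[1−F]² − 1 = s / ((4−s)(1−s)),

inverted through its quadratic (monotone on [0,1), clamped to [0,1];
g2 ≤ 0 → s = 0). The inversion ignores biparental inbreeding, which adds a
small positive g2 in small demes; the recovery suite (500 individuals × 8
loci, 20 replicates per s) bounds the net bias at |ŝ−s| ≤ 0.1 for
s ∈ {0.2, 0.5, 0.8} and in practice sees ~0.02.

Significance of g2 > 0 comes from permuting each locus's heterozygosity
column independently among individuals (1000 permutations by default),
which destroys across-locus correlation while preserving per-locus
heterozygosity and missingness counts; "selfing inferred" means p < 0.05
(the conventional threshold; the analysis it reproduces states none).

## Bottleneck test

For each polymorphic locus the equilibrium gene-diversity distribution
given the observed allele count k is simulated by a coalescent under the
two-phase mutation model: mutations are ±1 steps with probability
`p_single = 0.9`, otherwise a geometric multi-step of variance 12 (the
customary TPM setting for microsatellites; both exposed in `TPMParams`).
θ is first calibrated so the mean simulated allele count equals k — a
deterministic fit per (n, k, TPM), cached — then samples are collected at
that fixed θ by rejection on k exactly; the conditioning is never loosened,
and failures raise. 1000 accepted replicates per locus by default.

The per-locus standardized difference `DH = (H_obs − mean H_eq)/sd H_eq` is
reported. The across-loci summary is a one-tailed Wilcoxon signed-rank test
(exact for ≤ 15 loci) applied to the **probit of the exceedance position**
`P(H_eq < H_obs)` rather than to raw DH: the H_eq | k distribution is
left-skewed, so DH is not symmetric about zero under the null and a
signed-rank test on it over-rejects (measured ~16% at α = 0.05); the probit
position is symmetric by construction and restores nominal size (measured
5.5% over 200 equilibrium populations) while ordering loci by the same
excess signal. Only heterozygosity *excess* is flagged (α = 0.05);
deficiency is reported but never flagged. The test runs only on populations
with ŝ = 0, because mixed mating itself distorts the mutation-drift
equilibrium the null assumes — the pipeline enforces this gate.

## Differentiation

θ is the Weir–Cockerham (1984) variance-components estimator, summed over
alleles and loci (`θ = Σa / Σ(a+b+c)`), computed per pair and overall.
Negative estimates are kept in reports (they are the price of
unbiasedness) and clamped to 0 only where F/(1−F) needs them, with F also
capped at 0.999. Haplotype F_ST is the haploid AMOVA estimator with
identity/non-identity distances.

Geographic distances are haversine great circles, Earth radius fixed at
6371 km for bit-reproducibility; at the test's resolution ellipsoidal
corrections are irrelevant. The Mantel test correlates the upper triangles,
builds the null by joint row/column permutation of one matrix, and reports
the one-sided "greater" p with the +1 correction — raw km distance, not
log, and the positive alternative, matching the isolation-by-distance
hypothesis being tested. The MST is Kruskal with a deterministic
lexicographic tie-break on site-code pairs, verified against brute-force
enumeration of spanning trees.

Class contrasts compare mean pairwise F_ST among category members with the
mean among the remaining sites (cross pairs excluded), with a
label-shuffling null (1000 shuffles by default); the two-sided p counts
|Δ_perm| ≥ |Δ_obs|. Three-level expansion comparisons are run as three
pairwise class contrasts, each with its own null.

## Predictors

`lim` is the distance (km) from each site to the boundary of the convex
hull of all sites, computed on a local equirectangular projection about the
mean latitude — at spans of tens of degrees the planar error is far below
the predictor's noise, and the projection is testable against densely
sampled hull edges. `marg` is the Euclidean norm of the site's scores on
the retained axes of a correlation-matrix PCA of the climate columns;
retention is the Kaiser eigenvalue > 1 rule by default (broken-stick
optional) since "significant axes" is otherwise undefined. Quantile groups
take values strictly above the empirical q-quantile (type-7, q = 0.85), so
the marginal group is the top 15% — the contrast's intent; ties fall below.
`bar`, `bio` and `size` are curated inputs, not computed.

The refugial (ref) and Holocene (hol) classes are merged into one level
when two-sided permutation tests (10,000 shuffles) of the ref-vs-hol mean
difference fail to reject for every diversity measure at α = 0.05;
otherwise all three levels are kept. After the merge the expansion factor
enters models as a single dummy.

## Model selection

Every non-empty additive subset of the candidate predictors is fitted by
OLS with intercept (binary factors as 0/1 dummies, continuous predictors
untransformed, complete cases only). Two criteria are exposed:
`"gaussian-full"`, `AIC = N[ln(2π·SS_res/N)+1] + 2(k+1)` with k the number
of predictor terms, which is the convention that reproduces published
Gaussian-GLM tables built from (N, SS_res, d.f.); and `"aicc"`, which adds
`2K(K+1)/(N−K−1)` with `K = k+2` (slopes + intercept + variance) and is the
default for new analyses. Akaike weights are computed over the *full*
candidate set; the display threshold (weight > 0.05) only selects rows for
reporting. More than 12 predictors is refused unless forced.

## Synthetic data

The generator is a forward-time diploid metapopulation with non-overlapping
generations: each offspring is selfed with probability s, else outcrossed
to a uniformly drawn distinct parent in the deme; microsatellites mutate at
μ = 5×10⁻⁴ per gamete under the same TPM as the bottleneck test; mtDNA is
maternal with infinite-alleles mutation at 10⁻³ (only haplotype identity
matters downstream; FASTA sequences are synthesized on export). Migration
is distance-independent: each individual is replaced with probability m by
a copy of a random individual from a uniformly random other deme, the jump
dispersal of water-fowl-transported propagules. Demes are initialized at
mutation-drift equilibrium from per-locus coalescent TPM draws (θ = 2–2.5),
either independently per deme (long-isolated patches) or from one shared
pool (for drift-from-common-origin experiments); this keeps forward runs
short and the bottleneck null honest.

`scenario_range_expansion` (40 core demes of 60 along a SW–NE axis, 15
fringe demes founded at generation 10 of 40 by two colonists each from
scattered core sources, m = 0.005, partial selfing averaging ~0.2 and
slightly higher on the fringe) reproduces the qualitative study pattern:
lower H_E/A/H_mt and higher pairwise F_ST in the expansion class, and the
expansion factor dominating model selection. `scenario_null` (20
exchangeable demes, uniform s = 0, m = 0.02) is the type-I baseline; the
bottleneck calibration uses it with m = 0 and two forward generations,
because immigration and transient drift both push the excess test
conservative and the calibration should measure the test against its own
null. Problem sizes throughout (deme counts ≤ 55, N ≤ 100, ≤ 400
generations, 200–500 permutations or coalescent replicates in tests) were
chosen as the smallest at which the checked expectations are comfortably
resolved.

What the simulator does *not* emulate: selection, linkage, continuous
space, overlapping generations, genotyping error and allele binning noise,
or realistic climate fields (covariates are latitude gradients plus noise).
Passing calibration on it therefore validates the estimators' statistical
logic, not their robustness to those real-data complications.

## Determinism and numerics

A single pipeline seed fans out to independent per-stage substreams
(`SeedSequence.spawn`), so stages can be rerun in isolation and a rerun
with the same seed is byte-identical. Permutation p-values always carry the
+1 correction and have resolution 1/(n_perm+1). Rarefaction uses log-gamma
binomials for stability. The coalescent batch simulator is numba-compiled
when numba is importable, with an equivalent pure-NumPy path otherwise.

## Known limitations

- The g2 → s inversion assumes inbreeding equilibrium; populations far
  from equilibrium (very recent mating-system shifts) will be biased.
- The bottleneck test's θ-conditioning is a plug-in: the per-locus null is
  approximate, which is why the summary uses the probit position.
- The ref+hol merge rule accepts the null by non-rejection; with few sites
  per class it will merge for lack of power.
- Planar hull distances degrade near the poles and for ranges spanning
  >60° of longitude.
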