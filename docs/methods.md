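# Methods

## Kinship from genealogies

Relatedness is estimated purely from pedigree structure; no genetic
markers are involved. The kinship coefficient φ(i, j) is computed by
dynamic programming over a topological ordering of the parent relation:
processing individuals ancestors-first, each new individual's kinship to
every earlier individual is the mean of its parents' kinships to that
individual, and its self-kinship is ½(1 + F), where the inbreeding
coefficient F is the kinship of its parents. The table is O(n²) in time
and memory — for populations of a few thousand this is trivial, and it
avoids the exponential blow-up of naive recursion on looped pedigrees.

Conventions for incomplete data:

- A missing parent is treated as a unique, unrelated founder and
  contributes φ = 0. Individuals with exactly one known parent are
  allowed. No imputation is attempted.
- Wright's coefficient of relatedness is reported as r = 2φ for distinct
  pairs, the convention of standard pedigree software and exact for
  outbred pairs. In a population where nearly all marriages are between
  non-kin, inbred individuals are rare enough that the correction
  2φ/√((1+F_i)(1+F_j)) changes almost nothing; it is available via
  `relatedness_matrix(..., inbreeding_adjusted=True)` for populations
  where it matters.
- The diagonal of the relatedness matrix is NaN, never 1: any aggregation
  that accidentally includes self-pairs poisons its result visibly
  instead of biasing it quietly.

### Gene-dropping oracle

`gene_drop_ibd` simulates allele transmission down the pedigree: every
founder carries two globally unique alleles, every non-founder inherits
one uniformly random allele from each parent per replicate, and φ is
estimated as the average probability that random alleles drawn from the
two individuals match. Averaging the four allele-pair comparisons per
replicate keeps the estimator unbiased with variance at most the binomial
φ(1−φ)/n. Structurally unrelated pairs give exactly zero. The simulator
shares no code with the recursion and serves as its independent oracle in
the test suite (agreement within 3 binomial SE at 100,000 replicates on
random pedigrees).

## Shared reproductive interest

s(i, j) = (r_B + r_D)/(1 + r_C) with r_B = r(i, j), r_D = r(i, spouse of
j), r_C = r(i, own spouse). Unmarried individuals contribute zero to the
terms their spouse would supply (the reference "future offspring" has no
second parent yet, so no affinal term accrues). s is asymmetric: ego's
own marriage appears only in the denominator. When no one is married, s
reduces to r exactly; when ego's spouse is unrelated to ego, s(i, j) =
r_B + r_D ≥ r(i, j). Widowed or divorced status is not modelled — the
spouse map reflects current marriages only.

## Aggregation and camp statistics

- The three aggregation levels (group, individual, dyad means) are
  computed on a chosen subset: everyone, adults only, adult→child, or
  child↔child. Adult/child status comes from the supplied `adult` flag,
  not an age cutoff, so individuals with unknown ages can still be
  classified. Singleton camps drop out of the individual-level mean and
  camps without qualifying dyads out of the group-level mean.
- Camp stability is the mean Jaccard similarity of consecutive visit
  rosters. The field definition fixes only the endpoints (1 = no change,
  0 = complete turnover); Jaccard satisfies both, is symmetric in
  arrivals and departures, and is invariant to roster order and member
  relabelling. The choice is recorded in the run manifest.
- Kin-camp counts (camps containing kin at r ≥ 0.0625, the relatedness
  of a first cousin's child) include ego's own camp when it contains
  such kin; "how many camps could this household live in" logically
  includes the current one. The exclusive variant is an option flag.
  Household residence options are the union of both spouses' kin-camp
  sets plus each spouse's current camp.
- Spousal age gaps are signed (husband − wife); couples missing an age
  keep their consanguinity entry with a missing gap.

## Inference

- Permutation tests compare group means with a two-tailed add-one
  p-value, (b+1)/(m+1), default 10,000 permutations. The default null
  shuffles labels globally across individuals; a stratified option
  (e.g. within camps) is provided. Note that individuals' campmate
  means are not independent — co-resident same-sex kin share values — so
  on strongly kin-clustered residence patterns the global-shuffle test
  can be anti-conservative. See the generator notes below.
- Pearson correlations and p-values come from the standard
  product-moment machinery; Spearman p-values use exhaustive rank-
  permutation enumeration for n ≤ 9 and the t approximation above.
  First-order partial correlation uses the closed form
  (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) with a t test on n − 3 df;
  it equals the residual–residual correlation, which the tests verify
  to 1e-10.
- Distances are haversine great-circle on a sphere of radius
  6371.0088 km. At the ≤50 km scale of a municipality the difference
  from an ellipsoidal geodesic is far below the positional uncertainty
  of a camp.

## Synthetic populations

The generator produces a pedigree plus camp panel with the statistical
structure the analysis assumes, so every stage is testable without field
data. Defaults (all overridable via `GeneratorConfig`):

| parameter | default | rationale |
|---|---|---|
| camps | 15 | typical municipal study region |
| mean adults per camp | 18.1 | target for founder sizing |
| generations | 4 | bounded genealogical recall (mean depth ≈ 3) |
| dispersal | bilocal (p = 0.5) | couples settle with either side |
| kin-marriage prohibition | any known shared ancestry | with exception probability 2/80 |
| husband − wife age gap | N(4.29, 5.31²) y | husband-older norm |
| offspring per couple | Poisson(3) | minimal fertility model; only scale matters |
| generation interval | 25 y | conventional |
| camp extent | 40 km box | tens-of-km foraging region |
| marriage/move distance decay | exp(−d/20 km) | interaction falls with distance |
| turnover per visit | 0.33 | yields stability ≈ 0.5 |
| relocation rounds before census | 2 | residence is a snapshot of ongoing mobility |

Founder couples per camp are sized so that the expected adult census
matches the target given the fertility growth rate. Marriages are
monogamous, male-initiated, drawn from other camps with distance-decayed
weights, and prohibited between known kin except with the configured
exception rate. Couples settle with the husband's camp with probability
0.5 (bilocal), 1 (patrilocal), 0 (matrilocal) or a custom p.

**Mobility.** Households — a couple with dependent children, or a lone
unmarried adult — are the mobile unit. After post-marital settlement,
residence is churned by rounds of household relocation: each round a
household moves with the turnover probability, choosing among camps where
either adult has a kin tie at r ≥ 0.0625 (camp joining requires kinship
to a member, as documented for mobile foragers), weighted toward nearby
camps. The census is the state after two such rounds, and the same
process continues between visit rosters. This matters statistically: a
census frozen at the settlement outcome overstates co-residence of intact
sibling clusters, which makes sex labels non-exchangeable and the global
permutation test anti-conservative even under bilocal symmetry. With
mobility, the bilocal default is calibrated — the sex-difference test
rejects at the nominal 5% rate across replicate populations — while
sex-biased dispersal still produces the predicted asymmetry (the
philopatric sex is more related to its campmates), albeit attenuated
relative to a frozen-settlement world.

Ages are assigned top-down by generation (youngest generation uniform
child ages; adult women normal around their generation mean; husbands =
wife + the configured gap). Parent–child age ordering is not enforced
beyond the generation structure, and mortality, divorce, remarriage and
polygyny are not modelled. Within-camp relatedness magnitudes, age
profiles and covariate correlations in generated data are emergent, not
calibrated targets; passing tests demonstrate correctness of the
statistical machinery and the qualitative dispersal contrasts, not that
the generator matches any real population beyond the descriptive scales
listed above.

## Numerical and procedural choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give identical outputs.
- Aggregations are exact means (no weighting); reports round to 3
  decimals for display while retaining full precision internally.
- The two-community aggregation example (20 members at r = 0.1, 100 at
  r = 0.02) has C(20,2) + C(100,2) = 5140 co-resident dyads, and the
  dyad-level mean 118/5140 ≈ 0.02296 is computed on that combinatorial
  count.
- Permutation tests with one empty group, stability with fewer than two
  visits, correlations with zero variance, and collinear partial
  correlations raise informative errors rather than returning NaN.
- The acceptance script (`scripts/acceptance.py`) uses 200,000
  gene-dropping replicates per relationship as a run-time cross-check;
  the test suite's oracle-equivalence check uses 20 random pedigrees of
  up to 40 individuals at 100,000 replicates, and the calibration check
  uses 200 replicate populations at 499 permutations each — sizes chosen
  to keep Monte-Carlo error well inside the asserted bounds.

## Known limitations

- Genealogical relatedness is downward-biased for pairs whose true
  common ancestry predates recall depth; a three-to-four generation
  pedigree captures most, not all, variation in r.
- The permutation machinery treats individuals as exchangeable units;
  p-values on strongly clustered residence data inherit the usual
  caveats of permutation tests under dependence.
- The generator's marriage market clears greedily and leaves a small
  surplus of unmarried adults when cohort sex ratios are imbalanced;
  real marriage dynamics (age at marriage, remarriage) are not modelled.
- Camp covariates (foraging proportion) are synthetic uniform draws used
  only to exercise the correlation plumbing; they encode no behavioural
  model.
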