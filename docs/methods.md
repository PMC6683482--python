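# Methods

`lofmate` models the management of lethal recessive loss-of-function (LOF)
alleles in a beef-cattle breeding program: a herd of selection candidates
carries hidden lethal alleles at many loci; genotyping part of the herd and
running segregation analysis yields per-animal carrier probabilities; a
mate-selection optimizer then trades index gain, parental coancestry, and
expected embryonic mortality; and an economics layer prices the outcome.

Genotypes are coded `0 = AA`, `1 = Aa` (carrier), `2 = aa` (lethal homozygote,
dies as an embryo) throughout.

## Pedigree and kinship (`lofmate.pedigree`)

Pedigrees are lists of `(id, sire, dam, sex, role)` records with roles
`ancestor` or `candidate`; `0` marks an unknown parent. Construction validates
uniqueness, parent sexes, and acyclicity, and fixes a stable topological order
(parents before offspring, input order otherwise preserved).

Kinship uses the tabular (recursive) method: `f(i, j) = ½(f(s_i, j) + f(d_i,
j))` for `i ≠ j` with unknown parents contributing 0, and `f(i, i) = ½(1 +
F_i)` where the inbreeding coefficient `F_i` is the parents' kinship. Parental
coancestry of a mating list is the quadratic form `x'Kx`, where `x` gives each
parent's contribution proportion and each sex sums to ½ (one sire × one dam
gives 0.25). It is validated against an exponential-time oracle that
enumerates every gamete-inheritance pattern.

## Synthetic herd (`lofmate.synth`)

The generator emulates the *shape* of the study herd, not any real animal
data:

- **Pedigree**: ancestors in cohorts (founders first), random capacity-limited
  parents (≤ 25 offspring per sire, ≤ 8 per dam by default), candidates as the
  final cohort. Study scale: 546 ancestors, 85 male + 169 female candidates.
- **Traits**: the 7-trait maternal objective (HP, CED, CEM, WWD, WWM, FT,
  STAY) with the published heritabilities and genetic correlations (strongest:
  FT–STAY 0.53, CED–CEM −0.30). The correlation matrix is repaired to the
  nearest positive semidefinite matrix by eigenvalue clipping when needed
  (flagged via `psd_repaired`).
- **EPDs**: multivariate normal with covariance ¼ of the genetic covariance
  (an EPD is half a breeding value; candidate EPD variance is about half the
  additive variance, halved again). Missing EPDs become breed-average zeros.
- **Lethal panels**: scenario A = 7 high-frequency loci (mean q 0.0847, range
  [0.0527, 0.1001]), B = 76 low-frequency (mean 0.0112, [0.0004, 0.0695]),
  C = 50 mixed (mean 0.0488, [0.0044, 0.1436]). Panels include the exact
  endpoints, draw interior values from a beta, and are mean-shifted to the
  target within ±0.005.

## Gene dropping (`lofmate.genedrop`)

A 29-chromosome, 3-Gb genome at 1 cM/Mb with Kosambi mapping (`r = ½
tanh(2d)`) and mutation rate 2.2e-9 per bp per meiosis. Founder haplotypes
come from a burn-in: a random-union population (default 500 individuals, 1000
generations) with lethal-homozygote redraw and per-locus frequency pinning to
the panel targets (±0.01). Dropping genotypes down the pedigree samples one
gamete per parent (unlinked by default; linked mode uses the map's adjacent
recombination fractions) and redraws any `aa` conception — no lethal
homozygote ever survives, which is what depresses the allele frequency among
survivors of carrier × carrier matings to ⅓ instead of ½.

## Segregation analysis (`lofmate.segprob`)

A single-locus Bayesian network per pedigree: Hardy–Weinberg founder priors
`((1−q)², 2q(1−q), q²)`, Mendelian trio tables, evidence as point masses.
Inference is exact bucket-tree (junction-tree) elimination with a min-fill
ordering, used whenever the induced width stays ≤ 12 (exact on loops too);
wider pedigrees fall back to damped loopy sum-product belief propagation
(damping 0.5, tolerance 1e-8), which is approximate on loops (observed errors
~5e-3 on adversarial cases). Direct trio contradictions raise
`MendelianInconsistencyError` naming the trio. Optional survivor conditioning
removes `aa` mass from unobserved animals. Genotyping tiers are one random
permutation of the candidate cohort cut at `round(pct% × N)`, so subsets are
nested — more budget only adds information.

## Lethality metrics (`lofmate.lethal`)

With `a = P(Aa)/2 + P(aa)` the probability a parent transmits the lethal
allele, the per-locus progeny death probability of a pair is `a_s · a_d`
(transmissions are independent), and loci combine as `1 − Π(1 − p_l)`:

- **LethalG** — mean pair mortality over the mating list; ×100 gives expected
  affected conceptions per 100 matings.
- **LethalA** — grandprogeny mortality under random mating of surviving
  progeny at the current candidate frequencies: cohort transmission frequency
  `t̄_l` meets a mate allele at frequency `q_l`, combined across loci. By
  default the progeny genotype distribution is conditioned on survival
  (`t = ½ p_carrier / (1 − p_aa)`); unconditioned, `t = (a_s + a_d)/2` and the
  metric depends only on which parents are used, not the pairings.
- **GLS** — mating-weighted sum over sires of `Σ_l P(Aa at l) q_l²`, per
  mating.

## Mate selection (`lofmate.matesel`)

The decision variable is a mating list: `N` matings (default 100), each dam at
most once, at most 50 per sire. The penalized objective is
`mean progeny index − mortality_cost × (w_A·LethalA + w_G·LethalG)` with
`mortality_cost` $200. A frontier is anchored by two endpoints: truncation
selection (maximum mean index) and a Frank–Wolfe minimization of `x'Kx`
(minimum coancestry, rounded by largest remainder). The working point is
placed at a target angle (default 25°) on the normalized index-gain vs
coancestry-reduction frontier: an outer bisection on a coancestry penalty
multiplier wraps an elitist evolutionary algorithm (move/swap/replace
mutations, crossover on sire counts, greedy dam assignment and 2-opt pairing
polish when `w_G > 0`). On enumerable instances the EA reproduces the
exhaustive optimum (acceptance criterion), which is the behavior that matters;
global optimality at scale is not claimed.

## Economics (`lofmate.econ`)

Per 100 matings: an affected conception costs $200, a genotype test $30, and
genotyping `pct%` of the herd buys `pct` tests (the test base recovered from
the published savings/breakeven arithmetic). `$P = $M − 200 × LethalG`;
savings at a tier are the avoided mortality costs relative to the
0%-genotyped base run of the same weighting and replicate; net profit
subtracts test costs; the breakeven test value divides savings by tests
bought. Reported dollars round half-up to cents; internal math keeps full
precision.

## Experiments (`lofmate.experiments`)

A study cell = scenario × strategy × weighting × tier × replicate. Strategy 1
places the weighting on LethalA (carrier avoidance), strategy 2 on LethalG
(carrier-mating avoidance). Pedigree, EPDs, index values, kinship, panel, and
founder pool are fixed per scenario; every replicate re-drops true genotypes.
**Decisions are made on inferred probabilities** (posteriors from the
genotyped subset at the tier), **outcomes are scored on the true genotypes** —
the only split under which partial genotyping can change outcomes. Every
random stage draws from a named SHA-256 substream of the master seed
(`pedigree`, `epd`, `panel`, `burnin`, `drop:<rep>`, `scheme:<rep>`,
`ea:<cell>`), all below 2³¹, so any cell reproduces in isolation.

## What the generator does not model

Real Angus pedigree structure or EPD distributions; the published $P/$MB/GLS
magnitudes (they depend on a private pedigree and unpublished economic
weights); multi-generation selection dynamics; linkage disequilibrium between
panel loci beyond the burn-in; genotyping error.
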