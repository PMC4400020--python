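# Methods

## Model

`upievol` tracks an effectively infinite population of a single-celled,
isogamous, diploid eukaryote through discrete, non-overlapping generations.
The state is the exact joint distribution of (nuclear allele or genotype,
mutant organelle count): gametes carry `n/2` segregating units (`p` mutant),
diploids carry `n` (`i` mutant).  Because the population is infinite, the
probability of a cell type equals its population proportion, and the
recursion is fully deterministic — identical configurations give
bit-identical traces.

One generation composes four row-stochastic kernels:

* **Mating.** Two gametes are drawn at random; pairs violating mating-type
  compatibility are lethal and the survivors are renormalized (an ordered
  draw, so an unlike pair carries a factor 2 and a like pair does not).
  Biparental transmission sums the parental counts (discrete convolution
  with the bounds `max(0, i−n/2) ≤ p ≤ min(n/2, i)`).  Uniparental
  transmission discards the recipient's organelles and restores the diploid
  complement by sampling `n/2` units *with replacement* from the donor's
  `n/2` and appending them, so the zygote count is `p + Binomial(n/2, 2p/n)`.
  Mixed rules (leaky or random-donor inheritance) are convex combinations of
  these two outcomes.
* **Mutation.** Independently, each of the `n−i₀` wild-type units mutates
  with probability `μ` and each of the `i₀` mutant units back-mutates with
  probability `μ_b`; the transition probability to `i = i₀ + a − b` is the
  product of the two binomial terms summed over valid `(a, b)`.  Neutral
  runs use `μ_b = μ`; deleterious runs default to `μ_b = μ/100`,
  advantageous to `μ_b = 100μ`.
* **Selection.** Viability selection with relative fitness
  `w(i) = 1 − c_h·f(r)`, where `r` is the distance to the nearer homoplasmic
  state scaled to `[0, 1]` and `f` is `r²` (concave), `r` (linear) or `√r`
  (convex).  The convex form is a reconstruction: the source rendering of
  that equation is typographically ambiguous, and the square root is the
  minimal shape that is steeper than linear at low heteroplasmy while
  keeping the anchors `w = 1` at homoplasmy and `w = 1 − c_h` at `i = n/2`.
  Non-neutral haplotypes multiply a second component: decreasing from 1 to
  `1 − s_d` (deleterious) or increasing from `1 − s_a` to 1 (advantageous),
  concave or convex in `i/n`.  Multiplicative composition is likewise a
  design choice — the two printed anchor values (1 for a homoplasmic
  wild-type cell, `1 − s_d` for a homoplasmic mutant) survive it, and no
  additive alternative keeps both.  Mean fitness per genotype is reported
  from the pre-selection distribution.
* **Meiosis.** The complement doubles by the same with-replacement binomial
  sampling (`i → l`), then each gamete draws `n/2` of the `2n` units without
  replacement (hypergeometric), modelled as a single step because organelles
  segregate independently of the nuclear alleles; nuclear alleles split
  half–half, with a fraction `P_r` of recombinant alleles emitted by
  inheritance-heterozygous genotypes in the recombination scenarios.

Vegetative segregation (the `mitosis` scenario) inserts `d` divisions per
generation, each a doubling followed by a hypergeometric draw of `n` from
`2n` (both daughters are retained; their marginal laws coincide, so one draw
represents both).  The default order is mating → mutation → mitosis →
selection → meiosis; the placement of mutation relative to mitosis is
configurable (`mitosis_order`), and `midway` timing applies `d/2` divisions,
selection, then `d/2`.

## Protocol and equilibrium detection

A run starts from homoplasmic wild-type biparental gametes (B₁/B₂ at
0.5/0.5, or all-B without mating types), iterates to mutation–selection
equilibrium, then converts `intro_freq = 10⁻²` of the source gametes to the
uniparental allele — into the homoplasmic wild-type state by default, or
into the most heteroplasmic state whose proportion exceeds `intro_freq`.

Burn-in stops when the largest absolute change of any (allele, count) gamete
proportion between consecutive generations falls below `eq_tol` (10⁻¹²;
10⁻¹³ when `μ = 10⁻¹⁰`, where per-generation changes are otherwise of the
order of the tolerance itself).  For the post-introduction phase two metrics
are available: `per_type` (the default; same criterion as burn-in) and
`allele` (stop when the *allele frequencies* are stationary).  The second
exists because after the uniparental genotype fixes, the haplotype ratio
inside the fixed pool is quasi-neutral and drifts toward its interior
balance at a rate of order `μ`: at `μ = 10⁻⁷` the per-type criterion would
run for ~10⁷–10⁸ further generations without any reported quantity changing.
The allele metric is the natural reading of "the simulation ends when the
alleles reach equilibrium" and is used for the low-μ linked runs; all
polymorphic-equilibrium runs reported by the acceptance script converge
under the stricter per-type metric.

Generations are counted separately for the burn-in (`ge1`) and from the
introduction (generation 0).  A run that exhausts `max_generations`
(default 5×10⁶) is flagged, not raised.  Fixation is declared when the mass
of genotypes with any uniparental transmission exceeds 1 − 10⁻⁶.  The
UPI-transmission frequency is defined **per mating event**: post-mating
genotype frequencies weighted by each mating's uniparental-transmission
probability (1 for U×B, 0 for B×B, regime-dependent for U×U).  The source
material is not internally consistent about this accounting for U×U
matings; the per-event definition matches the supplementary tables' formula
`P(U₁B₂) + P(U₂B₁) + P(U₁U₂)(1 − P_b)` and is used throughout.

## Numerical choices

All distributions are dense double-precision vectors; proportions are never
truncated, so probabilities of order 10⁻³⁰⁰ survive (homoplasmy is exactly
absorbing only when `μ = 0`).  Kernels are built once per parameter set from
`scipy.stats` binomial/hypergeometric pmfs and cached; every row sums to 1
within 10⁻¹².  `n` must be even (gametes carry `n/2`); odd `n` is rejected
at validation.  The gamete-rescaled fitness (reporting only — gametes are
not under selection) substitutes `n/2` for `n` and tolerates odd `n/2` via
the piecewise form.  The production iteration runs on a precompiled
single-generation engine operating on a stacked (alleles × counts) array;
it composes exactly the same kernels as the public stage functions and the
suite asserts their equality to 10⁻¹⁵ across all scenario families.

## Validation strategy

Two independent oracles back the deterministic recursion:

* **Exhaustive enumeration** (n ≤ 6): mutation by all 2ⁿ per-unit outcomes,
  doubling by all mᵐ ordered draws, meiosis by all without-replacement
  subsets — agreement to 10⁻¹².  Enumeration fixes, for example, the
  residual heteroplasmic mass after 20 divisions at `n = 4` at 0.01501.
* **Monte-Carlo realization** (N = 10⁵ individuals): every stage as literal
  random draws.  A one-generation chi-square test (α = 0.01) checks the full
  state distribution.  The trajectory check restarts the finite population
  from the deterministic state each generation and compares the one-step
  update: a free-running finite population accumulates drift variance
  linearly in time and would leave any fixed per-generation envelope within
  ~20 generations, which would test drift, not the map.  The envelope is 4
  standard errors with a variance budget of four multinomial stages
  (start-sampling, pairing, selection resampling, meiotic allele
  assignment).  Seeds are fixed in the tests.

Structural identities provide end-to-end checks without reference values:
B₂ stays at exactly 0.5 in all linked runs; the no-mating-types UB frequency
equals the summed U₁B₂ + U₂B₁ frequency of the matched recombination run;
the didymium equilibrium depends only on `P_b`, not the donor split; the
leaky-UPI equilibrium BPI frequency equals `P_b` once U₁B₂ is fixed; and the
UPI ceiling under biparental U×U matings comes out at exactly 0.5 under
linear fitness.

## Problem sizes and study conditions

The generator defaults are the study conditions: `n = 20`, `c_h = 0.2`,
concave fitness, `intro_freq = 10⁻²`, with `μ = 10⁻⁷` for the headline
linked run and `μ = 10⁻⁴` for the polymorphic-equilibrium scenarios.  The
qualitative orderings (slower replacement at larger `n`, smaller `μ`, with
deleterious haplotypes or with mitotic divisions; faster with mildly
advantageous haplotypes or heteroplasmic introduction) are asserted at
`n = 8`–`20` with `μ = 10⁻³`–`10⁻⁵`, measured as generations until the
uniparental genotype passes a fixed threshold — the orderings are
parameter-robust and the threshold avoids the long post-fixation tail.
For the vegetative-segregation scenario the stability of biparental
inheritance requires divisions enough for segregation to be effectively
complete before selection acts: with the binomial-doubling/hypergeometric
kernels, 20 divisions at `n = 4` leave ~1.5% residual heteroplasmy (the
enumeration-fixed 0.01501 asserted in the suite), and the corresponding
residual selective differential sits well above the equilibrium tolerance,
so the uniparental allele still slowly fixes; at 100 divisions the residual
differential falls below the tolerance and the uniparental genotype stays
at the 0.02 implied by its introduction frequency.  The acceptance run
therefore uses 100 divisions as the "many divisions" condition.

## Limitations

Two organelle haplotypes only; no genetic drift (the infinite-population
recursion cannot address invasion of rare mutants under drift); no gamete
stage selection; no overlapping generations; mating-type evolution itself is
out of scope.  The Monte-Carlo oracle is a validation tool, not a drift
study.  Real vegetative segregation in yeast is faster per division than
the doubling/halving kernel used here, so the division counts in the
mitosis scenario should be read as effective segregation opportunities, not
literal cell divisions.
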