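# upievol

Why do mitochondria (and chloroplasts) usually come from only one parent,
even in isogamous organisms whose gametes are the same size?  `upievol` is a
deterministic population-genetic simulator for one answer: **selection
against heteroplasmy** — a fitness cost to carrying a mixture of organelle
haplotypes in one cell — favours nuclear alleles that enforce uniparental
organelle inheritance (UPI) over the ancestral biparental state (BPI).

The package is aimed at evolutionary geneticists studying organelle
transmission.  It propagates *exact* probability distributions of cell types
through the life cycle of a single-celled isogamous diploid (think
*Chlamydomonas*), so there is no Monte-Carlo noise in the main results; a
finite-population Monte-Carlo realization of the same life cycle ships as an
independent cross-check used by the test suite.

## The model

The population is effectively infinite.  A diploid cell carries `n`
segregating organelle units (`i` of them carrying the mutant haplotype), a
gamete carries `n/2` (`p` mutant).  Each generation composes four stages:

1. **Random mating** — gametes fuse respecting mating-type compatibility.
   Biparental zygotes receive both complements (`i = p + q`, a discrete
   convolution); uniparental zygotes discard the recipient's organelles and
   restore `n` by sampling `n/2` units with replacement from the donor's
   `n/2` (binomial kernel).  Inviable pairings are lethal and the population
   is renormalized.
2. **Mutation** — each wild-type unit mutates with probability `μ`, each
   mutant back-mutates with probability `μ_b`, independently (a product of
   binomial draws).
3. **Selection** — cell fitness `w(i)` equals 1 for homoplasmic cells and
   `1 − c_h` at maximal heteroplasmy `i = n/2`, with concave
   (`1 − c_h (i/(n/2))²`), linear, or convex (square-root) loss, mirrored
   about `n/2`.  Non-neutral haplotypes multiply in a second, monotone
   fitness component scaled by a selection coefficient `s`.
4. **Meiosis** — the complement doubles by with-replacement sampling
   (binomial), then each gamete draws `n/2` units without replacement
   (hypergeometric), and nuclear alleles split half–half (with recombinant
   alleles at rate `P_r` where applicable).

Scenarios assemble the allele/genotype sets and mating rules: `linked`
(mating type and inheritance loci inherited together), `recombination`
(four alleles, U×U matings possible), `no-mating-types`, `mitosis`
(vegetative segregation: extra double-and-halve divisions before selection),
`physarum` (leaky UPI: U×B matings biparental with probability `P_b`) and
`didymium` (random/biased donor in U×U matings).

A run burns the ancestral biparental population in to mutation–selection
equilibrium (per-cell-type change < 10⁻¹²), converts a fraction 10⁻² of
gametes to the UPI allele, and iterates until equilibrium.

## Worked example

The headline neutral case: `n = 20`, `μ = 10⁻⁷`, `c_h = 0.2`, concave
fitness, linked loci:

```bash
$ upievol --preset linked-neutral --eq-metric allele --trace-every 100 --out demo -v
scenario=linked n=20 mu=1e-07 mu_b=1e-07 c_h=0.2 concave eq_tol=1e-12
burn-in: 1947 generations (converged=True); post-introduction: 83822 (converged=True)
UPI frequency at equilibrium: 1.000000 (fixation=True) -> demo/summary.json
```

Reading: the ancestral B₁/B₂ population needs 1947 generations to reach
mutation–selection balance; after the UPI allele U₁ appears at frequency
0.01 it takes ~84k generations for the alleles to stop moving, by which
point every mating transmits organelles uniparentally (`fixation=True`) —
U₁ has replaced B₁ while the B₂ mating-type allele stays at exactly 0.5
(`equilibrium_allele_freqs` in `demo/summary.json` shows U₁ ≈ 0.5,
B₁ ≈ 1.2 × 10⁻⁹, B₂ = 0.5).  `demo/trace.csv` holds the per-generation
allele/genotype frequencies, mean cell fitness per genotype and the
UPI-transmission frequency.

The same protocol is available as a library:

```python
import upievol as uv

cfg = uv.RunConfig(n=20, mu=1e-4,
                   scenario=uv.build_no_mating_types("biparental"),
                   fitness=uv.FitnessSpec(0.2, "concave"))
summary = uv.simulate(cfg)
summary.equilibrium_upi_frequency   # 0.1108: polymorphic, no fixation
```

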