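"""Independent validation of the deterministic recursion.

Two cross-checks, used only by the test suite:

* a finite-population Monte-Carlo simulator of the identical life cycle, in
  which every individual carries an explicit mutant count and every sampling
  step (pairing, transmission, mutation, viability selection, meiosis) is a
  literal random draw;
* exhaustive small-instance enumeration of single stages (all per-unit
  mutation outcomes, all with-replacement doubling draws, all
  without-replacement partitions), computed without reference to the kernel
  code.

Both must agree with the deterministic modules — exactly for the enumerations,
within sampling error for the Monte-Carlo runs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .lifecycle import genotype_label
from .kernels import fitness_vector
from .runner import RunConfig

__all__ = [
    "AgentPopulation",
    "population_from_distribution",
    "gamete_distribution_of",
    "mc_generation",
    "enumerate_mutation",
    "enumerate_doubling",
    "enumerate_meiosis",
]


@dataclass
class AgentPopulation:
    """N gamete-stage individuals with explicit allele and mutant count."""

    n: int  # diploid complement; each gamete carries n // 2 units
    alleles: np.ndarray  # (N,) indices into allele_names
    counts: np.ndarray  # (N,) mutant counts in 0..n//2
    allele_names: tuple[str, ...]

    @property
    def size(self) -> int:
        return self.alleles.shape[0]

    def validate(self) -> None:
        half = self.n // 2
        if np.any(self.counts < 0) or np.any(self.counts > half):
            raise ValueError("gamete counts out of 0..n/2")


def population_from_distribution(gametes, size: int, rng: np.random.Generator) -> AgentPopulation:
    """Sample N individuals from a deterministic gamete distribution."""
    names = tuple(gametes.props)
    half = gametes.half
    states = [(gi, p) for gi, g in enumerate(names) for p in range(half + 1)]
    probs = np.array([gametes.props[names[gi]][p] for gi, p in states])
    probs = probs / probs.sum()
    draw = rng.choice(len(states), size=size, p=probs)
    alleles = np.array([states[k][0] for k in draw])
    counts = np.array([states[k][1] for k in draw])
    return AgentPopulation(gametes.n, alleles, counts, names)


def gamete_distribution_of(pop: AgentPopulation) -> dict[str, np.ndarray]:
    """Empirical (allele, count) frequencies of a population."""
    half = pop.n // 2
    out = {}
    for gi, name in enumerate(pop.allele_names):
        mask = pop.alleles == gi
        out[name] = np.bincount(pop.counts[mask], minlength=half + 1) / pop.size
    return out


def _pick_components(rule, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a transmission component index per mating under ``rule``."""
    weights = np.array([c.weight for c in rule.components])
    return rng.choice(len(rule.components), size=size, p=weights / weights.sum())


def mc_generation(
    pop: AgentPopulation, config: RunConfig, rng: np.random.Generator
) -> AgentPopulation:
    """One stochastic generation of the identical life cycle at finite N.

    Pairing draws ordered gamete pairs uniformly and discards inviable ones
    (matching the viability-conditioned renormalization of the deterministic
    model); selection is fitness-proportional multinomial resampling back to
    N; meiosis doubles with replacement, partitions without replacement and
    assigns the gamete allele by the scenario's meiotic weights.  Each diploid
    contributes one gamete.
    """
    sc = config.scenario
    n, half = pop.n, pop.n // 2
    N = pop.size
    names = pop.allele_names
    genotype_names = list(sc.genotypes)

    # ordered-pair viability lookup: allele indices -> rule index, -1 inviable
    nA = len(names)
    rule_lookup = -np.ones((nA, nA), dtype=np.int64)
    for ridx, rule in enumerate(sc.rules):
        x, y = names.index(rule.parents[0]), names.index(rule.parents[1])
        rule_lookup[x, y] = ridx
        rule_lookup[y, x] = ridx

    # --- random mating, conditioned on viability -------------------------
    count_parts: list[np.ndarray] = []
    geno_parts: list[np.ndarray] = []
    need = N
    attempts = 0
    while need > 0:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("population extinct: no viable matings")
        m = max(2 * need, 4096)
        i1 = rng.integers(0, N, size=m)
        i2 = rng.integers(0, N, size=m)
        a1, a2 = pop.alleles[i1], pop.alleles[i2]
        ridx = rule_lookup[a1, a2]
        ok = ridx >= 0
        a1, p1 = a1[ok][:need], pop.counts[i1[ok]][:need]
        p2 = pop.counts[i2[ok]][:need]
        ridx = ridx[ok][:need]
        k_tot = ridx.shape[0]
        counts_new = np.empty(k_tot, dtype=np.int64)
        geno_new = np.empty(k_tot, dtype=np.int64)
        for r_i, rule in enumerate(sc.rules):
            mask = ridx == r_i
            k = int(mask.sum())
            if k == 0:
                continue
            geno_new[mask] = genotype_names.index(
                genotype_label(*rule.parents, sc.alleles)
            )
            if len(rule.components) > 1:
                cw = np.array([c.weight for c in rule.components])
                comp_idx = rng.choice(len(cw), size=k, p=cw / cw.sum())
            else:
                comp_idx = np.zeros(k, dtype=np.int64)
            pm1, pm2, am1 = p1[mask], p2[mask], a1[mask]
            res = np.empty(k, dtype=np.int64)
            for c_i, comp in enumerate(rule.components):
                cm = comp_idx == c_i
                if not cm.any():
                    continue
                if comp.mode == "biparental":
                    res[cm] = pm1[cm] + pm2[cm]
                else:
                    donor_is_1 = am1[cm] == names.index(comp.donor)
                    dc = np.where(donor_is_1, pm1[cm], pm2[cm])
                    res[cm] = dc + rng.binomial(half, dc / half)
            counts_new[mask] = res
        count_parts.append(counts_new)
        geno_parts.append(geno_new)
        need -= k_tot
    zyg_counts = np.concatenate(count_parts)
    zyg_geno = np.concatenate(geno_parts)

    # --- mutation --------------------------------------------------------
    a = rng.binomial(n - zyg_counts, config.mu)
    b = rng.binomial(zyg_counts, config.mu_back)
    counts = zyg_counts + a - b

    # --- mitosis (vegetative segregation) --------------------------------
    d_pre, d_post = sc.divisions, 0
    if sc.mitosis_timing == "midway":
        d_pre = d_post = sc.divisions // 2
    for _ in range(d_pre):
        l = counts + rng.binomial(n, counts / n)
        counts = rng.hypergeometric(l, 2 * n - l, n)

    # --- viability selection (multinomial resampling to N) ---------------
    w = fitness_vector(n, config.fitness)[counts]
    tot = w.sum()
    if tot <= 0:
        raise RuntimeError("population extinct under selection")
    keep = rng.choice(N, size=N, p=w / tot)
    counts, geno = counts[keep], zyg_geno[keep]

    for _ in range(d_post):
        l = counts + rng.binomial(n, counts / n)
        counts = rng.hypergeometric(l, 2 * n - l, n)

    # --- meiosis ----------------------------------------------------------
    l = counts + rng.binomial(n, counts / n)
    p = rng.hypergeometric(l, 2 * n - l, half)
    out_alleles = np.empty(N, dtype=np.int64)
    for Gi, Gname in enumerate(genotype_names):
        mask = geno == Gi
        k = int(mask.sum())
        if k == 0:
            continue
        weights = sc.allele_map[Gname]
        choice_names = list(weights)
        probs = np.array([weights[c] for c in choice_names])
        picks = rng.choice(len(choice_names), size=k, p=probs / probs.sum())
        name_idx = np.array([names.index(c) for c in choice_names])
        out_alleles[mask] = name_idx[picks]
    return AgentPopulation(n, out_alleles, p, names)


# ---------------------------------------------------------------------------
# exhaustive small-instance enumerations (independent of the kernel code)
# ---------------------------------------------------------------------------


def enumerate_mutation(n: int, i0: int, mu: float, mu_b: float) -> np.ndarray:
    """Exact post-mutation pmf over 0..n from a cell with i0 mutants, by
    enumerating all 2^n per-unit outcomes."""
    units = [mu_b] * i0 + [mu] * (n - i0)  # per-unit flip probability
    out = np.zeros(n + 1)
    for flips in itertools.product((0, 1), repeat=n):
        prob = 1.0
        mutants = 0
        for unit_idx, flip in enumerate(flips):
            p_flip = units[unit_idx]
            prob *= p_flip if flip else 1.0 - p_flip
            is_mutant = unit_idx < i0
            mutants += (1 - flip) if is_mutant else flip
        out[mutants] += prob
    return out


def enumerate_doubling(m: int, p: int) -> np.ndarray:
    """Exact pmf over 0..2m after appending m with-replacement draws to a
    complement of m units of which p are mutant, by enumerating all m^m
    ordered draws."""
    out = np.zeros(2 * m + 1)
    total = m**m
    for draw in itertools.product(range(m), repeat=m):
        sampled_mutants = sum(1 for unit in draw if unit < p)
        out[p + sampled_mutants] += 1.0 / total
    return out


def enumerate_meiosis(n: int, i: int) -> np.ndarray:
    """Exact gamete-count pmf over 0..n/2 from a diploid with i mutants:
    enumerate every with-replacement doubling draw, then every
    without-replacement choice of n/2 units from the doubled complement."""
    half = n // 2
    out = np.zeros(half + 1)
    doubled = enumerate_doubling(n, i)
    for l, prob_l in enumerate(doubled):
        if prob_l == 0.0:
            continue
        denom = math.comb(2 * n, half)
        for subset in itertools.combinations(range(2 * n), half):
            mutants = sum(1 for u in subset if u < l)
            out[mutants] += prob_l / denom
    return out
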