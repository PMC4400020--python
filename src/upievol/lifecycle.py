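"""Life-cycle stage transforms on population distributions.

The population is effectively infinite, so the state of the model is the exact
probability distribution over cell types.  Gametes are described by (nuclear
allele, mutant count p in 0..n/2); diploid cells by (nuclear genotype, mutant
count i in 0..n).  One generation composes

    mate -> mutate -> [mitose] -> select -> meiose

where selection renormalizes the population and every other stage conserves
mass.  The allele/genotype sets and the transmission behaviour of each mating
are supplied by the scenario layer; this module is agnostic to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import (
    FitnessSpec,
    doubling_kernel,
    fitness_vector,
    gamete_fitness_vector,
    meiosis_kernel,
    mitosis_kernel,
    mutation_kernel,
)

__all__ = [
    "DegeneratePopulationError",
    "GameteDistribution",
    "DiploidDistribution",
    "Transmission",
    "MatingRule",
    "genotype_label",
    "mate",
    "mutate",
    "select",
    "meiose",
    "mitose",
    "gamete_mean_fitness",
]

MASS_TOL = 1e-9


class DegeneratePopulationError(RuntimeError):
    """Raised when the entire population mass is lost (inviable matings or
    zero total fitness)."""


@dataclass
class GameteDistribution:
    """Proportions over (allele, mutant count p in 0..n/2) at the gamete stage."""

    n: int  # diploid mitochondrial complement; gametes carry n // 2
    props: dict[str, np.ndarray]

    @property
    def half(self) -> int:
        return self.n // 2

    def total(self) -> float:
        return float(sum(v.sum() for v in self.props.values()))

    def allele_frequencies(self) -> dict[str, float]:
        return {g: float(v.sum()) for g, v in self.props.items()}

    def as_vector(self) -> np.ndarray:
        """All proportions concatenated in allele order (for convergence checks)."""
        return np.concatenate([self.props[g] for g in self.props])

    def validate(self) -> None:
        for g, v in self.props.items():
            if v.shape != (self.half + 1,):
                raise ValueError(f"allele {g}: expected {self.half + 1} states")
            if np.any(v < 0):
                raise ValueError(f"allele {g}: negative proportion")
        if abs(self.total() - 1.0) > MASS_TOL:
            raise ValueError(f"gamete proportions sum to {self.total()}, not 1")


@dataclass
class DiploidDistribution:
    """Proportions over (genotype, mutant count i in 0..n) at a diploid stage.

    ``viable_mass`` on the post-mating distribution records the total mass
    before renormalization (1 minus the mass lost to inviable pairings).
    """

    n: int
    props: dict[str, np.ndarray]
    stage: str = "post_mating"
    viable_mass: float | None = None

    def total(self) -> float:
        return float(sum(v.sum() for v in self.props.values()))

    def genotype_frequencies(self) -> dict[str, float]:
        return {G: float(v.sum()) for G, v in self.props.items()}

    def validate(self) -> None:
        for G, v in self.props.items():
            if np.any(v < 0):
                raise ValueError(f"genotype {G}: negative proportion")
        if abs(self.total() - 1.0) > MASS_TOL:
            raise ValueError(f"diploid proportions sum to {self.total()}, not 1")


@dataclass(frozen=True)
class Transmission:
    """One component of a mating's mitochondrial transmission.

    ``mode`` is ``"biparental"`` (the zygote receives both parents' n/2
    complements) or ``"uniparental"`` (the ``donor`` parent's complement is
    doubled by with-replacement sampling; the other parent's mitochondria are
    discarded).  Components of a rule carry weights summing to 1.
    """

    weight: float
    mode: str
    donor: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("biparental", "uniparental"):
            raise ValueError(f"unknown transmission mode {self.mode!r}")
        if self.mode == "uniparental" and self.donor is None:
            raise ValueError("uniparental transmission requires a donor allele")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"transmission weight must lie in [0, 1]")


@dataclass(frozen=True)
class MatingRule:
    """A viable unordered gamete pairing and how it transmits mitochondria."""

    parents: tuple[str, str]
    components: tuple[Transmission, ...]

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"transmission weights for {self.parents} sum to {w}")
        for c in self.components:
            if c.mode == "uniparental" and c.donor not in self.parents:
                raise ValueError(f"donor {c.donor} is not a parent of {self.parents}")

    @property
    def uniparental_probability(self) -> float:
        """Probability that a single mating under this rule transmits
        uniparentally."""
        return sum(c.weight for c in self.components if c.mode == "uniparental")


def genotype_label(g1: str, g2: str, allele_order: tuple[str, ...] | None = None) -> str:
    """Canonical genotype label for an unordered allele pair."""
    if allele_order is not None:
        g1, g2 = sorted((g1, g2), key=allele_order.index)
    else:
        g1, g2 = sorted((g1, g2))
    return g1 + g2


def mate(
    gametes: GameteDistribution,
    rules: tuple[MatingRule, ...],
    allele_order: tuple[str, ...] | None = None,
) -> DiploidDistribution:
    """Random union of gametes restricted to viable pairings.

    Each ordered draw of two gametes contributes its joint probability, so an
    unlike pair (g1, g2) carries the factor 2 for its two orderings while a
    like pair carries none.  Biparental transmission convolves the two count
    distributions (zygote count i = p + q); uniparental transmission sums over
    the recipient's states and doubles the donor's complement by the binomial
    with-replacement kernel.  Inviable pairings are lethal; the result is
    renormalized over the surviving mass.
    """
    n = gametes.n
    half = gametes.half
    D = doubling_kernel(half)
    props: dict[str, np.ndarray] = {}
    for rule in rules:
        g1, g2 = rule.parents
        v1 = gametes.props.get(g1)
        v2 = gametes.props.get(g2)
        if v1 is None or v2 is None:
            continue
        factor = 2.0 if g1 != g2 else 1.0
        vec = np.zeros(n + 1)
        for comp in rule.components:
            if comp.mode == "biparental":
                vec += comp.weight * np.convolve(v1, v2)
            else:
                donor, other = (v1, v2) if comp.donor == g1 else (v2, v1)
                vec += comp.weight * float(other.sum()) * (donor @ D)
        label = genotype_label(g1, g2, allele_order)
        if label in props:
            props[label] += factor * vec
        else:
            props[label] = factor * vec
    viable = float(sum(v.sum() for v in props.values()))
    if viable <= 0.0:
        raise DegeneratePopulationError("all mass fell on inviable matings")
    for G in props:
        props[G] = props[G] / viable
    return DiploidDistribution(n, props, stage="post_mating", viable_mass=viable)


def mutate(cells: DiploidDistribution, mu: float, mu_b: float) -> DiploidDistribution:
    """Propagate each genotype's count distribution through the mutation
    kernel.  Mass is conserved."""
    K = mutation_kernel(cells.n, mu, mu_b)
    props = {G: v @ K for G, v in cells.props.items()}
    return DiploidDistribution(cells.n, props, stage="post_mutation")


def select(
    cells: DiploidDistribution, spec: FitnessSpec
) -> tuple[DiploidDistribution, dict[str, float]]:
    """Viability selection on heteroplasmy (and haplotype accumulation).

    Returns the renormalized post-selection distribution together with each
    genotype's mean relative fitness, computed on the pre-selection
    distribution.  Genotypes with no mass get NaN.
    """
    w = fitness_vector(cells.n, spec)
    mean_w: dict[str, float] = {}
    props: dict[str, np.ndarray] = {}
    sigma = 0.0
    for G, v in cells.props.items():
        m = float(v.sum())
        wv = v * w
        mean_w[G] = float(wv.sum() / m) if m > 0 else float("nan")
        props[G] = wv
        sigma += float(wv.sum())
    if sigma <= 0.0:
        raise DegeneratePopulationError("zero total fitness after selection")
    for G in props:
        props[G] = props[G] / sigma
    return DiploidDistribution(cells.n, props, stage="post_selection"), mean_w


def meiose(
    cells: DiploidDistribution, allele_map: dict[str, dict[str, float]]
) -> GameteDistribution:
    """Meiosis: double the complement (with replacement), partition n/2 units
    into each gamete (without replacement), and split nuclear alleles.

    ``allele_map`` gives, per genotype, the weight of each gamete allele among
    its meiotic products (e.g. 1/2 each for a heterozygote; recombinant
    alleles appear here in recombination scenarios).
    """
    n = cells.n
    K = meiosis_kernel(n)
    out: dict[str, np.ndarray] = {}
    for G, v in cells.props.items():
        gvec = v @ K
        for allele, weight in allele_map[G].items():
            if allele in out:
                out[allele] += weight * gvec
            else:
                out[allele] = weight * gvec
    return GameteDistribution(n, out)


def mitose(cells: DiploidDistribution, divisions: int) -> DiploidDistribution:
    """Apply ``divisions`` rounds of mitotic division (vegetative segregation).

    Each division doubles the complement and draws a daughter's n units
    hypergeometrically; genotypes are unchanged and mass is conserved.
    """
    if divisions < 0:
        raise ValueError(f"divisions must be >= 0, got {divisions}")
    if divisions == 0:
        return cells
    K = mitosis_kernel(cells.n, divisions)
    props = {G: v @ K for G, v in cells.props.items()}
    return DiploidDistribution(cells.n, props, stage=cells.stage)


def gamete_mean_fitness(
    gametes: GameteDistribution, spec: FitnessSpec
) -> dict[str, float]:
    """Mean gamete-rescaled fitness per allele (reporting only).

    Gametes are not under selection; this tracks the fitness a diploid cell
    would have with each gamete's mitochondrial composition (capacity n/2, so
    the minimum sits near p = n/4).  Alleles with no mass get NaN.
    """
    w = gamete_fitness_vector(gametes.n, spec)
    out: dict[str, float] = {}
    for g, v in gametes.props.items():
        m = float(v.sum())
        out[g] = float((v * w).sum() / m) if m > 0 else float("nan")
    return out
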