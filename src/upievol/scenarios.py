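"""Named model scenarios: alleles, genotypes, mating rules and meiosis maps.

Each builder assembles a :class:`ScenarioSpec` describing one inheritance
regime:

``linked``
    Two self-incompatible mating types with the inheritance locus tightly
    linked to the mating-type locus.  Alleles U1, B1, B2; viable genotypes
    U1B2 (uniparental from U1) and B1B2 (biparental).
``recombination``
    The two loci recombine with probability P_r at meiosis of
    inheritance-heterozygous genotypes, so four alleles (U1, U2, B1, B2) and
    four genotypes exist and U1 x U2 matings become possible.
``no_mating_types``
    A single compatibility class: alleles U and B, all pairings viable.
``mitosis``
    The linked model with mitotic divisions (vegetative segregation) inserted
    into each generation, either all before selection or half before and half
    after ("midway").
``physarum``
    The linked model with leaky uniparental inheritance: U1 x B2 matings are
    biparental with probability P_b.
``didymium``
    The recombination model with a random/biased mitochondrial donor in
    U1 x U2 matings: uniparental from U1 with probability P_U1, from U2 with
    probability P_U2, biparental with probability P_b (summing to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lifecycle import MatingRule, Transmission, genotype_label

__all__ = [
    "ScenarioSpec",
    "build_linked",
    "build_recombination",
    "build_no_mating_types",
    "build_mitosis",
    "build_physarum",
    "build_didymium",
    "build_scenario",
]

UU_REGIMES = ("uniparental", "biparental", "mixture")
MITOSIS_TIMINGS = ("before_selection", "midway")


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete structural description of one inheritance scenario."""

    name: str
    alleles: tuple[str, ...]
    genotypes: tuple[str, ...]
    rules: tuple[MatingRule, ...]
    #: per genotype, weight of each gamete allele among its meiotic products
    allele_map: dict[str, dict[str, float]]
    #: gamete allele frequencies of the ancestral (pre-introduction) population
    initial_freqs: dict[str, float]
    #: allele introduced after burn-in, and the allele it mutates from
    intro_allele: str
    intro_source: str
    divisions: int = 0
    mitosis_timing: str = "before_selection"
    #: scenario parameters for provenance (P_r, P_b, ...)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for G, weights in self.allele_map.items():
            tot = sum(weights.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"allele map for {G} sums to {tot}")
        if abs(sum(self.initial_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("initial allele frequencies must sum to 1")
        if self.divisions < 0:
            raise ValueError("divisions must be >= 0")
        if self.mitosis_timing not in MITOSIS_TIMINGS:
            raise ValueError(f"mitosis_timing must be one of {MITOSIS_TIMINGS}")
        if self.mitosis_timing == "midway" and self.divisions % 2 != 0:
            raise ValueError("midway mitosis timing requires an even division count")

    def uniparental_probabilities(self) -> dict[str, float]:
        """Per genotype, the probability that the mating forming it transmitted
        mitochondria uniparentally."""
        out = {}
        for rule in self.rules:
            G = genotype_label(*rule.parents, self.alleles)
            out[G] = rule.uniparental_probability
        return out


def _uni(donor: str) -> tuple[Transmission, ...]:
    return (Transmission(1.0, "uniparental", donor),)


def _bi() -> tuple[Transmission, ...]:
    return (Transmission(1.0, "biparental"),)


def _uu_components(
    regime: str, g1: str, g2: str, p_b: float
) -> tuple[Transmission, ...]:
    """Transmission of a U x U mating under the three regimes."""
    if regime == "uniparental":
        return (
            Transmission(0.5, "uniparental", g1),
            Transmission(0.5, "uniparental", g2),
        )
    if regime == "biparental":
        return _bi()
    if regime == "mixture":
        if not 0.0 <= p_b <= 1.0:
            raise ValueError(f"P_b must lie in [0, 1], got {p_b}")
        return (
            Transmission(p_b, "biparental"),
            Transmission((1.0 - p_b) / 2.0, "uniparental", g1),
            Transmission((1.0 - p_b) / 2.0, "uniparental", g2),
        )
    raise ValueError(f"uu_regime must be one of {UU_REGIMES}, got {regime!r}")


def build_linked() -> ScenarioSpec:
    """Two mating types, tight linkage: the ancestral biparental population is
    invaded by a uniparental allele on the mating-type-1 background."""
    alleles = ("U1", "B1", "B2")
    rules = (
        MatingRule(("U1", "B2"), _uni("U1")),
        MatingRule(("B1", "B2"), _bi()),
    )
    return ScenarioSpec(
        name="linked",
        alleles=alleles,
        genotypes=("U1B2", "B1B2"),
        rules=rules,
        allele_map={
            "U1B2": {"U1": 0.5, "B2": 0.5},
            "B1B2": {"B1": 0.5, "B2": 0.5},
        },
        initial_freqs={"B1": 0.5, "B2": 0.5},
        intro_allele="U1",
        intro_source="B1",
    )


def build_recombination(
    p_r: float, uu_regime: str, p_b: float = 0.0
) -> ScenarioSpec:
    """Recombination between the inheritance and mating-type loci.

    Meiosis of the inheritance-heterozygous genotypes (U1B2, U2B1) emits
    recombinant alleles with total weight ``p_r`` split equally between the two
    recombinant classes; U1U2 and B1B2 carry a single inheritance-allele class
    on both chromatids and are unaffected.
    """
    if not 0.0 <= p_r <= 1.0:
        raise ValueError(f"P_r must lie in [0, 1], got {p_r}")
    alleles = ("U1", "U2", "B1", "B2")
    rules = (
        MatingRule(("U1", "B2"), _uni("U1")),
        MatingRule(("U2", "B1"), _uni("U2")),
        MatingRule(("U1", "U2"), _uu_components(uu_regime, "U1", "U2", p_b)),
        MatingRule(("B1", "B2"), _bi()),
    )
    return ScenarioSpec(
        name="recombination",
        alleles=alleles,
        genotypes=("U1B2", "U2B1", "U1U2", "B1B2"),
        rules=rules,
        allele_map={
            "U1B2": {
                "U1": (1.0 - p_r) / 2.0,
                "B2": (1.0 - p_r) / 2.0,
                "U2": p_r / 2.0,
                "B1": p_r / 2.0,
            },
            "U2B1": {
                "U2": (1.0 - p_r) / 2.0,
                "B1": (1.0 - p_r) / 2.0,
                "U1": p_r / 2.0,
                "B2": p_r / 2.0,
            },
            "U1U2": {"U1": 0.5, "U2": 0.5},
            "B1B2": {"B1": 0.5, "B2": 0.5},
        },
        initial_freqs={"B1": 0.5, "B2": 0.5},
        intro_allele="U1",
        intro_source="B1",
        params={"p_r": p_r, "uu_regime": uu_regime, "p_b": p_b},
    )


def build_no_mating_types(uu_regime: str, p_b: float = 0.0) -> ScenarioSpec:
    """No mating types: a single gamete pool with alleles U and B and every
    pairing viable (like-pairs carry no ordering factor of 2)."""
    alleles = ("U", "B")
    rules = (
        MatingRule(("U", "B"), _uni("U")),
        MatingRule(("U", "U"), _uu_components(uu_regime, "U", "U", p_b)),
        MatingRule(("B", "B"), _bi()),
    )
    return ScenarioSpec(
        name="no_mating_types",
        alleles=alleles,
        genotypes=("UU", "UB", "BB"),
        rules=rules,
        allele_map={
            "UU": {"U": 1.0},
            "UB": {"U": 0.5, "B": 0.5},
            "BB": {"B": 1.0},
        },
        initial_freqs={"B": 1.0},
        intro_allele="U",
        intro_source="B",
        params={"uu_regime": uu_regime, "p_b": p_b},
    )


def build_mitosis(d: int, timing: str = "before_selection") -> ScenarioSpec:
    """The linked model with ``d`` mitotic divisions (vegetative segregation)
    per generation, applied before selection or split around it."""
    base = build_linked()
    return ScenarioSpec(
        name="mitosis",
        alleles=base.alleles,
        genotypes=base.genotypes,
        rules=base.rules,
        allele_map=base.allele_map,
        initial_freqs=base.initial_freqs,
        intro_allele=base.intro_allele,
        intro_source=base.intro_source,
        divisions=d,
        mitosis_timing=timing,
        params={"d": d, "timing": timing},
    )


def build_physarum(p_b: float) -> ScenarioSpec:
    """Leaky uniparental inheritance: U1 x B2 matings are biparental with
    probability ``p_b``, uniparental from U1 otherwise."""
    if not 0.0 <= p_b <= 1.0:
        raise ValueError(f"P_b must lie in [0, 1], got {p_b}")
    base = build_linked()
    rules = (
        MatingRule(
            ("U1", "B2"),
            (
                Transmission(1.0 - p_b, "uniparental", "U1"),
                Transmission(p_b, "biparental"),
            )
            if p_b > 0.0
            else _uni("U1"),
        ),
        MatingRule(("B1", "B2"), _bi()),
    )
    return ScenarioSpec(
        name="physarum",
        alleles=base.alleles,
        genotypes=base.genotypes,
        rules=rules,
        allele_map=base.allele_map,
        initial_freqs=base.initial_freqs,
        intro_allele=base.intro_allele,
        intro_source=base.intro_source,
        params={"p_b": p_b},
    )


def build_didymium(
    p_u1: float, p_u2: float, p_b: float, p_r: float = 0.5
) -> ScenarioSpec:
    """Random or biased uniparental donor: U1 x U2 matings transmit from U1
    with probability ``p_u1``, from U2 with probability ``p_u2`` and
    biparentally with probability ``p_b`` (summing to 1), in the recombination
    scenario."""
    tot = p_u1 + p_u2 + p_b
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"P_U1 + P_U2 + P_b must equal 1, got {tot}")
    if min(p_u1, p_u2, p_b) < 0.0:
        raise ValueError("probabilities must be nonnegative")
    base = build_recombination(p_r, "biparental")
    components = tuple(
        t
        for t in (
            Transmission(p_u1, "uniparental", "U1") if p_u1 > 0 else None,
            Transmission(p_u2, "uniparental", "U2") if p_u2 > 0 else None,
            Transmission(p_b, "biparental") if p_b > 0 else None,
        )
        if t is not None
    )
    rules = tuple(
        MatingRule(("U1", "U2"), components) if rule.parents == ("U1", "U2") else rule
        for rule in base.rules
    )
    return ScenarioSpec(
        name="didymium",
        alleles=base.alleles,
        genotypes=base.genotypes,
        rules=rules,
        allele_map=base.allele_map,
        initial_freqs=base.initial_freqs,
        intro_allele=base.intro_allele,
        intro_source=base.intro_source,
        params={"p_u1": p_u1, "p_u2": p_u2, "p_b": p_b, "p_r": p_r},
    )


def build_scenario(name: str, **kwargs) -> ScenarioSpec:
    """Dispatch a scenario builder by name (CLI entry point)."""
    builders = {
        "linked": build_linked,
        "recombination": build_recombination,
        "no_mating_types": build_no_mating_types,
        "mitosis": build_mitosis,
        "physarum": build_physarum,
        "didymium": build_didymium,
    }
    key = name.replace("-", "_")
    if key not in builders:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(builders)}")
    return builders[key](**kwargs)
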