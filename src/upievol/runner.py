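"""Orchestration: burn-in, introduction of the uniparental allele, iteration
to equilibrium, and run summaries.

A run starts from a homoplasmic wild-type population of biparental gametes,
iterates the life cycle until mutation-selection equilibrium (the maximum
absolute change of any gamete-stage proportion between consecutive generations
falls below ``eq_tol``), converts a small fraction of gametes to the
uniparental allele, and iterates to the final equilibrium.  All dynamics are
deterministic: identical configurations produce bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .kernels import (
    FitnessSpec,
    doubling_kernel,
    fitness_vector,
    meiosis_kernel,
    mitosis_kernel,
    mutation_kernel,
)
from .lifecycle import (
    DegeneratePopulationError,
    DiploidDistribution,
    GameteDistribution,
    gamete_mean_fitness,
    genotype_label,
    mate,
    meiose,
    mitose,
    mutate,
    select,
)
from .scenarios import ScenarioSpec

__all__ = [
    "RunConfig",
    "RunSummary",
    "init_population",
    "step_generation",
    "run_to_equilibrium",
    "introduce_upi",
    "upi_frequency",
    "simulate",
]

INTRO_PLACEMENTS = ("homoplasmic_wild", "most_heteroplasmic_above_freq")
MITOSIS_ORDERS = ("after_mutation", "before_mutation")
FIXATION_THRESHOLD = 1.0 - 1e-6


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one deterministic run.

    ``eq_tol`` defaults to 1e-12, tightened to 1e-13 when mu = 1e-10 (changes
    per generation are then so small that the looser tolerance would trigger
    before the population is stationary).  ``mu_b`` defaults to ``mu``.
    """

    n: int
    mu: float
    scenario: ScenarioSpec
    fitness: FitnessSpec
    mu_b: float | None = None
    intro_freq: float = 1e-2
    intro_placement: str = "homoplasmic_wild"
    eq_tol: float | None = None
    max_generations: int = 5_000_000
    trace_every: int = 1
    #: record full stage distributions every k-th generation (0 disables)
    snapshot_every: int = 0
    mitosis_order: str = "after_mutation"
    #: equilibrium metric for the post-introduction phase: "per_type" stops
    #: when every (allele, count) gamete proportion is stationary; "allele"
    #: stops when the allele frequencies are (the criterion that ends the
    #: simulation once the inheritance alleles stop moving, even while the
    #: quasi-neutral haplotype ratio inside a fixed pool still drifts on the
    #: ~1/mu timescale).  Burn-in always uses the per-type metric.
    eq_metric: str = "per_type"

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2 != 0:
            raise ValueError(f"n must be even and >= 2, got {self.n}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if self.mu_b is not None and not 0.0 <= self.mu_b <= 1.0:
            raise ValueError(f"mu_b must lie in [0, 1], got {self.mu_b}")
        if not 0.0 <= self.intro_freq < 0.5:
            raise ValueError(f"intro_freq must lie in [0, 0.5), got {self.intro_freq}")
        if self.intro_placement not in INTRO_PLACEMENTS:
            raise ValueError(f"intro_placement must be one of {INTRO_PLACEMENTS}")
        if self.eq_tol is not None and self.eq_tol <= 0:
            raise ValueError("eq_tol must be positive")
        if self.trace_every < 1:
            raise ValueError("trace_every must be >= 1")
        if self.snapshot_every < 0:
            raise ValueError("snapshot_every must be >= 0")
        if self.mitosis_order not in MITOSIS_ORDERS:
            raise ValueError(f"mitosis_order must be one of {MITOSIS_ORDERS}")
        if self.eq_metric not in ("per_type", "allele"):
            raise ValueError("eq_metric must be 'per_type' or 'allele'")

    @property
    def mu_back(self) -> float:
        return self.mu if self.mu_b is None else self.mu_b

    @property
    def tol(self) -> float:
        if self.eq_tol is not None:
            return self.eq_tol
        return 1e-13 if self.mu == 1e-10 else 1e-12


@dataclass
class RunSummary:
    """Outcome of :func:`simulate`."""

    config: RunConfig
    generations_to_first_equilibrium: int
    generations_to_final_equilibrium: int
    burn_in_converged: bool
    converged: bool
    equilibrium_allele_freqs: dict[str, float]
    equilibrium_genotype_freqs: dict[str, float]
    equilibrium_upi_frequency: float
    fixation: bool
    final_gametes: GameteDistribution
    trace: pd.DataFrame = field(repr=False)
    #: (generation, phase, gamete props, post-mating props) full-distribution
    #: snapshots, recorded every ``snapshot_every`` generations when enabled
    snapshots: list[tuple] = field(default_factory=list, repr=False)


def init_population(config: RunConfig) -> GameteDistribution:
    """Ancestral population: the scenario's initial alleles, all homoplasmic
    for the wild-type haplotype (count 0)."""
    half = config.n // 2
    props = {}
    for allele, freq in config.scenario.initial_freqs.items():
        v = np.zeros(half + 1)
        v[0] = freq
        props[allele] = v
    return GameteDistribution(config.n, props)


def step_generation(
    gametes: GameteDistribution, config: RunConfig
) -> tuple[GameteDistribution, dict]:
    """One full generation: mate -> mutate -> [mitose] -> select -> meiose.

    With midway mitosis timing, half of the divisions precede selection and
    half follow it.  Diagnostics carry the post-mating distribution, genotype
    frequencies, per-genotype mean fitness (computed pre-selection), the
    uniparental-transmission frequency and the pre-normalization viable mass.
    """
    sc = config.scenario
    diploids = mate(gametes, sc.rules, sc.alleles)

    d_pre, d_post = sc.divisions, 0
    if sc.mitosis_timing == "midway":
        d_pre = d_post = sc.divisions // 2

    cells = diploids
    if sc.divisions and config.mitosis_order == "before_mutation":
        cells = mitose(cells, d_pre)
        cells = mutate(cells, config.mu, config.mu_back)
    else:
        cells = mutate(cells, config.mu, config.mu_back)
        if d_pre:
            cells = mitose(cells, d_pre)

    selected, mean_w = select(cells, config.fitness)
    if d_post:
        selected = mitose(selected, d_post)
    out = meiose(selected, sc.allele_map)

    diagnostics = {
        "post_mating": diploids,
        "genotype_freqs": diploids.genotype_frequencies(),
        "mean_fitness": mean_w,
        "upi_frequency": upi_frequency(diploids, sc),
        "viable_mass": diploids.viable_mass,
    }
    return out, diagnostics


def upi_frequency(diploids: DiploidDistribution, scenario: ScenarioSpec) -> float:
    """Expected fraction of matings transmitting mitochondria uniparentally:
    post-mating genotype frequencies weighted by each mating's uniparental
    transmission probability."""
    up = scenario.uniparental_probabilities()
    return float(
        sum(freq * up.get(G, 0.0) for G, freq in diploids.genotype_frequencies().items())
    )


def introduce_upi(gametes: GameteDistribution, config: RunConfig) -> GameteDistribution:
    """Convert ``intro_freq`` of the source allele's gametes to the
    uniparental allele.

    ``homoplasmic_wild`` places the new allele in homoplasmic wild-type
    gametes (count 0); ``most_heteroplasmic_above_freq`` places it in the most
    heteroplasmic source state whose proportion exceeds ``intro_freq``.  Total
    mass is unchanged.
    """
    sc = config.scenario
    f = config.intro_freq
    if f == 0.0:
        return gametes
    source = sc.intro_source
    props = {g: v.copy() for g, v in gametes.props.items()}
    src = props[source]
    if config.intro_placement == "homoplasmic_wild":
        idx = 0
    else:
        above = np.nonzero(src > f)[0]
        if above.size == 0:
            raise ValueError(
                f"no {source} gamete state has proportion above {f}; cannot place"
            )
        idx = int(above.max())
    if src[idx] < f:
        raise ValueError(
            f"state ({source}, count {idx}) holds {src[idx]:.3g} < intro_freq {f}"
        )
    src[idx] -= f
    intro = props.setdefault(sc.intro_allele, np.zeros_like(src))
    intro[idx] += f
    # keep scenario allele order for reproducible vector layout
    ordered = {g: props[g] for g in sc.alleles if g in props}
    return GameteDistribution(gametes.n, ordered)


class _Engine:
    """Precompiled single-generation update on plain arrays.

    Composes exactly the same kernels as the public stage functions (see the
    equivalence test in the suite) but avoids per-stage object construction,
    which matters over the millions of generations some equilibria need.
    State is a (n_alleles, n/2 + 1) proportion array in scenario allele order.
    """

    def __init__(self, config: RunConfig):
        sc = config.scenario
        n = config.n
        self.config = config
        self.alleles = sc.alleles
        self.genotypes = sc.genotypes
        self.n = n
        self.K_mut = mutation_kernel(n, config.mu, config.mu_back)
        self.K_mei = meiosis_kernel(n)
        self.D_half = doubling_kernel(n // 2)
        self.w = fitness_vector(n, config.fitness)
        d_pre, d_post = sc.divisions, 0
        if sc.mitosis_timing == "midway":
            d_pre = d_post = sc.divisions // 2
        self.K_mit_pre = mitosis_kernel(n, d_pre) if d_pre else None
        self.K_mit_post = mitosis_kernel(n, d_post) if d_post else None
        self.mitosis_first = (
            sc.divisions > 0 and config.mitosis_order == "before_mutation"
        )
        # (genotype idx, parent idx 1, parent idx 2, ordering factor, components)
        self.rules = []
        for rule in sc.rules:
            g1, g2 = rule.parents
            i1, i2 = self.alleles.index(g1), self.alleles.index(g2)
            gi = self.genotypes.index(genotype_label(g1, g2, self.alleles))
            factor = 2.0 if g1 != g2 else 1.0
            comps = [
                (c.weight, None if c.mode == "biparental" else self.alleles.index(c.donor))
                for c in rule.components
            ]
            self.rules.append((gi, i1, i2, factor, comps))
        up = sc.uniparental_probabilities()
        self.up = np.array([up.get(G, 0.0) for G in self.genotypes])
        # meiotic allele weights as a (genotypes x alleles) matrix
        self.A_map = np.zeros((len(self.genotypes), len(self.alleles)))
        for gi, G in enumerate(self.genotypes):
            for allele, weight in sc.allele_map[G].items():
                self.A_map[gi, self.alleles.index(allele)] = weight

    def state_from(self, gametes: GameteDistribution) -> np.ndarray:
        half = self.n // 2
        A = np.zeros((len(self.alleles), half + 1))
        for i, g in enumerate(self.alleles):
            if g in gametes.props:
                A[i] = gametes.props[g]
        return A

    def gametes_from(self, A: np.ndarray) -> GameteDistribution:
        return GameteDistribution(
            self.n, {g: A[i].copy() for i, g in enumerate(self.alleles)}
        )

    def step(
        self, A: np.ndarray, want_diag: bool = False
    ) -> tuple[np.ndarray, np.ndarray, dict | None]:
        n = self.n
        s = A.sum(axis=1)
        D2 = np.zeros((len(self.genotypes), n + 1))
        for gi, i1, i2, factor, comps in self.rules:
            v1, v2 = A[i1], A[i2]
            vec = np.zeros(n + 1)
            for weight, donor in comps:
                if donor is None:
                    vec += weight * np.convolve(v1, v2)
                else:
                    dvec, other = (v1, s[i2]) if donor == i1 else (v2, s[i1])
                    vec += (weight * other) * (dvec @ self.D_half)
            D2[gi] += factor * vec
        viable = D2.sum()
        if viable <= 0.0:
            raise DegeneratePopulationError("all mass fell on inviable matings")
        D2 /= viable

        cells = D2 @ self.K_mut if not self.mitosis_first else D2
        if self.K_mit_pre is not None:
            cells = cells @ self.K_mit_pre
        if self.mitosis_first:
            cells = cells @ self.K_mut
        selected = cells * self.w
        sigma = selected.sum()
        if sigma <= 0.0:
            raise DegeneratePopulationError("zero total fitness after selection")
        selected /= sigma
        if self.K_mit_post is not None:
            selected = selected @ self.K_mit_post

        G = selected @ self.K_mei
        A2 = self.A_map.T @ G
        if not want_diag:
            return A2, D2, None

        gfreq = D2.sum(axis=1)
        mass = cells.sum(axis=1)
        wsum = cells @ self.w
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_w = np.where(mass > 0, wsum / mass, np.nan)
        diag = {
            "genotype_freqs": dict(zip(self.genotypes, gfreq.tolist())),
            "mean_fitness": dict(zip(self.genotypes, mean_w.tolist())),
            "upi_frequency": float(gfreq @ self.up),
            "viable_mass": float(viable),
        }
        return A2, D2, diag

    def diploids_from(self, D2: np.ndarray) -> DiploidDistribution:
        return DiploidDistribution(
            self.n,
            {G: D2[i].copy() for i, G in enumerate(self.genotypes)},
            stage="post_mating",
        )


def run_to_equilibrium(
    gametes: GameteDistribution,
    config: RunConfig,
    on_step: Callable[[int, GameteDistribution, dict], None] | None = None,
    record_every: int = 1,
    metric: str = "per_type",
) -> tuple[GameteDistribution, int, bool]:
    """Iterate generations until the maximum absolute change of any
    gamete-stage proportion (``metric="per_type"``) or of any allele
    frequency (``metric="allele"``) falls below the equilibrium tolerance.

    Returns (final gametes, generations during which the population still
    changed, converged flag).  An input already at equilibrium therefore
    reports 0 generations.  Hitting ``max_generations`` returns
    ``converged=False`` rather than raising.  ``on_step`` is invoked every
    ``record_every``-th generation and on the final one, with the new gamete
    distribution and stage diagnostics.
    """
    tol = config.tol
    engine = _Engine(config)
    A = engine.state_from(gametes)
    per_type = metric == "per_type"
    gens = 0
    while True:
        want = on_step is not None and gens % record_every == 0
        A2, D2, diag = engine.step(A, want_diag=want)
        if per_type:
            delta = float(np.max(np.abs(A2 - A)))
        else:
            delta = float(np.max(np.abs(A2.sum(axis=1) - A.sum(axis=1))))
        done = delta < tol
        if on_step is not None and (want or done):
            if diag is None:  # final generation fell off the cadence
                _, D2, diag = engine.step(A, want_diag=True)
            diag["post_mating"] = engine.diploids_from(D2)
            on_step(gens, engine.gametes_from(A2), diag)
        if done:
            return engine.gametes_from(A2), gens, True
        gens += 1
        A = A2
        if gens >= config.max_generations:
            return engine.gametes_from(A), gens, False


def simulate(config: RunConfig, trace_burn_in: bool = False) -> RunSummary:
    """Full protocol: initialize, burn in to mutation-selection equilibrium,
    introduce the uniparental allele, iterate to the final equilibrium and
    summarize.

    Generations in the trace are counted from the introduction (generation 0
    is the first generation after the uniparental allele appears); burn-in
    generations, when traced, are negative.
    """
    records: list[dict] = []
    snapshots: list[tuple] = []
    sc = config.scenario

    def recorder(phase: str, sign: int):
        def on_step(t: int, gam: GameteDistribution, diag: dict) -> None:
            if config.snapshot_every and t % config.snapshot_every == 0:
                snapshots.append(
                    (
                        sign * t,
                        phase,
                        {g: v.copy() for g, v in gam.props.items()},
                        {G: v.copy() for G, v in diag["post_mating"].props.items()},
                    )
                )
            if t % config.trace_every:
                return
            row: dict = {"generation": sign * t, "phase": phase}
            for g, freq in gam.allele_frequencies().items():
                row[f"freq_{g}"] = freq
            for G, freq in diag["genotype_freqs"].items():
                row[f"geno_{G}"] = freq
            for G, w in diag["mean_fitness"].items():
                row[f"w_{G}"] = w
            for g, w in gamete_mean_fitness(gam, config.fitness).items():
                row[f"wg_{g}"] = w
            row["upi_frequency"] = diag["upi_frequency"]
            records.append(row)

        return on_step

    cadence = config.trace_every
    if config.snapshot_every:
        cadence = math.gcd(config.trace_every, config.snapshot_every)

    gametes = init_population(config)
    gametes, ge1, burn_ok = run_to_equilibrium(
        gametes,
        config,
        recorder("burn_in", -1) if trace_burn_in else None,
        record_every=cadence,
    )
    gametes = introduce_upi(gametes, config)

    last_diag: dict = {}

    main_recorder = recorder("main", 1)

    def on_step(t: int, gam: GameteDistribution, diag: dict) -> None:
        nonlocal last_diag
        last_diag = diag
        main_recorder(t, gam, diag)

    gametes, gens, converged = run_to_equilibrium(
        gametes, config, on_step, record_every=cadence, metric=config.eq_metric
    )

    geno = last_diag["genotype_freqs"]
    up = sc.uniparental_probabilities()
    upi_mass = sum(freq for G, freq in geno.items() if up.get(G, 0.0) > 0.0)
    trace = pd.DataFrame.from_records(records) if records else pd.DataFrame()
    return RunSummary(
        config=config,
        generations_to_first_equilibrium=ge1,
        generations_to_final_equilibrium=gens,
        burn_in_converged=burn_ok,
        converged=converged,
        equilibrium_allele_freqs=gametes.allele_frequencies(),
        equilibrium_genotype_freqs=geno,
        equilibrium_upi_frequency=last_diag["upi_frequency"],
        fixation=bool(upi_mass > FIXATION_THRESHOLD),
        final_gametes=gametes,
        trace=trace,
        snapshots=snapshots,
    )
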