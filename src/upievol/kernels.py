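"""Fitness functions and probability transition kernels.

The life cycle of the model is composed from four row-stochastic kernels acting
on distributions over mutant-haplotype counts:

* a *doubling* kernel (binomial sampling with replacement, appended to the
  source complement) used both to restore the diploid complement after
  uniparental mating and to double the complement before meiosis;
* a *mutation* kernel (two independent binomial draws: forward mutations among
  wild-type units at rate ``mu``, back mutations among mutant units at rate
  ``mu_b``);
* a *partition* kernel (hypergeometric sampling without replacement) that
  splits a doubled cell into gametes at meiosis;
* a *mitosis* kernel (doubling followed by a hypergeometric daughter draw)
  modelling vegetative segregation.

Cell fitness combines a cost of heteroplasmy (symmetric about the maximally
heteroplasmic state i = n/2) with an optional haplotype-accumulation component
for non-neutral mutant haplotypes.  All kernels are cached per parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import binom, hypergeom

__all__ = [
    "FitnessSpec",
    "heteroplasmy_fitness",
    "accumulation_fitness",
    "cell_fitness",
    "fitness_vector",
    "gamete_fitness_vector",
    "doubling_kernel",
    "mutation_kernel",
    "partition_kernel",
    "meiosis_kernel",
    "mitosis_kernel",
]

HET_SHAPES = ("concave", "linear", "convex")
DIRECTIONS = ("neutral", "deleterious", "advantageous")
ACC_SHAPES = ("concave", "convex")

#: rows of every kernel must sum to one within this tolerance
ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class FitnessSpec:
    """Parameters of the cell fitness function.

    Parameters
    ----------
    c_h
        Cost of heteroplasmy in [0, 1]: fitness decrement of the maximally
        heteroplasmic cell relative to homoplasmic cells.
    het_shape
        Shape of the heteroplasmy cost: ``"concave"``, ``"linear"`` or
        ``"convex"``.
    direction
        Whether the mutant haplotype is ``"neutral"``, ``"deleterious"`` or
        ``"advantageous"``.
    s
        Selection coefficient of the mutant haplotype (ignored when
        ``direction == "neutral"``).  A homoplasmic-mutant cell has fitness
        1 − s when deleterious; a homoplasmic-wild-type cell has fitness 1 − s
        when advantageous.
    acc_shape
        Shape of the accumulation component (``"concave"`` or ``"convex"``;
        ignored when neutral).
    """

    c_h: float
    het_shape: str = "concave"
    direction: str = "neutral"
    s: float = 0.0
    acc_shape: str = "concave"

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_h <= 1.0:
            raise ValueError(f"c_h must lie in [0, 1], got {self.c_h}")
        if self.het_shape not in HET_SHAPES:
            raise ValueError(f"het_shape must be one of {HET_SHAPES}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.direction != "neutral" and not 0.0 <= self.s < 1.0:
            raise ValueError(f"s must lie in [0, 1), got {self.s}")
        if self.acc_shape not in ACC_SHAPES:
            raise ValueError(f"acc_shape must be one of {ACC_SHAPES}")


def _het_weight(i: np.ndarray, capacity: int, c_h: float, shape: str) -> np.ndarray:
    """Piecewise heteroplasmy weight on 0..capacity, symmetric about capacity/2.

    Accepts odd capacities (needed for the gamete-rescaled fitness when n/2 is
    odd); the interior minimum is then between the two central states.
    """
    i = np.asarray(i, dtype=float)
    half = capacity / 2.0
    # distance ratio to the nearest homoplasmic state, in [0, 1]
    ratio = np.where(i < half, i / half, (capacity - i) / half)
    if shape == "concave":
        loss = ratio**2
    elif shape == "linear":
        loss = ratio
    elif shape == "convex":
        loss = np.sqrt(ratio)
    else:  # pragma: no cover - guarded by FitnessSpec
        raise ValueError(f"unknown shape {shape!r}")
    return 1.0 - c_h * loss


def _check_count(i, n: int) -> None:
    arr = np.asarray(i)
    if np.any(arr < 0) or np.any(arr > n):
        raise ValueError(f"mutant count must lie in 0..{n}, got {i}")


def heteroplasmy_fitness(i, n: int, c_h: float, shape: str = "concave"):
    """Relative fitness of a cell with ``i`` mutant units out of ``n``.

    Homoplasmic cells (i = 0 or i = n) have fitness 1; the maximally
    heteroplasmic cell (i = n/2) has fitness 1 − c_h.  ``shape`` selects a
    concave (squared), linear or convex (square-root) loss in the distance to
    the nearer homoplasmic state.
    """
    if n % 2 != 0:
        raise ValueError(f"cell capacity n must be even, got {n}")
    if not 0.0 <= c_h <= 1.0:
        raise ValueError(f"c_h must lie in [0, 1], got {c_h}")
    if shape not in HET_SHAPES:
        raise ValueError(f"shape must be one of {HET_SHAPES}")
    _check_count(i, n)
    out = _het_weight(np.asarray(i, dtype=float), n, c_h, shape)
    return float(out) if np.isscalar(i) else out


def accumulation_fitness(i, n: int, spec: FitnessSpec):
    """Fitness component tied to the total number of mutant units.

    Deleterious: decreases from 1 at i = 0 to 1 − s at i = n.  Advantageous:
    increases from 1 − s at i = 0 to 1 at i = n.  Neutral: identically 1.
    """
    _check_count(i, n)
    x = np.asarray(i, dtype=float) / n
    if spec.direction == "neutral":
        out = np.ones_like(x)
    elif spec.direction == "deleterious":
        loss = x**2 if spec.acc_shape == "concave" else np.sqrt(x)
        out = 1.0 - spec.s * loss
    else:  # advantageous
        loss = (1.0 - x) ** 2 if spec.acc_shape == "concave" else np.sqrt(1.0 - x)
        out = 1.0 - spec.s * loss
    return float(out) if np.isscalar(i) else out


def cell_fitness(i, n: int, spec: FitnessSpec):
    """Total relative fitness: heteroplasmy weight × accumulation weight."""
    het = heteroplasmy_fitness(i, n, spec.c_h, spec.het_shape)
    if spec.direction == "neutral":
        return het
    return het * accumulation_fitness(i, n, spec)


@lru_cache(maxsize=64)
def fitness_vector(n: int, spec: FitnessSpec) -> np.ndarray:
    """w(i) for i = 0..n as a read-only array (cached)."""
    w = np.asarray(cell_fitness(np.arange(n + 1), n, spec), dtype=float)
    w.flags.writeable = False
    return w


@lru_cache(maxsize=64)
def gamete_fitness_vector(n: int, spec: FitnessSpec) -> np.ndarray:
    """Fitness rescaled to the gamete complement n/2, for p = 0..n/2.

    Gametes are not under selection; this is the fitness a diploid cell would
    have with the gamete's mitochondrial composition, obtained by substituting
    n/2 for n in the cell fitness functions.  The minimum sits at p = n/4 when
    n is divisible by 4; for odd n/2 the piecewise form still applies, with the
    minimum between the two central states.
    """
    half = n // 2
    p = np.arange(half + 1)
    w = _het_weight(p, half, spec.c_h, spec.het_shape)
    if spec.direction != "neutral":
        w = w * np.asarray(accumulation_fitness(p, half, spec), dtype=float)
    w = np.asarray(w, dtype=float)
    w.flags.writeable = False
    return w


def _freeze(k: np.ndarray) -> np.ndarray:
    k.flags.writeable = False
    return k


@lru_cache(maxsize=64)
def doubling_kernel(m: int) -> np.ndarray:
    """Kernel from counts 0..m to 0..2m: draw m units with replacement from the
    m present and append them, so a source count p lands on p + k with
    probability Binomial(k; m, p/m)."""
    if m < 1:
        raise ValueError(f"capacity must be >= 1, got {m}")
    kern = np.zeros((m + 1, 2 * m + 1))
    k = np.arange(m + 1)
    for p in range(m + 1):
        kern[p, p : p + m + 1] = binom.pmf(k, m, p / m)
    return _freeze(kern)


@lru_cache(maxsize=64)
def mutation_kernel(n: int, mu: float, mu_b: float) -> np.ndarray:
    """Kernel on counts 0..n: each of the n − i0 wild-type units mutates
    forward with probability mu, each of the i0 mutant units back-mutates with
    probability mu_b, independently."""
    if not (0.0 <= mu <= 1.0 and 0.0 <= mu_b <= 1.0):
        raise ValueError(f"mutation rates must lie in [0, 1], got {mu}, {mu_b}")
    kern = np.zeros((n + 1, n + 1))
    for i0 in range(n + 1):
        fwd = binom.pmf(np.arange(n - i0 + 1), n - i0, mu)  # a new mutants
        back = binom.pmf(np.arange(i0 + 1), i0, mu_b)  # b reverted mutants
        # destination i = i0 + a - b: correlate the two pmfs
        joint = np.outer(fwd, back)
        for a in range(n - i0 + 1):
            for b in range(i0 + 1):
                kern[i0, i0 + a - b] += joint[a, b]
    return _freeze(kern)


@lru_cache(maxsize=64)
def partition_kernel(n: int) -> np.ndarray:
    """Kernel from doubled counts 0..2n to gamete counts 0..n/2: draw n/2 units
    without replacement from the 2n present (hypergeometric)."""
    if n % 2 != 0:
        raise ValueError(f"diploid capacity n must be even, got {n}")
    half = n // 2
    p = np.arange(half + 1)
    kern = np.zeros((2 * n + 1, half + 1))
    for l in range(2 * n + 1):
        kern[l] = hypergeom.pmf(p, 2 * n, l, half)
    return _freeze(kern)


@lru_cache(maxsize=64)
def meiosis_kernel(n: int) -> np.ndarray:
    """Composite kernel 0..n -> 0..n/2: double the complement, then partition
    into gametes."""
    return _freeze(doubling_kernel(n) @ partition_kernel(n))


@lru_cache(maxsize=64)
def mitosis_kernel(n: int, divisions: int = 1) -> np.ndarray:
    """Kernel on 0..n for ``divisions`` rounds of mitotic division.

    One division doubles the complement and draws a daughter's n units without
    replacement from the 2n; both daughters are retained and share this
    marginal law.
    """
    if divisions < 0:
        raise ValueError(f"divisions must be >= 0, got {divisions}")
    draw = np.zeros((2 * n + 1, n + 1))
    i = np.arange(n + 1)
    for l in range(2 * n + 1):
        draw[l] = hypergeom.pmf(i, 2 * n, l, n)
    one = doubling_kernel(n) @ draw
    return _freeze(np.linalg.matrix_power(one, divisions))
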