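"""Stateless primitives of the host-switching model.

The model follows a parasite population whose individuals each carry a
single quantitative phenotype ``p_i`` (a real number).  A host (resource)
imposes Gaussian stabilizing selection around its phenotypic optimum
``p_r``: the per-generation survival probability of an individual is

    S(p_i, p_r) = exp(-(p_i - p_r)^2 / (2 * sigma_r^2))

so a perfectly matched parasite survives with probability 1 and survival
decays with the standardized distance ``|p_i - p_r| / sigma_r``.
Reproduction is sexual with self-fertilization allowed: an offspring
phenotype is the midpoint of two uniformly drawn parents plus a Gaussian
mutational deviate of standard deviation ``sigma_v``.  Every generation a
single new resource is offered, with optimum drawn uniformly within
``delta_r`` of the current one, and each individual emigrates towards it
with probability ``d``.

These functions are pure (all randomness comes through an explicit
``numpy.random.Generator``) and are consumed by :mod:`hostswitch.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "SimulationParams",
    "PopulationState",
    "survival_probability",
    "draw_offspring_count",
    "generate_offspring",
    "propose_resource",
    "select_dispersers",
]


@dataclass(frozen=True)
class SimulationParams:
    """Model constants and run controls.

    Parameters
    ----------
    n0:
        Initial population size (individuals).
    b:
        Birth rate (expected offspring per individual per generation).
    K:
        Carrying capacity: hard cap on total population size, applied at
        reproduction.
    d:
        Per-individual emigration probability per generation, in [0, 1].
    sigma_r:
        Standard deviation of the Gaussian survival kernel (phenotype
        units).  All standardized distances are expressed in multiples
        of ``sigma_r``.
    sigma_v:
        Standard deviation of the mutational deviate added to each
        offspring (phenotype units).
    delta_r:
        Maximum offset of a newly offered resource optimum from the
        current one (phenotype units).
    p_r0:
        Optimum of the initially occupied resource (phenotype units).
    max_generations:
        Generation cap; a run stops here if the population has not gone
        extinct first.
    burn_in:
        Number of initial generations excluded from pooled statistics.
    offspring_law:
        How the integer number of offspring is drawn from the rate
        ``b * N``: ``"poisson"`` (default) draws Poisson(b*N);
        ``"binomial"`` gives each parent ``floor(b)`` offspring plus a
        Bernoulli(b - floor(b)) extra.  Both are truncated at ``K - N``.
    newborns_subject_to_events:
        If True, offspring born in generation ``n`` already take part in
        that generation's dispersal and mortality; by default they join
        the population untouched and are first exposed at ``n + 1``.
    failed_dispersers_die:
        If True, an emigrant that fails the colonization trial is lost.
        By default it returns to the occupied host and faces the same
        mortality there as every resident (survival evaluated at the
        current optimum), so a failed dispersal attempt is not in
        itself lethal.
    founder_mortality:
        If True (default), colonizers that pass the establishment trial
        still undergo the ordinary per-generation mortality of their
        generation, evaluated on the newly occupied resource — every
        individual faces host-imposed selection once per generation,
        dispersing or not.  If False, passing the colonization trial
        doubles as the founder's mortality for that generation.
    """

    n0: int = 1
    b: float = 0.5
    K: int = 500
    d: float = 0.05
    sigma_r: float = 0.5
    sigma_v: float = 0.2
    delta_r: float = 5.0
    p_r0: float = 5.0
    max_generations: int = 1000
    burn_in: int = 50
    offspring_law: Literal["poisson", "binomial"] = "poisson"
    newborns_subject_to_events: bool = False
    failed_dispersers_die: bool = False
    founder_mortality: bool = True

    def __post_init__(self) -> None:
        checks = [
            ("n0", self.n0 >= 1),
            ("b", self.b >= 0),
            ("K", self.K >= 1),
            ("d", 0.0 <= self.d <= 1.0),
            ("sigma_r", self.sigma_r > 0),
            ("sigma_v", self.sigma_v >= 0),
            ("delta_r", self.delta_r >= 0),
            ("max_generations", self.max_generations >= 0),
            ("burn_in", self.burn_in >= 0),
            ("offspring_law", self.offspring_law in ("poisson", "binomial")),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(
                    f"invalid parameter {name!r}: {getattr(self, name)!r}"
                )
        if self.n0 > self.K:
            raise ValueError(f"invalid parameter 'n0': {self.n0} exceeds K={self.K}")

    def with_overrides(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


@dataclass
class PopulationState:
    """Phenotypes of the living parasites and the occupied resource.

    ``last_switch_generation`` tracks the generation of the most recent
    established colonization (0 for the founding population), so the
    time since the last host switch is available per generation.
    """

    phenotypes: np.ndarray
    resource_optimum: float
    generation: int = 0
    last_switch_generation: int = 0

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.float64)

    @property
    def size(self) -> int:
        return int(self.phenotypes.size)

    @property
    def extinct(self) -> bool:
        return self.phenotypes.size == 0


def survival_probability(
    phenotype: np.ndarray | float,
    optimum: float,
    sigma_r: float,
) -> np.ndarray | float:
    """Survival probability of phenotype(s) under a host with optimum ``optimum``.

    Gaussian kernel ``exp(-z^2 / 2)`` with ``z = (phenotype - optimum) /
    sigma_r``; equals 1 exactly at zero distance and is strictly
    decreasing in ``|z|``.  Accepts scalars or arrays (broadcast).
    """
    if sigma_r <= 0:
        raise ValueError(f"invalid parameter 'sigma_r': {sigma_r!r} (must be > 0)")
    z = (np.asarray(phenotype, dtype=np.float64) - optimum) / sigma_r
    out = np.exp(-0.5 * z * z)
    if np.isscalar(phenotype) or np.ndim(phenotype) == 0:
        return float(out)
    return out


def draw_offspring_count(
    current_size: int,
    b: float,
    K: int,
    rng: np.random.Generator,
    law: str = "poisson",
) -> int:
    """Number of offspring produced this generation, capped at ``K - current_size``.

    The birth rate ``b`` is a per-capita expectation; with the default
    ``"poisson"`` law the count is Poisson(b * N).  The ``"binomial"``
    law gives every parent ``floor(b)`` offspring plus one more with
    probability ``b - floor(b)``.  Either way the total population never
    exceeds the carrying capacity.
    """
    if current_size > K:
        raise ValueError(
            f"invalid state: population size {current_size} exceeds K={K}"
        )
    if current_size < 0:
        raise ValueError(f"invalid state: negative population size {current_size}")
    room = K - current_size
    if current_size == 0 or room == 0 or b == 0:
        return 0
    if law == "poisson":
        count = int(rng.poisson(b * current_size))
    elif law == "binomial":
        whole = int(np.floor(b))
        frac = b - whole
        count = whole * current_size + int(rng.binomial(current_size, frac))
    else:
        raise ValueError(f"unknown offspring law {law!r}")
    return min(count, room)


def generate_offspring(
    parent_pool: np.ndarray,
    count: int,
    sigma_v: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``count`` offspring phenotypes from ``parent_pool``.

    Each offspring is the arithmetic mean of an ordered pair of parents
    drawn uniformly with replacement (the first parent is returned to
    the pool before the second draw, so self-fertilization happens with
    probability 1/N), plus an independent Normal(0, sigma_v) mutational
    deviate.
    """
    if sigma_v < 0:
        raise ValueError(f"invalid parameter 'sigma_v': {sigma_v!r}")
    parent_pool = np.asarray(parent_pool, dtype=np.float64)
    if count == 0:
        return np.empty(0, dtype=np.float64)
    if parent_pool.size == 0:
        raise ValueError("invalid state: cannot generate offspring from an empty pool")
    n = parent_pool.size
    first = parent_pool[rng.integers(0, n, size=count)]
    second = parent_pool[rng.integers(0, n, size=count)]
    midpoints = (first + second) / 2.0
    deviates = sigma_v * rng.standard_normal(count)
    return midpoints + deviates


def propose_resource(
    current_optimum: float,
    delta_r: float,
    rng: np.random.Generator,
) -> float:
    """Optimum of the resource offered this generation.

    Uniform on ``[current_optimum - delta_r, current_optimum + delta_r]``.
    """
    if delta_r < 0:
        raise ValueError(f"invalid parameter 'delta_r': {delta_r!r}")
    # written as optimum + delta_r * u, u ~ U(-1, 1), so that rescaling all
    # phenotype-unit quantities by a power of two is bit-exact under a
    # coupled RNG stream
    u = rng.uniform(-1.0, 1.0)
    return current_optimum + delta_r * u


def select_dispersers(
    population_size: int,
    d: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask over individuals: True = attempts dispersal this generation.

    Each individual emigrates independently with probability ``d``.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"invalid parameter 'd': {d!r} (must be in [0, 1])")
    if population_size == 0:
        return np.zeros(0, dtype=bool)
    return rng.random(population_size) < d
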