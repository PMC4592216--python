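"""Per-generation cycle and replicate driver.

Each generation the population (1) reproduces up to the carrying
capacity, (2) is offered one new resource whose optimum is uniform
within ``delta_r`` of the current one, (3) sends a random fraction of
emigrants to attempt colonization, each reaching the offered resource
with the Gaussian kernel evaluated at the *new* optimum, and (4)
undergoes mortality: colonizers under the new optimum, everybody else
(including, by default, emigrants whose attempt failed and who
returned) under the *current* optimum.  A host switch establishes only
if at least one colonizer is alive on the offered resource at the end
of the generation; the simulation then follows those founders alone —
the population left on the ancestral host is dropped from the model and
the new resource becomes the occupied one.

A colonization event is *successful* if the founded lineage does not go
extinct before the next established colonization (or before the run's
generation cap); it is a *failed* attempt if extinction comes first.
Classification is therefore retrospective, over a finished run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    PopulationState,
    SimulationParams,
    draw_offspring_count,
    generate_offspring,
    propose_resource,
    select_dispersers,
    survival_probability,
)

__all__ = [
    "GenerationRecord",
    "ColonizationEvent",
    "RunResult",
    "colonization_trial",
    "step_generation",
    "run_simulation",
    "classify_outcomes",
    "RECORD_COLUMNS",
    "EVENT_COLUMNS",
]


class GenerationRecord(NamedTuple):
    """End-of-generation observables for one generation of one run."""

    generation: int
    population_size: int
    p_min: float
    p_max: float
    resource_optimum: float
    offered_optimum: float
    n_dispersers: int
    n_founders: int
    switch_occurred: bool
    time_since_switch: int


RECORD_COLUMNS = list(GenerationRecord._fields)

EVENT_COLUMNS = [
    "generation",
    "source_optimum",
    "target_optimum",
    "standardized_distance",
    "n_founders",
    "pre_switch_size",
    "pre_switch_IS",
    "time_since_last_switch",
    "outcome",
    "resolution_generation",
]


@dataclass
class ColonizationEvent:
    """One established colonization (>= 1 surviving founder).

    Covariates (``pre_switch_*``, ``time_since_last_switch``) describe
    the source population at the start of the generation in which the
    establishment happened, i.e. just before the switch.  ``outcome``
    starts ``"pending"`` and is resolved exactly once to ``"success"``
    or ``"failure"`` by :func:`classify_outcomes`.
    """

    generation: int
    source_optimum: float
    target_optimum: float
    standardized_distance: float
    founder_phenotypes: np.ndarray
    pre_switch_size: int
    pre_switch_IS: float
    time_since_last_switch: int
    outcome: Literal["pending", "success", "failure"] = "pending"
    resolution_generation: Optional[int] = None

    @property
    def n_founders(self) -> int:
        return int(np.size(self.founder_phenotypes))

    def as_row(self) -> dict:
        return {
            "generation": self.generation,
            "source_optimum": self.source_optimum,
            "target_optimum": self.target_optimum,
            "standardized_distance": self.standardized_distance,
            "n_founders": self.n_founders,
            "pre_switch_size": self.pre_switch_size,
            "pre_switch_IS": self.pre_switch_IS,
            "time_since_last_switch": self.time_since_last_switch,
            "outcome": self.outcome,
            "resolution_generation": (
                -1 if self.resolution_generation is None else self.resolution_generation
            ),
        }


@dataclass
class RunResult:
    """Trajectory of one replicate.

    ``records`` holds one :class:`GenerationRecord` per simulated
    generation (generations ``1 .. final_generation``; generation 0 is
    the initial state and has no record).  ``termination`` is
    ``"extinct"`` if the population died out, else ``"reached_cap"``.
    """

    records: list[GenerationRecord]
    events: list[ColonizationEvent]
    termination: Literal["extinct", "reached_cap"]
    final_generation: int
    params: SimulationParams
    seed: object = None

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=RECORD_COLUMNS)

    def events_frame(self) -> pd.DataFrame:
        if not self.events:
            return pd.DataFrame(columns=EVENT_COLUMNS)
        return pd.DataFrame([e.as_row() for e in self.events], columns=EVENT_COLUMNS)


def colonization_trial(
    disperser_phenotypes: np.ndarray,
    target_optimum: float,
    sigma_r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of dispersers that survive on the offered resource.

    Each disperser independently survives with the Gaussian kernel
    evaluated at the target optimum.  For ``m`` dispersers all at
    standardized distance ``z`` the establishment probability (>= 1
    survivor) is ``1 - (1 - exp(-z^2/2))**m``.
    """
    disperser_phenotypes = np.asarray(disperser_phenotypes, dtype=np.float64)
    if disperser_phenotypes.size == 0:
        return np.zeros(0, dtype=bool)
    s = survival_probability(disperser_phenotypes, target_optimum, sigma_r)
    return rng.random(disperser_phenotypes.size) < s


def step_generation(
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[PopulationState, GenerationRecord, Optional[ColonizationEvent]]:
    """Advance the population by one generation.

    Stochastic draws consume the stream in a fixed order (offspring
    count, parent pairs, mutation deviates, resource proposal, dispersal
    flags, colonization trials, resident mortality trials), so a run is
    bit-reproducible from ``(params, seed)``.
    """
    if state.extinct:
        raise ValueError("invalid state: cannot step an extinct population")

    pop = state.phenotypes
    p_r = state.resource_optimum
    gen = state.generation + 1

    # (1) reproduction, capped at K
    n_off = draw_offspring_count(pop.size, params.b, params.K, rng, params.offspring_law)
    offspring = generate_offspring(pop, n_off, params.sigma_v, rng)

    # (2) one resource offered per generation
    p_new = propose_resource(p_r, params.delta_r, rng)

    # (3) dispersal among eligible individuals; newborns are exempt by
    # default and first face dispersal/mortality in the next generation
    if params.newborns_subject_to_events:
        eligible = np.concatenate([pop, offspring])
        offspring = np.empty(0, dtype=np.float64)
    else:
        eligible = pop
    disperse_mask = select_dispersers(eligible.size, params.d, rng)
    dispersers = eligible[disperse_mask]

    # (4) colonization trial on the offered resource.  With
    # founder_mortality (default) a colonizer must also survive this
    # generation's ordinary mortality, evaluated on the new host: a
    # switch establishes only if somebody is alive on the offered
    # resource at the end of the generation, otherwise the residents
    # simply carry on and the emigration leaves no trace.
    reached_mask = colonization_trial(dispersers, p_new, params.sigma_r, rng)
    founder_mask = reached_mask.copy()
    if params.founder_mortality and reached_mask.any():
        survived = colonization_trial(
            dispersers[reached_mask], p_new, params.sigma_r, rng
        )
        founder_mask[np.flatnonzero(reached_mask)[~survived]] = False
    founders = dispersers[founder_mask]

    event: Optional[ColonizationEvent] = None
    if founders.size > 0:
        # establishment: follow the founders; the ancestral population
        # (residents and same-generation offspring) leaves the model
        new_pop = founders
        new_optimum = p_new
        event = ColonizationEvent(
            generation=gen,
            source_optimum=p_r,
            target_optimum=p_new,
            standardized_distance=abs(p_r - p_new) / params.sigma_r,
            founder_phenotypes=founders.copy(),
            pre_switch_size=pop.size,
            pre_switch_IS=(pop.max() - pop.min()) / params.sigma_r,
            time_since_last_switch=state.generation - state.last_switch_generation,
        )
        last_switch = gen
    else:
        # (5) no establishment: mortality under the currently occupied
        # resource.  By default emigrants whose colonization attempt
        # failed return to the occupied host and face that same
        # mortality; with failed_dispersers_die they are lost outright.
        # emigrants that never reached the new host return (unless
        # failed_dispersers_die); the ones that reached it but died
        # under its selection are gone either way
        residents = eligible[~disperse_mask]
        if params.failed_dispersers_die:
            pool = residents
        else:
            pool = np.concatenate([residents, dispersers[~reached_mask]])
        alive = colonization_trial(pool, p_r, params.sigma_r, rng)
        new_pop = np.concatenate([pool[alive], offspring])
        new_optimum = p_r
        last_switch = state.last_switch_generation

    new_state = PopulationState(
        phenotypes=new_pop,
        resource_optimum=new_optimum,
        generation=gen,
        last_switch_generation=last_switch,
    )
    record = GenerationRecord(
        generation=gen,
        population_size=new_pop.size,
        p_min=float(new_pop.min()) if new_pop.size else float("nan"),
        p_max=float(new_pop.max()) if new_pop.size else float("nan"),
        resource_optimum=new_optimum,
        offered_optimum=p_new,
        n_dispersers=int(disperse_mask.sum()),
        n_founders=int(founders.size),
        switch_occurred=founders.size > 0,
        time_since_switch=gen - last_switch,
    )
    return new_state, record, event


def run_simulation(
    params: SimulationParams,
    seed,
    initial_phenotypes: Optional[Sequence[float]] = None,
) -> RunResult:
    """Run one replicate until extinction or the generation cap.

    The population starts as ``n0`` copies of the initial optimum
    ``p_r0`` (perfectly adapted founder), unless ``initial_phenotypes``
    overrides it (testing hook).  ``seed`` may be anything accepted by
    ``numpy.random.default_rng``.
    """
    rng = np.random.default_rng(seed)
    if initial_phenotypes is None:
        phenotypes = np.full(params.n0, params.p_r0, dtype=np.float64)
    else:
        phenotypes = np.asarray(initial_phenotypes, dtype=np.float64)
    state = PopulationState(phenotypes=phenotypes, resource_optimum=params.p_r0)

    records: list[GenerationRecord] = []
    events: list[ColonizationEvent] = []
    termination: Literal["extinct", "reached_cap"] = "reached_cap"
    for _ in range(params.max_generations):
        state, record, event = step_generation(state, params, rng)
        records.append(record)
        if event is not None:
            events.append(event)
        if state.extinct:
            termination = "extinct"
            break

    result = RunResult(
        records=records,
        events=events,
        termination=termination,
        final_generation=state.generation,
        params=params,
        seed=seed,
    )
    return result


def classify_outcomes(
    events: Sequence[ColonizationEvent],
    result: RunResult,
) -> list[ColonizationEvent]:
    """Resolve every pending event of a finished run, in place.

    Event ``k`` is a failure iff the population goes extinct after it
    and before any later colonization; it is a success if a later
    colonization establishes, or if the run reaches the generation cap
    with the population extant.
    """
    events = list(events)
    gens = [e.generation for e in events]
    if gens != sorted(gens):
        raise ValueError("invalid input: events must be ordered by generation")
    for k, ev in enumerate(events):
        if ev.outcome != "pending":
            raise ValueError(
                f"invalid input: event at generation {ev.generation} already resolved"
            )
        if k + 1 < len(events):
            ev.outcome = "success"
            ev.resolution_generation = events[k + 1].generation
        elif result.termination == "extinct":
            ev.outcome = "failure"
            ev.resolution_generation = result.final_generation
        else:
            ev.outcome = "success"
            ev.resolution_generation = result.final_generation
    return events
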