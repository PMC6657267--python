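"""Asynchronous, self-clocked, event-driven stochastic simulator.

Each cell owns an independent exponential timer whose rate grows with its
metabolic mutation count, and an action (asymmetric division, symmetric
division, apoptosis, migration) drawn at birth — the reactions do not
compete, so the action can be tossed when the timer is set.  When a timer
fires the action executes as a reaction:

* asymmetric division with a driver:    C -> C(d+u_i, m_m+1) + C(d, m_m+1)
* asymmetric division with a passenger: C -> C(m_n+1, m_m+1) + C(m_m+1)
* symmetric division with a driver:     C -> 2 C(d+u_i, m_m+1)
* symmetric division with a passenger:  C -> 2 C(m_n+1, m_m+1)
* apoptosis:                            C -> 0
* migration:                            C(k) -> C(k+1)

Every division consumes the parent and stamps one extra metabolic mutation
on each daughter.  An event whose daughters would leave the truncated state
space, overflow a per-(compartment, driver-count) capacity or exceed the
compartment energy budget is *put back*: the parent survives unchanged and
redraws both its timer and its action.  An optional drug removes every cell
matching its signature instantaneously at the administration time.
"""

from __future__ import annotations

import heapq
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .kinetics import (
    EnergyModel,
    KineticsParams,
    MutationExhaustedError,
    action_probabilities,
    compartment_energy,
    mutation_split,
    sample_waiting_time,
)
from .state_space import CellState, DriverOrderSpec, DrugSignature, matches_drug

ACTION_CODES = ("asym", "sym", "apop", "pass")


class EventRejected(Exception):
    """The drawn reaction would violate a state-space bound; put it back."""


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level settings for one simulated ensemble."""

    initial_cells: int
    t_end: float
    record_dt: float
    replicates: int = 1
    seed: int = 0
    t_drug: float | None = None
    drug: DrugSignature | None = None
    energy: EnergyModel = field(default_factory=EnergyModel)
    log_events: bool = False

    def __post_init__(self) -> None:
        if self.initial_cells < 1 or self.replicates < 1:
            raise ValueError("initial_cells and replicates must be >= 1")
        if self.t_end <= 0 or self.record_dt <= 0:
            raise ValueError("t_end and record_dt must be positive")
        if self.t_drug is not None:
            if self.drug is None:
                raise ValueError("t_drug given without a drug signature")
            if not 0.0 < self.t_drug < self.t_end:
                raise ValueError("t_drug must lie strictly inside (0, t_end)")

    @property
    def record_times(self) -> np.ndarray:
        n = int(math.floor(self.t_end / self.record_dt + 1e-9)) + 1
        return np.arange(n) * self.record_dt


@dataclass(frozen=True)
class EventRecord:
    """One processed scheduler event (bookkeeping for diagnostics/tests)."""

    time: float
    cell_id: int
    action: str  # asym | sym | apop | pass | drug_kill | rejected
    parent: CellState
    daughters: tuple[CellState, ...]


@dataclass
class PopulationTimeSeries:
    """Cell counts on a regular time grid, grouped by (compartment, m_d)."""

    times: np.ndarray  # (T,)
    counts: np.ndarray  # (T, k_max, m_d_max + 1)

    def total(self) -> np.ndarray:
        """Total population at each grid time."""
        return self.counts.sum(axis=(1, 2))

    def compartment_total(self, k: int) -> np.ndarray:
        """Total population of compartment ``k`` (1-based) over time."""
        return self.counts[:, k - 1, :].sum(axis=1)

    def to_dataframe(self, label: str = "counts") -> pd.DataFrame:
        """Tidy frame with columns (replicate, time, compartment, m_d, count)."""
        t_idx, k_idx, d_idx = np.meshgrid(
            np.arange(len(self.times)),
            np.arange(self.counts.shape[1]),
            np.arange(self.counts.shape[2]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "replicate": label,
                "time": self.times[t_idx.ravel()],
                "compartment": k_idx.ravel() + 1,
                "m_d": d_idx.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass
class ReplicateResult:
    series: PopulationTimeSeries
    events: list[EventRecord]
    post_drug_states: list[CellState] | None  # survivors right after the kill
    final_states: list[CellState]


@dataclass
class EnsembleResult:
    """Pointwise ensemble mean and standard deviation of the count series."""

    times: np.ndarray
    mean: np.ndarray  # (T, k_max, m_d_max + 1)
    sd: np.ndarray
    replicate_counts: np.ndarray  # (R, T, k_max, m_d_max + 1)

    @property
    def n_replicates(self) -> int:
        return self.replicate_counts.shape[0]

    def standard_error(self) -> np.ndarray:
        return self.sd / math.sqrt(self.n_replicates)

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            PopulationTimeSeries(self.times, self.mean).to_dataframe("mean"),
            PopulationTimeSeries(self.times, self.sd).to_dataframe("sd"),
        ]
        return pd.concat(frames, ignore_index=True)


def step_cell(
    state: CellState,
    rng: np.random.Generator,
    params: KineticsParams,
    order: DriverOrderSpec,
    action: str | None = None,
) -> list[CellState]:
    """Execute one reaction for a single cell and return its daughters.

    The action is drawn from :func:`action_probabilities` unless supplied
    (the scheduler pre-draws it at birth).  Raises :class:`EventRejected`
    when the daughters would leave the truncated state space or no mutable
    locus remains (every division carries a mutation).
    """
    if action is None:
        probs = action_probabilities(state, params, order)
        action = _draw_action(probs, rng)
    if action == "apop":
        return []
    if action == "pass":
        # k_pass in the rate guarantees can_migrate; bound check is defensive.
        if state.k + 1 > params.k_max:
            raise EventRejected("migration beyond the last compartment")
        return [CellState(state.d, state.m_n, state.m_m, state.k + 1)]
    # division
    if state.m_m + 1 > params.m_m_max:
        raise EventRejected("metabolic mutation bound reached")
    try:
        p_d, _ = mutation_split(state, params)
    except MutationExhaustedError as exc:
        raise EventRejected(str(exc)) from exc
    driver = rng.random() < p_d
    if driver:
        free = [i for i, di in enumerate(state.d) if di == 0]
        locus = free[rng.integers(len(free))]
        mutated = state.with_driver(locus)  # advances m_m
    else:
        mutated = CellState(state.d, state.m_n + 1, state.m_m + 1, state.k)
    if action == "sym":
        return [mutated, mutated]
    # asym: one mutated daughter plus one non-mutated daughter aged by m_m+1
    sibling = CellState(state.d, state.m_n, state.m_m + 1, state.k)
    return [mutated, sibling]


def _draw_action(probs: dict[str, float], rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for a in ACTION_CODES:
        acc += probs[a]
        if u < acc:
            return a
    return ACTION_CODES[-1]


class _Scheduler:
    """Priority-queue event loop for one replicate."""

    def __init__(
        self,
        config: SimulationConfig,
        params: KineticsParams,
        order: DriverOrderSpec,
        rng: np.random.Generator,
    ) -> None:
        self.config = config
        self.params = params
        self.order = order
        self.rng = rng
        self.heap: list[tuple[float, int, int]] = []
        self.cells: dict[int, tuple[CellState, str]] = {}
        self.group_counts: Counter[tuple[int, int]] = Counter()
        self._seq = 0
        # action probabilities depend on the state only through (d, m_n, k)
        self._prob_cache: dict[tuple[tuple[int, ...], int, int], dict[str, float]] = {}

    def _probs(self, state: CellState) -> dict[str, float]:
        key = (state.d, state.m_n, state.k)
        probs = self._prob_cache.get(key)
        if probs is None:
            probs = action_probabilities(state, self.params, self.order)
            self._prob_cache[key] = probs
        return probs

    def spawn(self, state: CellState, t_now: float) -> None:
        action = _draw_action(self._probs(state), self.rng)
        dt = sample_waiting_time(state.m_m, self.params, self.rng)
        cid = self._seq
        self._seq += 1
        self.cells[cid] = (state, action)
        self.group_counts[(state.k, state.m_d)] += 1
        heapq.heappush(self.heap, (t_now + dt, cid, cid))

    def remove(self, cid: int) -> None:
        state, _ = self.cells.pop(cid)
        self.group_counts[(state.k, state.m_d)] -= 1

    def admissible(self, parent: CellState, daughters: Iterable[CellState]) -> bool:
        """Per-event capacity/energy check: all daughters in, or none."""
        energy = self.config.energy
        if energy.capacity is None and energy.E_max is None:
            return True
        trial = Counter()
        trial[(parent.k, parent.m_d)] -= 1
        for d in daughters:
            trial[(d.k, d.m_d)] += 1
        if energy.capacity is not None:
            for key, delta in trial.items():
                if self.group_counts[key] + delta > energy.capacity:
                    return False
        if energy.E_max is not None and energy.e is not None:
            compartments = {k for (k, _), delta in trial.items() if delta}
            for k in compartments:
                budget = energy.budget(k)
                if budget is None:
                    continue
                census = {
                    m_d: self.group_counts[(k, m_d)] + trial[(k, m_d)]
                    for m_d in range(self.params.m_d_max + 1)
                }
                if compartment_energy(census, energy) > budget:
                    return False
        return True


def run_replicate(
    config: SimulationConfig,
    params: KineticsParams,
    order: DriverOrderSpec,
    rng: np.random.Generator,
) -> ReplicateResult:
    """Simulate one replicate and sample counts on the record grid.

    Returns the (compartment, m_d) count series, the event log (if enabled),
    and — when a drug is configured — the census of survivors immediately
    after the kill.
    """
    sched = _Scheduler(config, params, order, rng)
    sigma0 = CellState((0,) * params.m_d_max, 0, 0, 1)
    for _ in range(config.initial_cells):
        sched.spawn(sigma0, 0.0)

    grid = config.record_times
    counts = np.zeros((len(grid), params.k_max, params.m_d_max + 1))
    events: list[EventRecord] = []
    post_drug: list[CellState] | None = None
    next_grid = 0
    drug_pending = config.t_drug is not None

    def record_until(t: float) -> None:
        """Record every unrecorded grid point strictly before time t."""
        nonlocal next_grid
        while next_grid < len(grid) and grid[next_grid] < t - 1e-12:
            for (k, m_d), n in sched.group_counts.items():
                if n:
                    counts[next_grid, k - 1, m_d] = n
            next_grid += 1

    def apply_drug(t: float) -> None:
        nonlocal post_drug, drug_pending
        record_until(t)
        assert config.drug is not None
        victims = [
            cid
            for cid, (state, _) in sched.cells.items()
            if matches_drug(state, config.drug)
        ]
        for cid in victims:
            state, _ = sched.cells[cid]
            if config.log_events:
                events.append(EventRecord(t, cid, "drug_kill", state, ()))
            sched.remove(cid)
        post_drug = [state for state, _ in sched.cells.values()]
        drug_pending = False

    while sched.heap:
        t_event, _, cid = sched.heap[0]
        if t_event > config.t_end:
            break
        # the drug fires before any cell event at the same timestamp
        if drug_pending and config.t_drug <= t_event:
            apply_drug(config.t_drug)
            continue
        heapq.heappop(sched.heap)
        if cid not in sched.cells:
            continue  # stale entry of a drug-killed cell
        state, action = sched.cells[cid]
        record_until(t_event)
        try:
            daughters = step_cell(state, rng, params, order, action)
        except EventRejected:
            daughters = None
        if daughters is not None and not sched.admissible(state, daughters):
            daughters = None
        if daughters is None:
            # put back: parent unchanged, redraw timer and action
            sched.remove(cid)
            sched.spawn(state, t_event)
            if config.log_events:
                events.append(EventRecord(t_event, cid, "rejected", state, (state,)))
            continue
        sched.remove(cid)
        for d in daughters:
            sched.spawn(d, t_event)
        if config.log_events:
            events.append(EventRecord(t_event, cid, action, state, tuple(daughters)))

    if drug_pending:
        apply_drug(config.t_drug)
    record_until(config.t_end + 2e-12)
    # grid points at exactly t_end (or beyond the last event) carry the final census
    while next_grid < len(grid):
        for (k, m_d), n in sched.group_counts.items():
            if n:
                counts[next_grid, k - 1, m_d] = n
        next_grid += 1

    final_states = [state for state, _ in sched.cells.values()]
    series = PopulationTimeSeries(grid, counts)
    return ReplicateResult(series, events, post_drug, final_states)


def run_ensemble(
    config: SimulationConfig,
    params: KineticsParams,
    order: DriverOrderSpec,
) -> EnsembleResult:
    """Run the configured number of replicates with independent sub-seeds.

    Sub-streams are spawned from ``config.seed`` through
    ``numpy.random.SeedSequence``, so results are bit-reproducible for a
    fixed seed and replicate count.
    """
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.replicates)
    grid = config.record_times
    all_counts = np.zeros(
        (config.replicates, len(grid), params.k_max, params.m_d_max + 1)
    )
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        rep = run_replicate(config, params, order, rng)
        all_counts[i] = rep.series.counts
    mean = all_counts.mean(axis=0)
    sd = all_counts.std(axis=0, ddof=1) if config.replicates > 1 else np.zeros_like(mean)
    return EnsembleResult(grid, mean, sd, all_counts)
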