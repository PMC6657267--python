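"""Deterministic master-equation oracle on the truncated state space.

The physical-time master equation for the expected occupancy
``p(d, m_n, m_m, k, t)`` couples each state to its mutational predecessors
with clock-rate prefactors ``alpha*(r + m_m - 1)`` on the gain terms and
``alpha*(r + m_m)`` on the losses — each metabolic mutation speeds up the
clock, so older lineages move faster.  Two generator modes are provided:

``reaction_consistent``
    Derived directly from the reaction rules the simulator executes (the
    recommended mode, and the one used as the stochastic-engine oracle).
    Per-action jump rates are ``alpha*(r+m_m) * P_act`` — the put-back
    rejection scheme makes the simulator a continuous-time Markov jump
    process with exactly these rates and blocked channels zeroed.

``as_printed``
    A term-for-term transcription of the published form of the equation,
    kept for fidelity: the driver-locus gains carry a fixed ``1/m_d_max``
    prefactor (rather than one over the free loci) and asymmetric division
    carries no explicit parent-loss term.

Boundary handling: mutation flux that would leave the truncated space is
suppressed, mirroring the simulator's event rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .kinetics import (
    KineticsParams,
    MutationExhaustedError,
    StuckStateError,
    action_probabilities,
    mutation_split,
)
from .state_space import CellState, DriverOrderSpec


class StateSpaceTooLarge(ValueError):
    """The truncated state space exceeds the configured size limit."""


@dataclass(frozen=True)
class StateIndex:
    """Deterministic bijection between admissible cell states and 0..n-1."""

    states: tuple[CellState, ...]
    index: dict[CellState, int]

    @classmethod
    def build(cls, params: KineticsParams, limit: int = 200_000) -> "StateIndex":
        n = (
            2**params.m_d_max
            * (params.m_n_max + 1)
            * (params.m_m_max + 1)
            * params.k_max
        )
        if n > limit:
            raise StateSpaceTooLarge(
                f"truncated state space has {n} states (limit {limit})"
            )
        states = tuple(
            CellState(d, m_n, m_m, k)
            for d in product((0, 1), repeat=params.m_d_max)
            for m_n in range(params.m_n_max + 1)
            for m_m in range(params.m_m_max + 1)
            for k in range(1, params.k_max + 1)
        )
        return cls(states, {s: i for i, s in enumerate(states)})

    def __len__(self) -> int:
        return len(self.states)

    def initial_density(self, n0: float = 1.0) -> np.ndarray:
        """Mass ``n0`` concentrated on sigma_0 = (0, 0, 0, 1)."""
        p0 = np.zeros(len(self.states))
        sigma0 = CellState((0,) * len(self.states[0].d), 0, 0, 1)
        p0[self.index[sigma0]] = n0
        return p0


@dataclass
class GeneratorMatrix:
    """Sparse linear operator L with dp/dt = L p."""

    L: sparse.csr_matrix
    index: StateIndex
    mode: str


def _rates(
    state: CellState, params: KineticsParams, order: DriverOrderSpec
) -> dict[str, float] | None:
    """Normalized action probabilities, or None for a rate-free (stuck) state."""
    try:
        return action_probabilities(state, params, order)
    except StuckStateError:
        return None


def build_generator(
    params: KineticsParams,
    order: DriverOrderSpec,
    mode: str = "reaction_consistent",
    limit: int = 200_000,
) -> GeneratorMatrix:
    """Assemble the sparse generator of the truncated master equation.

    Iterates over source states (columns): each admissible reaction
    contributes a diagonal loss and off-diagonal gains into its product
    states.  Out-of-bounds flux is suppressed.
    """
    if mode not in ("reaction_consistent", "as_printed"):
        raise ValueError(f"unknown generator mode {mode!r}")
    idx = StateIndex.build(params, limit=limit)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i_row: int, i_col: int, v: float) -> None:
        if v != 0.0:
            rows.append(i_row)
            cols.append(i_col)
            vals.append(v)

    for j, s in enumerate(idx.states):
        probs = _rates(s, params, order)
        if probs is None:
            continue
        lam = params.clock_rate(s.m_m)
        divisions_open = s.m_m + 1 <= params.m_m_max
        try:
            p_d, p_n = mutation_split(s, params)
        except MutationExhaustedError:
            p_d = p_n = 0.0
            divisions_open = False
        free = [i for i, di in enumerate(s.d) if di == 0]

        if divisions_open:
            if mode == "reaction_consistent":
                locus_weight = p_d / len(free) if free else 0.0
            else:
                locus_weight = p_d / params.m_d_max
            for act, two_daughters_mutate in (("asym", False), ("sym", True)):
                q = lam * probs[act]
                if q == 0.0:
                    continue
                mult = 2.0 if two_daughters_mutate else 1.0
                # driver branch
                if p_d > 0.0 and free:
                    for i_locus in free:
                        tgt = s.with_driver(i_locus)
                        add(idx.index[tgt], j, mult * q * locus_weight)
                    if not two_daughters_mutate:
                        # asym: the non-mutated daughter also ages one step
                        sib = CellState(s.d, s.m_n, s.m_m + 1, s.k)
                        add(idx.index[sib], j, q * p_d)
                # passenger branch
                if p_n > 0.0 and s.m_n + 1 <= params.m_n_max:
                    tgt = CellState(s.d, s.m_n + 1, s.m_m + 1, s.k)
                    add(idx.index[tgt], j, mult * q * p_n)
                    if not two_daughters_mutate:
                        sib = CellState(s.d, s.m_n, s.m_m + 1, s.k)
                        add(idx.index[sib], j, q * p_n)
                # parent loss for the executed division
                if mode == "reaction_consistent":
                    q_loss = 0.0
                    if p_d > 0.0 and free:
                        q_loss += q * p_d
                    if p_n > 0.0 and s.m_n + 1 <= params.m_n_max:
                        q_loss += q * p_n
                    add(j, j, -q_loss)
                elif act == "sym":
                    # as printed: only the symmetric loss appears
                    add(j, j, -q)

        # apoptosis
        add(j, j, -lam * probs["apop"])
        # migration
        q_pass = lam * probs["pass"]
        if q_pass > 0.0:
            add(j, j, -q_pass)
            tgt = CellState(s.d, s.m_n, s.m_m, s.k + 1)
            add(idx.index[tgt], j, q_pass)

    n = len(idx)
    L = sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    return GeneratorMatrix(L, idx, mode)


def integrate(
    gen: GeneratorMatrix,
    p0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate dp/dt = L p on the given time grid.

    Returns expected counts per state, shape (len(times), n_states); the
    equation is linear, so an initial mass N0 at sigma_0 scales the whole
    trajectory linearly.
    """
    if np.any(p0 < 0):
        raise ValueError("initial density must be non-negative")
    times = np.asarray(times, dtype=float)
    L = gen.L
    dense = L.toarray() if L.shape[0] <= 2000 else None

    def rhs(_t: float, p: np.ndarray) -> np.ndarray:
        return L @ p

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        p0,
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        jac=(lambda _t, _p: dense) if dense is not None else None,
    )
    if not sol.success:
        raise RuntimeError(
            f"master-equation integration failed on [{times[0]}, {times[-1]}]: "
            f"{sol.message}"
        )
    return sol.y.T


def project_counts(
    index: StateIndex, trajectory: np.ndarray, params: KineticsParams
) -> np.ndarray:
    """Project a per-state trajectory onto (compartment, m_d) groups.

    Returns an array of shape (T, k_max, m_d_max + 1) directly comparable
    with the simulator's :class:`~metastasim.ca_engine.PopulationTimeSeries`.
    """
    out = np.zeros((trajectory.shape[0], params.k_max, params.m_d_max + 1))
    for i, s in enumerate(index.states):
        out[:, s.k - 1, s.m_d] += trajectory[:, i]
    return out
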