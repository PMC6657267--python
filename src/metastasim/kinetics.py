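"""Stemness, action rates, waiting times and capacity accounting.

Every cell carries an internal exponential clock whose rate,
``alpha * (r + m_m)``, accelerates with each metabolic mutation; ``1/(alpha*r)``
is the mean cell-cycle time of an unmutated cell.  When the clock fires the
cell performs one of four actions — asymmetric division, symmetric division,
apoptosis, migration — drawn with probabilities

    P_act = A_act * chi_act(s) * k_act(m_e, k) / N,       N = sum of numerators,

where ``A_act`` is a constant amplitude, ``chi_act`` an indicator support
window on the cancer stemness ``s``, and ``k_act`` a filter on effective
drivers (identically 1 except for migration, which requires enough effective
drivers to leave the compartment).  Stemness itself is a function of the
mutation counts only: s = s_bar * m_d / sqrt(1 + m_n), clipped to [0, s_bar].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .state_space import CellState, DriverOrderSpec, can_migrate, effective_drivers

ACTIONS = ("asym", "sym", "apop", "pass")


class StuckStateError(RuntimeError):
    """Raised when a cell state has no action with nonzero rate.

    Signals a mis-specified scenario (e.g. support windows that exclude the
    initial stemness value 0).
    """


class MutationExhaustedError(RuntimeError):
    """No driver or passenger locus left to mutate: proliferation blocked."""


@dataclass(frozen=True)
class KineticsParams:
    """Rate parameters of the cell-level kinetics.

    Parameters
    ----------
    alpha
        Cell-cycle rate scale (1 / simulation time unit); each metabolic
        mutation adds ``alpha`` to the clock rate.
    r
        Dimensionless baseline multiplier: an unmutated cell cycles at rate
        ``alpha * r``.
    amplitudes
        Constant weights ``A_act`` for the four actions.
    centers
        Support-window centers ``c_act`` (stemness units) for the three
        stemness-gated actions; the model requires
        c_asym < c_sym < c_apop < s_bar so that asymmetric division belongs
        to one stemness regime and apoptosis to another.
    width
        Common support width ``w`` (stemness units); the window for an
        action is the closed interval [c_act - w/2, c_act + w/2].
    s_bar
        Maximum stemness; the stemness function is clipped to [0, s_bar].
    driver_split_beta
        Weight ``beta`` of remaining passenger loci in the driver-vs-
        passenger mutation split (see :func:`mutation_split`).
    m_d_max, m_n_max, m_m_max, k_max
        State-space truncation bounds.
    """

    alpha: float
    r: float
    amplitudes: Mapping[str, float]
    centers: Mapping[str, float]
    width: float
    s_bar: float
    m_d_max: int
    m_n_max: int
    m_m_max: int
    k_max: int
    driver_split_beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.r <= 0 or self.width <= 0 or self.s_bar <= 0:
            raise ValueError("alpha, r, width and s_bar must be positive")
        missing = set(ACTIONS) - set(self.amplitudes)
        if missing:
            raise ValueError(f"missing amplitudes for actions: {sorted(missing)}")
        if any(self.amplitudes[a] < 0 for a in ACTIONS):
            raise ValueError("amplitudes must be non-negative")
        c = self.centers
        if not (c["asym"] < c["sym"] < c["apop"] < self.s_bar):
            raise ValueError(
                "support centers must satisfy c_asym < c_sym < c_apop < s_bar, "
                f"got {c['asym']}, {c['sym']}, {c['apop']}, s_bar={self.s_bar}"
            )
        if self.driver_split_beta <= 0:
            raise ValueError("driver_split_beta must be positive")
        if min(self.m_d_max, self.m_n_max, self.m_m_max, self.k_max) < 1:
            raise ValueError("state-space bounds must be >= 1")

    def clock_rate(self, m_m: int) -> float:
        """Exponential event rate alpha*(r + m_m) of a cell with m_m metabolic mutations."""
        return self.alpha * (self.r + m_m)


@dataclass(frozen=True)
class EnergyModel:
    """Per-compartment admission constraints.

    ``e`` maps a driver count j to the energetic need of one such cell;
    the compartment-wide budget E_max (a single number, or a mapping from
    compartment index to number) caps sum_j e(j) N(j).  Independently,
    ``capacity`` caps the cell count per (compartment, driver count).
    Either constraint may be absent (None = unbounded).
    """

    e: Mapping[int, float] | None = None
    E_max: float | Mapping[int, float] | None = None
    capacity: int | None = None

    def __post_init__(self) -> None:
        if self.e is not None and any(v < 0 for v in self.e.values()):
            raise ValueError("energetic needs e(j) must be non-negative")
        if self.capacity is not None and self.capacity < 1:
            raise ValueError("capacity must be a positive integer")

    def budget(self, compartment: int) -> float | None:
        """Energy budget of one compartment (None = unbounded)."""
        if self.E_max is None:
            return None
        if isinstance(self.E_max, Mapping):
            return self.E_max.get(compartment)
        return self.E_max


def stemness(m_d: int, m_n: int, s_bar: float) -> float:
    """Cancer stemness s = s_bar * m_d / sqrt(1 + m_n), clipped to [0, s_bar].

    Strictly increasing in the driver count, strictly decreasing in the
    passenger count (before clipping), and independent of metabolic
    mutations.
    """
    if m_d < 0 or m_n < 0:
        raise ValueError("mutation counts must be non-negative")
    return min(s_bar * m_d / math.sqrt(1.0 + m_n), s_bar)


def support(s: float, center: float, width: float) -> int:
    """Indicator of the closed stemness window |s - center| <= width/2."""
    if width <= 0:
        raise ValueError("width must be positive")
    return 1 if abs(s - center) <= width / 2.0 else 0


def action_probabilities(
    state: CellState, params: KineticsParams, order: DriverOrderSpec
) -> dict[str, float]:
    """Normalized probabilities of the four actions for a given cell state.

    chi_pass = 1 (migration is not stemness-gated) and
    k_asym = k_sym = k_apop = 1 (divisions and apoptosis are not gated on
    effective drivers); k_pass is the migration filter.
    """
    s = stemness(state.m_d, state.m_n, params.s_bar)
    numer = {
        "asym": params.amplitudes["asym"] * support(s, params.centers["asym"], params.width),
        "sym": params.amplitudes["sym"] * support(s, params.centers["sym"], params.width),
        "apop": params.amplitudes["apop"] * support(s, params.centers["apop"], params.width),
        "pass": params.amplitudes["pass"] * (1 if can_migrate(state, order) else 0),
    }
    total = sum(numer.values())
    if total <= 0.0:
        raise StuckStateError(
            f"state {state} (stemness {s:.4g}) has no action with nonzero rate"
        )
    return {a: v / total for a, v in numer.items()}


def sample_waiting_time(m_m: int, params: KineticsParams, rng: np.random.Generator) -> float:
    """Draw the time to the cell's next event: Exp with rate alpha*(r + m_m)."""
    if m_m < 0:
        raise ValueError("m_m must be non-negative")
    return rng.exponential(1.0 / params.clock_rate(m_m))


def mutation_split(state: CellState, params: KineticsParams) -> tuple[float, float]:
    """Probability the mutation carried by a division is driver vs passenger.

    Proportional to the loci still available in each class:
    p_driver = (m_d_max - m_d) / ((m_d_max - m_d) + beta * (m_n_max - m_n)).
    """
    d_left = params.m_d_max - state.m_d
    n_left = params.m_n_max - state.m_n
    if d_left <= 0 and n_left <= 0:
        raise MutationExhaustedError(
            f"state {state}: no driver or passenger locus left to mutate"
        )
    p_d = d_left / (d_left + params.driver_split_beta * n_left)
    return p_d, 1.0 - p_d


def compartment_energy(counts: Mapping[int, float], model: EnergyModel) -> float:
    """Total energetic need E = sum_j e(j) N(j) of a compartment census.

    Driver counts without an explicit e(j) entry cost 0.
    """
    if model.e is None:
        return 0.0
    return float(sum(model.e.get(j, 0.0) * n for j, n in counts.items()))
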