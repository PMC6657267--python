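"""Compartment-graph path formalism.

Compartments (tissues) form a small directed graph with row-stochastic
transition probabilities ``T``; the last ``s`` compartments are absorbing
secondary sites.  A migration path starts at the primary site, follows
simple (non-revisiting) sequences, and ends at the first absorbing site it
reaches; its density is the product of the traversed transition entries.
The per-compartment required driver sets ``S_k`` along a chosen path induce
the ordered driver blocks and exit thresholds the simulator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .state_space import ConfigurationError, DriverOrderSpec


class InvalidPathError(ValueError):
    """A path that revisits a compartment or passes through an absorbing site."""


@dataclass(frozen=True)
class CompartmentGraph:
    """Compartment labels, transition matrix and required driver sets.

    ``transition`` is an m x m row-stochastic matrix; the last
    ``n_secondary`` compartments are absorbing (diagonal 1).
    ``required_drivers[i]`` is the set of driver gene names compartment
    ``i+1`` demands before a cell can move on (or seed, for a secondary
    site).
    """

    labels: tuple[str, ...]
    transition: tuple[tuple[float, ...], ...]
    n_secondary: int
    required_drivers: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        T = np.asarray(self.transition, dtype=float)
        m = len(self.labels)
        if T.shape != (m, m):
            raise ConfigurationError(f"transition matrix must be {m}x{m}")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("every transition-matrix row must sum to 1")
        if not 1 <= self.n_secondary < m:
            raise ConfigurationError("need at least one secondary and one non-secondary site")
        for i in range(m - self.n_secondary, m):
            if not np.isclose(T[i, i], 1.0):
                raise ConfigurationError(
                    f"secondary site {self.labels[i]!r} must be absorbing (T[{i},{i}]=1)"
                )
        if len(self.required_drivers) != m:
            raise ConfigurationError("required_drivers must list one set per compartment")

    @property
    def m(self) -> int:
        return len(self.labels)

    def is_absorbing(self, comp: int) -> bool:
        """1-based compartment index test for secondary (absorbing) sites."""
        return comp > self.m - self.n_secondary

    def T(self) -> np.ndarray:
        return np.asarray(self.transition, dtype=float)


def path_density(graph: CompartmentGraph, path: Sequence[int]) -> float:
    """Probability of traversing ``path`` (1-based compartment indices).

    The initial density is concentrated on the primary site, so the path
    must start at compartment 1; an absorbing site may appear only as the
    final element.
    """
    path = list(path)
    if not path or path[0] != 1:
        raise InvalidPathError("a path must start at the primary site (compartment 1)")
    if any(not 1 <= c <= graph.m for c in path):
        raise InvalidPathError(f"compartment index out of range in {path}")
    if len(set(path)) != len(path):
        raise InvalidPathError(f"path revisits a compartment: {path}")
    for c in path[:-1]:
        if graph.is_absorbing(c):
            raise InvalidPathError(
                f"path passes through absorbing compartment {c}: {path}"
            )
    T = graph.T()
    rho = 1.0
    for a, b in zip(path[:-1], path[1:]):
        rho *= T[a - 1, b - 1]
    return float(rho)


def most_probable_paths(
    graph: CompartmentGraph, max_compartments: int = 10
) -> list[tuple[tuple[int, ...], float]]:
    """All maximal-density first-passage paths from the primary site.

    Enumerates every simple path starting at compartment 1 that stops at
    the first absorbing site reached, and returns the argmax set (ties all
    returned) with its density.  Empty when no path has positive density.
    """
    if graph.m > max_compartments:
        raise ConfigurationError(
            f"path enumeration guarded at {max_compartments} compartments, got {graph.m}"
        )
    T = graph.T()
    results: list[tuple[tuple[int, ...], float]] = []

    def extend(path: list[int], rho: float) -> None:
        here = path[-1]
        if graph.is_absorbing(here):
            if rho > 0.0:
                results.append((tuple(path), rho))
            return
        for nxt in range(1, graph.m + 1):
            if nxt in path:
                continue
            t = T[here - 1, nxt - 1]
            if t > 0.0:
                extend(path + [nxt], rho * t)

    extend([1], 1.0)
    if not results:
        return []
    best = max(rho for _, rho in results)
    return [(p, rho) for p, rho in results if np.isclose(rho, best)]


def ordered_sets(
    graph: CompartmentGraph, path: Sequence[int]
) -> tuple[list[tuple[str, ...]], list[tuple[str, ...]]]:
    """Cumulative unions S'_k and per-compartment increments S''_k along a path.

    S'_k is the union of the required sets of the first k compartments on
    the path; S''_k = S'_k minus S'_{k-1} is the increment of genes that
    first become necessary at step k (S''_1 = S'_1).  When the
    per-compartment sets are disjoint, S''_k equals S_k.  Gene order within
    a set follows first appearance along the path.
    """
    sets = [graph.required_drivers[c - 1] for c in path]
    s_prime: list[tuple[str, ...]] = []
    seen: list[str] = []
    for sk in sets:
        for g in sk:
            if g not in seen:
                seen.append(g)
        s_prime.append(tuple(seen))
    s_dprime: list[tuple[str, ...]] = []
    for k, sp in enumerate(s_prime):
        prev = set(s_prime[k - 1]) if k >= 1 else set()
        s_dprime.append(tuple(g for g in sp if g not in prev))
    return s_prime, s_dprime


def driver_order_from_path(
    graph: CompartmentGraph, path: Sequence[int], ordered_mode: bool = True
) -> DriverOrderSpec:
    """Export the ordered driver blocks and exit thresholds for the simulator.

    Blocks are the per-compartment increments of new required genes along
    the path; the exit threshold of the k-th compartment on the path is
    |S'_k|, the cumulative number of required drivers.
    """
    s_prime, _ = ordered_sets(graph, path)
    genes: list[str] = list(s_prime[-1])
    blocks: list[tuple[int, ...]] = []
    placed = 0
    for sp in s_prime:
        block = tuple(range(placed, len(sp)))
        placed = len(sp)
        if block:
            blocks.append(block)
    # compartments that add no new requirement share the running threshold
    thresholds = tuple(len(sp) for sp in s_prime)
    blocks_t = tuple(b for b in blocks)
    return DriverOrderSpec(
        gene_names=tuple(genes),
        blocks=blocks_t,
        exit_threshold=thresholds,
        ordered_mode=ordered_mode,
    )
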