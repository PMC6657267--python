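"""Cell state, driver-order logic and drug-signature matching.

A cancer cell is tracked by its position in mutation x compartment space:
which of the ``m_d_max`` driver loci it has mutated (a binary vector ``d``),
how many non-driver (passenger) mutations ``m_n`` and metabolic mutations
``m_m`` it carries, and which tissue compartment ``k`` it occupies
(1-based, compartment 1 is the primary site).

Driver mutations may be subject to a sequential order imposed by the
compartment path: a driver acquired out of order stays *ineffective* until
every driver that should precede it has also been acquired.  Effective
drivers are what gates migration between compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Sequence


class ConfigurationError(ValueError):
    """Inconsistent model configuration (e.g. mismatched vector lengths)."""


@dataclass(frozen=True)
class CellState:
    """One cell's position in mutation x compartment space.

    Parameters
    ----------
    d
        Binary tuple over driver loci, 1 = mutated.  Components never
        revert to 0 along a trajectory.
    m_n
        Number of non-driver (passenger) mutations acquired.
    m_m
        Number of metabolic mutations; increments by exactly one at every
        proliferation event, so it doubles as the cell's mutational age.
    k
        Compartment index, 1-based.
    """

    d: tuple[int, ...]
    m_n: int
    m_m: int
    k: int

    def __post_init__(self) -> None:
        if any(x not in (0, 1) for x in self.d):
            raise ConfigurationError(f"driver vector must be binary, got {self.d}")
        if self.m_n < 0 or self.m_m < 0 or self.k < 1:
            raise ConfigurationError(
                f"m_n, m_m must be >= 0 and k >= 1, got {self}"
            )

    @property
    def m_d(self) -> int:
        """Number of acquired driver mutations (order-blind count)."""
        return sum(self.d)

    def with_driver(self, locus: int) -> "CellState":
        """Return a copy with driver `locus` (0-based) set, m_m advanced."""
        if self.d[locus]:
            raise ConfigurationError(f"locus {locus} already mutated in {self.d}")
        d = list(self.d)
        d[locus] = 1
        return CellState(tuple(d), self.m_n, self.m_m + 1, self.k)


@dataclass(frozen=True)
class DriverOrderSpec:
    """The ordered driver blocks and per-compartment migration thresholds.

    ``blocks`` lists disjoint groups of driver loci (0-based indices) in the
    order imposed by the compartment path; within a block the order of
    acquisition is irrelevant.  ``exit_threshold[k-1]`` is the number of
    effective drivers a cell needs to leave compartment ``k`` (for the last,
    secondary-site compartment the threshold is the count needed to seed —
    migration out of it is never allowed).
    """

    gene_names: tuple[str, ...]
    blocks: tuple[tuple[int, ...], ...]
    exit_threshold: tuple[int, ...]
    ordered_mode: bool = True

    def __post_init__(self) -> None:
        loci = [i for b in self.blocks for i in b]
        if sorted(loci) != list(range(len(self.gene_names))):
            raise ConfigurationError(
                "blocks must partition the driver loci "
                f"{list(range(len(self.gene_names)))}, got {self.blocks}"
            )
        if list(self.exit_threshold) != sorted(self.exit_threshold):
            raise ConfigurationError(
                f"exit thresholds must be non-decreasing, got {self.exit_threshold}"
            )

    @property
    def n_loci(self) -> int:
        return len(self.gene_names)

    @property
    def n_compartments(self) -> int:
        return len(self.exit_threshold)

    def entry_requirement(self, k: int) -> tuple[int, ...]:
        """Loci a cell must carry to have reached compartment ``k`` in order.

        The union of all blocks needed to traverse compartments 1..k-1,
        i.e. the first ``exit_threshold[k-2]`` loci in block order (empty
        for the primary site).
        """
        if k <= 1:
            return ()
        needed = self.exit_threshold[k - 2]
        out: list[int] = []
        for block in self.blocks:
            if len(out) >= needed:
                break
            out.extend(block)
        return tuple(out[:needed]) if len(out) >= needed else tuple(out)


@dataclass(frozen=True)
class DrugSignature:
    """Partial cell-state pattern targeted by an instantaneous drug.

    Any all-zero component imposes no constraint ("disregarded"); a cell is
    killed at ``t_drug`` iff every nonzero component matches its state
    exactly, and additionally either ``m_d_drug`` is 0 or the cell's total
    driver count equals it.
    """

    d_drug: tuple[int, ...]
    m_n_drug: int = 0
    m_m_drug: int = 0
    k_drug: int = 0
    m_d_drug: int = 0
    t_drug: float = 0.0

    def __post_init__(self) -> None:
        if any(x not in (0, 1) for x in self.d_drug):
            raise ConfigurationError(f"d_drug must be binary, got {self.d_drug}")
        if min(self.m_n_drug, self.m_m_drug, self.k_drug, self.m_d_drug) < 0:
            raise ConfigurationError("drug signature components must be >= 0")


def effective_drivers(state: CellState, order: DriverOrderSpec) -> int:
    """Count the cell's *effective* driver mutations, m_e.

    In ordered mode blocks are scanned in order: complete blocks contribute
    their full size; the first incomplete block contributes its acquired
    loci and stops the scan (drivers in later blocks remain ineffective).
    In unordered mode every acquired driver is effective, m_e = m_d.
    """
    if len(state.d) != order.n_loci:
        raise ConfigurationError(
            f"driver vector length {len(state.d)} != {order.n_loci} loci in order"
        )
    if not order.ordered_mode:
        return state.m_d
    m_e = 0
    for block in order.blocks:
        acquired = sum(state.d[i] for i in block)
        m_e += acquired
        if acquired < len(block):
            break
    return m_e


def can_migrate(state: CellState, order: DriverOrderSpec) -> bool:
    """True iff the cell has enough effective drivers to leave compartment k.

    Always False in the terminal (secondary-site) compartment: there is no
    compartment k_max + 1 to migrate into.
    """
    if state.k >= order.n_compartments:
        return False
    return effective_drivers(state, order) >= order.exit_threshold[state.k - 1]


def matches_drug(state: CellState, sig: DrugSignature) -> bool:
    """Hadamard-product signature match: sigma_drug o sigma == sigma_drug o sigma_drug.

    Zero components of the signature are disregarded; ``m_d_drug`` adds the
    separate constraint m_d_drug * ||d||_1 == m_d_drug**2.
    """
    if len(state.d) != len(sig.d_drug):
        raise ConfigurationError(
            f"signature length {len(sig.d_drug)} != state length {len(state.d)}"
        )
    for di, si in zip(state.d, sig.d_drug):
        if si and di != si:
            return False
    if sig.m_n_drug and state.m_n != sig.m_n_drug:
        return False
    if sig.m_m_drug and state.m_m != sig.m_m_drug:
        return False
    if sig.k_drug and state.k != sig.k_drug:
        return False
    if sig.m_d_drug and state.m_d != sig.m_d_drug:
        return False
    return True


def _viable_vectors(
    order: DriverOrderSpec, m_d: int, compartment: int
) -> list[tuple[int, ...]]:
    """All driver vectors with sum m_d that can exist in `compartment`.

    Ordered mode: the vector must contain every locus required to have
    traversed compartments 1..k-1 (the cumulative blocks up to the previous
    exit threshold).  Unordered mode: any vector with the right weight.
    """
    n = order.n_loci
    required = set(order.entry_requirement(compartment)) if order.ordered_mode else set()
    if len(required) > m_d:
        return []
    free = [i for i in range(n) if i not in required]
    out = []
    for extra in combinations(free, m_d - len(required)):
        vec = [0] * n
        for i in required:
            vec[i] = 1
        for i in extra:
            vec[i] = 1
        out.append(tuple(vec))
    return out


def fraction_targeted(
    sig: DrugSignature, order: DriverOrderSpec, m_d: int, compartment: int
) -> Fraction | None:
    """Exact fraction of viable driver combinations the drug signature hits.

    Enumerates every driver vector of weight ``m_d`` that is viable in the
    given compartment (see :func:`_viable_vectors`) and returns the exact
    rational fraction whose loci include all of ``sig.d_drug``.  Returns
    ``None`` when no combination is viable (empty domain).
    """
    if not 1 <= m_d <= order.n_loci:
        raise ConfigurationError(f"m_d must be in [1, {order.n_loci}], got {m_d}")
    viable = _viable_vectors(order, m_d, compartment)
    if not viable:
        return None
    hit = sum(
        1
        for vec in viable
        if all(v >= s for v, s in zip(vec, sig.d_drug))
    )
    return Fraction(hit, len(viable))
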