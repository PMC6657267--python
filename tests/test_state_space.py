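"""Driver-order logic, migration gating and drug-signature matching."""

from fractions import Fraction
from itertools import combinations, product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metastasim import (
    CellState,
    DriverOrderSpec,
    DrugSignature,
    can_migrate,
    effective_drivers,
    fraction_targeted,
    matches_drug,
)
from metastasim.state_space import ConfigurationError, _viable_vectors


def state(d, m_n=0, m_m=0, k=1):
    return CellState(tuple(d), m_n, m_m, k)


class TestEffectiveDrivers:
    @pytest.mark.parametrize(
        "d, ordered, expected",
        [
            ((1, 0, 0, 0), True, 1),  # EPCAM alone unlocks breast exit
            ((0, 1, 1, 1), True, 0),  # EPCAM missing blocks every later driver
            ((1, 0, 0, 1), True, 1),  # MET waits for the CD47/CD44 block
            ((1, 0, 0, 1), False, 2),  # unordered: every driver counts
            ((1, 1, 0, 0), True, 2),  # half of the middle block counts
            ((1, 0, 1, 0), True, 2),  # within-block order is irrelevant
            ((1, 1, 1, 0), True, 3),
            ((1, 1, 1, 1), True, 4),
        ],
    )
    def test_block_prefix_counting(self, table2_order, d, ordered, expected):
        order = table2_order if ordered else DriverOrderSpec(
            table2_order.gene_names,
            table2_order.blocks,
            table2_order.exit_threshold,
            ordered_mode=False,
        )
        assert effective_drivers(state(d), order) == expected

    def test_length_mismatch_is_configuration_error(self, table2_order):
        with pytest.raises(ConfigurationError):
            effective_drivers(state((1, 0)), table2_order)

    def test_bounded_by_total_drivers_and_unordered_equality(self, table2_order):
        """m_e <= m_d over the whole driver hypercube; equality without order."""
        unordered = DriverOrderSpec(
            table2_order.gene_names,
            table2_order.blocks,
            table2_order.exit_threshold,
            ordered_mode=False,
        )
        for d in product((0, 1), repeat=4):
            s = state(d)
            assert effective_drivers(s, table2_order) <= s.m_d
            assert effective_drivers(s, unordered) == s.m_d

    def test_monotone_in_acquisition(self, table2_order):
        """Acquiring any additional driver never decreases m_e."""
        for d in product((0, 1), repeat=4):
            base = effective_drivers(state(d), table2_order)
            for i in range(4):
                if d[i] == 0:
                    up = list(d)
                    up[i] = 1
                    assert effective_drivers(state(up), table2_order) >= base


class TestCanMigrate:
    def test_threshold_met_in_circulation(self, table2_order):
        assert can_migrate(state((1, 1, 1, 0), k=2), table2_order)

    def test_below_threshold(self, table2_order):
        assert not can_migrate(state((1, 1, 0, 0), k=2), table2_order)

    def test_terminal_compartment_never_migrates(self, table2_order):
        assert not can_migrate(state((1, 1, 1, 1), k=3), table2_order)


class TestMatchesDrug:
    def test_specific_driver_signature(self):
        sig = DrugSignature((0, 1, 0, 0), k_drug=2)
        assert matches_drug(state((1, 1, 0, 0), k=2), sig)
        assert not matches_drug(state((1, 0, 1, 0), k=2), sig)
        assert not matches_drug(state((1, 1, 0, 0), k=1), sig)

    def test_all_zero_signature_matches_everything(self):
        sig = DrugSignature((0, 0, 0, 0))
        for d in product((0, 1), repeat=4):
            assert matches_drug(state(d, m_n=3, m_m=5, k=2), sig)

    def test_driver_count_constraint(self):
        sig = DrugSignature((0, 0, 0, 0), k_drug=2, m_d_drug=1)
        assert matches_drug(state((0, 0, 1, 0), k=2), sig)
        assert not matches_drug(state((1, 1, 0, 0), k=2), sig)

    @given(
        d=st.tuples(*[st.integers(0, 1)] * 4),
        extra=st.sampled_from(["m_n", "m_m", "k", "m_d"]),
    )
    @settings(max_examples=60, derandomize=True)
    def test_adding_constraints_shrinks_matches(self, d, extra):
        """Any nonzero component can only remove states from the matched set."""
        cell = state(d, m_n=1, m_m=2, k=2)
        loose = DrugSignature((0, 0, 0, 0))
        tight = DrugSignature(
            (0, 0, 0, 0),
            m_n_drug=2 if extra == "m_n" else 0,
            m_m_drug=1 if extra == "m_m" else 0,
            k_drug=1 if extra == "k" else 0,
            m_d_drug=1 if extra == "m_d" else 0,
        )
        if matches_drug(cell, tight):
            assert matches_drug(cell, loose)


def brute_force_fraction(sig, order, m_d, compartment):
    """Independent enumeration oracle over the full driver hypercube."""
    if order.ordered_mode:
        required = set(order.entry_requirement(compartment))
    else:
        required = set()
    viable = [
        v
        for v in product((0, 1), repeat=order.n_loci)
        if sum(v) == m_d and all(v[i] == 1 for i in required)
    ]
    if not viable:
        return None
    hit = [v for v in viable if all(v[i] >= s for i, s in enumerate(sig.d_drug))]
    return Fraction(len(hit), len(viable))


class TestFractionTargeted:
    @pytest.mark.parametrize(
        "ordered, m_d, expected",
        [
            (False, 1, Fraction(1, 4)),
            (False, 2, Fraction(1, 2)),
            (False, 3, Fraction(3, 4)),
            (True, 1, Fraction(0)),
            (True, 2, Fraction(1, 3)),
            (True, 3, Fraction(2, 3)),
        ],
    )
    def test_cd47_drug_in_circulation(self, table2_order, ordered, m_d, expected):
        """The six printed combinatorial fractions for the CD47-specific drug."""
        sig = DrugSignature((0, 1, 0, 0), k_drug=2)
        order = DriverOrderSpec(
            table2_order.gene_names,
            table2_order.blocks,
            table2_order.exit_threshold,
            ordered_mode=ordered,
        )
        assert fraction_targeted(sig, order, m_d, 2) == expected

    def test_empty_domain_is_explicit(self, table2_order):
        # compartment 3 requires three specific loci; m_d=1 admits no vector
        sig = DrugSignature((0, 1, 0, 0))
        assert fraction_targeted(sig, table2_order, 1, 3) is None

    def test_agrees_with_brute_force(self):
        """Cross-check against full-hypercube enumeration on random orders."""
        import numpy as np

        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            loci = list(range(n))
            rng.shuffle(loci)
            cut = sorted(rng.choice(range(1, n), size=min(2, n - 1), replace=False))
            blocks = []
            prev = 0
            for c in list(cut) + [n]:
                if c > prev:
                    blocks.append(tuple(loci[prev:c]))
                    prev = c
            thresholds = tuple(
                sum(len(b) for b in blocks[: i + 1]) for i in range(len(blocks))
            )
            order = DriverOrderSpec(
                tuple(f"g{i}" for i in range(n)),
                tuple(blocks),
                thresholds,
                ordered_mode=bool(rng.integers(2)),
            )
            sig = DrugSignature(tuple(int(x) for x in rng.integers(0, 2, n)))
            m_d = int(rng.integers(1, n + 1))
            comp = int(rng.integers(1, len(blocks) + 1))
            assert fraction_targeted(sig, order, m_d, comp) == brute_force_fraction(
                sig, order, m_d, comp
            )

    def test_viable_vectors_respect_entry_requirement(self, table2_order):
        for v in _viable_vectors(table2_order, 2, 2):
            assert v[0] == 1  # EPCAM needed to have entered the circulation
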