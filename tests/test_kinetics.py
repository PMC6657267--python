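"""Stemness function, support windows, action rates and waiting times."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metastasim import (
    CellState,
    DriverOrderSpec,
    EnergyModel,
    KineticsParams,
    action_probabilities,
    compartment_energy,
    mutation_split,
    sample_waiting_time,
    stemness,
    support,
)
from metastasim.kinetics import MutationExhaustedError, StuckStateError


class TestStemness:
    def test_no_drivers_means_no_stemness(self):
        assert stemness(0, 5, 1.0) == 0.0

    def test_closed_form_value(self):
        assert stemness(3, 8, 1.0) == pytest.approx(1.0)  # 3/sqrt(9)

    def test_clipped_to_s_bar(self):
        assert stemness(2, 0, 1.0) == 1.0  # raw value 2 exceeds the ceiling

    def test_strict_monotonicity_below_ceiling(self):
        """Increasing in drivers, decreasing in passengers (unclipped regime).

        The raw surface m_d / sqrt(1 + m_n) stays below the ceiling only
        while m_d < sqrt(1 + m_n); monotonicity is strict there and weak
        after clipping.
        """
        s_bar = 1.0
        checked = 0
        for m_d in range(1, 6):
            for m_n in range(0, 40):
                if (m_d + 1) ** 2 <= 1 + m_n:  # both evaluations unclipped
                    assert stemness(m_d + 1, m_n, s_bar) > stemness(m_d, m_n, s_bar)
                    assert stemness(m_d, m_n + 1, s_bar) < stemness(m_d, m_n, s_bar)
                    checked += 1
                else:
                    assert stemness(m_d + 1, m_n, s_bar) >= stemness(m_d, m_n, s_bar)
        assert checked > 20


class TestSupport:
    @pytest.mark.parametrize(
        "s, expected",
        [(0.5, 1), (0.75, 1), (0.25, 1), (1.0, 0), (0.0, 0)],
    )
    def test_closed_window(self, s, expected):
        assert support(s, center=0.5, width=0.5) == expected


class TestActionProbabilities:
    def test_single_available_action(self, pure_death_params):
        order = DriverOrderSpec(("g",), ((0,),), (1,), ordered_mode=True)
        probs = action_probabilities(CellState((0,), 0, 0, 1), pure_death_params, order)
        assert probs == {"asym": 0.0, "sym": 0.0, "apop": 1.0, "pass": 0.0}

    def test_equal_numerators_split_evenly(self):
        params = KineticsParams(
            alpha=1.0, r=1.0,
            amplitudes={"asym": 1.0, "sym": 0.0, "apop": 0.0, "pass": 1.0},
            centers={"asym": 0.0, "sym": 0.4, "apop": 0.8},
            width=0.5, s_bar=1.0, m_d_max=1, m_n_max=30, m_m_max=2, k_max=2,
        )
        order = DriverOrderSpec(("g",), ((0,),), (1, 1), ordered_mode=True)
        # one driver, many passengers: s ~ 0.19 inside the asym window only
        cell = CellState((1,), 26, 0, 1)
        probs = action_probabilities(cell, params, order)
        assert probs["asym"] == pytest.approx(0.5)
        assert probs["pass"] == pytest.approx(0.5)

    def test_stuck_state_is_reported(self, small_params, small_order):
        starved = KineticsParams(
            alpha=1.0, r=1.0,
            amplitudes={"asym": 0.0, "sym": 0.0, "apop": 1.0, "pass": 0.0},
            centers={"asym": 0.1, "sym": 0.2, "apop": 0.3},
            width=0.1, s_bar=1.0, m_d_max=2, m_n_max=2, m_m_max=6, k_max=2,
        )
        with pytest.raises(StuckStateError):
            action_probabilities(CellState((0, 0), 0, 0, 1), starved, small_order)

    @given(
        m_d=st.integers(0, 2),
        m_n=st.integers(0, 2),
        m_m=st.integers(0, 6),
        k=st.integers(1, 2),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=200, derandomize=True)
    def test_probabilities_sum_to_one(self, m_d, m_n, m_m, k, seed):
        """Normalization holds for random states and random valid parameters."""
        small_order = DriverOrderSpec(("g1", "g2"), ((0,), (1,)), (1, 2))
        rng = np.random.default_rng(seed)
        c = np.sort(rng.uniform(0.0, 0.9, size=3))
        if not (c[0] < c[1] < c[2] < 1.0):
            c = np.array([0.2, 0.5, 0.8])
        params = KineticsParams(
            alpha=float(rng.uniform(0.1, 3)), r=float(rng.uniform(0.1, 3)),
            amplitudes={a: float(rng.uniform(0.05, 2)) for a in ("asym", "sym", "apop", "pass")},
            centers={"asym": float(c[0]), "sym": float(c[1]), "apop": float(c[2])},
            width=float(rng.uniform(2.0, 3.0)),  # wide enough to cover [0, 1]: no stuck states
            s_bar=1.0, m_d_max=2, m_n_max=2, m_m_max=6, k_max=2,
        )
        d = tuple(1 if i < m_d else 0 for i in range(2))
        probs = action_probabilities(CellState(d, m_n, m_m, k), params, small_order)
        assert abs(sum(probs.values()) - 1.0) < 1e-12

    def test_migration_not_stemness_gated(self, small_order):
        """chi_pass = 1: the migration numerator ignores the stemness windows."""
        params = KineticsParams(
            alpha=1.0, r=1.0,
            amplitudes={"asym": 1.0, "sym": 1.0, "apop": 1.0, "pass": 1.0},
            centers={"asym": 0.1, "sym": 0.2, "apop": 0.3},
            width=10.0, s_bar=1.0, m_d_max=2, m_n_max=2, m_m_max=6, k_max=2,
        )
        # migration allowed at k=1 with one effective driver, any stemness
        for m_n in (0, 1, 2):
            probs = action_probabilities(CellState((1, 0), m_n, 0, 1), params, small_order)
            assert probs["pass"] > 0


class TestWaitingTime:
    def test_mean_matches_metabolic_clock(self, small_params, rng):
        """E[t] = 1/(alpha (r + m_m)); metabolic mutations accelerate the clock."""
        draws = np.array([sample_waiting_time(3, small_params, rng) for _ in range(100_000)])
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.25) < 3 * se

    def test_acceleration_is_monotone(self, small_params):
        rng = np.random.default_rng(0)
        means = []
        for m_m in (0, 2, 5):
            d = [sample_waiting_time(m_m, small_params, rng) for _ in range(20_000)]
            means.append(np.mean(d))
        assert means[0] > means[1] > means[2]

    def test_exponential_law_kolmogorov_smirnov(self, small_params):
        rng = np.random.default_rng(99)
        for m_m in (0, 1, 3):
            draws = [sample_waiting_time(m_m, small_params, rng) for _ in range(10_000)]
            rate = small_params.alpha * (small_params.r + m_m)
            res = stats.kstest(draws, "expon", args=(0, 1 / rate))
            assert res.pvalue > 0.01


class TestMutationSplit:
    def test_no_drivers_left(self, small_params):
        assert mutation_split(CellState((1, 1), 0, 0, 1), small_params) == (0.0, 1.0)

    def test_no_passengers_left(self, small_params):
        assert mutation_split(CellState((0, 0), 2, 0, 1), small_params) == (1.0, 0.0)

    def test_remaining_locus_proportion(self):
        params = KineticsParams(
            alpha=1.0, r=1.0,
            amplitudes={"asym": 1.0, "sym": 1.0, "apop": 1.0, "pass": 1.0},
            centers={"asym": 0.2, "sym": 0.5, "apop": 0.8},
            width=1.0, s_bar=1.0, m_d_max=4, m_n_max=10, m_m_max=20, k_max=2,
        )
        p_d, p_n = mutation_split(CellState((1, 0, 0, 0), 4, 0, 1), params)
        assert p_d == pytest.approx(3 / 9)
        assert p_n == pytest.approx(6 / 9)
        assert p_d + p_n == 1.0

    def test_exhaustion_signalled(self, small_params):
        with pytest.raises(MutationExhaustedError):
            mutation_split(CellState((1, 1), 2, 0, 1), small_params)


class TestEnergyAndValidation:
    def test_compartment_energy(self):
        model = EnergyModel(e={0: 1.0, 1: 2.0}, E_max=100.0)
        assert compartment_energy({}, model) == 0.0
        assert compartment_energy({0: 10, 1: 5}, model) == 20.0

    def test_unit_weights_count_cells(self):
        model = EnergyModel(e={j: 1.0 for j in range(3)}, E_max=100.0)
        assert compartment_energy({0: 4, 1: 3, 2: 2}, model) == 9.0

    def test_center_ordering_enforced(self):
        with pytest.raises(ValueError):
            KineticsParams(
                alpha=1.0, r=1.0,
                amplitudes={"asym": 1.0, "sym": 1.0, "apop": 1.0, "pass": 1.0},
                centers={"asym": 0.5, "sym": 0.2, "apop": 0.8},
                width=1.0, s_bar=1.0, m_d_max=2, m_n_max=2, m_m_max=6, k_max=2,
            )

    def test_apoptosis_center_below_ceiling(self):
        with pytest.raises(ValueError):
            KineticsParams(
                alpha=1.0, r=1.0,
                amplitudes={"asym": 1.0, "sym": 1.0, "apop": 1.0, "pass": 1.0},
                centers={"asym": 0.2, "sym": 0.5, "apop": 1.5},
                width=1.0, s_bar=1.0, m_d_max=2, m_n_max=2, m_m_max=6, k_max=2,
            )
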