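import numpy as np
import pytest

from metastasim import DriverOrderSpec, EnergyModel, KineticsParams, SimulationConfig


@pytest.fixture
def table2_order() -> DriverOrderSpec:
    """The breast -> circulatory -> bone driver order: EPCAM | CD47, CD44 | MET."""
    return DriverOrderSpec(
        gene_names=("EPCAM", "CD47", "CD44", "MET"),
        blocks=((0,), (1, 2), (3,)),
        exit_threshold=(1, 3, 4),
        ordered_mode=True,
    )


@pytest.fixture
def small_params() -> KineticsParams:
    """Two-locus, two-compartment kinetics small enough to enumerate exactly."""
    return KineticsParams(
        alpha=1.0,
        r=1.0,
        amplitudes={"asym": 0.5, "sym": 0.3, "apop": 0.2, "pass": 0.3},
        centers={"asym": 0.2, "sym": 0.5, "apop": 0.8},
        width=1.2,
        s_bar=1.0,
        m_d_max=2,
        m_n_max=2,
        m_m_max=6,
        k_max=2,
    )


@pytest.fixture
def small_order() -> DriverOrderSpec:
    return DriverOrderSpec(
        gene_names=("g1", "g2"),
        blocks=((0,), (1,)),
        exit_threshold=(1, 2),
        ordered_mode=True,
    )


@pytest.fixture
def pure_death_params() -> KineticsParams:
    """Only apoptosis has nonzero amplitude: N(t) = N0 exp(-alpha r t)."""
    return KineticsParams(
        alpha=1.0,
        r=1.0,
        amplitudes={"asym": 0.0, "sym": 0.0, "apop": 1.0, "pass": 0.0},
        centers={"asym": 0.2, "sym": 0.5, "apop": 0.8},
        width=5.0,
        s_bar=1.0,
        m_d_max=1,
        m_n_max=1,
        m_m_max=2,
        k_max=1,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
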