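"""Shared fixtures: hand-built toy registries and a small reusable simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lineagebias.engine import (FEMALE, MALE, OPEN, PopulationRegistry,
                                SimConfig, run_simulation)
from lineagebias.rates import constant_params, synth_rates

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_registry(rows, span=(0, 12 * 2100), end_year=None) -> PopulationRegistry:
    """Build a registry from (sex, birth_month, death_month, mother, father) rows.

    ``sex`` is 'f'/'m'; death_month None means still alive; pids are the
    1-based row numbers.
    """
    sex = np.array([FEMALE if r[0] == "f" else MALE for r in rows], dtype=np.int8)
    birth = np.array([r[1] for r in rows], dtype=np.int64)
    death = np.array([OPEN if r[2] is None else r[2] for r in rows], dtype=np.int64)
    mother = np.array([r[3] for r in rows], dtype=np.int64)
    father = np.array([r[4] for r in rows], dtype=np.int64)
    spouse = np.zeros(len(rows), dtype=np.int64)
    meta = {} if end_year is None else {"config": {"end_year": end_year}}
    return PopulationRegistry(
        sex=sex, birth_month=birth, death_month=death, mother_pid=mother,
        father_pid=father, spouse_pid=spouse,
        marriages=pd.DataFrame(columns=["wife_pid", "husband_pid", "month"]),
        span=span, meta=meta)


def y(year: int, month: int = 0) -> int:
    """Month index of (calendar year, month-in-year)."""
    return year * 12 + month


@pytest.fixture(scope="session")
def toy_registry() -> PopulationRegistry:
    """Three generations, hand-checkable.

    Pids: 1 grandma(f), 2 grandpa(m), 3 mother(f, child of 1+2),
    4 aunt(f, child of 1+2, childless, died at 40),
    5 uncle(m, child of 1+2, died age 3),
    6 father(m, parents unknown), 7 ego(f, child of 3+6),
    8 sibling(m, child of 3+6, died age 2), 9 unrelated woman(f).
    """
    rows = [
        ("f", y(1900), y(1975), 0, 0),          # 1 grandma, died 75
        ("m", y(1898), y(1960), 0, 0),          # 2 grandpa
        ("f", y(1925), None, 1, 2),             # 3 mother
        ("f", y(1927), y(1967), 1, 2),          # 4 aunt, childless, died 40
        ("m", y(1930), y(1933), 1, 2),          # 5 uncle, died age 3
        ("m", y(1923), None, 0, 0),             # 6 father
        ("f", y(1955), None, 3, 6),             # 7 ego
        ("m", y(1957), y(1959), 3, 6),          # 8 sibling, died age 2
        ("f", y(1950), None, 0, 0),             # 9 unrelated
    ]
    return make_registry(rows, span=(y(1890), y(2030)), end_year=2022)


@pytest.fixture(scope="session")
def const_schedule():
    """Constant high-fertility, high-mortality regime (TFR 4.3, e0 40)."""
    return synth_rates(constant_params(1800, 1900, tfr=4.3, e0=40.0), seed=1)


@pytest.fixture(scope="session")
def sim_registry(const_schedule):
    """One small replicate reused by invariant tests."""
    cfg = SimConfig(n_initial=1000, start_year=1800, end_year=1900,
                    burn_in_years=50, tail_years=10, seed=7)
    return run_simulation(cfg, const_schedule)


@pytest.fixture(scope="session")
def sim_config_small():
    return SimConfig(n_initial=1000, start_year=1800, end_year=1900,
                     burn_in_years=50, tail_years=10, seed=7)
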