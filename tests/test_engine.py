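"""Microsimulation engine: waiting times, competing risks, matching, invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from lineagebias.engine import (
    EV_BIRTH,
    EV_DEATH,
    FEMALE,
    MALE,
    OPEN,
    ExtinctionError,
    SimConfig,
    Simulation,
    draw_waiting_time,
    run_simulation,
)
from lineagebias.rates import RateSchedule, constant_params, synth_rates


def flat_schedule(death_f=0.0, death_m=0.0, birth=0.0, year=1800,
                  fertile=(0, 1332), max_age=1332) -> RateSchedule:
    """Uniform single-band schedule for controlled engine tests."""
    rows = [
        (year, "f", "death", 0, max_age, death_f),
        (year, "m", "death", 0, max_age, death_m),
    ]
    lo, hi = fertile
    if lo > 0:
        rows.append((year, "f", "birth", 0, lo, 0.0))
    rows.append((year, "f", "birth", lo, hi, birth))
    if hi < max_age:
        rows.append((year, "f", "birth", hi, max_age, 0.0))
    bands = pd.DataFrame(rows, columns=["year", "sex", "event", "age_lo_months",
                                        "age_hi_months", "monthly_rate"])
    return RateSchedule(bands=bands, fertile_band=fertile, max_age_months=max_age)


class TestDrawWaitingTime:
    def test_all_zero_hazard_is_no_event(self):
        rng = np.random.default_rng(0)
        assert draw_waiting_time(rng, np.zeros(100)) == math.inf

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            draw_waiting_time(np.random.default_rng(0), [-0.1])

    def test_delayed_risk_draws_after_delay(self):
        rng = np.random.default_rng(1)
        h = np.concatenate([np.zeros(12), np.full(1000, 0.2)])
        draws = [draw_waiting_time(rng, h) for _ in range(200)]
        assert all(t >= 12 for t in draws)

    def test_constant_hazard_matches_exponential_mean(self):
        lam = 0.05
        rng = np.random.default_rng(2)
        h = np.full(10_000, lam)
        draws = np.array([draw_waiting_time(rng, h) for _ in range(10_000)])
        se = (1 / lam) / math.sqrt(len(draws))
        assert abs(draws.mean() - 1 / lam) < 3 * se


class TestScheduling:
    def test_male_gets_death_event_only(self):
        sim = Simulation(SimConfig(n_initial=50, start_year=1800, end_year=1801,
                                   burn_in_years=0, tail_years=0, seed=1),
                         flat_schedule(death_m=0.01, birth=0.5))
        sim._segment(1800)
        males = np.nonzero(sim.sex[:sim.n] == MALE)[0]
        sim.schedule(males, 1800 * 12, from_current_month=True, min_month=1800 * 12)
        assert (sim.sched_event[males] == EV_DEATH).all()

    def test_competing_risk_selection_frequencies(self):
        """P(birth wins) for two flat hazards is lam_b / (lam_b + lam_d)."""
        lam_d, lam_b = 0.02, 0.04
        cfg = SimConfig(n_initial=10_000, start_year=1800, end_year=1801,
                        burn_in_years=0, tail_years=0, seed=3,
                        initial_max_age_years=1)
        sim = Simulation(cfg, flat_schedule(death_f=lam_d, death_m=lam_d,
                                            birth=lam_b))
        sim._segment(1800)
        women = np.nonzero(sim.sex[:sim.n] == FEMALE)[0]
        sim.schedule(women, 1800 * 12, from_current_month=True, min_month=1800 * 12)
        frac = (sim.sched_event[women] == EV_BIRTH).mean()
        p = lam_b / (lam_b + lam_d)
        se = math.sqrt(p * (1 - p) / len(women))
        assert abs(frac - p) < 3 * se

    def test_birth_shifted_past_minimum_interval(self):
        cfg = SimConfig(n_initial=200, start_year=1800, end_year=1801,
                        burn_in_years=0, tail_years=0, seed=4,
                        initial_max_age_years=1)
        sim = Simulation(cfg, flat_schedule(birth=0.9))
        sim._segment(1800)
        women = np.nonzero(sim.sex[:sim.n] == FEMALE)[0]
        now = 1800 * 12
        sim.last_birth[women] = now - 2  # gave birth two months ago
        sim.schedule(women, now, from_current_month=True, min_month=now)
        scheduled = sim.sched_month[women]
        births = sim.sched_event[women] == EV_BIRTH
        assert births.any()
        assert (scheduled[births] >= (now - 2) + cfg.min_birth_interval_months).all()


class TestPartnerMatching:
    def _sim(self, men_births, woman_birth, seed=0):
        """Simulation with one adult woman and men born at given months."""
        cfg = SimConfig(n_initial=1, start_year=1900, end_year=1901,
                        burn_in_years=0, tail_years=0, seed=seed)
        sim = Simulation(cfg, flat_schedule(birth=0.01))
        # overwrite the lone initial individual as the mother
        sim.sex[0], sim.birth[0] = FEMALE, woman_birth
        for b in men_births:
            sim._append(MALE, b, 0, 0)
        return sim

    def test_single_eligible_man_is_chosen(self):
        now = 1900 * 12
        sim = self._sim([now - 30 * 12], now - 25 * 12)
        assert sim.match_partner(0, now) == 1

    def test_no_eligible_men_returns_none(self):
        now = 1900 * 12
        sim = self._sim([now - 10 * 12], now - 25 * 12)  # only a 10-year-old
        assert sim.match_partner(0, now) is None

    def test_best_gap_against_empty_histogram(self):
        """Candidates offering gaps -5, +2, +11 years: +2 fits Normal(2,3) best."""
        now = 1900 * 12
        wb = now - 25 * 12
        sim = self._sim([wb + 5 * 12, wb - 2 * 12, wb - 11 * 12], wb)
        chosen = sim.match_partner(0, now)
        gap = (sim.birth[0] - sim.birth[chosen]) / 12
        assert gap == 2

    def test_score_ties_break_to_smallest_pid(self):
        now = 1900 * 12
        wb = now - 25 * 12
        sim = self._sim([wb - 2 * 12, wb - 2 * 12], wb)  # identical gaps
        assert sim.match_partner(0, now) == 1


class TestExecuteMonth:
    def test_no_due_events_changes_nothing(self):
        cfg = SimConfig(n_initial=20, start_year=1800, end_year=1801,
                        burn_in_years=0, tail_years=0, seed=5)
        sim = Simulation(cfg, flat_schedule())
        sim._segment(1800)
        before = sim.n
        births, deaths = sim.execute_month(1800 * 12)
        assert (births, deaths) == (0, 0) and sim.n == before

    def test_due_birth_adds_one_individual(self):
        cfg = SimConfig(n_initial=2, start_year=1800, end_year=1801,
                        burn_in_years=0, tail_years=0, seed=6)
        sim = Simulation(cfg, flat_schedule(birth=0.01))
        sim._segment(1800)
        m = 1800 * 12
        sim.sex[0], sim.birth[0] = FEMALE, m - 25 * 12
        sim.sex[1], sim.birth[1] = MALE, m - 27 * 12
        sim.sched_event[0], sim.sched_month[0] = EV_BIRTH, m
        sim.sched_event[1], sim.sched_month[1] = EV_DEATH, m + 600
        births, _ = sim.execute_month(m)
        assert births == 1 and sim.n == 3
        assert sim.birth[2] == m and sim.mother[2] == 1
        assert sim.father[2] == 2  # the only single adult man was matched
        assert sim.marital[0] == sim.marital[1] == 1


class TestRunSimulation:
    def test_zero_rates_keeps_initial_cohort(self):
        cfg = SimConfig(n_initial=100, start_year=1800, end_year=1801,
                        burn_in_years=0, tail_years=0, seed=7)
        reg = run_simulation(cfg, flat_schedule())
        assert reg.n == 100
        assert (reg.death_month == OPEN).all()
        assert (reg.mother_pid == 0).all()

    def test_determinism_byte_for_byte(self, tmp_path, const_schedule):
        cfg = SimConfig(n_initial=300, start_year=1800, end_year=1830,
                        burn_in_years=10, tail_years=0, seed=11)
        paths = []
        for name in ("a.csv", "b.csv"):
            reg = run_simulation(cfg, const_schedule)
            p = tmp_path / name
            reg.to_csv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_extinction_raises_with_month(self):
        sched = flat_schedule(death_f=0.9, death_m=0.9)
        cfg = SimConfig(n_initial=20, start_year=1800, end_year=1803,
                        burn_in_years=0, tail_years=0, seed=8,
                        initial_max_age_years=30)
        with pytest.raises(ExtinctionError) as err:
            run_simulation(cfg, sched)
        assert 1800 * 12 <= err.value.month <= 1804 * 12


class TestRegistryInvariants:
    def test_monthly_conservation(self, sim_registry):
        b, d = sim_registry.birth_month, sim_registry.death_month
        lo, hi = sim_registry.span
        months = np.arange(lo + 1, hi + 1)
        alive_prev = sim_registry.alive_at(lo)
        for m in months[:: 17]:  # sample months across the span
            alive = sim_registry.alive_at(m)
            births = int(((b > m - 17) & (b <= m)).sum())
            deaths = int(((d > m - 17) & (d <= m)).sum())
            m_prev = m - 17
            expected = int(sim_registry.alive_at(m_prev).sum()) + births - deaths
            assert int(alive.sum()) == expected

    def test_every_nonfounder_has_live_fertile_mother(self, sim_registry, const_schedule):
        reg = sim_registry
        kids = reg.pids[reg.mother_pid > 0]
        mothers = reg.mother_pid[kids - 1]
        assert (reg.sex[mothers - 1] == FEMALE).all()
        mb = reg.birth_month[mothers - 1]
        md = reg.death_month[mothers - 1]
        cb = reg.birth_month[kids - 1]
        assert ((md == OPEN) | (md > cb)).all()  # mother alive at the birth
        age = cb - mb
        lo, hi = const_schedule.fertile_band
        assert (age >= lo).all() and (age < hi + 9).all()  # + interval shift

    def test_fathers_alive_at_conception(self, sim_registry):
        reg = sim_registry
        kids = reg.pids[reg.father_pid > 0]
        fathers = reg.father_pid[kids - 1]
        assert (reg.sex[fathers - 1] == MALE).all()
        fd = reg.death_month[fathers - 1]
        cb = reg.birth_month[kids - 1]
        assert ((fd == OPEN) | (fd >= cb - 9)).all()

    def test_consecutive_births_spaced_by_interval(self, sim_registry):
        reg = sim_registry
        df = pd.DataFrame({"mother": reg.mother_pid, "birth": reg.birth_month})
        df = df[df.mother > 0].sort_values(["mother", "birth"])
        gaps = df.groupby("mother")["birth"].diff().dropna()
        assert (gaps >= 9).all()

    def test_age_gap_distribution_near_target(self, sim_registry):
        mar = sim_registry.marriages
        gaps = (sim_registry.birth_month[mar.wife_pid - 1]
                - sim_registry.birth_month[mar.husband_pid - 1]) / 12.0
        assert len(gaps) > 500
        assert 1.0 <= gaps.mean() <= 3.0
        assert 2.0 <= gaps.std() <= 4.0

    def test_registry_roundtrip_bit_exact(self, sim_registry, tmp_path):
        p = tmp_path / "reg.csv"
        sim_registry.to_csv(p)
        again = sim_registry.from_csv(p)
        for name in ("sex", "birth_month", "death_month", "mother_pid",
                     "father_pid", "spouse_pid"):
            assert np.array_equal(getattr(again, name), getattr(sim_registry, name))
        assert again.span == sim_registry.span


class TestGrowthSign:
    def test_growth_sign_matches_nrr(self):
        """Long constant-rate runs grow iff the schedule's NRR exceeds one."""
        from lineagebias.measures import OPEN_AGE, build_life_table

        for tfr, e0, expect_growth in ((4.3, 40.0, True), (1.5, 80.0, False)):
            sched = synth_rates(constant_params(1800, 1801, tfr=tfr, e0=e0), seed=2)
            mx = sched.monthly_hazard(1800, "f", "death") * 12
            annual = np.array([mx[a * 12] for a in range(OPEN_AGE + 1)])
            lt = build_life_table(annual).table
            fert = sched.monthly_hazard(1800, "f", "birth") * 12
            asfr = np.array([fert[a * 12] for a in range(OPEN_AGE + 1)])
            p_female = 1 - 0.5122
            nrr = float((asfr[:100] * lt.Lx.to_numpy()[:100] / 100000.0).sum()) * p_female
            assert (nrr > 1) == expect_growth  # regimes chosen far from NRR = 1

            cfg = SimConfig(n_initial=5000, start_year=1800, end_year=1880,
                            burn_in_years=60, tail_years=0, seed=13)
            reg = run_simulation(cfg, sched)
            n0 = int(reg.alive_at(1810 * 12).sum())
            n1 = int(reg.alive_at(1880 * 12).sum())
            growth = math.log(n1 / n0)
            assert (growth > 0) == (nrr > 1)
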