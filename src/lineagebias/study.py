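"""Canonical desk-scale study runs.

These functions bundle the package's end-to-end analyses at sizes a single
CPU handles in minutes: a synthetic complete pedigree for the structural
ancestor count, a Swedish-like preset run for the with-duplicates TFR
check, a constant-rate input-recovery validation, and a direction suite for
the three bias experiments under a high-infant-mortality regime.  They are
what ``scripts/acceptance.py`` executes and what the integration tests
assert on; problem sizes are deliberately modest (initial cohorts of
1,500-3,000 and 150-250 simulated years) so everything stays desk-scale
while each structural effect keeps a comfortable margin over its Monte
Carlo noise.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .engine import FEMALE, MALE, PopulationRegistry, SimConfig
from .experiments import (pooled_tfr_windows, run_experiment, run_replicates,
                          summarise_experiment)
from .genealogy import ExperimentConfig, trace_direct_ancestors
from .measures import OPEN_AGE, build_life_table, pool_window
from .rates import RateSchedule, constant_params, sweden_like_params, synth_rates


def _subseed(seed: int, k: int) -> int:
    """Derive a stream-specific seed below 2**31."""
    return int((seed * 1_000_003 + k * 7_919 + 1) % (2**31))


# ---------------------------------------------------------------------------
# structural pedigree


def synthetic_complete_pedigree(generations: int = 9) -> PopulationRegistry:
    """A synthetic registry holding one ego with a fully occupied pedigree.

    Every position in every generation up to ``generations`` is filled by a
    distinct individual, so the ascendant tree is maximal: sum of 2^g
    positions, 1,022 for nine generations.
    """
    sexes, births, deaths, mothers, fathers = [0], [2000 * 12], [-1], [0], [0]
    level = [0]  # index of ego
    for g in range(1, generations + 1):
        nxt = []
        for child in level:
            for parent_sex in (FEMALE, MALE):
                idx = len(sexes)
                sexes.append(parent_sex)
                births.append((2000 - 30 * g) * 12 - parent_sex)
                deaths.append((2000 - 30 * g + 70) * 12)
                mothers.append(0)
                fathers.append(0)
                if parent_sex == FEMALE:
                    mothers[child] = idx + 1
                else:
                    fathers[child] = idx + 1
                nxt.append(idx)
        level = nxt
    return PopulationRegistry(
        sex=np.array(sexes, dtype=np.int8),
        birth_month=np.array(births, dtype=np.int64),
        death_month=np.array(deaths, dtype=np.int64),
        mother_pid=np.array(mothers, dtype=np.int64),
        father_pid=np.array(fathers, dtype=np.int64),
        spouse_pid=np.zeros(len(sexes), dtype=np.int64),
        marriages=pd.DataFrame(columns=["wife_pid", "husband_pid", "month"]),
        span=(1500 * 12, 2100 * 12),
        meta={"config": {"end_year": 2022}, "synthetic": "complete pedigree"})


def complete_pedigree_positions(generations: int = 9) -> int:
    """Direct-ancestor attribution count of a fully occupied pedigree."""
    reg = synthetic_complete_pedigree(generations)
    sub = trace_direct_ancestors(reg, 1, max_generations=generations)
    return int((sub.attributions["kin_type"] == "direct_ancestor").sum())


# ---------------------------------------------------------------------------
# preset run: structural with-duplicates TFR


def preset_study(seed: int, n_initial: int = 2000, year_start: int = 1873,
                 year_end: int = 2022, burn_in_years: int = 100,
                 tail_years: int = 50, replicates: int = 2,
                 window_years: int = 25) -> dict:
    """Swedish-like preset run and the Experiment-1 duplicate accounting.

    Returns the pooled with-duplicates TFR per multi-year window (the
    structural "one child per female ancestor" level) together with the
    Experiment-1 bias summary.
    """
    params = sweden_like_params(year_start, year_end, seed=_subseed(seed, 1))
    schedule = synth_rates(params, seed=_subseed(seed, 1))
    cfg = SimConfig(n_initial=n_initial, start_year=year_start, end_year=year_end,
                    burn_in_years=burn_in_years, tail_years=tail_years,
                    seed=_subseed(seed, 2))
    registries, _ = run_replicates(cfg, schedule, replicates)
    years = range(year_start, year_end + 1)
    ecfg = ExperimentConfig(seed=_subseed(seed, 3))
    results = run_experiment(registries, ecfg, "1", years)
    windows = pooled_tfr_windows(results, "direct_dup", window_years=window_years)
    summary = summarise_experiment(results)
    return {"windows": windows, "summary": summary, "results": results,
            "registries": registries}


# ---------------------------------------------------------------------------
# input recovery


def input_recovery_study(seed: int, replicates: int = 10, n_initial: int = 3000,
                         tfr: float = 4.3, e0: float = 40.0,
                         year_start: int = 1800, year_end: int = 1850,
                         burn_in_years: int = 50) -> dict:
    """Constant-rate run: do output-estimated measures recover the inputs?

    Returns replicate-averaged TFR and e0 against the input-implied values,
    plus pooled age-band z-scores (observed minus input over the Poisson
    Monte-Carlo standard error) for ASFR and ASMR from the first replicate.
    """
    schedule = synth_rates(constant_params(year_start, year_end, tfr=tfr, e0=e0),
                           seed=_subseed(seed, 4))
    cfg = SimConfig(n_initial=n_initial, start_year=year_start, end_year=year_end,
                    burn_in_years=burn_in_years, tail_years=0,
                    seed=_subseed(seed, 5))
    registries, _ = run_replicates(cfg, schedule, replicates)
    years = range(year_start + 5, year_end + 1)

    input_e0 = {}
    for sex in ("f", "m"):
        mx = schedule.monthly_hazard(year_start, sex, "death") * 12
        annual = np.array([mx[a * 12] for a in range(OPEN_AGE + 1)])
        input_e0[sex] = build_life_table(annual).e0

    from .measures import PopulationView, compute_measures
    tfrs, e0s = [], {"f": [], "m": []}
    all_measures = []
    for rep, reg in enumerate(registries):
        pm = compute_measures(PopulationView(reg, label="full"), years, replicate=rep)
        all_measures.append(pm)
        tfrs.append(float(pm.tfr["tfr"].mean()))
        for sex in ("f", "m"):
            e0s[sex].append(float(pm.e0[pm.e0["sex"] == sex]["e0"].mean()))

    zscores = _band_zscores(all_measures[0], schedule, year_start, years)
    return {
        "input_tfr": tfr,
        "measured_tfr": float(np.mean(tfrs)),
        "tfr_rel_err_pct": float(100 * (np.mean(tfrs) / tfr - 1)),
        "input_e0_f": input_e0["f"], "input_e0_m": input_e0["m"],
        "measured_e0_f": float(np.mean(e0s["f"])),
        "measured_e0_m": float(np.mean(e0s["m"])),
        "e0_err_years_f": float(np.mean(e0s["f"]) - input_e0["f"]),
        "e0_err_years_m": float(np.mean(e0s["m"]) - input_e0["m"]),
        "band_zscores": zscores,
    }


def _band_zscores(pm, schedule: RateSchedule, rate_year: int,
                  years, band: int = 5, min_exposure: float = 2000.0) -> pd.DataFrame:
    """(observed - input) / Poisson SE per pooled 5-year age band.

    The null rate for a band is the *exposure-weighted* mean of the input
    single-age rates: with steeply rising hazards the band's person-years
    concentrate at its younger ages, so an unweighted mean would fake a
    mortality deficit at old ages.
    """
    rows = []

    def add(table, event_col, rates_by_age, measure, sex):
        pooled = pool_window(table, min(years), max(years) + 1, event_col)
        lo0 = 15 if measure == "asfr" else 0
        hi0 = 50 if measure == "asfr" else 90
        for lo in range(lo0, hi0, band):
            cells = pooled[(pooled["age"] >= lo) & (pooled["age"] < lo + band)]
            events, exposure = cells[event_col].sum(), cells["exposure"].sum()
            if exposure < min_exposure or events == 0:
                continue
            per_age = rates_by_age[cells["age"].to_numpy() * 12]
            expected = float((per_age * cells["exposure"].to_numpy()).sum() / exposure)
            se = np.sqrt(events) / exposure
            rows.append((measure, sex, lo, (events / exposure - expected) / se))

    add(pm.asfr, "births",
        schedule.monthly_hazard(rate_year, "f", "birth") * 12, "asfr", "f")
    for sex in ("f", "m"):
        add(pm.asmr[pm.asmr["sex"] == sex], "deaths",
            schedule.monthly_hazard(rate_year, sex, "death") * 12, "asmr", sex)
    return pd.DataFrame(rows, columns=["measure", "sex", "age_band", "z"])


# ---------------------------------------------------------------------------
# direction suite


def direction_study(seed: int, replicates: int = 2, n_initial: int = 1500,
                    tfr: float = 4.5, e0: float = 38.0,
                    year_start: int = 1800, year_end: int = 1960,
                    burn_in_years: int = 80, tail_years: int = 30,
                    proportions: Sequence[float] = (0.25, 0.5, 0.75, 1.0)) -> dict:
    """All three experiments under a high-infant-mortality constant regime.

    Returns whole-period female TFR and e0 biases (subset minus full
    simulation) for Experiments 1 (both duplicate modes), 2, and 3A/3B per
    omission proportion.
    """
    schedule = synth_rates(constant_params(year_start, year_end, tfr=tfr, e0=e0),
                           seed=_subseed(seed, 6))
    cfg = SimConfig(n_initial=n_initial, start_year=year_start, end_year=year_end,
                    burn_in_years=burn_in_years, tail_years=tail_years,
                    seed=_subseed(seed, 7))
    registries, _ = run_replicates(cfg, schedule, replicates)
    years = range(year_start, year_end + 1)
    ecfg = ExperimentConfig(seed=_subseed(seed, 8))

    out: dict = {"proportions": list(proportions)}
    summaries = {}
    for experiment in ("1", "2", "3a", "3b"):
        results = run_experiment(registries, ecfg, experiment, years, proportions)
        summaries[experiment] = summarise_experiment(results)

    def bias(experiment, dataset, measure):
        t = summaries[experiment]
        row = t[(t["dataset"] == dataset) & (t["measure"] == measure)
                & (t["window"] == "whole")]
        return float(row["abs_mean_diff"].iloc[0])

    out["exp1_tfr_bias_dedup"] = bias("1", "direct_dedup", "tfr")
    out["exp1_tfr_bias_withdup"] = bias("1", "direct_dup", "tfr")
    out["exp1_e0_bias"] = bias("1", "direct_dedup", "e0")
    out["exp2_tfr_bias"] = bias("2", "complete", "tfr")
    out["exp2_e0_bias"] = bias("2", "complete", "e0")
    for p in proportions:
        pc = int(round(100 * p))
        out[f"exp3a_e0_bias_{pc}"] = bias("3a", f"omit_under5_deaths_{pc}", "e0")
        out[f"exp3a_tfr_bias_{pc}"] = bias("3a", f"omit_under5_deaths_{pc}", "tfr")
        out[f"exp3b_e0_bias_{pc}"] = bias("3b", f"omit_childless_women_{pc}", "e0")
        out[f"exp3b_tfr_bias_{pc}"] = bias("3b", f"omit_childless_women_{pc}", "tfr")
    out["summaries"] = summaries
    return out
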