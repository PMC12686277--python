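"""Period fertility and mortality measures from registries and genealogical subsets.

All measures follow the classic period definitions: age-specific rates are
events in a calendar year divided by the mid-year population at that age,
TFR is the age-sum of single-age ASFR, and e0 comes from a period life
table built from single-age mortality rates.

A :class:`PopulationView` selects who is counted.  For the full synthetic
population every individual counts once; for a genealogical subset only the
member pids count, optionally weighted by their number of attributions so
that duplicate appearances across family trees inflate both numerators and
denominators the way they would in merged real-world genealogies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: oldest single age in rate tabulations; the life table closes with an
#: open interval at OPEN_AGE.
MAX_TAB_AGE = 110
OPEN_AGE = 100
RADIX = 100_000.0
#: open-interval hazard used when a dataset records no deaths past OPEN_AGE
#: at all (m = 0 would otherwise imply unbounded remaining life expectancy).
OPEN_INTERVAL_M_FLOOR = 0.05

FERTILE_AGES = range(15, 50)


# ---------------------------------------------------------------------------
# population views


@dataclass
class PopulationView:
    """A registry plus an optional member filter with per-member weights.

    Parameters
    ----------
    registry
        Any object exposing ``sex``, ``birth_month``, ``death_month``,
        ``mother_pid`` and ``father_pid`` integer arrays (1-based pids,
        0 = none, death_month < 0 = open).
    member_pids, weights
        Restrict counting to these pids.  ``weights`` defaults to 1 per
        member; passing attribution counts gives the "with duplicates" mode.
    """

    registry: object
    member_pids: np.ndarray | None = None
    weights: np.ndarray | None = None
    label: str = "full"

    def __post_init__(self) -> None:
        n = len(self.registry.birth_month)
        w = np.zeros(n + 1, dtype=np.float64)  # indexed by pid
        if self.member_pids is None:
            w[1:] = 1.0
        else:
            pids = np.asarray(self.member_pids, dtype=np.int64)
            if self.weights is None:
                w[pids] = 1.0
            else:
                np.add.at(w, pids, np.asarray(self.weights, dtype=np.float64))
        self._pid_weight = w

    @property
    def pid_weight(self) -> np.ndarray:
        """Weight per pid (index 0 unused)."""
        return self._pid_weight


def _registry_arrays(view: PopulationView):
    r = view.registry
    return (
        np.asarray(r.sex, dtype=np.int8),
        np.asarray(r.birth_month, dtype=np.int64),
        np.asarray(r.death_month, dtype=np.int64),
        np.asarray(r.mother_pid, dtype=np.int64),
    )


def midyear_month(year: int) -> int:
    """Month index of the mid-year point (July) of a calendar year."""
    return year * 12 + 6


def midyear_population(view: PopulationView, year: int, sex: str | None = None,
                       age_group: tuple[int, int] | int | None = None) -> float:
    """Weighted count of members alive at mid-year in an age group.

    ``age_group`` is a single completed age in years or a half-open
    ``(lo, hi)`` interval in years; ``None`` counts all ages.
    Zero is a legitimate result.
    """
    sexes, b, d, _ = _registry_arrays(view)
    w = view.pid_weight[1:]
    m = midyear_month(year)
    mask = (b <= m) & ((d < 0) | (d > m)) & (w > 0)
    if sex is not None:
        mask &= sexes == _sex_code(sex)
    if age_group is not None:
        lo, hi = (age_group, age_group + 1) if np.isscalar(age_group) else age_group
        age = (m - b) // 12
        mask &= (age >= lo) & (age < hi)
    return float(w[mask].sum())


def _sex_code(sex: str | int) -> int:
    if isinstance(sex, str):
        s = sex.lower()
        if s in ("f", "female"):
            return 0
        if s in ("m", "male"):
            return 1
        raise ValueError(f"unknown sex label {sex!r}")
    return int(sex)


def _exposure_grid(view: PopulationView, years: np.ndarray, sex_code: int | None) -> np.ndarray:
    """Mid-year weighted population per (year, single age 0..MAX_TAB_AGE)."""
    sexes, b, d, _ = _registry_arrays(view)
    w = view.pid_weight[1:]
    keep = w > 0
    if sex_code is not None:
        keep &= sexes == sex_code
    b, d, w = b[keep], d[keep], w[keep]
    out = np.zeros((len(years), MAX_TAB_AGE + 1))
    for i, y in enumerate(years):
        m = midyear_month(int(y))
        alive = (b <= m) & ((d < 0) | (d > m))
        age = np.clip((m - b[alive]) // 12, 0, MAX_TAB_AGE)
        out[i] = np.bincount(age, weights=w[alive], minlength=MAX_TAB_AGE + 1)
    return out


# ---------------------------------------------------------------------------
# fertility


def compute_asfr(view: PopulationView, years: Sequence[int],
                 ages: Iterable[int] = range(10, 55)) -> pd.DataFrame:
    """Single-age period ASFR table.

    A birth enters the numerator only when the child *and* its mother are
    members of the view; weights are the child's membership weight.  This is
    exactly what makes ancestor-only genealogies underestimate fertility:
    children outside the subset are invisible, so their mothers appear to
    have had fewer births.  Cells with zero mid-year exposure are flagged
    undefined rather than zero.
    """
    years = np.asarray(sorted(years), dtype=np.int64)
    ages = np.asarray(sorted(ages), dtype=np.int64)
    sexes, b, d, mother = _registry_arrays(view)
    w = view.pid_weight

    child_w = w[1:]
    has_mother = mother > 0
    counted = (child_w > 0) & has_mother & (w[mother] > 0)
    cb = b[counted]
    cm = mother[counted]
    cw = child_w[counted]
    mother_age = (cb - b[cm - 1]) // 12
    birth_year = np.floor_divide(cb, 12)

    births = np.zeros((len(years), MAX_TAB_AGE + 1))
    pos = np.searchsorted(years, birth_year)
    ok = (pos < len(years)) & (years[np.minimum(pos, len(years) - 1)] == birth_year)
    ai = np.clip(mother_age[ok], 0, MAX_TAB_AGE)
    np.add.at(births, (pos[ok], ai), cw[ok])

    exposure = _exposure_grid(view, years, sex_code=0)

    rows = []
    for i, y in enumerate(years):
        for a in ages:
            e = exposure[i, a]
            n = births[i, a]
            rows.append((int(y), int(a), n, e, n / e if e > 0 else np.nan, e > 0))
    return pd.DataFrame(rows, columns=["year", "age", "births", "exposure", "rate", "defined"])


def compute_tfr(asfr: pd.DataFrame, year: int) -> float:
    """TFR as the sum of defined single-age ASFR for one year.

    Undefined cells contribute zero; use :func:`tfr_series` for the
    per-year coverage diagnostics.
    """
    sub = asfr[(asfr["year"] == year) & asfr["defined"]]
    return float(sub["rate"].sum())


def tfr_series(asfr: pd.DataFrame) -> pd.DataFrame:
    """Per-year TFR with exposure, Monte-Carlo standard error and coverage.

    ``se`` is the delta-method Poisson error sqrt(sum B_a / W_a^2); ``coverage``
    is the fraction of fertile-age cells with defined rates.
    """
    fert = asfr[asfr["age"].isin(FERTILE_AGES)]
    out = []
    for y, g in fert.groupby("year"):
        d = g[g["defined"]]
        tfr = float(d["rate"].sum())
        se = float(np.sqrt((d["births"] / d["exposure"] ** 2).sum())) if len(d) else np.nan
        out.append((int(y), tfr, se, float(d["exposure"].sum()),
                    float(len(d)) / len(g) if len(g) else 0.0))
    return pd.DataFrame(out, columns=["year", "tfr", "se", "exposure", "coverage"])


# ---------------------------------------------------------------------------
# mortality


def compute_asmr(view: PopulationView, years: Sequence[int], sex: str,
                 ages: Iterable[int] = range(0, MAX_TAB_AGE + 1)) -> pd.DataFrame:
    """Single-age period ASMR: member deaths over member mid-year counts.

    Zero-death cells with positive exposure are genuine zeros; zero-exposure
    cells are undefined.
    """
    years = np.asarray(sorted(years), dtype=np.int64)
    ages = np.asarray(sorted(ages), dtype=np.int64)
    code = _sex_code(sex)
    sexes, b, d, _ = _registry_arrays(view)
    w = view.pid_weight[1:]

    died = (w > 0) & (sexes == code) & (d >= 0)
    db, dd, dw = b[died], d[died], w[died]
    death_year = np.floor_divide(dd, 12)
    death_age = np.clip((dd - db) // 12, 0, MAX_TAB_AGE)

    deaths = np.zeros((len(years), MAX_TAB_AGE + 1))
    pos = np.searchsorted(years, death_year)
    ok = (pos < len(years)) & (years[np.minimum(pos, len(years) - 1)] == death_year)
    np.add.at(deaths, (pos[ok], death_age[ok]), dw[ok])

    exposure = _exposure_grid(view, years, sex_code=code)

    rows = []
    for i, y in enumerate(years):
        for a in ages:
            e = exposure[i, a]
            n = deaths[i, a]
            rows.append((int(y), sex, int(a), n, e, n / e if e > 0 else np.nan, e > 0))
    return pd.DataFrame(rows, columns=["year", "sex", "age", "deaths", "exposure", "rate", "defined"])


def pool_window(table: pd.DataFrame, lo: int, hi: int,
                event_col: str) -> pd.DataFrame:
    """Pool a single-age rate table over calendar years [lo, hi).

    Numerators are summed and exposures summed (equivalently averaged up to
    the common factor), matching multi-year panel conventions.
    """
    sub = table[(table["year"] >= lo) & (table["year"] < hi)]
    keys = ["age"] if "sex" not in table.columns else ["sex", "age"]
    g = sub.groupby(keys, as_index=False)[[event_col, "exposure"]].sum()
    g["rate"] = np.where(g["exposure"] > 0, g[event_col] / g["exposure"], np.nan)
    g["defined"] = g["exposure"] > 0
    g.insert(0, "window", f"{lo}-{hi}")
    return g


# ---------------------------------------------------------------------------
# life table


@dataclass
class LifeTable:
    """Single-age period life table with an open interval at OPEN_AGE."""

    table: pd.DataFrame  # columns: age, mx, ax, qx, lx, Lx, Tx, ex

    @property
    def e0(self) -> float:
        return float(self.table["ex"].iloc[0])

    def ex(self, age: int) -> float:
        return float(self.table.loc[self.table["age"] == age, "ex"].iloc[0])


def _life_columns(mx: Sequence[float]):
    """Numeric life-table columns (no frame); shared by the fast e0 path."""
    m = np.asarray(mx, dtype=np.float64)
    if m.shape != (OPEN_AGE + 1,):
        raise ValueError(f"expected {OPEN_AGE + 1} single-age rates, got {m.shape}")
    if np.any(~np.isfinite(m)) or np.any(m < 0):
        raise ValueError("death rates must be finite and non-negative")

    ax = np.full(OPEN_AGE, 0.5)
    ax[0] = 0.07 + 1.7 * m[0]
    qx = m[:OPEN_AGE] / (1.0 + (1.0 - ax) * m[:OPEN_AGE])
    if np.any(qx > 1.0):
        warnings.warn("death probabilities above 1 clamped", RuntimeWarning, stacklevel=3)
        qx = np.minimum(qx, 1.0)

    lx = np.empty(OPEN_AGE + 1)
    lx[0] = RADIX
    np.cumprod(1.0 - qx, out=lx[1:])
    lx[1:] *= RADIX
    dx = lx[:OPEN_AGE] - lx[1:]
    Lx = np.empty(OPEN_AGE + 1)
    Lx[:OPEN_AGE] = lx[1:] + ax * dx
    m_open = m[OPEN_AGE] if m[OPEN_AGE] > 0 else OPEN_INTERVAL_M_FLOOR
    Lx[OPEN_AGE] = lx[OPEN_AGE] / m_open if lx[OPEN_AGE] > 0 else 0.0

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    return m, m_open, ax, qx, lx, Lx, Tx, ex


def e0_from_mx(mx: Sequence[float]) -> float:
    """Life expectancy at birth from single-age rates (fast, no table)."""
    *_, Tx, _ex = _life_columns(mx)
    return float(Tx[0] / RADIX)


def build_life_table(mx: Sequence[float]) -> LifeTable:
    """Build a period life table from single-age death rates.

    ``mx`` has OPEN_AGE + 1 entries for ages 0..OPEN_AGE, the last being the
    open-interval rate.  Conversion uses q = m / (1 + (1 - a) m) with
    a(0) = 0.07 + 1.7 m(0) (infant deaths concentrated early) and a = 0.5
    elsewhere; the open interval takes e(OPEN_AGE) = 1 / m(OPEN_AGE).
    Rates implying q > 1 are clamped with a warning.
    """
    m, m_open, ax, qx, lx, Lx, Tx, ex = _life_columns(mx)
    mx_col = np.append(m[:OPEN_AGE], m_open)
    qx_col = np.append(qx, 1.0)
    ax_col = np.append(ax, ex[OPEN_AGE])
    table = pd.DataFrame({
        "age": np.arange(OPEN_AGE + 1),
        "mx": mx_col, "ax": ax_col, "qx": qx_col,
        "lx": lx, "Lx": Lx, "Tx": Tx, "ex": ex,
    })
    return LifeTable(table)


def resolve_subset_mx(rates: np.ndarray, defined: np.ndarray) -> np.ndarray:
    """Resolve undefined single-age rates before life-table construction.

    Genealogical subsets record no deaths below some age simply because the
    members had to survive to reproduce; the subset literally contains zero
    deaths there, so undefined cells below the first observed death age
    become 0 (this is the source of the e0 overestimation, not an artifact).
    Undefined cells at older ages reflect missing exposure and carry the
    last defined rate forward.
    """
    m = np.array(rates, dtype=np.float64)
    defined = np.asarray(defined, dtype=bool)
    observed = defined & (m > 0)
    first_death = int(np.argmax(observed)) if observed.any() else len(m)
    out = np.zeros_like(m)
    last = 0.0
    for x in range(len(m)):
        if defined[x]:
            last = m[x]
            out[x] = m[x]
        else:
            out[x] = 0.0 if x < first_death else last
    return out


def e0_from_asmr(asmr: pd.DataFrame, year: int, fill: str = "subset") -> float:
    """Period e0 for one year from a single-age ASMR table of one sex.

    ``fill='subset'`` applies :func:`resolve_subset_mx`; ``fill='strict'``
    raises if any age below the open interval is undefined.
    """
    sub = asmr[asmr["year"] == year].sort_values("age")
    ages = sub["age"].to_numpy()
    if len(ages) < OPEN_AGE + 1 or ages[0] != 0:
        raise ValueError("ASMR table must cover single ages from 0")
    rates = sub["rate"].to_numpy()[: MAX_TAB_AGE + 1]
    defined = sub["defined"].to_numpy()[: MAX_TAB_AGE + 1]
    deaths = sub["deaths"].to_numpy()[: MAX_TAB_AGE + 1]
    exposure = sub["exposure"].to_numpy()[: MAX_TAB_AGE + 1]

    if fill == "strict" and not defined[:OPEN_AGE].all():
        raise ValueError(f"undefined mortality cells in {year}")
    resolved = resolve_subset_mx(np.nan_to_num(rates), defined)
    # fold ages OPEN_AGE..MAX_TAB_AGE into the open interval
    open_d = deaths[OPEN_AGE:].sum()
    open_e = exposure[OPEN_AGE:].sum()
    m = np.empty(OPEN_AGE + 1)
    m[:OPEN_AGE] = resolved[:OPEN_AGE]
    m[OPEN_AGE] = open_d / open_e if open_e > 0 else 0.0
    return build_life_table(m).e0


def e0_series(asmr: pd.DataFrame, fill: str = "subset") -> pd.DataFrame:
    """Per-year e0 with exposure/death totals for coverage decisions."""
    rows = []
    for y, g in asmr.groupby("year"):
        e0 = e0_from_asmr(asmr, int(y), fill=fill)
        rows.append((int(y), e0, float(g["exposure"].sum()), float(g["deaths"].sum())))
    return pd.DataFrame(rows, columns=["year", "e0", "exposure", "deaths"])


# ---------------------------------------------------------------------------
# bundled measures


@dataclass
class PeriodMeasures:
    """ASFR/ASMR/TFR/e0 series for one dataset (full population or subset)."""

    label: str
    replicate: int
    asfr: pd.DataFrame
    asmr: pd.DataFrame  # both sexes stacked
    tfr: pd.DataFrame
    e0: pd.DataFrame  # per sex
    meta: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format export: dataset, replicate, measure, year, sex, age, value, defined."""
        parts = []
        a = self.asfr.copy()
        a["measure"], a["sex"], a["value"] = "asfr", "f", a["rate"]
        parts.append(a[["measure", "year", "sex", "age", "value", "defined"]])
        m = self.asmr.copy()
        m["measure"], m["value"] = "asmr", m["rate"]
        parts.append(m[["measure", "year", "sex", "age", "value", "defined"]])
        t = self.tfr.copy()
        t["measure"], t["sex"], t["age"], t["value"] = "tfr", "f", np.nan, t["tfr"]
        t["defined"] = t["exposure"] > 0
        parts.append(t[["measure", "year", "sex", "age", "value", "defined"]])
        e = self.e0.copy()
        e["measure"], e["age"], e["value"] = "e0", np.nan, e["e0"]
        e["defined"] = e["exposure"] > 0
        parts.append(e[["measure", "year", "sex", "age", "value", "defined"]])
        out = pd.concat(parts, ignore_index=True)
        out.insert(0, "replicate", self.replicate)
        out.insert(0, "dataset", self.label)
        return out


def compute_measures(view: PopulationView, years: Sequence[int],
                     replicate: int = 0, sexes: Sequence[str] = ("f", "m"),
                     fill: str = "subset") -> PeriodMeasures:
    """Compute the full measure bundle for a view over calendar years."""
    asfr = compute_asfr(view, years)
    tfr = tfr_series(asfr)
    asmr_parts, e0_parts = [], []
    for s in sexes:
        t = compute_asmr(view, years, s)
        asmr_parts.append(t)
        e = e0_series(t, fill=fill)
        e.insert(1, "sex", s)
        e0_parts.append(e)
    return PeriodMeasures(
        label=view.label, replicate=replicate,
        asfr=asfr, asmr=pd.concat(asmr_parts, ignore_index=True),
        tfr=tfr, e0=pd.concat(e0_parts, ignore_index=True),
    )
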