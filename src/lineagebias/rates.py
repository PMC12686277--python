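"""Rate schedules: simulator inputs as piecewise-constant monthly hazards.

The microsimulator is parameterised entirely by a :class:`RateSchedule`:
monthly birth and death hazards by sex, single-year age band and calendar
year.  Schedules can be read from HFD/HMD-style text tables, from the native
long-format CSV, or synthesised.  The synthetic generator emulates the broad
structure of Swedish vital rates 1751-2022 — pre-industrial fertility
fluctuating above four children per woman declining below two after the
demographic transition, and life expectancy rising from the mid-30s to the
low 80s with collapsing infant mortality — so the whole pipeline runs with
no external data.

Annual quantities convert to monthly hazards as follows: ASFR and central
death rates m(x) divide by 12; death probabilities q(x) invert the
constant-hazard survival relation, -ln(1 - q)/12.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .measures import OPEN_AGE, e0_from_mx

logger = logging.getLogger(__name__)

#: monthly hazard assigned when q(x) = 1 (or above) in an input table;
#: survival through a year at this hazard is ~6e-6.
QX_ONE_CAP = 1.0

DEFAULT_MAX_AGE_YEARS = 111
DEFAULT_SEX_RATIO = 0.5122  # probability of a male birth

SEXES = ("f", "m")
EVENTS = ("birth", "death")


def to_monthly_rates(annual_value: float, kind: str, cap: float = QX_ONE_CAP) -> float:
    """Convert an annual rate or probability to a monthly hazard.

    ``kind`` is ``asfr`` or ``mx`` (divide by 12) or ``qx``
    (constant-hazard inversion -ln(1-q)/12).  q >= 1 is capped with a
    warning since it implies an infinite hazard.
    """
    if kind not in ("asfr", "mx", "qx"):
        raise ValueError(f"unknown rate kind {kind!r}")
    if annual_value < 0:
        raise ValueError(f"negative {kind} value {annual_value}")
    if kind in ("asfr", "mx"):
        return annual_value / 12.0
    if annual_value >= 1.0:
        logger.warning("qx = %s >= 1 capped at monthly hazard %s", annual_value, cap)
        return cap
    return -math.log1p(-annual_value) / 12.0


@dataclass
class RateSchedule:
    """Monthly event hazards by (year, sex, event, age band).

    ``bands`` is a long-format frame with columns
    ``year, sex, event, age_lo_months, age_hi_months, monthly_rate``.
    Within each (year, sex, event) the bands partition ``[0, max_age_months)``;
    birth rates exist for females only and are zero outside ``fertile_band``.
    Lookups outside the year range clamp to the nearest covered year, which
    is how burn-in (first year) and tail (last year) segments are served.
    """

    bands: pd.DataFrame
    fertile_band: tuple[int, int]
    max_age_months: int = DEFAULT_MAX_AGE_YEARS * 12
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        b = self.bands
        required = ["year", "sex", "event", "age_lo_months", "age_hi_months", "monthly_rate"]
        missing = [c for c in required if c not in b.columns]
        if missing:
            raise ValueError(f"bands frame missing columns {missing}")
        if len(b) == 0:
            raise ValueError("no rate rows")
        r = b["monthly_rate"].to_numpy()
        if np.any(~np.isfinite(r)) or np.any(r < 0):
            raise ValueError("monthly rates must be finite and >= 0")
        if np.any((b["event"] == "birth") & (b["sex"] != "f")):
            raise ValueError("birth rates exist for females only")
        fb = b[b["event"] == "birth"]
        lo, hi = self.fertile_band
        outside = fb[(fb["age_hi_months"] <= lo) | (fb["age_lo_months"] >= hi)]
        if np.any(outside["monthly_rate"] > 0):
            raise ValueError("nonzero birth rates outside the fertile band")
        for (year, sex, event), g in b.groupby(["year", "sex", "event"]):
            g = g.sort_values("age_lo_months")
            lo_arr = g["age_lo_months"].to_numpy()
            hi_arr = g["age_hi_months"].to_numpy()
            if lo_arr[0] != 0 or hi_arr[-1] != self.max_age_months or \
                    np.any(lo_arr[1:] != hi_arr[:-1]):
                raise ValueError(
                    f"age bands for {sex}/{event}/{year} do not partition "
                    f"[0, {self.max_age_months})")

    # -- lookup -------------------------------------------------------------

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.bands["year"].unique())

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def _clamp_year(self, year: int) -> int:
        return int(min(max(year, self.first_year), self.last_year))

    def monthly_hazard(self, year: int, sex: str, event: str) -> np.ndarray:
        """Dense per-age-month hazard array of length ``max_age_months``."""
        year = self._clamp_year(year)
        key = (year, sex, event)
        if key not in self._cache:
            g = self.bands[(self.bands["year"] == year) & (self.bands["sex"] == sex)
                           & (self.bands["event"] == event)]
            out = np.zeros(self.max_age_months)
            for lo, hi, rate in g[["age_lo_months", "age_hi_months", "monthly_rate"]].itertuples(index=False):
                out[int(lo):int(hi)] = rate
            self._cache[key] = out
        return self._cache[key]

    def lookup(self, month: int, sex: str, age_months: int, event: str) -> float:
        """Rate at one (calendar month, sex, age, event) point."""
        if not 0 <= age_months < self.max_age_months:
            raise ValueError(f"age {age_months} outside [0, {self.max_age_months})")
        return float(self.monthly_hazard(month // 12, sex, event)[age_months])

    # -- io ------------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        cols = ["year", "sex", "event", "age_lo_months", "age_hi_months", "monthly_rate"]
        out = self.bands[cols].sort_values(cols[:5]).reset_index(drop=True)
        header = f"# fertile_band={self.fertile_band[0]},{self.fertile_band[1]} max_age_months={self.max_age_months}\n"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            out.to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RateSchedule":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing schedule header line")
            parts = dict(tok.split("=") for tok in header[1:].split())
            lo, hi = (int(v) for v in parts["fertile_band"].split(","))
            max_age = int(parts["max_age_months"])
            bands = pd.read_csv(fh)
        return cls(bands=bands, fertile_band=(lo, hi), max_age_months=max_age)


def _bands_from_grid(year: int, sex: str, event: str, annual_ages: np.ndarray,
                     monthly_rates: np.ndarray, max_age_months: int) -> list[tuple]:
    """Single-year-of-age bands padded with zeros to cover [0, max_age)."""
    rows = []
    cursor = 0
    for a, r in zip(annual_ages, monthly_rates):
        lo, hi = a * 12, (a + 1) * 12
        if lo > cursor:
            rows.append((year, sex, event, cursor, lo, 0.0))
        rows.append((year, sex, event, lo, hi, float(r)))
        cursor = hi
    if cursor < max_age_months:
        rows.append((year, sex, event, cursor, max_age_months, 0.0))
    return rows


# ---------------------------------------------------------------------------
# HFD / HMD style readers


def _parse_age_label(label: str) -> int:
    """Parse an HFD/HMD age label; '12-' and '55+'/'110+' fold to the edge age."""
    s = str(label).strip()
    if s.endswith("-") or s.endswith("+"):
        s = s[:-1]
    return int(s)


def _check_year_gaps(years: np.ndarray, path) -> None:
    got = np.sort(np.unique(years))
    expected = np.arange(got[0], got[-1] + 1)
    missing = sorted(set(expected) - set(got))
    if missing:
        raise ValueError(f"{path}: missing years inside declared range: {missing}")


def read_asfr_table(path: str | Path, max_age_months: int = DEFAULT_MAX_AGE_YEARS * 12) -> RateSchedule:
    """Read an HFD ``asfrRR.txt``-style table (Year, Age, ASFR columns).

    Whitespace-delimited with a header row; age labels may carry open-ended
    markers ('12-', '55+') which are folded into the edge single-year band.
    Returns a schedule containing only the birth event; merge with a
    mortality schedule via :func:`combine_schedules`.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("year", "age", "asfr"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: no rate rows")
    if (df["asfr"].astype(str) == ".").any():
        raise ValueError(f"{path}: missing-value markers ('.') in ASFR column")
    df["asfr"] = df["asfr"].astype(float)
    if (df["asfr"] < 0).any():
        raise ValueError(f"{path}: negative fertility rates")
    df["age_years"] = df["age"].map(_parse_age_label)
    _check_year_gaps(df["year"].to_numpy(), path)

    rows = []
    lo_age = int(df["age_years"].min())
    hi_age = int(df["age_years"].max()) + 1
    for year, g in df.groupby("year"):
        g = g.sort_values("age_years")
        rows.extend(_bands_from_grid(int(year), "f", "birth",
                                     g["age_years"].to_numpy(),
                                     g["asfr"].to_numpy() / 12.0, max_age_months))
    bands = pd.DataFrame(rows, columns=["year", "sex", "event", "age_lo_months",
                                        "age_hi_months", "monthly_rate"])
    return RateSchedule(bands=bands, fertile_band=(lo_age * 12, hi_age * 12),
                        max_age_months=max_age_months)


def read_mortality_table(path: str | Path, kind: str = "mx",
                         max_age_months: int = DEFAULT_MAX_AGE_YEARS * 12,
                         allow_missing: bool = False) -> RateSchedule:
    """Read an HMD ``Mx_1x1``/``qx``-style table (Year, Age, Female, Male).

    ``kind='mx'`` treats values as central death rates (monthly hazard m/12);
    ``kind='qx'`` as annual death probabilities (-ln(1-q)/12, q = 1 capped).
    '.' markers are errors unless ``allow_missing`` fills them from the
    nearest year with data for that (sex, age).
    """
    if kind not in ("mx", "qx"):
        raise ValueError(f"unknown mortality table kind {kind!r}")
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("year", "age", "female", "male"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected column {col!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: no rate rows")
    df["age_years"] = df["age"].map(_parse_age_label)
    _check_year_gaps(df["year"].to_numpy(), path)

    for col in ("female", "male"):
        vals = df[col].astype(str).str.strip()
        miss = vals == "."
        df[col] = pd.to_numeric(vals.where(~miss), errors="raise")
        if miss.any():
            if not allow_missing:
                raise ValueError(f"{path}: missing-value markers ('.') in column {col}")
            df = df.sort_values(["age_years", "year"])
            df[col] = df.groupby("age_years")[col].transform(
                lambda s: s.ffill().bfill())
            df = df.sort_index()
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative {kind} values in column {col}")
        if kind == "qx" and (df[col] > 1).any():
            raise ValueError(f"{path}: qx values above 1 in column {col}")

    rows = []
    for year, g in df.groupby("year"):
        g = g.sort_values("age_years")
        for sex, col in (("f", "female"), ("m", "male")):
            monthly = np.array([to_monthly_rates(v, kind) for v in g[col]])
            ages = g["age_years"].to_numpy()
            # fold an open '110+' style top band into the closing band
            rows.extend(_bands_from_grid(int(year), sex, "death", ages, monthly,
                                         max_age_months))
    bands = pd.DataFrame(rows, columns=["year", "sex", "event", "age_lo_months",
                                        "age_hi_months", "monthly_rate"])
    # a pure-mortality schedule still needs a fertile band for the type; use
    # the conventional 15-50 span (no birth bands are present).
    return RateSchedule(bands=bands, fertile_band=(15 * 12, 50 * 12),
                        max_age_months=max_age_months)


def combine_schedules(fertility: RateSchedule, mortality: RateSchedule) -> RateSchedule:
    """Merge a birth-only and a death-only schedule into one."""
    if fertility.max_age_months != mortality.max_age_months:
        raise ValueError("schedules disagree on max_age_months")
    bands = pd.concat([fertility.bands[fertility.bands["event"] == "birth"],
                       mortality.bands[mortality.bands["event"] == "death"]],
                      ignore_index=True)
    return RateSchedule(bands=bands, fertile_band=fertility.fertile_band,
                        max_age_months=fertility.max_age_months)


# ---------------------------------------------------------------------------
# synthetic rate generation


@dataclass
class SyntheticRateParams:
    """Targets and shapes for the synthetic rate generator.

    ``tfr_path`` and ``e0_path`` map every simulated year to a target TFR
    and life expectancy at birth.  Fertility uses a unimodal age schedule
    (mode ``fertility_mode`` years, spread ``fertility_spread``) on the
    15-49 span renormalised exactly to the TFR target.  Mortality uses a
    Siler hazard (infant exponential decay + background + senescent
    Gompertz) blended between a high-mortality and a low-mortality regime;
    the blend is tuned per year by 1-D root finding to hit the e0 target.
    """

    year_range: tuple[int, int]
    tfr_path: Mapping[int, float]
    e0_path: Mapping[int, float]
    fertility_mode: float = 28.0
    fertility_spread: float = 6.5
    fertile_ages: tuple[int, int] = (15, 50)
    # Siler parameters (a1, b1, a2, a3, b3) for the two anchor regimes
    mortality_old: tuple[float, ...] = (0.45, 1.3, 0.015, 9e-5, 0.092)
    mortality_modern: tuple[float, ...] = (0.0015, 1.5, 1.2e-4, 8e-6, 0.107)
    sex_ratio_at_birth: float = DEFAULT_SEX_RATIO
    male_mortality_factor: float = 1.08
    e0_tolerance: float = 0.05

    def __post_init__(self) -> None:
        y0, y1 = self.year_range
        for y in range(y0, y1 + 1):
            if y not in self.tfr_path or y not in self.e0_path:
                raise ValueError(f"tfr_path/e0_path undefined for year {y}")
            if self.tfr_path[y] <= 0:
                raise ValueError(f"tfr_path must be positive (year {y})")
            if not 0 < self.e0_path[y] < DEFAULT_MAX_AGE_YEARS:
                raise ValueError(f"e0_path out of range (year {y})")


def _siler_hazard(ages: np.ndarray, p: Sequence[float]) -> np.ndarray:
    a1, b1, a2, a3, b3 = p
    return a1 * np.exp(-b1 * ages) + a2 + a3 * np.exp(b3 * ages)


def _blend_siler(theta: float, old: Sequence[float], modern: Sequence[float]) -> np.ndarray:
    old, modern = np.asarray(old), np.asarray(modern)
    out = old.copy()
    for i in (0, 2, 3):  # level parameters blend on the log scale
        out[i] = math.exp((1 - theta) * math.log(old[i]) + theta * math.log(modern[i]))
    for i in (1, 4):
        out[i] = (1 - theta) * old[i] + theta * modern[i]
    return out


def _siler_mx(theta: float, params: SyntheticRateParams) -> np.ndarray:
    """Annual m(x) for ages 0..OPEN_AGE at blend theta (midpoint-of-age evaluation)."""
    ages = np.arange(OPEN_AGE + 1) + 0.5
    p = _blend_siler(theta, params.mortality_old, params.mortality_modern)
    mx = _siler_hazard(ages, p)
    # infant year: integrate the rapidly-decaying component over age 0-1
    a1, b1, a2, a3, b3 = p
    mx[0] = a1 * (1 - math.exp(-b1)) / b1 + a2 + a3 * (math.exp(b3) - 1) / b3
    return mx


def _e0_of_theta(theta: float, params: SyntheticRateParams) -> float:
    return e0_from_mx(_siler_mx(theta, params))


def _solve_theta(target_e0: float, params: SyntheticRateParams) -> float:
    lo, hi = _e0_of_theta(0.0, params), _e0_of_theta(1.0, params)
    if not lo - 0.25 <= target_e0 <= hi + 0.25:
        raise ValueError(
            f"e0 target {target_e0:.2f} unattainable for mortality shape "
            f"(range {lo:.2f}..{hi:.2f})")
    if target_e0 <= lo:
        return 0.0
    if target_e0 >= hi:
        return 1.0
    return float(brentq(lambda t: _e0_of_theta(t, params) - target_e0, 0.0, 1.0,
                        xtol=1e-4))


def _fertility_weights(params: SyntheticRateParams) -> np.ndarray:
    lo, hi = params.fertile_ages
    ages = np.arange(lo, hi) + 0.5
    w = np.exp(-0.5 * ((ages - params.fertility_mode) / params.fertility_spread) ** 2)
    return w / w.sum()


def synth_rates(params: SyntheticRateParams, seed: int = 0,
                max_age_months: int = DEFAULT_MAX_AGE_YEARS * 12) -> RateSchedule:
    """Generate a rate schedule meeting the yearly TFR and e0 targets.

    Deterministic given (params, seed); the seed only matters for presets
    whose target paths were themselves drawn with it (see
    :func:`sweden_like_params`).  Every year's annual ASFR sums exactly to
    the TFR target (renormalised), and the period life table of the
    generated mortality matches the e0 target to ``params.e0_tolerance``.
    """
    y0, y1 = params.year_range
    lo, hi = params.fertile_ages
    fw = _fertility_weights(params)
    rows = []
    theta_cache: dict[float, float] = {}
    for year in range(y0, y1 + 1):
        tfr = params.tfr_path[year]
        asfr = tfr * fw
        rows.extend(_bands_from_grid(year, "f", "birth", np.arange(lo, hi),
                                     asfr / 12.0, max_age_months))
        e0t = round(float(params.e0_path[year]), 3)
        if e0t not in theta_cache:
            theta_cache[e0t] = _solve_theta(e0t, params)
        mx = _siler_mx(theta_cache[e0t], params)
        # extend beyond the open age with the Gompertz tail, closing the
        # oldest band so nobody outlives max_age
        ages_full = np.arange(max_age_months // 12)
        p = _blend_siler(theta_cache[e0t], params.mortality_old, params.mortality_modern)
        mx_full = _siler_hazard(ages_full + 0.5, p)
        mx_full[: OPEN_AGE + 1] = mx
        for sex, factor in (("f", 1.0), ("m", params.male_mortality_factor)):
            rows.extend(_bands_from_grid(year, sex, "death", ages_full,
                                         factor * mx_full / 12.0, max_age_months))
    bands = pd.DataFrame(rows, columns=["year", "sex", "event", "age_lo_months",
                                        "age_hi_months", "monthly_rate"])
    return RateSchedule(bands=bands, fertile_band=(lo * 12, hi * 12),
                        max_age_months=max_age_months)


def sweden_like_params(year_start: int = 1751, year_end: int = 2022,
                       seed: int = 0) -> SyntheticRateParams:
    """Target paths emulating Swedish vital trends 1751-2022.

    TFR fluctuates above four children per woman before 1900, declines
    through the demographic transition to below two, and hovers near
    replacement afterwards; e0 follows a logistic rise from ~35 to ~82
    years.  Fluctuations are drawn once from ``seed`` so the preset is
    reproducible.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(year_start, year_end + 1)
    tfr_path, e0_path = {}, {}
    wobble = rng.normal(0.0, 0.05, size=len(years))
    for i, y in enumerate(years):
        if y < 1900:
            base = 4.35 + 0.22 * math.sin(2 * math.pi * (y - year_start) / 34.0)
        elif y < 1935:
            # demographic transition: linear decline to 1.8 by 1935
            base = 4.2 + (1.8 - 4.2) * (y - 1900) / (1935 - 1900)
        else:
            base = 1.85 + 0.15 * math.sin(2 * math.pi * (y - 1935) / 40.0)
        tfr = base + wobble[i]
        if y < 1900:
            tfr = max(tfr, 4.05)  # the pre-transition regime stays above four
        tfr_path[int(y)] = float(max(tfr, 1.5))
        e0_path[int(y)] = float(35.0 + 48.0 / (1.0 + math.exp(-(y - 1920) / 28.0)))
    return SyntheticRateParams(year_range=(year_start, year_end),
                               tfr_path=tfr_path, e0_path=e0_path)


def constant_params(year_start: int, year_end: int, tfr: float, e0: float) -> SyntheticRateParams:
    """A constant-rate regime: every year gets the same TFR and e0 target."""
    years = range(year_start, year_end + 1)
    return SyntheticRateParams(year_range=(year_start, year_end),
                               tfr_path={y: tfr for y in years},
                               e0_path={y: e0 for y in years})
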