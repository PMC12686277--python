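"""Discrete-event demographic microsimulation under competing risks.

Every living individual always carries exactly one scheduled event.  For
each risk the individual is exposed to (death for everyone, birth for
females of fertile age), a random waiting time is drawn from the
piecewise-exponential distribution implied by the monthly age-specific
hazards; the shortest waiting time wins and is scheduled.  All events due
in a month execute in random order, then the month counter advances.  When
the calendar year changes the rate segment changes, and every living
individual is rescheduled under the new rates — which is exactly right for
piecewise-constant hazards because the waiting-time distribution is
memoryless within a segment.

Partnerships form at a previously single woman's first birth: a living
never-married man is chosen so that the observed husband-wife age-gap
distribution tracks a Normal(mean 2, sd 3) target.  The simulation
produces a fully-recorded registry of everyone who ever lived, with parent,
spouse and vital-event links.

Time is a global month counter with month ``0`` = January of calendar year
0, so ``year = month // 12``; ages are completed months.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .rates import RateSchedule

logger = logging.getLogger(__name__)

FEMALE, MALE = 0, 1
SINGLE, MARRIED, WIDOWED = 0, 1, 2
EV_NONE, EV_DEATH, EV_BIRTH = 0, 1, 2
OPEN = -1  # death_month sentinel: still alive at end of simulation
NO_PID = 0
_FAR = np.int64(2**40)  # "never" month sentinel
_LB_NONE = -(2**40)  # "never gave birth" sentinel

GAP_BIN_LO, GAP_BIN_HI = -30, 30  # husband-minus-wife age gap bins, years

SEX_LABEL = {FEMALE: "f", MALE: "m"}
SEX_CODE = {"f": FEMALE, "m": MALE}


class ExtinctionError(RuntimeError):
    """The whole simulated population died out before the end."""

    def __init__(self, month: int):
        super().__init__(f"population extinct at month {month} (year {month // 12})")
        self.month = month


@dataclass
class SimConfig:
    """Simulation design: initial cohort, period layout, matching targets."""

    n_initial: int = 1000
    start_year: int = 1751
    end_year: int = 2022
    burn_in_years: int = 100  # at the first year's rates
    tail_years: int = 50  # at the last year's rates
    seed: int = 0
    match_mean: float = 2.0  # target husband-minus-wife age gap, years
    match_sd: float = 3.0
    min_birth_interval_months: int = 9
    min_groom_age_years: int = 15
    sex_ratio_at_birth: float = 0.5122  # P(male)
    initial_max_age_years: int = 50

    def __post_init__(self) -> None:
        if self.n_initial <= 0:
            raise ValueError("n_initial must be positive")
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")
        if not 0.0 < self.sex_ratio_at_birth < 1.0:
            raise ValueError("sex_ratio_at_birth must be in (0, 1)")

    @property
    def first_month(self) -> int:
        return (self.start_year - self.burn_in_years) * 12

    @property
    def last_month(self) -> int:
        """Last simulated month (inclusive)."""
        return (self.end_year + self.tail_years + 1) * 12 - 1

    @property
    def reference_month(self) -> int:
        """End of the final main-period year (December), when genealogists live."""
        return (self.end_year + 1) * 12 - 1


def draw_waiting_time(rng: np.random.Generator, hazard_path: Sequence[float]) -> float:
    """Waiting time (months, continuous) under piecewise-constant monthly hazards.

    ``hazard_path[k]`` applies during the k-th month from now.  Sampling is
    by inverse CDF over the accumulated hazard; if the total accumulated
    hazard is finite and the exponential draw exceeds it, ``math.inf`` is
    returned (the no-event marker).
    """
    h = np.asarray(hazard_path, dtype=np.float64)
    if np.any(h < 0) or np.any(~np.isfinite(h)):
        raise ValueError("hazards must be finite and non-negative")
    e = rng.exponential()
    cum = np.concatenate([[0.0], np.cumsum(h)])
    if e >= cum[-1]:
        return math.inf
    k = int(np.searchsorted(cum, e, side="right")) - 1
    return k + (e - cum[k]) / h[k]


@dataclass
class PopulationRegistry:
    """Fully-recorded synthetic population.

    Parallel arrays indexed by ``pid - 1``; pid 0 means "none".  Dead
    individuals have a closed ``death_month``; survivors carry ``OPEN``.
    """

    sex: np.ndarray
    birth_month: np.ndarray
    death_month: np.ndarray
    mother_pid: np.ndarray
    father_pid: np.ndarray
    spouse_pid: np.ndarray
    marriages: pd.DataFrame  # wife_pid, husband_pid, month
    span: tuple[int, int]  # first and last simulated month (inclusive)
    meta: dict = field(default_factory=dict)
    _children: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- basics ---------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.birth_month)

    @property
    def pids(self) -> np.ndarray:
        return np.arange(1, self.n + 1, dtype=np.int64)

    @property
    def token(self) -> str:
        """Cheap fingerprint used to refuse cross-registry operations."""
        h = hashlib.sha256()
        for a in (self.sex, self.birth_month, self.death_month, self.mother_pid):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:16]

    def validate(self) -> None:
        n = self.n
        for name in ("sex", "death_month", "mother_pid", "father_pid", "spouse_pid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name} length mismatch")
        for name in ("mother_pid", "father_pid", "spouse_pid"):
            links = getattr(self, name)
            if links.min(initial=0) < 0 or links.max(initial=0) > n:
                raise ValueError(f"{name} contains pids outside the registry")
        closed = self.death_month >= 0
        if np.any(self.death_month[closed] < self.birth_month[closed]):
            raise ValueError("death before birth")

    def alive_at(self, month: int) -> np.ndarray:
        return (self.birth_month <= month) & (
            (self.death_month == OPEN) | (self.death_month > month))

    def age_months(self, pids: np.ndarray, month: int) -> np.ndarray:
        return month - self.birth_month[np.asarray(pids) - 1]

    # -- children index --------------------------------------------------------

    def _children_csr(self):
        if self._children is None:
            parents = np.concatenate([self.mother_pid, self.father_pid])
            kids = np.tile(np.arange(1, self.n + 1, dtype=np.int64), 2)
            keep = parents > 0
            parents, kids = parents[keep], kids[keep]
            order = np.argsort(parents, kind="stable")
            parents, kids = parents[order], kids[order]
            counts = np.bincount(parents, minlength=self.n + 1)
            offsets = np.concatenate([[0], np.cumsum(counts)])
            self._children = (offsets, kids)
        return self._children

    def children_of(self, pid: int) -> np.ndarray:
        """Child pids of one parent (as mother or father)."""
        offsets, kids = self._children_csr()
        return kids[offsets[pid]:offsets[pid + 1]]

    def child_counts(self) -> np.ndarray:
        """Number of children ever born per pid (index 0 unused)."""
        offsets, _ = self._children_csr()
        return np.diff(offsets)

    # -- io ---------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pid": self.pids,
            "sex": np.where(self.sex == FEMALE, "f", "m"),
            "birth_month": self.birth_month,
            "death_month": self.death_month,
            "mother_pid": self.mother_pid,
            "father_pid": self.father_pid,
            "spouse_pid": self.spouse_pid,
        })

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        for col in ("mother_pid", "father_pid", "spouse_pid"):
            df[col] = df[col].astype("object")
            df.loc[df[col] == NO_PID, col] = ""
        df["death_month"] = df["death_month"].astype("object")
        df.loc[df["death_month"] == OPEN, "death_month"] = ""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# span={self.span[0]},{self.span[1]}\n")
            df.to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path,
                 marriages: pd.DataFrame | None = None) -> "PopulationRegistry":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("# span="):
                raise ValueError(f"{path}: not a population registry file (bad header)")
            lo, hi = (int(v) for v in header.strip().split("=", 1)[1].split(","))
            df = pd.read_csv(fh)
        expected = ["pid", "sex", "birth_month", "death_month",
                    "mother_pid", "father_pid", "spouse_pid"]
        if list(df.columns) != expected:
            raise ValueError(f"{path}: unexpected registry columns {list(df.columns)}")
        if not np.array_equal(df["pid"].to_numpy(), np.arange(1, len(df) + 1)):
            raise ValueError(f"{path}: pids must be 1..n in order")
        def _ints(col, sentinel):
            return df[col].fillna(sentinel).astype(np.int64).to_numpy()
        if marriages is None:
            marriages = pd.DataFrame(columns=["wife_pid", "husband_pid", "month"])
        return cls(
            sex=np.where(df["sex"].to_numpy() == "f", FEMALE, MALE).astype(np.int8),
            birth_month=df["birth_month"].astype(np.int64).to_numpy(),
            death_month=_ints("death_month", OPEN),
            mother_pid=_ints("mother_pid", NO_PID),
            father_pid=_ints("father_pid", NO_PID),
            spouse_pid=_ints("spouse_pid", NO_PID),
            marriages=marriages, span=(lo, hi))


# ---------------------------------------------------------------------------
# the simulation engine


class Simulation:
    """One replicate: growable state arrays plus the event loop."""

    def __init__(self, config: SimConfig, rates: RateSchedule):
        self.config = config
        self.rates = rates
        self.L = rates.max_age_months
        ss = np.random.SeedSequence(config.seed)
        sched_ss, sex_ss, shuffle_ss, init_ss = ss.spawn(4)
        self.rng_sched = np.random.default_rng(sched_ss)
        self.rng_sex = np.random.default_rng(sex_ss)
        self.rng_shuffle = np.random.default_rng(shuffle_ss)
        self.rng_init = np.random.default_rng(init_ss)

        cap = max(config.n_initial * 4, 1024)
        self._alloc(cap)
        self.n = 0
        self.marriages: list[tuple[int, int, int]] = []
        self._gap_bins = np.arange(GAP_BIN_LO, GAP_BIN_HI + 1)
        edges = np.concatenate([[-np.inf], self._gap_bins[:-1] + 0.5, [np.inf]])
        target = norm(config.match_mean, config.match_sd)
        self._gap_target = np.diff(target.cdf(edges))
        self._gap_counts = np.zeros(len(self._gap_bins), dtype=np.int64)
        self._n_marr = 0
        self._init_population()

    # -- storage ---------------------------------------------------------------

    def _alloc(self, cap: int) -> None:
        self.sex = np.zeros(cap, dtype=np.int8)
        self.birth = np.zeros(cap, dtype=np.int64)
        self.death = np.full(cap, OPEN, dtype=np.int64)
        self.mother = np.zeros(cap, dtype=np.int64)
        self.father = np.zeros(cap, dtype=np.int64)
        self.spouse = np.zeros(cap, dtype=np.int64)
        self.marital = np.zeros(cap, dtype=np.int8)
        self.last_birth = np.full(cap, _LB_NONE, dtype=np.int64)
        self.alive = np.zeros(cap, dtype=bool)
        self.sched_event = np.zeros(cap, dtype=np.int8)
        self.sched_month = np.full(cap, _FAR, dtype=np.int64)

    def _grow(self) -> None:
        old = dict(self.__dict__)
        cap = len(self.sex) * 2
        arrays = ("sex", "birth", "death", "mother", "father", "spouse",
                  "marital", "last_birth", "alive", "sched_event", "sched_month")
        self._alloc(cap)
        for name in arrays:
            getattr(self, name)[: self.n] = old[name][: self.n]

    def _append(self, sex: int, birth: int, mother: int, father: int) -> int:
        if self.n == len(self.sex):
            self._grow()
        i = self.n
        self.n += 1
        self.sex[i] = sex
        self.birth[i] = birth
        self.death[i] = OPEN
        self.mother[i] = mother
        self.father[i] = father
        self.spouse[i] = NO_PID
        self.marital[i] = SINGLE
        self.last_birth[i] = _LB_NONE
        self.alive[i] = True
        return i

    def _init_population(self) -> None:
        cfg = self.config
        m0 = cfg.first_month
        sexes = (self.rng_init.random(cfg.n_initial) < cfg.sex_ratio_at_birth)
        ages = self.rng_init.integers(0, cfg.initial_max_age_years * 12,
                                      size=cfg.n_initial)
        for k in range(cfg.n_initial):
            self._append(MALE if sexes[k] else FEMALE, m0 - int(ages[k]),
                         NO_PID, NO_PID)

    # -- scheduling --------------------------------------------------------------

    def _segment(self, year: int) -> None:
        """Install cumulative monthly hazards for one rate segment (year)."""
        L = self.L
        self._S_death = {}
        for s in (FEMALE, MALE):
            h = self.rates.monthly_hazard(year, SEX_LABEL[s], "death")
            self._S_death[s] = np.concatenate([[0.0], np.cumsum(h)])
        hb = self.rates.monthly_hazard(year, "f", "birth")
        self._S_birth = np.concatenate([[0.0], np.cumsum(hb)])

    def schedule(self, idx: np.ndarray, month: int, *, from_current_month: bool,
                 min_month: int) -> None:
        """(Re)draw competing waiting times and schedule the winning event.

        ``from_current_month`` includes the hazard of the month the
        individual is currently living through (used at segment starts and
        for newborns); post-event rescheduling starts with the next month.
        Waiting times for each risk are independent; the minimum wins and
        equal waiting times resolve to death.
        """
        idx = np.asarray(idx, dtype=np.int64)
        if len(idx) == 0:
            return
        L = self.L
        ages = month - self.birth[idx]
        start = np.clip(ages + (0 if from_current_month else 1), 0, L)

        ev_month = np.empty(len(idx), dtype=np.int64)
        ev_kind = np.full(len(idx), EV_DEATH, dtype=np.int8)

        for s in (FEMALE, MALE):
            sel = np.nonzero(self.sex[idx] == s)[0]
            if len(sel) == 0:
                continue
            S = self._S_death[s]
            st = start[sel]
            e = self.rng_sched.exponential(size=len(sel))
            pos = np.searchsorted(S, S[st] + e, side="left")
            x = np.minimum(pos - 1, L)  # death forced at the oldest-band closure
            ev_month[sel] = self.birth[idx[sel]] + x

            if s == FEMALE:
                # birth waiting times accumulate hazard from the current age
                # but are shifted past the minimum birth interval, so the
                # interval delays births without suppressing them
                Sb = self._S_birth
                lb_age = self.last_birth[idx[sel]] - self.birth[idx[sel]]
                # within the lockout the pending (clamped) birth has not yet
                # happened, so a redraw restarts accrual at the month after
                # the last birth; this keeps the event-month distribution
                # invariant under segment rescheduling
                stb = np.where(st <= lb_age + self.config.min_birth_interval_months,
                               np.minimum(lb_age + 1, st), st)
                stb = np.clip(stb, 0, L)
                eb = self.rng_sched.exponential(size=len(sel))
                posb = np.searchsorted(Sb, Sb[stb] + eb, side="left")
                has_birth = posb <= L
                xb = np.maximum(posb - 1,
                                lb_age + self.config.min_birth_interval_months)
                bm = np.where(has_birth, self.birth[idx[sel]] + xb, _FAR)
                birth_wins = bm < ev_month[sel]  # ties go to death
                ev_kind[sel] = np.where(birth_wins, EV_BIRTH, EV_DEATH)
                ev_month[sel] = np.minimum(ev_month[sel], bm)

        self.sched_event[idx] = ev_kind
        self.sched_month[idx] = np.maximum(ev_month, min_month)

    def schedule_next_event(self, i: int, month: int,
                            newborn: bool = False) -> None:
        """Reschedule one individual after an executed event or status change."""
        self.schedule(np.array([i]), month, from_current_month=newborn,
                      min_month=month + 1)

    # -- partner matching ---------------------------------------------------------

    def match_partner(self, mother_i: int, month: int) -> int | None:
        """Pick a husband among living never-married men past the minimum age.

        The chosen candidate minimises the squared difference between the
        observed husband-wife age-gap histogram (including the new couple)
        and the Normal(2, 3) target mass; score ties break to the smallest
        pid.  Returns the husband's index, or None if no man is eligible.
        """
        cfg = self.config
        n = self.n
        cand = np.nonzero(self.alive[:n] & (self.sex[:n] == MALE)
                          & (self.marital[:n] == SINGLE)
                          & (month - self.birth[:n] >= cfg.min_groom_age_years * 12)
                          )[0]
        if len(cand) == 0:
            return None
        gap_years = (self.birth[mother_i] - self.birth[cand]) / 12.0
        bins = np.clip(np.rint(gap_years).astype(np.int64),
                       GAP_BIN_LO, GAP_BIN_HI) - GAP_BIN_LO
        # adding one couple to bin b changes the squared-difference score by
        # (c_b + 1 - p_b (n+1))^2 - (c_b - p_b (n+1))^2, up to the common 1/(n+1)^2
        delta = 2.0 * self._gap_counts[bins] + 1.0 \
            - 2.0 * self._gap_target[bins] * (self._n_marr + 1)
        best = cand[int(np.argmin(delta))]  # argmin returns the smallest index on ties
        self._gap_counts[bins[int(np.argmin(delta))]] += 1
        self._n_marr += 1
        return int(best)

    # -- event execution -----------------------------------------------------------

    def _die(self, i: int, month: int) -> None:
        self.death[i] = month
        self.alive[i] = False
        self.sched_event[i] = EV_NONE
        self.sched_month[i] = _FAR
        s = self.spouse[i]
        if s != NO_PID and self.alive[s - 1]:
            self.marital[s - 1] = WIDOWED
            self.schedule_next_event(s - 1, month)

    def _give_birth(self, i: int, month: int) -> None:
        cfg = self.config
        sex = MALE if self.rng_sex.random() < cfg.sex_ratio_at_birth else FEMALE
        father = NO_PID
        if self.marital[i] == MARRIED:
            father = int(self.spouse[i])
        elif self.marital[i] == WIDOWED:
            s = int(self.spouse[i])
            # the late husband is the father only if alive at conception
            if s != NO_PID and self.death[s - 1] >= month - 9:
                father = s
        else:  # single mother: lifelong partnership forms at first birth
            h = self.match_partner(i, month)
            if h is not None:
                self.spouse[i] = h + 1
                self.spouse[h] = i + 1
                self.marital[i] = MARRIED
                self.marital[h] = MARRIED
                self.marriages.append((i + 1, h + 1, month))
                father = h + 1
                self.schedule_next_event(h, month)  # status change
        child = self._append(sex, month, i + 1, father)
        self.last_birth[i] = month
        self.schedule_next_event(i, month)
        self.schedule_next_event(child, month, newborn=True)

    def execute_month(self, month: int) -> tuple[int, int]:
        """Run all events due this month in random order; returns (births, deaths)."""
        n = self.n
        due = np.nonzero(self.alive[:n] & (self.sched_month[:n] == month))[0]
        births = deaths = 0
        if len(due):
            due = due[self.rng_shuffle.permutation(len(due))]
        for i in due:
            if not self.alive[i] or self.sched_month[i] != month:
                continue  # rescheduled by an earlier event this month
            ev = self.sched_event[i]
            if ev == EV_DEATH:
                self._die(int(i), month)
                deaths += 1
            elif ev == EV_BIRTH:
                self._give_birth(int(i), month)
                births += 1
            else:
                raise RuntimeError(f"living individual {i + 1} due with no event")
        return births, deaths

    # -- main loop -------------------------------------------------------------------

    def run(self) -> PopulationRegistry:
        cfg = self.config
        first, last = cfg.first_month, cfg.last_month
        for year in range(first // 12, last // 12 + 1):
            self._segment(year)
            m_start = max(year * 12, first)
            alive_idx = np.nonzero(self.alive[: self.n])[0]
            if len(alive_idx) == 0:
                raise ExtinctionError(m_start)
            self.schedule(alive_idx, m_start, from_current_month=True,
                          min_month=m_start)
            for month in range(m_start, min((year + 1) * 12, last + 1)):
                self.execute_month(month)
                if not self.alive[: self.n].any():
                    raise ExtinctionError(month)
        return self._registry()

    def _registry(self) -> PopulationRegistry:
        n = self.n
        cfg = self.config
        marriages = pd.DataFrame(self.marriages,
                                 columns=["wife_pid", "husband_pid", "month"])
        return PopulationRegistry(
            sex=self.sex[:n].copy(),
            birth_month=self.birth[:n].copy(),
            death_month=self.death[:n].copy(),
            mother_pid=self.mother[:n].copy(),
            father_pid=self.father[:n].copy(),
            spouse_pid=self.spouse[:n].copy(),
            marriages=marriages,
            span=(cfg.first_month, cfg.last_month),
            meta={"config": asdict(cfg)},
        )


def run_simulation(config: SimConfig, rates: RateSchedule) -> PopulationRegistry:
    """Simulate one replicate: burn-in, main period, tail.

    Burn-in years run at the first rate year, the main period at
    year-specific rates, and the tail at the final year's rates (rate
    lookups clamp to the schedule's range).  Deterministic given
    (config, rates, seed); raises :class:`ExtinctionError` if everyone dies.
    """
    return Simulation(config, rates).run()
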